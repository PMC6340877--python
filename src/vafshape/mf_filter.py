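"""Filter chain producing per-sample purity-adjusted VAF vectors.

The analysis restricts each tumor to its "more functional" (MF) point
mutations in copy-neutral regions and with adequate sequencing depth:

1. depth filter      — keep mutations with ref + alt reads >= 20,
2. functional filter — keep mutations PolyPhen-2-classified as probably
   or possibly damaging (anything else, including unannotated, is non-MF),
3. copy-neutral filter — keep mutations lying inside a same-sample
   segment with |log2 ratio| <= 0.2 supported by >= 10 probes; mutations
   in altered segments, under-supported segments, or covered by no
   segment at all are excluded,
4. VAF computation — raw VAF = alt / (alt + ref), then divided by tumor
   purity and capped at 1.

Samples retaining fewer than two MF mutations cannot yield distribution
shape parameters and are excluded, with the reason reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ClinicalRecord,
    CNVSegment,
    MutationRecord,
    MF_CLASSES,
    group_by_sample,
)

__all__ = [
    "FilteredVAFSet",
    "FilterChainResult",
    "filter_depth",
    "filter_mf",
    "filter_copy_neutral",
    "compute_adjusted_vafs",
    "run_filter_chain",
]


@dataclass
class FilteredVAFSet:
    """Purity-adjusted VAFs of one sample's MF mutations, with the
    per-stage counts of the filter chain that produced them."""

    sample_id: str
    vafs: np.ndarray
    n_input: int
    n_after_depth: int
    n_after_mf: int
    n_after_cnv: int
    n_capped: int = 0
    purity: float = 1.0
    mutations: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.vafs = np.asarray(self.vafs, dtype=float)
        if self.vafs.size and (self.vafs.min() < 0 or self.vafs.max() > 1):
            raise ValueError("adjusted VAFs must lie in [0, 1]")
        counts = (self.n_input, self.n_after_depth, self.n_after_mf, self.n_after_cnv)
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError("filter-stage counts must be non-increasing")

    def __len__(self) -> int:
        return self.vafs.size


def filter_depth(
    muts: Sequence[MutationRecord], min_depth: int = 20
) -> list[MutationRecord]:
    """Keep mutations whose total read depth (ref + alt) is >= ``min_depth``."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    return [m for m in muts if m.depth >= min_depth]


def filter_mf(muts: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Keep the MF mutations: PolyPhen-2 probably/possibly damaging."""
    return [m for m in muts if m.polyphen_class in MF_CLASSES]


def filter_copy_neutral(
    muts: Sequence[MutationRecord],
    segs: Sequence[CNVSegment],
    mean_lo: float = -0.2,
    mean_hi: float = 0.2,
    min_probes: int = 10,
) -> list[MutationRecord]:
    """Keep mutations covered by at least one qualifying copy-neutral segment.

    A segment qualifies when it belongs to the mutation's sample, has
    ``mean_lo <= segment_mean <= mean_hi`` and ``num_probes >= min_probes``.
    A mutation covered by no segment is dropped: unknown copy status is
    not treated as copy-neutral.
    """
    neutral = [
        s
        for s in segs
        if mean_lo <= s.segment_mean <= mean_hi and s.num_probes >= min_probes
    ]
    by_sample_chrom: dict[tuple[str, str], list[CNVSegment]] = {}
    for s in neutral:
        by_sample_chrom.setdefault((s.sample_id, s.chrom), []).append(s)
    kept = []
    for m in muts:
        for s in by_sample_chrom.get((m.sample_id, m.chrom), ()):
            if s.start <= m.pos <= s.end:
                kept.append(m)
                break
    return kept


def compute_adjusted_vafs(
    muts: Sequence[MutationRecord],
    purity: float,
    cap: bool = True,
) -> tuple[np.ndarray, int, list[MutationRecord]]:
    """Compute purity-adjusted VAFs, in input order.

    raw VAF = alt / (alt + ref); adjusted = raw / purity, capped at 1
    unless ``cap`` is off.  Records with zero total reads cannot yield a
    VAF and are rejected (returned separately, not silently dropped).

    Returns ``(vafs, n_capped, rejected_records)``.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must lie in (0, 1], got {purity}")
    vafs, rejected = [], []
    n_capped = 0
    for m in muts:
        total = m.depth
        if total == 0:
            rejected.append(m)
            continue
        adjusted = (m.alt_count / total) / purity
        if adjusted > 1.0:
            if cap:
                adjusted = 1.0
            n_capped += 1
        vafs.append(adjusted)
    return np.asarray(vafs, dtype=float), n_capped, rejected


class FilterChainResult(NamedTuple):
    """Output of :func:`run_filter_chain`.

    ``vafsets`` holds samples that survived the chain with >= ``min_mutations``
    MF mutations; ``excluded`` maps sample_id -> reason for the rest;
    ``report`` tabulates per-stage counts for every sample seen.
    """

    vafsets: dict[str, FilteredVAFSet]
    excluded: dict[str, str]
    report: pd.DataFrame


def run_filter_chain(
    muts: Sequence[MutationRecord],
    segs: Sequence[CNVSegment],
    clinical: Sequence[ClinicalRecord],
    min_depth: int = 20,
    mean_lo: float = -0.2,
    mean_hi: float = 0.2,
    min_probes: int = 10,
    min_mutations: int = 2,
    cap: bool = True,
    missing_purity: str = "drop",
) -> FilterChainResult:
    """Run depth -> MF -> copy-neutral -> VAF on every sample.

    Samples present in the mutation table but absent from the clinical
    table are excluded (reason ``no_clinical``) — without a purity
    estimate the VAFs cannot be adjusted, unless ``missing_purity`` is
    set to ``"assume_pure"`` in which case purity 1 is used.
    """
    if missing_purity not in ("drop", "assume_pure"):
        raise ValueError("missing_purity must be 'drop' or 'assume_pure'")
    purity_by_sample = {c.sample_id: c.purity for c in clinical}
    muts_by_sample = group_by_sample(muts)
    segs_by_sample = group_by_sample(segs)

    vafsets: dict[str, FilteredVAFSet] = {}
    excluded: dict[str, str] = {}
    rows = []
    for sample_id in sorted(muts_by_sample):
        sample_muts = muts_by_sample[sample_id]
        n_input = len(sample_muts)
        if sample_id not in purity_by_sample and missing_purity == "drop":
            excluded[sample_id] = "no_clinical"
            rows.append((sample_id, n_input, None, None, None, None, "no_clinical"))
            continue
        purity = purity_by_sample.get(sample_id, 1.0)

        after_depth = filter_depth(sample_muts, min_depth)
        after_mf = filter_mf(after_depth)
        after_cnv = filter_copy_neutral(
            after_mf,
            segs_by_sample.get(sample_id, []),
            mean_lo=mean_lo,
            mean_hi=mean_hi,
            min_probes=min_probes,
        )
        vafs, n_capped, rejected = compute_adjusted_vafs(after_cnv, purity, cap=cap)
        rejected_ids = set(map(id, rejected))
        surviving = [m for m in after_cnv if id(m) not in rejected_ids]
        if len(vafs) < min_mutations:
            excluded[sample_id] = "too_few_mf_mutations"
            rows.append(
                (sample_id, n_input, len(after_depth), len(after_mf), len(after_cnv),
                 n_capped, "too_few_mf_mutations")
            )
            continue
        vafsets[sample_id] = FilteredVAFSet(
            sample_id=sample_id,
            vafs=vafs,
            n_input=n_input,
            n_after_depth=len(after_depth),
            n_after_mf=len(after_mf),
            n_after_cnv=len(after_cnv),
            n_capped=n_capped,
            purity=purity,
            mutations=surviving,
        )
        rows.append(
            (sample_id, n_input, len(after_depth), len(after_mf), len(after_cnv),
             n_capped, "")
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "n_input", "n_after_depth", "n_after_mf",
            "n_after_cnv", "n_capped", "exclusion_reason",
        ],
    )
    return FilterChainResult(vafsets, excluded, report)
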