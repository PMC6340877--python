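"""Tabular input/output for somatic mutation, copy-number and clinical data.

Three tables drive the pipeline, all plain tab-separated text:

* a MAF-like somatic point-mutation table (one row per mutation, with
  tumor read counts and a PolyPhen-2 functional class),
* a SEG-like copy-number segmentation table (one row per segment, with
  probe count and log2 copy-ratio segment mean),
* a clinical table keyed by sample, carrying tumor purity, overall
  survival and optional covariates.

Column names are mapped through a *dialect* (a ``{field: column}`` dict) so
that GDC MAF exports and locally generated tables load through the same
reader.  Coordinates are 1-based and inclusive throughout, following
MAF/SEG conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "MutationRecord",
    "CNVSegment",
    "ClinicalRecord",
    "ReadResult",
    "DEFAULT_MUTATION_DIALECT",
    "SIMPLE_MUTATION_DIALECT",
    "MF_CLASSES",
    "POLYPHEN_CLASSES",
    "read_mutations",
    "read_segments",
    "read_clinical",
    "write_mutations",
    "write_segments",
    "write_clinical",
]


class FormatError(ValueError):
    """Raised when an input table violates the expected format."""


BASES = frozenset("ACGT")

#: PolyPhen-2 functional classes recognised on input.  Anything else
#: (including missing annotation) is normalised to ``unknown``.
POLYPHEN_CLASSES = ("probably_damaging", "possibly_damaging", "benign", "unknown")

#: The two classes that define a "more functional" (MF) mutation.
MF_CLASSES = frozenset({"probably_damaging", "possibly_damaging"})

STAGES = ("I", "II", "III", "IV")

#: Field -> column mapping matching GDC MAF exports.
DEFAULT_MUTATION_DIALECT: Mapping[str, str] = {
    "sample_id": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref_allele": "Reference_Allele",
    "alt_allele": "Tumor_Seq_Allele2",
    "ref_count": "t_ref_count",
    "alt_count": "t_alt_count",
    "polyphen_class": "PolyPhen",
    "gene": "Hugo_Symbol",
}

#: Plain lowercase column names, convenient for hand-built tables.
SIMPLE_MUTATION_DIALECT: Mapping[str, str] = {
    "sample_id": "sample_id",
    "chrom": "chrom",
    "pos": "pos",
    "ref_allele": "ref",
    "alt_allele": "alt",
    "ref_count": "ref_count",
    "alt_count": "alt_count",
    "polyphen_class": "polyphen",
    "gene": "gene",
}

SEG_COLUMNS = ("ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean")

CLINICAL_REQUIRED = ("sample_id", "cancer_type", "purity", "survival_days", "event")
CLINICAL_OPTIONAL = ("age", "gender", "stage", "smoking", "subtype")


@dataclass
class MutationRecord:
    """One somatic single-nucleotide variant with tumor read counts."""

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_count: int
    alt_count: int
    polyphen_class: str = "unknown"
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_allele not in BASES or self.alt_allele not in BASES:
            raise ValueError(
                f"alleles must be single bases A/C/G/T, got "
                f"{self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical: {self.ref_allele}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.polyphen_class not in POLYPHEN_CLASSES:
            raise ValueError(f"unknown PolyPhen class {self.polyphen_class!r}")

    @property
    def depth(self) -> int:
        """Total read depth at the site (ref + alt reads)."""
        return self.ref_count + self.alt_count

    @property
    def is_mf(self) -> bool:
        """True when classified probably/possibly damaging by PolyPhen-2."""
        return self.polyphen_class in MF_CLASSES


@dataclass
class CNVSegment:
    """One copy-number segment with probe support and log2 ratio mean."""

    sample_id: str
    chrom: str
    start: int
    end: int
    num_probes: int
    segment_mean: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.num_probes < 1:
            raise ValueError(f"num_probes must be >= 1, got {self.num_probes}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass
class ClinicalRecord:
    """Per-sample clinical annotation: purity, survival and covariates.

    Optional fields are ``None`` when absent from the input; they are
    never silently zero-filled.
    """

    sample_id: str
    cancer_type: str
    purity: float
    survival_days: float
    event: int
    age: Optional[float] = None
    gender: Optional[str] = None
    stage: Optional[str] = None
    smoking: Optional[str] = None
    subtype: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must lie in (0, 1], got {self.purity}")
        if self.survival_days < 0:
            raise ValueError("survival_days must be non-negative")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")
        if self.stage is not None and self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.age is not None and self.age < 0:
            raise ValueError("age must be non-negative")


class ReadResult(NamedTuple):
    """Records accepted by a reader plus a per-reason skip tally."""

    records: list
    skipped: dict


def _normalise_polyphen(value) -> str:
    """Map a raw PolyPhen column value onto one of the four classes.

    GDC MAF files carry values like ``probably_damaging(0.98)``; the score
    suffix is stripped.  Missing/unrecognised values become ``unknown``.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return "unknown"
    text = str(value).strip().lower().replace(" ", "_")
    if "(" in text:
        text = text.split("(", 1)[0]
    return text if text in POLYPHEN_CLASSES[:3] else "unknown"


def read_mutations(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> ReadResult:
    """Read a MAF-like mutation table.

    Rows that are not simple single-nucleotide substitutions (multi-base
    or ``-`` alleles), rows with identical ref/alt alleles, and rows with
    missing read counts are dropped and tallied in the returned skip
    report rather than raising.  A count value that is present but not an
    integer is a hard error naming the offending line.

    Returns
    -------
    ReadResult
        ``records``: validated :class:`MutationRecord` list,
        ``skipped``: ``{reason: count}`` with reasons among
        ``non_snv``, ``ref_equals_alt``, ``missing_counts``.
    """
    dialect = dict(dialect or DEFAULT_MUTATION_DIALECT)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = [f for f in dialect if f != "gene"]
    missing = [dialect[f] for f in required if dialect[f] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    has_gene = dialect.get("gene") in df.columns

    records: list[MutationRecord] = []
    skipped = {"non_snv": 0, "ref_equals_alt": 0, "missing_counts": 0}
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based, after header
        ref = str(row[dialect["ref_allele"]]).strip().upper()
        alt = str(row[dialect["alt_allele"]]).strip().upper()
        if ref not in BASES or alt not in BASES:
            skipped["non_snv"] += 1
            continue
        if ref == alt:
            skipped["ref_equals_alt"] += 1
            continue
        raw_ref_n = row[dialect["ref_count"]]
        raw_alt_n = row[dialect["alt_count"]]
        if pd.isna(raw_ref_n) or pd.isna(raw_alt_n):
            skipped["missing_counts"] += 1
            continue
        try:
            ref_n, alt_n = int(raw_ref_n), int(raw_alt_n)
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path} line {line_no}: unparsable read count "
                f"({raw_ref_n!r}, {raw_alt_n!r})"
            ) from exc
        try:
            pos = int(row[dialect["pos"]])
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path} line {line_no}: unparsable position {row[dialect['pos']]!r}"
            ) from exc
        records.append(
            MutationRecord(
                sample_id=str(row[dialect["sample_id"]]),
                chrom=str(row[dialect["chrom"]]),
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                ref_count=ref_n,
                alt_count=alt_n,
                polyphen_class=_normalise_polyphen(row[dialect["polyphen_class"]]),
                gene=str(row[dialect["gene"]]) if has_gene and pd.notna(row[dialect["gene"]]) else None,
            )
        )
    return ReadResult(records, skipped)


def read_segments(path: str | Path) -> list[CNVSegment]:
    """Read a SEG-format copy-number table (ID, chrom, loc.start, loc.end,
    num.mark, seg.mean).  Overlapping segments are accepted as-is; no
    merging is performed."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    segments = []
    for idx, row in df.iterrows():
        try:
            segments.append(
                CNVSegment(
                    sample_id=str(row["ID"]),
                    chrom=str(row["chrom"]),
                    start=int(row["loc.start"]),
                    end=int(row["loc.end"]),
                    num_probes=int(row["num.mark"]),
                    segment_mean=float(row["seg.mean"]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path} line {idx + 2}: {exc}") from exc
    return segments


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the clinical table.  Optional covariates absent from the file
    (or empty in a row) are stored as ``None``.  Duplicate sample ids and
    out-of-range purities are hard errors."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].unique()
    if len(dupes):
        raise FormatError(f"{path}: duplicate sample_id(s): {', '.join(map(str, dupes))}")

    records = []
    for idx, row in df.iterrows():
        opt = {}
        for field_name in CLINICAL_OPTIONAL:
            if field_name in df.columns and pd.notna(row[field_name]):
                value = row[field_name]
                opt[field_name] = float(value) if field_name == "age" else str(value)
            else:
                opt[field_name] = None
        try:
            records.append(
                ClinicalRecord(
                    sample_id=str(row["sample_id"]),
                    cancer_type=str(row["cancer_type"]),
                    purity=float(row["purity"]),
                    survival_days=float(row["survival_days"]),
                    event=int(row["event"]),
                    **opt,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path} line {idx + 2}: {exc}") from exc
    return records


def write_mutations(
    records: Iterable[MutationRecord],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    dialect = dict(dialect or DEFAULT_MUTATION_DIALECT)
    rows = [
        {
            dialect["sample_id"]: r.sample_id,
            dialect["chrom"]: r.chrom,
            dialect["pos"]: r.pos,
            dialect["ref_allele"]: r.ref_allele,
            dialect["alt_allele"]: r.alt_allele,
            dialect["ref_count"]: r.ref_count,
            dialect["alt_count"]: r.alt_count,
            dialect["polyphen_class"]: r.polyphen_class,
            dialect["gene"]: r.gene if r.gene is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=[dialect[f] for f in dialect]).to_csv(
        path, sep="\t", index=False
    )


def write_segments(segments: Iterable[CNVSegment], path: str | Path) -> None:
    rows = [
        {
            "ID": s.sample_id,
            "chrom": s.chrom,
            "loc.start": s.start,
            "loc.end": s.end,
            "num.mark": s.num_probes,
            "seg.mean": s.segment_mean,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=list(SEG_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    cols = list(CLINICAL_REQUIRED) + list(CLINICAL_OPTIONAL)
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in cols}
        rows.append({k: ("" if v is None else v) for k, v in row.items()})
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def group_by_sample(items: Sequence) -> dict:
    """Group records (anything with a ``sample_id`` attribute) by sample."""
    out: dict[str, list] = {}
    for item in items:
        out.setdefault(item.sample_id, []).append(item)
    return out
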