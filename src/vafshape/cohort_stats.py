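"""Cluster-level genetic and clinical comparisons.

Covers the descriptive and inferential statistics run across VAF-shape
clusters: the six-class substitution spectrum (pyrimidine-strand
collapsed), copy-number-variant abundance as the altered fraction of the
covered genome, per-gene MF mutation frequencies, categorical tests with
the chi-square/Fisher switch, ANOVA + Tukey HSD for continuous traits,
and Benjamini–Hochberg adjustment across comparison families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io_formats import CNVSegment, MutationRecord

__all__ = [
    "SPECTRUM_CLASSES",
    "SpectrumCounts",
    "GroupTestResult",
    "mutation_spectrum",
    "cnv_abundance",
    "per_gene_mf_frequency",
    "compare_categorical",
    "compare_continuous",
    "adjust_bh",
]

#: The six pyrimidine-strand substitution classes.
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Strand collapse: purine-reference changes mapped to their
#: reverse-complement pyrimidine equivalents.  Covers all 12 substitution
#: types exactly once.
_COLLAPSE = {
    "C>A": "C>A", "C>G": "C>G", "C>T": "C>T",
    "T>A": "T>A", "T>C": "T>C", "T>G": "T>G",
    "G>T": "C>A", "G>C": "C>G", "G>A": "C>T",
    "A>T": "T>A", "A>G": "T>C", "A>C": "T>G",
}


@dataclass
class SpectrumCounts:
    """Counts and fractions of the six substitution classes."""

    counts: dict[str, int]
    total: int
    fractions: dict[str, float]


@dataclass
class GroupTestResult:
    """Outcome of one between-group comparison."""

    comparison: str
    test_used: str  # chi_square | fisher_exact | anova_tukey
    raw_p: float
    adjusted_p: float = float("nan")
    effect: str = ""


def mutation_spectrum(muts: Sequence[MutationRecord]) -> SpectrumCounts:
    """Tally substitutions into the six classes after strand collapse.

    A G>A change is the same event as C>T on the opposite strand, so
    purine-reference substitutions are counted under their pyrimidine
    equivalent.
    """
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for m in muts:
        counts[_COLLAPSE[f"{m.ref_allele}>{m.alt_allele}"]] += 1
    total = sum(counts.values())
    fractions = {
        c: (counts[c] / total if total else float("nan")) for c in SPECTRUM_CLASSES
    }
    return SpectrumCounts(counts=counts, total=total, fractions=fractions)


def cnv_abundance(segs: Sequence[CNVSegment], threshold: float = 0.2) -> float:
    """Fraction of the covered genome in copy-altered segments.

    Altered means ``|segment_mean| > threshold`` (strictly); the
    denominator is the total length covered by all segments of the
    sample.  NaN when no segments cover anything.
    """
    total = sum(s.length for s in segs)
    if total == 0:
        return float("nan")
    altered = sum(s.length for s in segs if abs(s.segment_mean) > threshold)
    return altered / total


def per_gene_mf_frequency(
    muts: Sequence[MutationRecord],
    labels: Mapping[str, int],
    top_n: int | None = None,
) -> pd.DataFrame:
    """Per-cluster fraction of samples carrying >= 1 MF mutation per gene.

    A sample counts once per gene however many mutations it has there.
    Returns a gene x cluster table of fractions; with ``top_n``, only the
    union of each cluster's top-N genes is kept.
    """
    cluster_sizes: dict[int, set] = {}
    for sample, cluster in labels.items():
        cluster_sizes.setdefault(cluster, set()).add(sample)
    hits: dict[str, dict[int, set]] = {}
    for m in muts:
        if not m.is_mf or m.gene is None or m.sample_id not in labels:
            continue
        cluster = labels[m.sample_id]
        hits.setdefault(m.gene, {}).setdefault(cluster, set()).add(m.sample_id)
    clusters = sorted(cluster_sizes)
    table = pd.DataFrame(
        {
            c: {
                g: len(hits[g].get(c, ())) / len(cluster_sizes[c])
                for g in hits
            }
            for c in clusters
        }
    ).fillna(0.0)
    table.index.name = "gene"
    if top_n is not None and not table.empty:
        keep: set[str] = set()
        for c in clusters:
            keep.update(table[c].nlargest(top_n).index)
        table = table.loc[sorted(keep)]
    return table


def compare_categorical(
    table: np.ndarray | Sequence[Sequence[int]],
    comparison: str = "",
    seed: int = 0,
    max_exact_cells: int = 4,
    n_monte_carlo: int = 200_000,
) -> GroupTestResult:
    """Chi-square test, switching to Fisher's exact when warranted.

    Expected frequencies are computed first; if any cell's expectation is
    <= 5, Fisher's exact test is used instead of chi-square.  For tables
    larger than 2x2 the Fisher p-value is estimated by Monte-Carlo
    sampling of tables with the observed margins (fixed seed), since
    exhaustive enumeration is infeasible in general.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a row or column margin is zero")
    chi2, chi_p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected <= 5).any():
        if table.size <= max_exact_cells and table.shape == (2, 2):
            _, p = stats.fisher_exact(table)
        else:
            p = _fisher_monte_carlo(table, seed=seed, n_samples=n_monte_carlo)
        return GroupTestResult(comparison=comparison, test_used="fisher_exact",
                               raw_p=float(p))
    return GroupTestResult(comparison=comparison, test_used="chi_square",
                           raw_p=float(chi_p))


def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of a contingency table under fixed margins
    (multivariate hypergeometric)."""
    from scipy.special import gammaln

    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(row + 1).sum() + gammaln(col + 1).sum()
        - gammaln(n + 1) - gammaln(table + 1).sum()
    )


def _fisher_monte_carlo(table: np.ndarray, seed: int, n_samples: int) -> float:
    """Monte-Carlo Fisher p: fraction of margin-preserving random tables
    at most as probable as the observed one."""
    from scipy.special import gammaln

    rng = np.random.default_rng(seed)
    observed_logp = _log_table_prob(table)
    sampler = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    draws = sampler.rvs(n_samples, random_state=rng)
    # only the cell term varies across margin-preserving tables
    cell_term = gammaln(np.asarray(draws) + 1).sum(axis=(1, 2))
    observed_cell_term = gammaln(table + 1).sum()
    hits = int((cell_term >= observed_cell_term - 1e-9).sum())
    # add-one correction keeps the estimate a valid p-value
    return (hits + 1) / (n_samples + 1)


def compare_continuous(
    groups: Mapping[str, Sequence[float]] | Mapping[int, Sequence[float]],
    comparison: str = "",
    with_tukey: bool = True,
) -> tuple[GroupTestResult, pd.DataFrame]:
    """One-way ANOVA across groups followed by Tukey's HSD.

    Returns the omnibus F-test result and the pairwise Tukey table
    (group1, group2, mean difference, adjusted p, reject flag); pass
    ``with_tukey=False`` to skip the post-hoc table when only the
    omnibus test is needed.
    """
    keys = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if np.ptp(np.concatenate(arrays)) == 0:
        # all values identical everywhere: no variance to partition
        result = GroupTestResult(comparison=comparison, test_used="anova_tukey",
                                 raw_p=1.0, effect="degenerate: zero variance")
        return result, pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p_adj", "reject"]
        )
    f_stat, p = stats.f_oneway(*arrays)
    if with_tukey:
        values = np.concatenate(arrays)
        group_labels = np.concatenate(
            [[str(k)] * len(a) for k, a in zip(keys, arrays)]
        )
        tukey = pairwise_tukeyhsd(values, group_labels)
        tukey_df = pd.DataFrame(
            tukey.summary().data[1:],
            columns=[c.strip() for c in tukey.summary().data[0]],
        )[["group1", "group2", "meandiff", "p-adj", "reject"]]
        tukey_df = tukey_df.rename(columns={"p-adj": "p_adj"})
    else:
        tukey_df = pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p_adj", "reject"]
        )
    result = GroupTestResult(
        comparison=comparison,
        test_used="anova_tukey",
        raw_p=float(p) if np.isfinite(p) else 1.0,
        effect=f"F={float(f_stat):.4g}" if np.isfinite(f_stat) else "F=0",
    )
    return result, tukey_df


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
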