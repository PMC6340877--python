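"""Cluster-level survival comparison: Kaplan–Meier and Cox models.

Overall survival (days; death = event) is compared across VAF-shape
clusters.  Clusters with fewer than 10 samples in a cancer type are too
small for stable hazard estimation and are excluded before fitting.
Cluster membership enters a Cox proportional-hazards model as indicator
variables against a reference cluster; hazard ratios are reported with
Wald 95% confidence intervals, and the proportional-hazards assumption
is checked with a scaled-Schoenfeld-residual test.  Ties in event times
use the Efron approximation.

The reference cluster can be chosen by the all-HRs-above-one rule: the
cluster which, used as reference, gives HR > 1 against every other
eligible cluster (i.e. the uniformly lowest-hazard group).  When no
single cluster qualifies, a deterministic minimax fallback is applied
and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test

__all__ = [
    "ClusterHazard",
    "CoxResult",
    "km_estimate",
    "fit_cox",
    "univariate_cluster_cox",
    "select_reference_from_table",
    "select_reference_cluster",
    "SurvivalError",
]

MIN_CLUSTER_SIZE = 10


class SurvivalError(RuntimeError):
    """Raised when a survival model cannot be fitted."""


@dataclass
class ClusterHazard:
    """Hazard ratio of one cluster versus the reference."""

    cluster: int
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    unstable: bool = False  # e.g. no events in the cluster


@dataclass
class CoxResult:
    """A fitted cluster-versus-reference Cox model."""

    cancer_type: str
    reference_cluster: int
    hazards: dict[int, ClusterHazard]
    covariates_used: list[str]
    n_samples: int
    excluded_clusters: dict[int, int] = field(default_factory=dict)  # cluster -> size
    ph_test_p: dict[str, float] = field(default_factory=dict)

    def hazard_ratio(self, cluster: int) -> float:
        return self.hazards[cluster].hazard_ratio


def km_estimate(
    times: Sequence[float],
    events: Sequence[int],
    labels: Sequence,
    groups: Sequence | None = None,
) -> dict:
    """Kaplan–Meier product-limit curves, one per group label.

    Returns ``{label: DataFrame(time, survival)}``; each curve starts at
    S(0) = 1 and is non-increasing.  ``groups`` fixes the expected group
    set (defaults to the labels observed); an expected group with no
    samples is skipped with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    if times.min() < 0:
        raise ValueError("survival times must be non-negative")
    curves = {}
    for label in (pd.unique(labels) if groups is None else groups):
        mask = labels == label
        if not mask.any():
            warnings.warn(f"group {label!r} is empty; skipped")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return curves


def _prepare_frame(
    times, events, labels, reference, covariates, min_cluster_size
):
    df = pd.DataFrame(
        {"time": np.asarray(times, dtype=float),
         "event": np.asarray(events, dtype=int),
         "cluster": np.asarray(labels)}
    )
    if covariates is not None:
        cov = covariates.reset_index(drop=True).copy()
        for c in cov.columns:
            df[c] = cov[c].to_numpy()
    # complete-case analysis: rows missing a covariate leave the model
    n_total = len(df)
    df = df.dropna().reset_index(drop=True)
    df.attrs["n_dropped_missing"] = n_total - len(df)
    sizes = df["cluster"].value_counts()
    eligible = sorted(int(c) for c in sizes.index[sizes >= min_cluster_size])
    excluded = {int(c): int(sizes[c]) for c in sizes.index if sizes[c] < min_cluster_size}
    if reference not in eligible:
        raise SurvivalError(
            f"reference cluster {reference} has fewer than "
            f"{min_cluster_size} samples (or is absent)"
        )
    if len(eligible) < 2:
        raise SurvivalError("fewer than 2 eligible clusters: nothing to compare")
    df = df[df["cluster"].isin(eligible)].reset_index(drop=True)
    return df, eligible, excluded


def _encode_stage(series: pd.Series, binary: bool = True) -> pd.Series:
    """Encode tumor stage: by default binarised to I/II (0) vs III/IV (1)."""
    if binary:
        return series.map({"I": 0, "II": 0, "III": 1, "IV": 1}).astype(float)
    return series.map({"I": 1, "II": 2, "III": 3, "IV": 4}).astype(float)


def build_covariate_frame(
    clinical_df: pd.DataFrame,
    covariates: Sequence[str],
    stage_binary: bool = True,
) -> pd.DataFrame:
    """Numeric design columns for the optional covariates age/gender/stage.

    Gender is encoded 0/1 by sorted category; stage is binarised I/II vs
    III/IV by default.  Rows with missing covariate values are dropped by
    the caller (complete-case analysis).
    """
    out = pd.DataFrame(index=clinical_df.index)
    for cov in covariates:
        if cov == "age":
            out["age"] = clinical_df["age"].astype(float)
        elif cov == "gender":
            cats = sorted(clinical_df["gender"].dropna().unique())
            out["gender"] = clinical_df["gender"].map(
                {c: i for i, c in enumerate(cats)}
            ).astype(float)
        elif cov == "stage":
            out["stage"] = _encode_stage(clinical_df["stage"], binary=stage_binary)
        else:
            raise ValueError(f"unsupported covariate {cov!r}")
    return out


def fit_cox(
    times: Sequence[float],
    events: Sequence[int],
    labels: Sequence,
    reference: int,
    covariates: pd.DataFrame | None = None,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    cancer_type: str = "",
) -> CoxResult:
    """Cox proportional-hazards fit of cluster membership vs a reference.

    Clusters below the size gate are excluded (and reported); the rest are
    encoded as indicators against ``reference``.  Wald 95% CIs and
    p-values per cluster; Efron handling of tied event times; scaled
    Schoenfeld residual test per term.  A non-reference cluster with no
    observed events yields a numerically unstable HR, which is flagged
    rather than suppressed.
    """
    df, eligible, excluded = _prepare_frame(
        times, events, labels, reference, covariates, min_cluster_size
    )
    others = [c for c in eligible if c != reference]
    design = pd.DataFrame({"time": df["time"], "event": df["event"]})
    for c in others:
        design[f"cluster_{c}"] = (df["cluster"] == c).astype(float)
    cov_names = []
    if covariates is not None:
        for c in covariates.columns:
            design[c] = df[c]
            cov_names.append(c)

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise SurvivalError(f"Cox model did not converge: {exc}") from exc

    summary = cph.summary
    hazards = {}
    for c in others:
        row = summary.loc[f"cluster_{c}"]
        sub = df[df["cluster"] == c]
        no_events = int(sub["event"].sum()) == 0
        hazards[c] = ClusterHazard(
            cluster=c,
            hazard_ratio=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p_value=float(row["p"]),
            n=int(len(sub)),
            unstable=no_events,
        )
    ph_p = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ph = proportional_hazard_test(cph, design, time_transform="rank")
        ph_p = {str(i): float(v) for i, v in ph.summary["p"].items()}
    except Exception:  # diagnostic only; never fail the fit for it
        ph_p = {}
    return CoxResult(
        cancer_type=cancer_type,
        reference_cluster=reference,
        hazards=hazards,
        covariates_used=cov_names,
        n_samples=int(len(design)),
        excluded_clusters=excluded,
        ph_test_p=ph_p,
    )


def univariate_cluster_cox(
    times: Sequence[float],
    events: Sequence[int],
    labels: Sequence,
    reference: int,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    cancer_type: str = "",
) -> CoxResult:
    """Cox fit with cluster membership as the only covariate."""
    return fit_cox(
        times, events, labels, reference,
        covariates=None,
        min_cluster_size=min_cluster_size,
        cancer_type=cancer_type,
    )


def select_reference_from_table(
    hr_table: Mapping[int, Mapping[int, float]],
) -> tuple[int, bool]:
    """Apply the all-HRs-above-one rule to a table of pairwise fits.

    ``hr_table[r][j]`` is the hazard ratio of cluster j when r is the
    reference.  Returns ``(cluster, qualified)``: the unique cluster with
    every HR > 1 when one exists; otherwise the deterministic minimax
    fallback — the cluster minimising ``max_j 1 / HR(j vs r)`` (lowest id
    on ties) — with ``qualified=False``.
    """
    qualifying = [
        r for r, row in hr_table.items() if row and all(hr > 1.0 for hr in row.values())
    ]
    if len(qualifying) == 1:
        return qualifying[0], True
    scores = {
        r: max(1.0 / hr for hr in row.values()) if row else np.inf
        for r, row in hr_table.items()
    }
    fallback = min(sorted(scores), key=lambda r: scores[r])
    return fallback, False


def select_reference_cluster(
    times: Sequence[float],
    events: Sequence[int],
    labels: Sequence,
    covariates: pd.DataFrame | None = None,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
) -> tuple[int, bool]:
    """Select the reference cluster by refitting with every candidate.

    Each eligible cluster is tried as reference; the one yielding HR > 1
    for all the others is returned.  The boolean flag reports whether the
    rule held exactly (False = minimax fallback used).
    """
    sizes = pd.Series(labels).value_counts()
    candidates = sorted(int(c) for c in sizes.index[sizes >= min_cluster_size])
    if len(candidates) < 2:
        raise SurvivalError("fewer than 2 eligible clusters")
    table: dict[int, dict[int, float]] = {}
    for r in candidates:
        result = fit_cox(
            times, events, labels, r,
            covariates=covariates,
            min_cluster_size=min_cluster_size,
        )
        table[r] = {c: h.hazard_ratio for c, h in result.hazards.items()}
    return select_reference_from_table(table)


def cox_result_frame(results: Sequence[CoxResult]) -> pd.DataFrame:
    """Flatten CoxResults into the HR report table."""
    rows = []
    for res in results:
        for c, h in sorted(res.hazards.items()):
            rows.append(
                {
                    "cancer_type": res.cancer_type,
                    "cluster": c,
                    "reference": res.reference_cluster,
                    "hazard_ratio": h.hazard_ratio,
                    "ci_low": h.ci_low,
                    "ci_high": h.ci_high,
                    "p_value": h.p_value,
                    "n": h.n,
                    "unstable": h.unstable,
                }
            )
    return pd.DataFrame(rows)
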