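"""The three parameters that define the shape of a VAF distribution.

A tumor's purity-adjusted VAF histogram is summarised multidimensionally
rather than by a single heterogeneity index:

* ``m_peak``  — the VAF at which a Gaussian kernel density estimate of
  the distribution attains its maximum (the dominant mode's position;
  roughly half the cancer-cell fraction of the dominant clone),
* ``m_count`` — log2 of the number of MF mutations (mutation burden on a
  doubling scale),
* ``m_math``  — the MATH score of the VAFs: the scaled median absolute
  deviation divided by the median (dispersion relative to location).

Together the three describe where the distribution sits, how many
mutations feed it, and how spread out it is — enough to distinguish
clonal, subclonal and dispersed architectures that a one-dimensional
score conflates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .mf_filter import FilteredVAFSet

__all__ = [
    "ShapeParams",
    "compute_m_count",
    "compute_m_math",
    "compute_m_peak",
    "profile_cohort",
    "PARAM_NAMES",
]

#: Canonical feature order used by the clustering and classifier stages.
PARAM_NAMES = ("m_peak", "m_count", "m_math")

#: Consistency constant making the MAD estimate the standard deviation
#: under normality (1 / Phi^-1(3/4)).
MAD_SCALE = 1.4826

VAFInput = Union[FilteredVAFSet, Sequence[float], np.ndarray]


@dataclass
class ShapeParams:
    """The three shape parameters of one sample's VAF distribution."""

    sample_id: str
    m_peak: float
    m_count: float
    m_math: float
    n_mutations: int = 0
    cancer_type: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.m_peak, self.m_count, self.m_math], dtype=float)


def _as_vaf_array(vafs: VAFInput) -> np.ndarray:
    if isinstance(vafs, FilteredVAFSet):
        arr = vafs.vafs
    else:
        arr = np.asarray(vafs, dtype=float)
    if arr.ndim != 1:
        raise ValueError("VAF input must be one-dimensional")
    if arr.size < 2:
        raise ValueError("at least 2 VAFs are required")
    return arr


def compute_m_count(vafs: VAFInput) -> float:
    """log2 of the number of MF mutations.

    Requires at least two mutations (log2 >= 1), the minimum for any
    distribution-shape statistic.
    """
    return float(np.log2(_as_vaf_array(vafs).size))


def compute_m_math(
    vafs: VAFInput,
    scale_constant: float = MAD_SCALE,
    percent: bool = False,
) -> float:
    """MATH score: scaled median absolute deviation over the median.

    ``scale_constant * median(|v - median(v)|) / median(v)``; the result
    is dimensionless (0 when all VAFs coincide) and is multiplied by 100
    only when ``percent`` is on, matching the original head-and-neck
    formulation which reported percentages.
    """
    arr = _as_vaf_array(vafs)
    med = float(np.median(arr))
    if med == 0:
        raise ValueError("median VAF is 0: MATH undefined for degenerate input")
    mad = float(np.median(np.abs(arr - med)))
    score = scale_constant * mad / med
    return score * 100.0 if percent else score


def compute_m_peak(
    vafs: VAFInput,
    grid_points: int = 512,
    bw_method: str | float = "silverman",
) -> float:
    """Position of the highest mode of a Gaussian KDE of the VAFs.

    The density is evaluated on an even grid over [0, 1] — the full VAF
    range, not the data range — so peak positions are comparable across
    samples.  Ties take the smallest grid value.  A zero-variance vector
    has no KDE; its common value is returned directly.
    """
    arr = _as_vaf_array(vafs)
    if np.ptp(arr) == 0.0:
        return float(arr[0])
    grid = np.linspace(0.0, 1.0, grid_points)
    kde = stats.gaussian_kde(arr, bw_method=bw_method)
    density = kde(grid)
    return float(grid[int(np.argmax(density))])


def profile_cohort(
    vafsets: Iterable[FilteredVAFSet],
    cancer_types: dict | None = None,
    grid_points: int = 512,
    bw_method: str | float = "silverman",
    math_scale: float = MAD_SCALE,
    math_percent: bool = False,
) -> tuple[list[ShapeParams], pd.DataFrame]:
    """Compute the three shape parameters for every sample in a cohort.

    Also returns the pairwise Pearson correlation matrix of the three
    parameters across samples — the diagnostic used to argue the
    parameters act as quasi-independent axes.  Correlations are NaN when
    undefined (fewer than two samples, or a zero-variance parameter).
    """
    cancer_types = cancer_types or {}
    params = [
        ShapeParams(
            sample_id=vs.sample_id,
            m_peak=compute_m_peak(vs, grid_points=grid_points, bw_method=bw_method),
            m_count=compute_m_count(vs),
            m_math=compute_m_math(vs, scale_constant=math_scale, percent=math_percent),
            n_mutations=len(vs),
            cancer_type=cancer_types.get(vs.sample_id, ""),
        )
        for vs in vafsets
    ]
    corr = pd.DataFrame(
        np.full((3, 3), np.nan), index=PARAM_NAMES, columns=PARAM_NAMES
    )
    if len(params) >= 2:
        mat = np.array([p.as_array() for p in params])
        with np.errstate(invalid="ignore", divide="ignore"):
            corr_values = np.corrcoef(mat, rowvar=False)
        corr = pd.DataFrame(corr_values, index=PARAM_NAMES, columns=PARAM_NAMES)
    return params, corr


def params_frame(params: Sequence[ShapeParams]) -> pd.DataFrame:
    """Tabulate shape parameters, one row per sample."""
    return pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in params],
            "cancer_type": [p.cancer_type for p in params],
            "m_peak": [p.m_peak for p in params],
            "m_count": [p.m_count for p in params],
            "m_math": [p.m_math for p in params],
            "n_mf_mutations": [p.n_mutations for p in params],
        }
    )
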