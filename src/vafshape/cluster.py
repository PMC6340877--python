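"""Cohort embedding and k-medoids partitioning of VAF-shape parameters.

Samples are embedded by principal component analysis of the three shape
parameters (standardized by default: the parameters live on incommensurate
scales) and partitioned in the 2-D PC plane with the PAM k-medoids
algorithm under squared Euclidean distance.  Five clusters separate the
canonical architectures: many-clonal, many-subclonal, few-clonal-tight,
few-with-selected-subclone, and few-dispersed.

PAM is implemented directly (classic BUILD initialisation followed by
SWAP steepest-descent to a local optimum) so that the fit is fully
deterministic given the input order; ties always resolve to the lowest
index.  Medoids are actual samples, which keeps cluster centres
interpretable as concrete tumors.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .shape_params import PARAM_NAMES, ShapeParams

__all__ = [
    "PCAModel",
    "ClusterModel",
    "CohortModel",
    "fit_pca",
    "fit_kmedoids",
    "kmedoids_cost",
    "exhaustive_kmedoids",
    "choose_k_diagnostics",
    "assign_new_sample",
    "cluster_cohort",
    "save_model",
    "load_model",
]


@dataclass
class PCAModel:
    """A frozen PCA transform of the three shape parameters."""

    feature_means: np.ndarray
    feature_scales: np.ndarray
    loadings: np.ndarray  # (3, 3); columns are components
    explained_variance_fraction: np.ndarray

    def transform(self, x: np.ndarray, n_components: int = 2) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = (x - self.feature_means) / self.feature_scales
        return z @ self.loadings[:, :n_components]


@dataclass
class ClusterModel:
    """A fitted k-medoids partition in the embedded space."""

    k: int
    medoid_indices: list[int]
    medoid_coords: np.ndarray  # (k, d)
    medoid_sample_ids: list[str]
    labels: dict[str, int]  # sample_id -> cluster id in 1..k
    cost: float
    distance: str = "sqeuclidean"


@dataclass
class CohortModel:
    """PCA transform + k-medoids partition fitted on one cohort."""

    pca: PCAModel
    clusters: ClusterModel
    coords: np.ndarray
    sample_ids: list[str]


def fit_pca(
    params: Sequence[ShapeParams],
    standardize: bool = True,
    n_components: int = 2,
) -> tuple[PCAModel, np.ndarray]:
    """Fit PCA to the (m_peak, m_count, m_math) matrix of a cohort.

    Features are centered, and scaled to unit variance when
    ``standardize`` is on.  Returns the model (with all three components
    and their explained-variance fractions) and the first
    ``n_components`` scores per sample.  Component signs are fixed so the
    largest-magnitude loading of each component is positive, making fits
    reproducible across library versions.
    """
    x = np.array([p.as_array() for p in params], dtype=float)
    if x.shape[0] < 3:
        raise ValueError("PCA requires at least 3 samples")
    means = x.mean(axis=0)
    stds = x.std(axis=0, ddof=1)
    if standardize:
        zero_var = np.flatnonzero(stds == 0)
        if zero_var.size:
            names = ", ".join(PARAM_NAMES[i] for i in zero_var)
            raise ValueError(f"cannot standardize zero-variance feature(s): {names}")
        scales = stds
    else:
        scales = np.ones(3)
    z = (x - means) / scales

    pca = PCA(n_components=3)
    pca.fit(z)
    loadings = pca.components_.T.copy()  # columns are components
    # deterministic sign convention
    for j in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] *= -1
    model = PCAModel(
        feature_means=means,
        feature_scales=scales,
        loadings=loadings,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
    )
    return model, model.transform(x, n_components=n_components)


def _sq_dist_matrix(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def kmedoids_cost(points: np.ndarray, medoid_indices: Sequence[int]) -> float:
    """Total within-cluster squared Euclidean cost of a medoid set."""
    points = np.asarray(points, dtype=float)
    med = points[np.asarray(medoid_indices, dtype=int)]
    d = ((points[:, None, :] - med[None, :, :]) ** 2).sum(axis=2)
    return float(d.min(axis=1).sum())


def exhaustive_kmedoids(points: np.ndarray, k: int) -> tuple[list[int], float]:
    """Globally optimal medoid set by exhaustive enumeration (small n only)."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    best_set, best_cost = None, np.inf
    for combo in itertools.combinations(range(n), k):
        cost = kmedoids_cost(points, combo)
        if cost < best_cost - 1e-12:
            best_set, best_cost = list(combo), cost
    return best_set, best_cost


def fit_kmedoids(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
    max_iter: int = 100,
) -> ClusterModel:
    """PAM k-medoids under squared Euclidean distance.

    BUILD greedily selects medoids minimising total cost; SWAP repeatedly
    applies the single (medoid, non-medoid) exchange with the largest
    cost reduction until none improves.  All ties break to the lowest
    point index, so the fit is deterministic for a given input order;
    ``seed`` is accepted for interface uniformity but never consulted.

    SWAP converges to a local optimum that is occasionally sub-optimal on
    small instances; whenever the whole search space is small
    (C(n, k) <= 3000 medoid sets) the optimum is found by exhaustive
    enumeration instead, so small problems are always solved exactly.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n < 2:
        raise ValueError("k-medoids requires at least 2 points")
    if not (1 <= k <= n):
        raise ValueError(f"k must satisfy 1 <= k <= n, got k={k}, n={n}")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]

    d = _sq_dist_matrix(points)

    import math

    if math.comb(n, k) <= 3000:
        medoids, cost = exhaustive_kmedoids(points, k)
        medoids = sorted(medoids)
        assignment = np.argmin(d[:, medoids], axis=1)
        labels = {sample_ids[i]: int(assignment[i]) + 1 for i in range(n)}
        return ClusterModel(
            k=k,
            medoid_indices=[int(m) for m in medoids],
            medoid_coords=points[medoids].copy(),
            medoid_sample_ids=[sample_ids[m] for m in medoids],
            labels=labels,
            cost=float(cost),
        )

    # BUILD
    medoids: list[int] = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        # gain of adding each candidate point as a new medoid
        gains = np.maximum(current[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    # SWAP (steepest descent)
    cost = d[:, medoids].min(axis=1).sum()
    for _ in range(max_iter):
        best_delta, best_swap = -1e-12, None
        in_set = set(medoids)
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            base = d[:, others].min(axis=1) if others else np.full(n, np.inf)
            for h in range(n):
                if h in in_set:
                    continue
                new_cost = np.minimum(base, d[:, h]).sum()
                delta = cost - new_cost
                if delta > best_delta + 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        cost = d[:, medoids].min(axis=1).sum()

    medoids = sorted(medoids)
    assignment = np.argmin(d[:, medoids], axis=1)
    labels = {sample_ids[i]: int(assignment[i]) + 1 for i in range(n)}
    return ClusterModel(
        k=k,
        medoid_indices=[int(m) for m in medoids],
        medoid_coords=points[medoids].copy(),
        medoid_sample_ids=[sample_ids[m] for m in medoids],
        labels=labels,
        cost=float(cost),
    )


def choose_k_diagnostics(
    points: np.ndarray,
    k_range: Sequence[int],
    seed: int = 0,
) -> pd.DataFrame:
    """Cost and mean silhouette for each candidate k.

    Purely diagnostic: the number of clusters is an analyst's call (five
    gives visually distinct VAF architectures on real cohorts), so no
    automatic selection is performed.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    rows = []
    for k in k_range:
        if not (2 <= k <= n - 1):
            raise ValueError(f"each k must satisfy 2 <= k <= n-1, got {k}")
        model = fit_kmedoids(points, k, seed=seed)
        flat_labels = [model.labels[str(i)] if str(i) in model.labels else None
                       for i in range(n)]
        if any(l is None for l in flat_labels):  # custom ids: recompute
            d = ((points[:, None, :] - model.medoid_coords[None, :, :]) ** 2).sum(2)
            flat_labels = (np.argmin(d, axis=1) + 1).tolist()
        sil = float(
            silhouette_score(points, flat_labels, metric="sqeuclidean")
        ) if len(set(flat_labels)) > 1 else float("nan")
        rows.append({"k": k, "cost": model.cost, "mean_silhouette": sil})
    return pd.DataFrame(rows)


def assign_new_sample(
    pca: PCAModel, clusters: ClusterModel, params: ShapeParams
) -> int:
    """Embed an unseen sample with the frozen transform and return the
    cluster of its nearest medoid (ties -> lowest cluster id)."""
    point = pca.transform(params.as_array(), n_components=clusters.medoid_coords.shape[1])[0]
    d = ((clusters.medoid_coords - point) ** 2).sum(axis=1)
    return int(np.argmin(d)) + 1


def _relabel_by_archetype_order(
    params: Sequence[ShapeParams], model: ClusterModel
) -> ClusterModel:
    """Renumber clusters by descending median m_count, then descending
    median m_peak, approximating the canonical 1..5 archetype order
    (1-2: high burden, 3-5: low burden; within each tier the higher peak
    first)."""
    by_cluster: dict[int, list[ShapeParams]] = {}
    for p in params:
        by_cluster.setdefault(model.labels[p.sample_id], []).append(p)
    order = sorted(
        by_cluster,
        key=lambda c: (
            -float(np.median([p.m_count for p in by_cluster[c]])),
            -float(np.median([p.m_peak for p in by_cluster[c]])),
        ),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    perm = np.argsort([remap[i + 1] for i in range(model.k)])
    return ClusterModel(
        k=model.k,
        medoid_indices=[model.medoid_indices[i] for i in perm],
        medoid_coords=model.medoid_coords[perm].copy(),
        medoid_sample_ids=[model.medoid_sample_ids[i] for i in perm],
        labels={s: remap[c] for s, c in model.labels.items()},
        cost=model.cost,
    )


def cluster_cohort(
    params: Sequence[ShapeParams],
    k: int = 5,
    seed: int = 0,
    standardize: bool = True,
    n_components: int = 2,
) -> CohortModel:
    """Fit PCA + PAM on a cohort's shape parameters.

    Clustering runs on the first two principal components by default
    (``n_components=3`` clusters in the full space).  Cluster ids are
    re-ordered to the canonical archetype numbering after fitting.
    """
    pca, coords = fit_pca(params, standardize=standardize, n_components=n_components)
    sample_ids = [p.sample_id for p in params]
    model = fit_kmedoids(coords, k, seed=seed, sample_ids=sample_ids)
    model = _relabel_by_archetype_order(params, model)
    return CohortModel(pca=pca, clusters=model, coords=coords, sample_ids=sample_ids)


def save_model(model: CohortModel, path: str | Path) -> None:
    """Persist a fitted cohort model as JSON (means, scales, loadings,
    medoids, labels) for reuse by assignment and classification."""
    payload = {
        "pca": {
            "feature_means": model.pca.feature_means.tolist(),
            "feature_scales": model.pca.feature_scales.tolist(),
            "loadings": model.pca.loadings.tolist(),
            "explained_variance_fraction": model.pca.explained_variance_fraction.tolist(),
        },
        "clusters": {
            "k": model.clusters.k,
            "medoid_indices": model.clusters.medoid_indices,
            "medoid_coords": model.clusters.medoid_coords.tolist(),
            "medoid_sample_ids": model.clusters.medoid_sample_ids,
            "labels": model.clusters.labels,
            "cost": model.clusters.cost,
            "distance": model.clusters.distance,
        },
        "coords": model.coords.tolist(),
        "sample_ids": model.sample_ids,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> CohortModel:
    payload = json.loads(Path(path).read_text())
    pca = PCAModel(
        feature_means=np.array(payload["pca"]["feature_means"]),
        feature_scales=np.array(payload["pca"]["feature_scales"]),
        loadings=np.array(payload["pca"]["loadings"]),
        explained_variance_fraction=np.array(
            payload["pca"]["explained_variance_fraction"]
        ),
    )
    c = payload["clusters"]
    clusters = ClusterModel(
        k=c["k"],
        medoid_indices=c["medoid_indices"],
        medoid_coords=np.array(c["medoid_coords"]),
        medoid_sample_ids=c["medoid_sample_ids"],
        labels={s: int(v) for s, v in c["labels"].items()},
        cost=c["cost"],
        distance=c["distance"],
    )
    return CohortModel(
        pca=pca,
        clusters=clusters,
        coords=np.array(payload["coords"]),
        sample_ids=payload["sample_ids"],
    )
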