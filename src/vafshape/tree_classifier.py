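"""CART classifier mapping shape parameters to cluster labels.

A binary decision tree over (m_peak, m_count, m_math) gives clinicians a
set of explicit split rules for placing a new tumor into one of the
five VAF-shape clusters without re-running PCA and k-medoids.  The tree
is grown on Gini impurity and pruned with a complexity parameter in the
rpart convention: a subtree survives only while its weakest link reduces
the tree's misclassification risk by at least ``cp`` times the root
risk.  Accuracy is estimated by stratified 10-fold cross-validation.

The implementation is self-contained and fully deterministic: split
thresholds sit at midpoints between consecutive sorted unique values,
ties in impurity decrease resolve to the lower feature index then the
lower threshold, and samples with a feature exactly at a threshold are
routed right (the >= branch).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .shape_params import PARAM_NAMES, ShapeParams

__all__ = [
    "TreeNode",
    "TreeModel",
    "CVResult",
    "fit_cart",
    "predict",
    "predict_many",
    "cross_validate",
    "render_text",
]


@dataclass
class TreeNode:
    """One node of the fitted tree (internal split or leaf)."""

    prediction: int
    n: int
    n_misclassified: int
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def purity(self) -> float:
        return 1.0 - self.n_misclassified / self.n if self.n else 0.0

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def subtree_miscount(self) -> int:
        if self.is_leaf:
            return self.n_misclassified
        return self.left.subtree_miscount() + self.right.subtree_miscount()


@dataclass
class TreeModel:
    """A fitted, pruned CART tree plus its training metadata."""

    root: TreeNode
    cp: float
    min_leaf: int
    classes: list[int]
    feature_names: tuple[str, ...] = PARAM_NAMES
    n_training: int = 0

    def n_leaves(self) -> int:
        return self.root.n_leaves()


@dataclass
class CVResult:
    """Stratified k-fold cross-validation accuracies."""

    fold_accuracies: list[float]
    mean: float
    sd: float
    max: float
    stratified: bool = True


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def _best_split(
    x: np.ndarray, y: np.ndarray, classes: np.ndarray, min_leaf: int
) -> Optional[tuple[int, float, float]]:
    """Best (feature, threshold, impurity_decrease) under Gini.

    Scans features in index order and thresholds in increasing order,
    accepting only strict improvements, which realises the documented
    tie-breaking (lower feature index, then lower threshold).
    """
    n = len(y)
    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_index[v] for v in y])
    parent_counts = np.bincount(y_idx, minlength=len(classes))
    parent_gini = _gini(parent_counts)
    best = None
    best_decrease = 1e-12
    for f in range(x.shape[1]):
        order = np.argsort(x[:, f], kind="stable")
        xs, ys = x[order, f], y_idx[order]
        left_counts = np.zeros(len(classes))
        right_counts = parent_counts.astype(float).copy()
        i = 0
        while i < n:
            j = i
            while j < n and xs[j] == xs[i]:
                left_counts[ys[j]] += 1
                right_counts[ys[j]] -= 1
                j += 1
            if j >= n:
                break
            n_left = j
            n_right = n - j
            if n_left >= min_leaf and n_right >= min_leaf:
                threshold = (xs[j - 1] + xs[j]) / 2.0
                weighted = (n_left * _gini(left_counts) + n_right * _gini(right_counts)) / n
                decrease = parent_gini - weighted
                if decrease > best_decrease + 1e-12:
                    best_decrease = decrease
                    best = (f, float(threshold), float(decrease))
            i = j
    return best


def _grow(x: np.ndarray, y: np.ndarray, classes: np.ndarray, min_leaf: int) -> TreeNode:
    class_index = {c: i for i, c in enumerate(classes)}
    counts = np.bincount([class_index[v] for v in y], minlength=len(classes))
    prediction = int(classes[int(np.argmax(counts))])
    node = TreeNode(
        prediction=prediction,
        n=len(y),
        n_misclassified=int(len(y) - counts.max()),
    )
    if counts.max() == len(y) or len(y) < 2 * min_leaf:
        return node
    split = _best_split(x, y, classes, min_leaf)
    if split is None:
        return node
    f, threshold, _ = split
    go_left = x[:, f] < threshold  # values at the threshold go right
    node.feature, node.threshold = f, threshold
    node.left = _grow(x[go_left], y[go_left], classes, min_leaf)
    node.right = _grow(x[~go_left], y[~go_left], classes, min_leaf)
    return node


def _prune(root: TreeNode, cp: float, scale_by_root_risk: bool = True) -> TreeNode:
    """Weakest-link cost-complexity pruning, rpart-style.

    The link value of an internal node t is
    ``g(t) = (R(t) - R(T_t)) / (leaves(T_t) - 1)`` with R measured as the
    misclassification count; the subtree at the weakest link is collapsed
    while ``g(t) < cp * R(root)`` (or ``cp * n`` absolute when the
    root-risk scaling is off).
    """
    n_total = root.n
    root_risk = root.n_misclassified if scale_by_root_risk else n_total
    if root_risk == 0:  # a pure root never grew splits
        return root
    threshold = cp * root_risk

    def internal_nodes(node: TreeNode) -> list[TreeNode]:
        if node.is_leaf:
            return []
        return [node] + internal_nodes(node.left) + internal_nodes(node.right)

    while True:
        candidates = internal_nodes(root)
        if not candidates:
            break
        links = [
            (node.n_misclassified - node.subtree_miscount())
            / max(node.n_leaves() - 1, 1)
            for node in candidates
        ]
        weakest = int(np.argmin(links))
        if links[weakest] >= threshold - 1e-12:
            break
        node = candidates[weakest]
        node.feature = node.threshold = node.left = node.right = None
    return root


def _as_matrix(params) -> np.ndarray:
    if len(params) and isinstance(params[0], ShapeParams):
        return np.array([p.as_array() for p in params], dtype=float)
    return np.atleast_2d(np.asarray(params, dtype=float))


def fit_cart(
    params,
    labels: Sequence[int],
    cp: float = 0.1,
    min_leaf: int = 5,
    scale_by_root_risk: bool = True,
) -> TreeModel:
    """Grow and prune a CART tree on the shape parameters.

    ``params`` is a list of :class:`ShapeParams` or an (n, 3) array in
    (m_peak, m_count, m_math) order.  A single-class input yields a
    trivial one-leaf tree with a warning.
    """
    x = _as_matrix(params)
    y = np.asarray(labels)
    if len(y) != x.shape[0]:
        raise ValueError("params and labels length mismatch")
    classes = np.unique(y)
    if len(classes) < 2:
        warnings.warn("single-class input: fitting a trivial one-leaf tree")
    root = _grow(x, y, classes, min_leaf)
    root = _prune(root, cp, scale_by_root_risk=scale_by_root_risk)
    return TreeModel(
        root=root,
        cp=cp,
        min_leaf=min_leaf,
        classes=[int(c) for c in classes],
        n_training=len(y),
    )


def predict(tree: TreeModel, params) -> int:
    """Route one sample down the tree; at a threshold the >= branch wins."""
    if isinstance(params, ShapeParams):
        x = params.as_array()
    else:
        x = np.asarray(params, dtype=float)
    node = tree.root
    while not node.is_leaf:
        node = node.left if x[node.feature] < node.threshold else node.right
    return node.prediction


def predict_many(tree: TreeModel, params) -> np.ndarray:
    x = _as_matrix(params)
    return np.array([predict(tree, row) for row in x])


def cross_validate(
    params,
    labels: Sequence[int],
    folds: int = 10,
    seed: int = 0,
    cp: float = 0.1,
    min_leaf: int = 5,
) -> CVResult:
    """Stratified k-fold cross-validation of the pruned tree.

    Folds are stratified by cluster label; when a class has fewer members
    than folds, stratification is impossible and a plain shuffled split is
    used (with a warning).  Reports per-fold accuracy plus mean, SD and
    max.
    """
    x = _as_matrix(params)
    y = np.asarray(labels)
    n = len(y)
    if folds > n:
        raise ValueError(f"folds={folds} exceeds n={n}")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    stratified = bool((counts >= folds).all())
    fold_of = np.empty(n, dtype=int)
    if stratified:
        for c in classes:
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            fold_of[idx] = np.arange(len(idx)) % folds
    else:
        warnings.warn("a class has fewer members than folds; "
                      "falling back to unstratified folds")
        idx = rng.permutation(n)
        fold_of[idx] = np.arange(n) % folds

    accuracies = []
    for fold in range(folds):
        test = fold_of == fold
        model = fit_cart(x[~test], y[~test], cp=cp, min_leaf=min_leaf)
        pred = predict_many(model, x[test])
        accuracies.append(float((pred == y[test]).mean()))
    acc = np.array(accuracies)
    return CVResult(
        fold_accuracies=accuracies,
        mean=float(acc.mean()),
        sd=float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
        max=float(acc.max()),
        stratified=stratified,
    )


def render_text(tree: TreeModel) -> str:
    """Indented text rendering of the split rules and leaves."""
    lines: list[str] = []

    def walk(node: TreeNode, depth: int, prefix: str) -> None:
        pad = "  " * depth
        if node.is_leaf:
            lines.append(
                f"{pad}{prefix}-> cluster {node.prediction} "
                f"(n={node.n}, purity={node.purity:.3f})"
            )
            return
        name = tree.feature_names[node.feature]
        lines.append(f"{pad}{prefix}split on {name} @ {node.threshold:.4g}")
        walk(node.left, depth + 1, f"{name} < {node.threshold:.4g} ")
        walk(node.right, depth + 1, f"{name} >= {node.threshold:.4g} ")

    walk(tree.root, 0, "")
    return "\n".join(lines)


def _node_to_dict(node: TreeNode) -> dict:
    d = {
        "prediction": node.prediction,
        "n": node.n,
        "n_misclassified": node.n_misclassified,
    }
    if not node.is_leaf:
        d.update(
            feature=node.feature,
            threshold=node.threshold,
            left=_node_to_dict(node.left),
            right=_node_to_dict(node.right),
        )
    return d


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(
        prediction=d["prediction"], n=d["n"], n_misclassified=d["n_misclassified"]
    )
    if "feature" in d:
        node.feature = d["feature"]
        node.threshold = d["threshold"]
        node.left = _node_from_dict(d["left"])
        node.right = _node_from_dict(d["right"])
    return node


def save_tree(tree: TreeModel, path: str | Path) -> None:
    payload = {
        "cp": tree.cp,
        "min_leaf": tree.min_leaf,
        "classes": tree.classes,
        "feature_names": list(tree.feature_names),
        "n_training": tree.n_training,
        "root": _node_to_dict(tree.root),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_tree(path: str | Path) -> TreeModel:
    payload = json.loads(Path(path).read_text())
    return TreeModel(
        root=_node_from_dict(payload["root"]),
        cp=payload["cp"],
        min_leaf=payload["min_leaf"],
        classes=payload["classes"],
        feature_names=tuple(payload["feature_names"]),
        n_training=payload["n_training"],
    )
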