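"""Functional classification trees (FCTs).

An FCT is a CART-style binary tree grown not on the raw discretized signals
but on a feature matrix derived from their functional representation: the
principal-component score matrix ``V`` (data-driven basis) or the B-spline
coefficient matrix ``C`` (fixed basis).  Each split compares one feature
against a threshold: rows with value below the threshold go left, the rest
right.  Split quality is the decrease of node impurity (Gini or
Shannon–Wiener entropy); candidate thresholds are midpoints between
consecutive distinct sorted feature values.

Grown trees can be pruned by weakest-link cost-complexity pruning with the
penalty chosen by stratified cross-validated misclassification.

Determinism: the grower breaks ties by larger impurity decrease, then lower
feature index, then smaller threshold; leaf class ties predict the class
that sorts first in the label set (with a logged warning).
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .basis import BasisExpansion
from .fpca import ScoreMatrix

__all__ = [
    "FeatureMatrix",
    "TreeParams",
    "Node",
    "FCTModel",
    "gini",
    "entropy",
    "grow_tree",
    "predict_tree",
    "prune_tree",
    "cost_complexity_alphas",
    "prune_at_alpha",
    "render_tree",
]

log = logging.getLogger(__name__)

_GAIN_TOL = 1e-12


# ---------------------------------------------------------------------------
# feature matrices

@dataclass
class FeatureMatrix:
    """An ``(N, P)`` matrix of per-curve features with column provenance.

    ``kind`` records which functional representation produced the columns
    (``"fpc"`` for principal-component scores, ``"bspline"`` for basis
    coefficients); ``column_ids`` name the columns (1-based component or
    basis indices by default).
    """

    values: np.ndarray
    kind: str = "generic"
    column_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if self.column_ids is None:
            self.column_ids = list(range(1, self.values.shape[1] + 1))
        if len(self.column_ids) != self.values.shape[1]:
            raise ValueError("one column id per feature column is required")
        if len(set(self.column_ids)) != len(self.column_ids):
            raise ValueError("column ids must be unique")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_scores(cls, scores: ScoreMatrix) -> "FeatureMatrix":
        return cls(scores.values, kind="fpc")

    @classmethod
    def from_expansion(cls, exp: BasisExpansion) -> "FeatureMatrix":
        return cls(exp.coefs, kind="bspline")


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    if isinstance(features, ScoreMatrix):
        return features.values
    return np.atleast_2d(np.asarray(features, dtype=float))


# ---------------------------------------------------------------------------
# impurity indices

def _check_fractions(fractions: np.ndarray) -> np.ndarray:
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0):
        raise ValueError("class fractions must be nonnegative")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    return fractions


def gini(class_fractions) -> float:
    """Gini heterogeneity index 1 − Σ f²; 0 for a pure node."""
    f = _check_fractions(class_fractions)
    return float(1.0 - np.sum(f * f))


def entropy(class_fractions) -> float:
    """Shannon–Wiener entropy −Σ f log f (natural log, 0·log 0 := 0)."""
    f = _check_fractions(class_fractions)
    nz = f[f > 0]
    return float(-np.sum(nz * np.log(nz)))


def _impurity_from_counts(counts: np.ndarray, criterion: str) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    f = counts / n
    if criterion == "gini":
        return float(1.0 - np.sum(f * f))
    nz = f[f > 0]
    return float(-np.sum(nz * np.log(nz)))


# ---------------------------------------------------------------------------
# model types

@dataclass
class TreeParams:
    """Hyperparameters of the grower; defaults mirror common CART tooling."""

    criterion: str = "gini"  # "gini" or "entropy"
    minsplit: int = 20  # smallest node the grower will try to split
    minbucket: int = 7  # smallest admissible child
    cp: float = 0.01  # complexity gate on the weighted impurity decrease
    max_depth: int = 30
    mtry: int | None = None  # features sampled per split; None = all

    def __post_init__(self) -> None:
        if self.criterion not in ("gini", "entropy"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.minsplit < 2 or self.minbucket < 1 or self.max_depth < 0:
            raise ValueError("invalid tree size parameters")


@dataclass
class Node:
    """A tree node; a leaf when ``left`` is None."""

    node_id: int
    depth: int
    counts: np.ndarray  # per-class training counts, sorted-class order
    prediction: int  # class index
    members: np.ndarray  # training row indices reaching this node
    feature: int | None = None
    threshold: float | None = None
    gain: float | None = None  # weighted impurity decrease of the split
    left: "Node | None" = None
    right: "Node | None" = None
    leaf_id: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class FCTModel:
    """A fitted functional classification tree."""

    root: Node
    params: TreeParams
    classes: np.ndarray  # sorted label set
    feature_kind: str
    n_features: int
    n_train: int

    def leaves(self) -> list[Node]:
        out: list[Node] = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def internal_nodes(self) -> list[Node]:
        out: list[Node] = []

        def walk(node: Node) -> None:
            if not node.is_leaf:
                out.append(node)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def find_node(self, node_id: int) -> Node:
        found = [
            n for n in self.internal_nodes() + self.leaves() if n.node_id == node_id
        ]
        if not found:
            raise KeyError(f"no node with id {node_id}")
        return found[0]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(_model_payload(self)))

    @classmethod
    def from_json(cls, path) -> "FCTModel":
        return _model_from_payload(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# growing

def _best_split(
    X: np.ndarray,
    y: np.ndarray,
    rows: np.ndarray,
    n_classes: int,
    minbucket: int,
    candidates: np.ndarray,
    criterion: str,
):
    """Exhaustive search over candidate features and midpoint thresholds.

    Returns ``(delta, feature, threshold)`` for the best admissible split or
    ``None``; ties resolve to the lower feature index, then the smaller
    threshold.
    """
    n = rows.size
    parent_counts = np.bincount(y[rows], minlength=n_classes).astype(float)
    parent_imp = _impurity_from_counts(parent_counts, criterion)
    best = None
    for j in candidates:
        v = X[rows, j]
        order = np.argsort(v, kind="stable")
        vs = v[order]
        ys = y[rows][order]
        cut = np.nonzero(np.diff(vs) > 0)[0]  # left block ends at index cut
        if cut.size == 0:
            continue
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)
        n_left = cut + 1
        n_right = n - n_left
        ok = (n_left >= minbucket) & (n_right >= minbucket)
        if not np.any(ok):
            continue
        cut = cut[ok]
        n_left = n_left[ok]
        n_right = n_right[ok]
        left_counts = cum[cut]
        right_counts = parent_counts - left_counts
        fl = left_counts / n_left[:, None]
        fr = right_counts / n_right[:, None]
        if criterion == "gini":
            imp_l = 1.0 - np.sum(fl * fl, axis=1)
            imp_r = 1.0 - np.sum(fr * fr, axis=1)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                imp_l = -np.sum(np.where(fl > 0, fl * np.log(fl), 0.0), axis=1)
                imp_r = -np.sum(np.where(fr > 0, fr * np.log(fr), 0.0), axis=1)
        delta = parent_imp - (n_left * imp_l + n_right * imp_r) / n
        pick = int(np.argmax(delta))  # first max -> smallest threshold
        if delta[pick] <= _GAIN_TOL:
            continue
        threshold = (vs[cut[pick]] + vs[cut[pick] + 1]) / 2.0
        if best is None or delta[pick] > best[0]:
            best = (float(delta[pick]), int(j), float(threshold))
    return best


def grow_tree(
    features,
    labels,
    params: TreeParams | None = None,
    rng: np.random.Generator | None = None,
) -> FCTModel:
    """Grow an FCT by recursive binary splitting.

    ``features`` is a :class:`FeatureMatrix` (or a plain array); ``labels``
    any array of class labels.  Growth stops on node purity, ``minsplit``,
    ``minbucket``, ``max_depth``, or when no split clears the complexity
    gate ``cp`` (measured as the impurity decrease weighted by node size,
    relative to the root impurity).  With ``params.mtry`` set, each split
    considers a fresh random sample of that many features, drawn from
    ``rng``.
    """
    params = params or TreeParams()
    X = _as_matrix(features)
    kind = features.kind if isinstance(features, FeatureMatrix) else "generic"
    labels = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("empty data")
    if labels.shape[0] != X.shape[0]:
        raise ValueError("one label per feature row is required")
    classes, y = np.unique(labels, return_inverse=True)
    N, P = X.shape
    n_classes = classes.size
    mtry = params.mtry
    if mtry is not None and not 1 <= mtry <= P:
        raise ValueError(f"mtry must be in [1, {P}]")
    if mtry is not None and mtry < P and rng is None:
        rng = np.random.default_rng(0)
    root_counts = np.bincount(y, minlength=n_classes).astype(float)
    root_imp = _impurity_from_counts(root_counts, params.criterion)
    gate = params.cp * root_imp
    counter = {"id": 0, "ties": 0}

    def make_node(rows: np.ndarray, depth: int) -> Node:
        counts = np.bincount(y[rows], minlength=n_classes).astype(float)
        winners = np.nonzero(counts == counts.max())[0]
        if winners.size > 1:
            counter["ties"] += 1
        node = Node(
            node_id=counter["id"],
            depth=depth,
            counts=counts,
            prediction=int(winners[0]),
            members=rows.copy(),
        )
        counter["id"] += 1
        pure = counts.max() == rows.size
        if pure or rows.size < params.minsplit or depth >= params.max_depth:
            return node
        if mtry is not None and mtry < P:
            candidates = np.sort(rng.choice(P, size=mtry, replace=False))
        else:
            candidates = np.arange(P)
        best = _best_split(
            X, y, rows, n_classes, params.minbucket, candidates, params.criterion
        )
        if best is None:
            return node
        delta, j, threshold = best
        if (rows.size / N) * delta < gate - _GAIN_TOL:
            return node
        go_left = X[rows, j] < threshold
        node.feature = j
        node.threshold = threshold
        node.gain = (rows.size / N) * delta
        node.left = make_node(rows[go_left], depth + 1)
        node.right = make_node(rows[~go_left], depth + 1)
        return node

    root = make_node(np.arange(N), 0)
    if counter["ties"]:
        log.warning(
            "%d node class tie(s) broken toward the sorted-first label",
            counter["ties"],
        )
    model = FCTModel(
        root=root,
        params=params,
        classes=classes,
        feature_kind=kind,
        n_features=P,
        n_train=N,
    )
    _assign_leaf_ids(model)
    return model


def _assign_leaf_ids(model: FCTModel) -> None:
    """Number leaves 1..L in left-to-right order."""
    next_id = {"l": 1}

    def walk(node: Node) -> None:
        if node.is_leaf:
            node.leaf_id = next_id["l"]
            next_id["l"] += 1
        else:
            node.leaf_id = None
            walk(node.left)
            walk(node.right)

    walk(model.root)


# ---------------------------------------------------------------------------
# prediction

def predict_tree(model: FCTModel, features) -> tuple[np.ndarray, np.ndarray]:
    """Route each feature row down the tree.

    Returns ``(labels, leaf_ids)``; a row whose feature value equals the
    threshold exactly goes right (the ≥ branch).
    """
    X = _as_matrix(features)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1]} does not match training width "
            f"{model.n_features}"
        )
    preds = np.empty(X.shape[0], dtype=int)
    leaf_ids = np.empty(X.shape[0], dtype=int)
    for i in range(X.shape[0]):
        node = model.root
        while not node.is_leaf:
            node = node.left if X[i, node.feature] < node.threshold else node.right
        preds[i] = node.prediction
        leaf_ids[i] = node.leaf_id
    return model.classes[preds], leaf_ids


# ---------------------------------------------------------------------------
# cost-complexity pruning

def _leaf_risk(node: Node, n_train: int) -> float:
    return float(node.counts.sum() - node.counts.max()) / n_train


def _subtree_stats(node: Node, n_train: int) -> tuple[float, int]:
    if node.is_leaf:
        return _leaf_risk(node, n_train), 1
    rl, cl = _subtree_stats(node.left, n_train)
    rr, cr = _subtree_stats(node.right, n_train)
    return rl + rr, cl + cr


def _weakest_links(model: FCTModel) -> list[tuple[float, Node]]:
    """g(t) = (R(t) − R(T_t)) / (|leaves(T_t)| − 1) for every internal node."""
    out = []
    for node in model.internal_nodes():
        sub_risk, n_leaves = _subtree_stats(node, model.n_train)
        g = (_leaf_risk(node, model.n_train) - sub_risk) / (n_leaves - 1)
        out.append((g, node))
    return out


def prune_at_alpha(model: FCTModel, alpha: float) -> FCTModel:
    """Smallest subtree optimal for the complexity penalty ``alpha``.

    Internal nodes whose weakest-link value is strictly below ``alpha`` are
    collapsed, repeatedly, until none remain; ``alpha = 0`` returns the tree
    unchanged and ``alpha = inf`` the root-only tree.
    """
    pruned = copy.deepcopy(model)
    while True:
        links = [(g, node) for g, node in _weakest_links(pruned) if g < alpha]
        if not links:
            break
        g_min = min(g for g, _ in links)
        for g, node in links:
            if g == g_min:
                node.left = node.right = None
                node.feature = node.threshold = node.gain = None
    _assign_leaf_ids(pruned)
    return pruned


def cost_complexity_alphas(model: FCTModel) -> list[float]:
    """The increasing sequence of weakest-link penalty values of the tree."""
    alphas = [0.0]
    work = copy.deepcopy(model)
    while True:
        links = _weakest_links(work)
        if not links:
            break
        g_min = min(g for g, _ in links)
        for g, node in links:
            if g <= g_min:
                node.left = node.right = None
                node.feature = node.threshold = node.gain = None
        if not alphas or g_min > alphas[-1]:
            alphas.append(float(g_min))
    return alphas


def _candidate_alphas(alphas: list[float]) -> list[float]:
    """One representative penalty per subtree in the weakest-link sequence."""
    cands = [0.0]
    for k in range(1, len(alphas)):
        lo = alphas[k]
        hi = alphas[k + 1] if k + 1 < len(alphas) else None
        if hi is None:
            cands.append(2.0 * lo if lo > 0 else 1.0)
        elif lo > 0:
            cands.append(float(np.sqrt(lo * hi)))
        else:
            cands.append(hi / 2.0)
    return cands


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold assignment per sample, balanced within each class."""
    folds = np.empty(y.size, dtype=int)
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def prune_tree(
    model: FCTModel,
    features,
    labels,
    n_folds: int = 10,
    seed: int = 0,
    cp: float | None = None,
) -> FCTModel:
    """Weakest-link cost-complexity pruning.

    With ``cp`` given, the tree is pruned directly at the penalty
    ``cp * R(root)`` where R(root) is the misclassification risk of the
    root-only tree.  Otherwise the penalty is chosen to minimize the
    cross-validated misclassification error over the weakest-link sequence
    (folds stratified by class, seeded); ties prefer the larger penalty,
    i.e. the simpler tree.
    """
    X = _as_matrix(features)
    labels = np.asarray(labels)
    if cp is not None:
        root_risk = _leaf_risk(model.root, model.n_train)
        return prune_at_alpha(model, cp * root_risk)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > X.shape[0]:
        raise ValueError("n_folds exceeds the number of samples")
    candidates = _candidate_alphas(cost_complexity_alphas(model))
    rng = np.random.default_rng(seed)
    _, y = np.unique(labels, return_inverse=True)
    folds = _stratified_folds(y, n_folds, rng)
    errors = np.zeros(len(candidates))
    for f in range(n_folds):
        train = folds != f
        if np.unique(labels[train]).size < 1 or not np.any(~train):
            continue
        fold_model = grow_tree(
            FeatureMatrix(X[train], kind=model.feature_kind),
            labels[train],
            params=model.params,
        )
        for c, alpha in enumerate(candidates):
            sub = prune_at_alpha(fold_model, alpha)
            pred, _ = predict_tree(sub, X[~train])
            errors[c] += np.sum(pred != labels[~train])
    best = np.nonzero(errors == errors.min())[0][-1]  # tie -> larger penalty
    return prune_at_alpha(model, candidates[best])


# ---------------------------------------------------------------------------
# rendering and serialization

def render_tree(model: FCTModel) -> str:
    """Plain-text rendering of the tree (splits, counts, predictions)."""
    lines: list[str] = []

    def name(j: int) -> str:
        prefix = {"fpc": "FPC", "bspline": "phi"}.get(model.feature_kind, "x")
        return f"{prefix}{j + 1}"

    def walk(node: Node, indent: str) -> None:
        counts = "/".join(str(int(c)) for c in node.counts)
        if node.is_leaf:
            lines.append(
                f"{indent}leaf {node.leaf_id}: predict "
                f"{model.classes[node.prediction]} (n={node.n}, counts={counts})"
            )
        else:
            lines.append(
                f"{indent}node {node.node_id}: {name(node.feature)} < "
                f"{node.threshold:.6g} (n={node.n}, counts={counts}, "
                f"gain={node.gain:.4g})"
            )
            walk(node.left, indent + "  ")
            walk(node.right, indent + "  ")

    walk(model.root, "")
    return "\n".join(lines)


def _node_payload(node: Node) -> dict:
    payload = {
        "node_id": node.node_id,
        "depth": node.depth,
        "counts": node.counts.tolist(),
        "prediction": node.prediction,
        "members": node.members.tolist(),
        "leaf_id": node.leaf_id,
    }
    if not node.is_leaf:
        payload.update(
            feature=node.feature,
            threshold=node.threshold,
            gain=node.gain,
            left=_node_payload(node.left),
            right=_node_payload(node.right),
        )
    return payload


def _node_from_payload(payload: dict) -> Node:
    node = Node(
        node_id=payload["node_id"],
        depth=payload["depth"],
        counts=np.asarray(payload["counts"], dtype=float),
        prediction=payload["prediction"],
        members=np.asarray(payload["members"], dtype=int),
        leaf_id=payload["leaf_id"],
    )
    if "feature" in payload:
        node.feature = payload["feature"]
        node.threshold = payload["threshold"]
        node.gain = payload["gain"]
        node.left = _node_from_payload(payload["left"])
        node.right = _node_from_payload(payload["right"])
    return node


def _model_payload(model: FCTModel) -> dict:
    return {
        "root": _node_payload(model.root),
        "params": vars(model.params),
        "classes": [str(c) for c in model.classes],
        "feature_kind": model.feature_kind,
        "n_features": model.n_features,
        "n_train": model.n_train,
    }


def _model_from_payload(payload: dict) -> FCTModel:
    return FCTModel(
        root=_node_from_payload(payload["root"]),
        params=TreeParams(**payload["params"]),
        classes=np.asarray(payload["classes"]),
        feature_kind=payload["feature_kind"],
        n_features=payload["n_features"],
        n_train=payload["n_train"],
    )
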