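"""Functional bagging (FBG) and functional random forests (FRF).

Both train an ensemble of H functional classification trees, each grown
unpruned on a bootstrap sample of the N training curves drawn with
replacement (the "in-bag" set; its complement is the "out-of-bag" set for
that tree).  The forest adds a decorrelating tweak: at every split only a
fresh random subset of ``m`` of the P features is considered.  At ``m = P``
the forest degenerates exactly to bagging.

Predictions aggregate the H tree votes by majority; the out-of-bag (OOB)
votes — each sample judged only by trees that did not train on it — give an
almost unbiased error estimate without a held-out set.  Feature relevance is
measured by mean decrease accuracy: the drop in per-tree OOB accuracy after
permuting one feature column.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical seeds give bit-identical
forests regardless of platform.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tree import (
    FCTModel,
    FeatureMatrix,
    TreeParams,
    _as_matrix,
    _model_from_payload,
    _model_payload,
    grow_tree,
    predict_tree,
)

__all__ = [
    "ForestModel",
    "OOBResult",
    "fit_forest",
    "fit_bagging",
    "predict_forest",
    "oob_error",
    "permutation_importance",
    "deep_tree_params",
]

log = logging.getLogger(__name__)


def deep_tree_params(criterion: str = "gini", mtry: int | None = None) -> TreeParams:
    """Parameters for the unpruned, fully grown trees used inside ensembles."""
    return TreeParams(
        criterion=criterion, minsplit=2, minbucket=1, cp=0.0, max_depth=50, mtry=mtry
    )


@dataclass
class ForestModel:
    """An ensemble of FCTs with their bootstrap bookkeeping."""

    trees: list[FCTModel]
    ibfd: list[np.ndarray]  # per-tree in-bag index multisets, each of size N
    oobfd: list[np.ndarray]  # per-tree out-of-bag index sets
    m: int  # features tried per split
    seed: int
    classes: np.ndarray
    feature_kind: str
    n_features: int
    n_train: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def to_json(self, path) -> None:
        payload = {
            "m": self.m,
            "seed": self.seed,
            "classes": [str(c) for c in self.classes],
            "feature_kind": self.feature_kind,
            "n_features": self.n_features,
            "n_train": self.n_train,
            "ibfd": [idx.tolist() for idx in self.ibfd],
            "trees": [_model_payload(t) for t in self.trees],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "ForestModel":
        payload = json.loads(Path(path).read_text())
        ibfd = [np.asarray(i, dtype=int) for i in payload["ibfd"]]
        n = payload["n_train"]
        return cls(
            trees=[_model_from_payload(p) for p in payload["trees"]],
            ibfd=ibfd,
            oobfd=[np.setdiff1d(np.arange(n), i) for i in ibfd],
            m=payload["m"],
            seed=payload["seed"],
            classes=np.asarray(payload["classes"]),
            feature_kind=payload["feature_kind"],
            n_features=payload["n_features"],
            n_train=n,
        )


def fit_forest(
    features,
    labels,
    n_trees: int = 100,
    m: int | None = None,
    tree_params: TreeParams | None = None,
    seed: int = 0,
    bootstrap: bool = True,
) -> ForestModel:
    """Fit an FRF (or FBG when ``m`` equals the number of features).

    Each of the ``n_trees`` trees is grown unpruned (``minsplit=2``,
    ``minbucket=1`` unless ``tree_params`` overrides) on a bootstrap sample
    of size N; every split considers a fresh random subset of ``m`` features.
    ``m`` defaults to floor(sqrt(P)).  ``bootstrap=False`` is a test hook
    that trains every tree on the full sample.
    """
    X = _as_matrix(features)
    kind = features.kind if isinstance(features, FeatureMatrix) else "generic"
    labels = np.asarray(labels)
    N, P = X.shape
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if m is None:
        m = max(1, int(np.sqrt(P)))
    if not 1 <= m <= P:
        raise ValueError(f"m must be in [1, {P}]; got {m}")
    params = tree_params or deep_tree_params()
    params = TreeParams(**{**vars(params), "mtry": m})
    classes = np.unique(labels)
    trees: list[FCTModel] = []
    ibfd: list[np.ndarray] = []
    oobfd: list[np.ndarray] = []
    everyone = np.arange(N)
    for child in np.random.SeedSequence(seed).spawn(n_trees):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, N, size=N) if bootstrap else everyone.copy()
        tree = grow_tree(
            FeatureMatrix(X[idx], kind=kind), labels[idx], params=params, rng=rng
        )
        tree.classes = classes  # align vote indexing across trees
        _reindex_tree_classes(tree, np.unique(labels[idx]), classes)
        trees.append(tree)
        ibfd.append(idx)
        oobfd.append(np.setdiff1d(everyone, idx))
    return ForestModel(
        trees=trees,
        ibfd=ibfd,
        oobfd=oobfd,
        m=m,
        seed=seed,
        classes=classes,
        feature_kind=kind,
        n_features=P,
        n_train=N,
    )


def _reindex_tree_classes(
    tree: FCTModel, local: np.ndarray, global_classes: np.ndarray
) -> None:
    """Remap a tree grown on a bootstrap sample (which may miss classes) so
    its predictions and counts index the full, sorted class set."""
    if local.size == global_classes.size and np.all(local == global_classes):
        return
    mapping = np.searchsorted(global_classes, local)

    def walk(node) -> None:
        counts = np.zeros(global_classes.size)
        counts[mapping] = node.counts
        node.counts = counts
        node.prediction = int(mapping[node.prediction])
        if not node.is_leaf:
            walk(node.left)
            walk(node.right)

    walk(tree.root)


def fit_bagging(
    features,
    labels,
    n_trees: int = 100,
    tree_params: TreeParams | None = None,
    seed: int = 0,
    bootstrap: bool = True,
) -> ForestModel:
    """Functional bagging: the forest with every feature eligible at every
    split (``m = P``)."""
    P = _as_matrix(features).shape[1]
    return fit_forest(
        features,
        labels,
        n_trees=n_trees,
        m=P,
        tree_params=tree_params,
        seed=seed,
        bootstrap=bootstrap,
    )


def _vote_matrix(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """(n_rows, n_classes) counts of tree votes."""
    votes = np.zeros((X.shape[0], model.classes.size), dtype=int)
    for tree in model.trees:
        pred, _ = predict_tree(tree, X)
        idx = np.searchsorted(model.classes, pred)
        votes[np.arange(X.shape[0]), idx] += 1
    return votes


def _majority(votes: np.ndarray, classes: np.ndarray):
    """Majority vote per row; ties go to the first class in sorted order and
    are flagged."""
    top = votes.max(axis=1)
    pred_idx = votes.argmax(axis=1)  # argmax returns the first max: sorted-label rule
    ties = (votes == top[:, None]).sum(axis=1) > 1
    total = votes.sum(axis=1)
    with np.errstate(invalid="ignore"):
        fractions = np.where(total > 0, top / np.maximum(total, 1), np.nan)
    return classes[pred_idx], fractions, ties


def predict_forest(
    model: ForestModel, features
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Majority-vote predictions.

    Returns ``(labels, vote_fractions, tie_flags)``; the fraction is the
    share of trees voting for the winning class.
    """
    X = _as_matrix(features)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1]} does not match training width "
            f"{model.n_features}"
        )
    labels, fractions, ties = _majority(_vote_matrix(model, X), model.classes)
    if np.any(ties):
        log.warning("%d tied votes broken toward the sorted-first class", ties.sum())
    return labels, fractions, ties


@dataclass
class OOBResult:
    error: float  # misclassified fraction of samples with OOB coverage
    predictions: np.ndarray  # per-sample OOB majority label ('' if never OOB)
    n_never_oob: int


def oob_error(model: ForestModel, features, labels) -> OOBResult:
    """Out-of-bag misclassification: each sample voted on only by trees whose
    OOB set contains it; samples never out of bag are excluded and counted."""
    X = _as_matrix(features)
    labels = np.asarray(labels).astype(str)
    N = X.shape[0]
    votes = np.zeros((N, model.classes.size), dtype=int)
    for tree, oob in zip(model.trees, model.oobfd):
        if oob.size == 0:
            continue
        pred, _ = predict_tree(tree, X[oob])
        idx = np.searchsorted(model.classes, pred)
        votes[oob, idx] += 1
    covered = votes.sum(axis=1) > 0
    if not np.any(covered):
        raise ValueError("no OOB coverage: every sample was in-bag for every tree")
    pred_labels, _, _ = _majority(votes, model.classes)
    predictions = np.where(covered, pred_labels.astype(str), "")
    error = float(np.mean(predictions[covered] != labels[covered]))
    return OOBResult(error=error, predictions=predictions, n_never_oob=int(N - covered.sum()))


def permutation_importance(
    model: ForestModel, features, labels, seed: int = 0
) -> np.ndarray:
    """Mean decrease accuracy per feature.

    For each tree, OOB accuracy minus OOB accuracy after permuting one
    feature column (a fresh seeded permutation per tree and feature),
    averaged over trees with nonempty OOB sets.
    """
    X = _as_matrix(features)
    labels = np.asarray(labels).astype(str)
    P = X.shape[1]
    drops = np.zeros(P)
    n_used = 0
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for tree, oob in zip(model.trees, model.oobfd):
        if oob.size == 0:
            continue
        n_used += 1
        y_oob = labels[oob]
        base_pred, _ = predict_tree(tree, X[oob])
        base_acc = np.mean(base_pred.astype(str) == y_oob)
        for j in range(P):
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            pred, _ = predict_tree(tree, Xp)
            drops[j] += base_acc - np.mean(pred.astype(str) == y_oob)
    if n_used == 0:
        raise ValueError("no OOB coverage: every sample was in-bag for every tree")
    return drops / n_used
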