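"""Interpretive machinery for functional classification trees.

Two families of tools translate tree split rules back into the time domain:

* **Splitting curves.**  The *theoretical splitting curve* (TSC) of an
  internal node is the linear combination of the basis functions appearing
  on the root-to-node path, weighted by the split thresholds — a synthetic
  curve representing the separation rule.  When the same feature is split
  twice on a path, the deepest (binding) threshold is used.  The *empirical
  splitting curve* (ESC) is the training curve closest to the TSC: under the
  score semi-metric for principal-component features (the TSC's score
  vector has the thresholds at the path features and zeros elsewhere), or
  under the L2 distance for B-spline features.

* **Leaf variability.**  The functional deviance of a leaf DEV(t) (pointwise
  sum of squared deviations from the leaf mean) decomposes into the
  between-group sum of squares FBGSS(t) plus the within-group deviances — a
  pointwise one-way ANOVA.  Between-leaf variability of one class across
  leaves (FBLSS) and between a leaf and a reference leaf localizes, in time,
  why members of one class were routed to different leaves.  For binary
  outcomes the group roles specialize to TP/FP (disease-predicting leaves)
  and TN/FN (healthy-predicting leaves).

Relative ("rel") variants are pointwise ratios; wherever a denominator is
zero the result is reported as a masked value (0 where the numerator is
also 0), never as an infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BSplineBasis
from .curves import CurveSet, functional_mean
from .fpca import FPCAModel, ScoreMatrix
from .proximity import l2_distance
from .tree import FCTModel, Node

__all__ = [
    "split_path",
    "tsc",
    "esc",
    "leaf_deviance",
    "rel_leaf_deviance",
    "fbgss",
    "LeafDiagnostics",
    "leaf_diagnostics",
    "confusion_roles",
    "fblss_all",
    "fblss_pair",
    "select_reference_leaf",
]


# ---------------------------------------------------------------------------
# splitting curves

def split_path(model: FCTModel, node_id: int) -> list[tuple[int, float]]:
    """The ordered (feature, threshold) pairs from the root to the node
    ``node_id`` inclusive.  The node must be internal (it defines a split)."""
    target = model.find_node(node_id)
    if target.is_leaf:
        raise ValueError("splitting curves are defined for internal nodes, not leaves")

    path: list[tuple[int, float]] = []

    def walk(node: Node) -> bool:
        if not node.is_leaf:
            path.append((node.feature, node.threshold))
            if node.node_id == node_id:
                return True
            if walk(node.left) or walk(node.right):
                return True
            path.pop()
        return False

    if not walk(model.root):
        raise KeyError(f"no internal node with id {node_id}")
    return path


def _path_thresholds(path: list[tuple[int, float]]) -> dict[int, float]:
    """One threshold per distinct path feature; a feature split twice keeps
    the deepest (binding) threshold."""
    out: dict[int, float] = {}
    for feature, threshold in path:
        out[feature] = threshold
    return out


def tsc(model: FCTModel, node_id: int, basis: FPCAModel | BSplineBasis,
        grid: np.ndarray | None = None) -> np.ndarray:
    """Theoretical splitting curve of an internal node.

    Σ over the distinct features on the root-to-node path of
    threshold × basis function, evaluated on the model grid (principal
    components) or on ``grid`` (B-splines).
    """
    thresholds = _path_thresholds(split_path(model, node_id))
    if isinstance(basis, FPCAModel):
        curve = np.zeros_like(basis.grid)
        for k, theta in thresholds.items():
            curve = curve + theta * basis.eigenfunctions[k]
        return curve
    if grid is None:
        raise ValueError("a grid is required to evaluate a B-spline splitting curve")
    phi = basis.design_matrix(np.asarray(grid, dtype=float))  # (T, S)
    curve = np.zeros(phi.shape[0])
    for s, theta in thresholds.items():
        curve = curve + theta * phi[:, s]
    return curve


def esc(
    model: FCTModel,
    node_id: int,
    train: CurveSet,
    train_scores: ScoreMatrix | None = None,
    basis: FPCAModel | BSplineBasis | None = None,
) -> tuple[int, np.ndarray]:
    """Empirical splitting curve: the training curve nearest to the TSC.

    Principal-component trees measure nearness with the score semi-metric
    against the padded threshold vector (thresholds at path features, zeros
    elsewhere, over all model components); B-spline trees use the L2
    distance between raw curves and the TSC.  Ties resolve to the lowest
    curve index.  Returns ``(index, curve)``.
    """
    thresholds = _path_thresholds(split_path(model, node_id))
    if isinstance(basis, FPCAModel):
        if train_scores is None:
            raise ValueError("training scores are required for the score semi-metric")
        target = np.zeros(train_scores.n_components)
        for k, theta in thresholds.items():
            target[k] = theta
        dists = np.linalg.norm(train_scores.values - target, axis=1)
    else:
        curve = tsc(model, node_id, basis, grid=train.grid)
        dists = np.array(
            [l2_distance(x, curve, train.grid) for x in train.values]
        )
    best = int(np.argmin(dists))  # argmin takes the first minimum: lowest index
    return best, train.values[best].copy()


# ---------------------------------------------------------------------------
# leaf variability

def _masked_ratio(num: np.ndarray, den: np.ndarray) -> np.ma.MaskedArray:
    """Pointwise num/den with the degenerate-denominator convention:
    wherever den == 0 the value is masked (0 when num is also 0)."""
    mask = den == 0
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=~mask)
    return np.ma.MaskedArray(out, mask=mask)


def leaf_deviance(values: np.ndarray) -> np.ndarray:
    """Functional deviance: Σ_i (x_i(t) − x̄(t))² pointwise over the member
    curves (rows of ``values``)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 0:
        raise ValueError("empty leaf")
    return np.sum((values - values.mean(axis=0)) ** 2, axis=0)


def rel_leaf_deviance(
    leaf_values: np.ndarray, root_values: np.ndarray
) -> np.ma.MaskedArray:
    """Leaf deviance relative to the deviance of the whole training sample."""
    return _masked_ratio(leaf_deviance(leaf_values), leaf_deviance(root_values))


def fbgss(
    values: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ma.MaskedArray]:
    """Between-group sum of squares of a leaf and its relative version.

    FBGSS(t) = Σ_g n_g (x̄_g(t) − x̄(t))² over the groups present in the
    leaf; relFBGSS(t) = FBGSS(t) / DEV(t) with the masked-zero convention.
    Together with the within-group deviances this decomposes DEV(t) exactly
    (pointwise ANOVA identity).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(labels)
    if values.shape[0] == 0:
        raise ValueError("empty leaf")
    overall = values.mean(axis=0)
    between = np.zeros(values.shape[1])
    for g in np.unique(labels):
        member = labels == g
        gm = values[member].mean(axis=0)
        between += member.sum() * (gm - overall) ** 2
    return between, _masked_ratio(between, leaf_deviance(values))


@dataclass
class LeafDiagnostics:
    """Per-leaf functional summary used by the between-leaf measures."""

    leaf_id: int
    members: np.ndarray  # training row indices
    n: int
    predicted_class: str
    group_counts: dict  # class -> n_g
    mean: np.ndarray  # leaf functional mean
    group_means: dict  # class -> group functional mean
    deviance: np.ndarray
    rel_deviance: np.ma.MaskedArray
    between_group: np.ndarray
    rel_between_group: np.ma.MaskedArray

    @property
    def purity(self) -> float:
        return self.group_counts.get(self.predicted_class, 0) / self.n


def leaf_diagnostics(model: FCTModel, train: CurveSet) -> list[LeafDiagnostics]:
    """Compute :class:`LeafDiagnostics` for every leaf of a fitted tree,
    using the training curves and their labels."""
    if train.labels is None:
        raise ValueError("training curves must carry labels")
    out: list[LeafDiagnostics] = []
    for leaf in model.leaves():
        members = leaf.members
        values = train.values[members]
        labels = train.labels[members]
        groups = np.unique(labels)
        between, rel_between = fbgss(values, labels)
        out.append(
            LeafDiagnostics(
                leaf_id=leaf.leaf_id,
                members=members.copy(),
                n=members.size,
                predicted_class=str(model.classes[leaf.prediction]),
                group_counts={str(g): int((labels == g).sum()) for g in groups},
                mean=values.mean(axis=0),
                group_means={
                    str(g): values[labels == g].mean(axis=0) for g in groups
                },
                deviance=leaf_deviance(values),
                rel_deviance=rel_leaf_deviance(values, train.values),
                between_group=between,
                rel_between_group=rel_between,
            )
        )
    return out


def confusion_roles(
    leaf: LeafDiagnostics, labels: np.ndarray, positive_label: str
) -> np.ndarray:
    """TP/FP/TN/FN role of every member of a leaf under a binary outcome.

    Members of a leaf predicting the positive class are TP (true label
    positive) or FP; members of a leaf predicting the negative class are TN
    or FN.
    """
    labels = np.asarray(labels).astype(str)
    label_set = np.unique(labels)
    if label_set.size != 2:
        raise ValueError(
            "confusion roles are a binary specialization; got "
            f"{label_set.size} classes"
        )
    positive_label = str(positive_label)
    if positive_label not in label_set:
        raise ValueError(f"positive label {positive_label!r} not among {label_set}")
    member_labels = labels[leaf.members]
    if leaf.predicted_class == positive_label:
        return np.where(member_labels == positive_label, "TP", "FP")
    return np.where(member_labels == positive_label, "FN", "TN")


def _group_leaves(leaves: list[LeafDiagnostics], group: str) -> list[LeafDiagnostics]:
    present = [l for l in leaves if l.group_counts.get(str(group), 0) > 0]
    if not present:
        raise ValueError(f"group {group!r} is absent from every leaf")
    return present


def fblss_all(leaves: list[LeafDiagnostics], group: str) -> np.ndarray:
    """Between-leaf sum of squares of one group across all leaves:
    Σ_l n_g^(l) (x̄_g^(l)(t) − x̄_g(t))², with x̄_g the overall mean of the
    group pooled over every leaf."""
    group = str(group)
    present = _group_leaves(leaves, group)
    counts = np.array([l.group_counts[group] for l in present], dtype=float)
    means = np.stack([l.group_means[group] for l in present])
    overall = (counts[:, None] * means).sum(axis=0) / counts.sum()
    return np.sum(counts[:, None] * (means - overall) ** 2, axis=0)


def fblss_pair(
    leaves: list[LeafDiagnostics],
    leaf_id: int,
    reference_id: int,
    group: str,
) -> tuple[np.ndarray, np.ma.MaskedArray]:
    """Between-leaf sum of squares of one group between a leaf and a
    reference leaf, and its version relative to the all-leaves measure.

    The pooled mean uses only the two leaves; the relative curve divides by
    :func:`fblss_all` over the full leaf list with the masked-zero
    convention.
    """
    group = str(group)
    by_id = {l.leaf_id: l for l in leaves}
    try:
        a, b = by_id[leaf_id], by_id[reference_id]
    except KeyError as err:
        raise KeyError(f"unknown leaf id {err.args[0]}") from None
    for l in (a, b):
        if l.group_counts.get(group, 0) == 0:
            raise ValueError(f"group {group!r} is absent from leaf {l.leaf_id}")
    na, nb = a.group_counts[group], b.group_counts[group]
    ma, mb = a.group_means[group], b.group_means[group]
    if leaf_id == reference_id:
        pair = np.zeros_like(ma)
    else:
        pooled = (na * ma + nb * mb) / (na + nb)
        pair = na * (ma - pooled) ** 2 + nb * (mb - pooled) ** 2
    return pair, _masked_ratio(pair, fblss_all(leaves, group))


def select_reference_leaf(
    leaves: list[LeafDiagnostics], cls: str, ranking: str = "purity"
) -> int:
    """The reference leaf for a class: among leaves predicting ``cls``, the
    one with the highest fraction of correct predictions (ties: larger leaf,
    then lower leaf id).  ``ranking="size"`` instead trades purity for
    coverage by ranking on n × purity (the count of correctly predicted
    members)."""
    cls = str(cls)
    predicting = [l for l in leaves if l.predicted_class == cls]
    if not predicting:
        raise ValueError(f"no leaf predicts class {cls!r}")
    if ranking == "purity":
        key = lambda l: (-l.purity, -l.n, l.leaf_id)
    elif ranking == "size":
        key = lambda l: (-l.purity * l.n, -l.n, l.leaf_id)
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    return min(predicting, key=key).leaf_id
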