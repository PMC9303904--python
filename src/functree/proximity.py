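"""Distances and semi-metrics between curves.

Three proximities commonly used for functional data:

* the (weighted, normalized) L2 distance between curves on a grid;
* the semi-metric of r-th order derivatives, computed analytically on a
  shared B-spline expansion;
* the semi-metric of principal-component scores — the Euclidean distance of
  truncated score vectors, which equals the L2 distance of the rank-K
  reconstructions when the eigenfunctions are orthonormal.

The score semi-metric is a proper metric on score space but only a
semi-metric on curve space (curves differing outside the retained
components are at distance zero).
"""

from __future__ import annotations

import numpy as np

from .basis import BasisExpansion, evaluate_expansion
from .curves import trapezoid_weights

__all__ = ["l2_distance", "derivative_semimetric", "fpc_semimetric"]


def l2_distance(
    x1: np.ndarray,
    x2: np.ndarray,
    grid: np.ndarray,
    w: np.ndarray | None = None,
) -> float:
    """Weighted L2 distance sqrt( ∫ (x1−x2)² w dt / ∫ w dt ).

    ``w`` is a strictly positive weight curve; by default w ≡ 1, so the
    normalization divides by the domain length.  Scaling ``w`` by any
    positive constant leaves the distance unchanged.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if x1.shape != x2.shape or x1.shape != grid.shape:
        raise ValueError("curves and grid must have equal lengths")
    if w is None:
        w = np.ones_like(grid)
    else:
        w = np.asarray(w, dtype=float)
        if w.shape != grid.shape:
            raise ValueError("weight curve must live on the same grid")
        if np.any(w <= 0):
            raise ValueError("weight curve must be strictly positive")
    quad = trapezoid_weights(grid)
    num = float(np.sum(quad * w * (x1 - x2) ** 2))
    den = float(np.sum(quad * w))
    return float(np.sqrt(num / den))


def derivative_semimetric(
    exp: BasisExpansion, i: int, j: int, r: int, n_eval: int | None = None
) -> float:
    """Semi-metric of the r-th derivatives of two expanded curves.

    sqrt( (1/|T|) ∫ (x_i^{(r)} − x_j^{(r)})² dt ) with |T| the domain
    length; the derivatives are taken analytically on the spline expansion.
    ``r`` must be below the spline order.  With ``r = 0`` this reduces to the
    unweighted L2 distance of the fitted curves.
    """
    if r >= exp.basis.order:
        raise ValueError(
            f"derivative order {r} must be < spline order {exp.basis.order}"
        )
    a, b = exp.basis.domain
    grid = np.linspace(a, b, n_eval) if n_eval else exp.grid
    d = evaluate_expansion(exp, grid, deriv=r)
    quad = trapezoid_weights(grid)
    diff = d[i] - d[j]
    return float(np.sqrt(np.sum(quad * diff**2) / (b - a)))


def fpc_semimetric(scores1: np.ndarray, scores2: np.ndarray) -> float:
    """Euclidean distance between two principal-component score vectors."""
    scores1 = np.asarray(scores1, dtype=float)
    scores2 = np.asarray(scores2, dtype=float)
    if scores1.shape != scores2.shape:
        raise ValueError("score vectors must have equal length")
    return float(np.linalg.norm(scores1 - scores2))
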