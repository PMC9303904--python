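"""B-spline basis expansions of discretely observed curves.

Curves are represented as :math:`x_i(t) \\approx \\sum_{s=1}^S c_{is}\\,\\varphi_s(t)`
where the :math:`\\varphi_s` form a B-spline system of a given order on the
curve domain.  The coefficient matrix ``C`` (one row per curve) doubles as a
feature matrix for tree classifiers, and the expansion gives analytic access
to derivatives for the derivative semi-metric.

Knots are equally spaced over the domain with boundary knots repeated to the
order; smoothing is plain least squares (no roughness penalty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .curves import CurveSet

__all__ = ["BSplineBasis", "BasisExpansion", "smooth_curves", "evaluate_expansion"]


class BSplineBasis:
    """A B-spline system of ``n_basis`` functions of a given order on ``domain``.

    ``order`` is the spline order (degree + 1); the default 4 gives cubic
    splines.  The basis satisfies the partition of unity: the S basis
    functions sum to 1 at every point of the domain.
    """

    def __init__(self, domain: tuple[float, float], n_basis: int, order: int = 4):
        a, b = float(domain[0]), float(domain[1])
        if not b > a:
            raise ValueError("domain must have positive length")
        if order < 2:
            raise ValueError("spline order must be >= 2")
        if n_basis < order:
            raise ValueError(f"n_basis ({n_basis}) must be >= order ({order})")
        self.domain = (a, b)
        self.order = int(order)
        self.n_basis = int(n_basis)
        n_interior = n_basis - order
        interior = np.linspace(a, b, n_interior + 2)[1:-1]
        self.knots = np.concatenate([np.full(order, a), interior, np.full(order, b)])

    @property
    def degree(self) -> int:
        return self.order - 1

    def design_matrix(self, grid: np.ndarray, deriv: int = 0) -> np.ndarray:
        """Evaluate the S basis functions (or their ``deriv``-th derivatives)
        at ``grid``; returns a ``(len(grid), S)`` dense matrix."""
        grid = np.asarray(grid, dtype=float)
        a, b = self.domain
        if np.any(grid < a - 1e-12) or np.any(grid > b + 1e-12):
            raise ValueError("evaluation point outside the basis domain (no extrapolation)")
        grid = np.clip(grid, a, b)
        if deriv >= self.order:
            raise ValueError(
                f"derivative order {deriv} must be < spline order {self.order}"
            )
        # identity coefficients evaluate every basis function at once
        spl = BSpline(self.knots, np.eye(self.n_basis), self.degree)
        if deriv:
            spl = spl.derivative(deriv)
        return spl(grid)


@dataclass
class BasisExpansion:
    """Coefficients of N curves in a shared B-spline basis (rows of ``coefs``)."""

    basis: BSplineBasis
    coefs: np.ndarray
    grid: np.ndarray  # the grid the expansion was fitted on

    def __post_init__(self) -> None:
        self.coefs = np.atleast_2d(np.asarray(self.coefs, dtype=float))
        self.grid = np.asarray(self.grid, dtype=float)
        if self.coefs.shape[1] != self.basis.n_basis:
            raise ValueError("coefficient width does not match the basis size")

    @property
    def n_curves(self) -> int:
        return self.coefs.shape[0]


def smooth_curves(curves: CurveSet, basis: BSplineBasis) -> BasisExpansion:
    """Least-squares fit of each curve onto the basis.

    Requires ``S <= T`` so the fit is identifiable; the design matrix must
    have full column rank (it does for equally spaced knots and a grid that
    populates every knot span).
    """
    S, T = basis.n_basis, curves.n_points
    if S > T:
        raise ValueError(
            f"underdetermined fit: n_basis ({S}) exceeds the number of grid "
            f"points ({T}); choose a smaller basis"
        )
    phi = basis.design_matrix(curves.grid)  # (T, S)
    rank = np.linalg.matrix_rank(phi)
    if rank < S:
        raise ValueError(
            f"singular design: basis evaluation matrix has rank {rank} < {S}; "
            "the grid leaves some knot spans empty"
        )
    coefs, *_ = np.linalg.lstsq(phi, curves.values.T, rcond=None)
    return BasisExpansion(basis, coefs.T, curves.grid)


def evaluate_expansion(
    exp: BasisExpansion, grid: np.ndarray, deriv: int = 0
) -> np.ndarray:
    """Evaluate each expanded curve (or its derivative) on ``grid``.

    Returns an ``(N, len(grid))`` matrix; linear in the coefficients.
    """
    phi = exp.basis.design_matrix(grid, deriv=deriv)  # (|grid|, S)
    return exp.coefs @ phi.T
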