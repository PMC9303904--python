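"""Discretely observed functional samples on a shared time grid.

A functional datum here is a curve :math:`x_i(t)` recorded at the common,
strictly increasing grid points :math:`t_1 < \\dots < t_T` spanning the domain
``[a, b]``.  All integrals in this package are approximated by the trapezoidal
rule on that grid, through the single quadrature routine defined below, so
every module agrees numerically on inner products, norms and variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CurveSet",
    "trapezoid_weights",
    "trapezoid_inner_product",
    "functional_mean",
]


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Quadrature weights ``w`` such that ``sum(w * f)`` approximates ∫ f dt.

    The weights are the standard trapezoidal ones: half the adjacent interval
    lengths at the end points, the mean of the two adjacent intervals inside.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be one-dimensional with at least 2 points")
    w = np.empty_like(grid)
    w[0] = (grid[1] - grid[0]) / 2.0
    w[-1] = (grid[-1] - grid[-2]) / 2.0
    w[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    return w


def trapezoid_inner_product(f: np.ndarray, g: np.ndarray, grid: np.ndarray) -> float:
    """L2 inner product ⟨f, g⟩ = ∫ f(t) g(t) dt by trapezoidal quadrature.

    Symmetric and bilinear; ⟨f, f⟩ ≥ 0 with equality iff ``f`` vanishes on
    the whole grid.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if f.shape != g.shape or f.shape != grid.shape:
        raise ValueError(
            f"length mismatch: f has {f.shape}, g has {g.shape}, grid has {grid.shape}"
        )
    return float(np.sum(trapezoid_weights(grid) * f * g))


def functional_mean(values: np.ndarray, member_idx) -> np.ndarray:
    """Pointwise mean curve of the rows of ``values`` selected by ``member_idx``."""
    values = np.asarray(values, dtype=float)
    member_idx = np.asarray(member_idx)
    if member_idx.size == 0:
        raise ValueError("empty group: cannot take a functional mean over no curves")
    return values[member_idx].mean(axis=0)


@dataclass
class CurveSet:
    """N discrete curves on a shared grid, with optional class labels.

    Parameters
    ----------
    grid
        Strictly increasing time points ``t_1..t_T`` (arbitrary units).
    values
        ``(N, T)`` matrix; row ``i`` holds :math:`x_i(t_j)`.
    labels
        Optional length-N class labels (stored as strings).
    """

    grid: np.ndarray
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.grid.ndim != 1:
            raise ValueError("grid must be one-dimensional")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.values.shape[1] != self.grid.size:
            raise ValueError(
                f"values have {self.values.shape[1]} columns but grid has "
                f"{self.grid.size} points"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels).astype(str)
            if self.labels.shape != (self.values.shape[0],):
                raise ValueError("labels must have one entry per curve")

    @property
    def n_curves(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid.size

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.grid[0]), float(self.grid[-1])

    @property
    def classes(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("this curve set has no labels")
        return np.unique(self.labels)

    def quadrature_weights(self) -> np.ndarray:
        return trapezoid_weights(self.grid)

    def mean_curve(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def subset(self, idx) -> "CurveSet":
        """A new :class:`CurveSet` restricted to the rows ``idx``."""
        idx = np.asarray(idx)
        labels = None if self.labels is None else self.labels[idx]
        return CurveSet(self.grid, self.values[idx], labels)

    def __len__(self) -> int:
        return self.n_curves
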