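"""Functional principal component decomposition of a curve sample.

The decomposition approximates each curve as

.. math:: x_i(t) \\approx \\bar x(t) + \\sum_{k=1}^K \\nu_{ik}\\,\\xi_k(t),

where the eigenfunctions :math:`\\xi_k` maximize the variance of the
projected scores subject to ∫ ξ_k² dt = 1 and mutual orthogonality, and the
scores are :math:`\\nu_{ik} = \\langle x_i - \\bar x, \\xi_k\\rangle`.

The covariance operator is discretized with trapezoidal quadrature weights
``W = diag(w)``: the eigenproblem of ``W^{1/2} Cov W^{1/2}`` is solved via
an SVD of the weighted, centered data matrix, and the eigenvectors are
mapped back by ``W^{-1/2}`` so that the eigenfunctions are orthonormal in
the quadrature inner product.  Sample variances of training scores equal the
eigenvalues λ_k, and Σ_k λ_k equals the integrated pointwise variance.

Curves observed later (e.g. a test set) must be projected onto the
eigenfunctions estimated on the training data, centering with the *training*
mean — refitting the decomposition on new data would produce a different,
incomparable basis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .curves import CurveSet, trapezoid_weights

__all__ = [
    "FPCAModel",
    "ScoreMatrix",
    "fit_fpca",
    "explained_variance",
    "project",
    "reconstruct",
]

log = logging.getLogger(__name__)

_RANK_RTOL = 1e-12  # eigenvalues below this fraction of λ1 are numerical noise


@dataclass
class ScoreMatrix:
    """An ``(N, K)`` matrix of principal-component scores ν_ik.

    ``eigenvalues`` records λ_k for each column so downstream consumers know
    each column's provenance.
    """

    values: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.values.shape[1] != self.eigenvalues.size:
            raise ValueError("one eigenvalue is required per score column")

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


@dataclass
class FPCAModel:
    """Trained decomposition: mean curve, eigenfunctions, eigenvalues, weights."""

    grid: np.ndarray
    mean_curve: np.ndarray
    eigenfunctions: np.ndarray  # (K, T), orthonormal under the quadrature
    eigenvalues: np.ndarray  # (K,), non-increasing
    weights: np.ndarray  # trapezoidal quadrature weights, length T
    total_variance: float  # ∫ Var[x(t)] dt of the training sample

    @property
    def n_components(self) -> int:
        return self.eigenfunctions.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "grid": self.grid.tolist(),
            "mean_curve": self.mean_curve.tolist(),
            "eigenfunctions": self.eigenfunctions.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "total_variance": self.total_variance,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "FPCAModel":
        payload = json.loads(Path(path).read_text())
        grid = np.asarray(payload["grid"], dtype=float)
        return cls(
            grid=grid,
            mean_curve=np.asarray(payload["mean_curve"], dtype=float),
            eigenfunctions=np.asarray(payload["eigenfunctions"], dtype=float),
            eigenvalues=np.asarray(payload["eigenvalues"], dtype=float),
            weights=trapezoid_weights(grid),
            total_variance=float(payload["total_variance"]),
        )


def fit_fpca(train: CurveSet, n_components: int = 15) -> tuple[FPCAModel, ScoreMatrix]:
    """Fit the decomposition on ``train`` and return the model with the
    training scores.

    ``n_components`` is capped at min(N−1, T) and at the numerical rank of
    the centered sample (eigenvalues below 1e−12·λ1 are discarded); a warning
    is logged when fewer components than requested are available.  The sign
    of each eigenfunction is fixed so that its largest-magnitude value is
    positive, which makes downstream tree thresholds reproducible.
    """
    N, T = train.n_curves, train.n_points
    if N < 2:
        raise ValueError("at least two curves are required")
    k_max = min(N - 1, T)
    if not 1 <= n_components <= k_max:
        raise ValueError(
            f"n_components must be in [1, {k_max}] for N={N}, T={T}; got {n_components}"
        )
    w = train.quadrature_weights()
    mean = train.mean_curve()
    centered = train.values - mean
    # SVD of the weighted data: eigenpairs of W^{1/2} Cov W^{1/2}
    sqrt_w = np.sqrt(w)
    Y = centered * sqrt_w / np.sqrt(N - 1)
    _, s, vt = np.linalg.svd(Y, full_matrices=False)
    lam = s**2
    # centering residues of identical curves produce eigenvalues at the
    # square of machine precision relative to the data scale
    noise_floor = (1e-12 * max(1.0, float(np.abs(train.values).max()))) ** 2
    if lam.size == 0 or lam[0] <= noise_floor:
        raise ValueError("degenerate covariance: the training curves are all identical")
    rank = int(np.sum(lam > _RANK_RTOL * lam[0]))
    if rank == 0:
        raise ValueError("degenerate covariance: the training curves are all identical")
    keep = min(n_components, rank, k_max)
    if keep < n_components:
        log.warning(
            "requested %d components but the sample supports only %d; keeping %d",
            n_components, rank, keep,
        )
    xi = vt[:keep] / sqrt_w  # back-transform: orthonormal under the quadrature
    # deterministic sign: largest-|value| entry of each eigenfunction positive
    flip = np.sign(xi[np.arange(keep), np.argmax(np.abs(xi), axis=1)])
    flip[flip == 0] = 1.0
    xi = xi * flip[:, None]
    total_variance = float(np.sum(lam[:min(rank, k_max)]))
    model = FPCAModel(
        grid=train.grid.copy(),
        mean_curve=mean,
        eigenfunctions=xi,
        eigenvalues=lam[:keep],
        weights=w,
        total_variance=total_variance,
    )
    return model, project(model, train)


def explained_variance(model: FPCAModel) -> np.ndarray:
    """Proportion of total variance carried by each retained component."""
    if model.total_variance <= 0:
        raise ValueError("model has no variance")
    return model.eigenvalues / model.total_variance


def project(model: FPCAModel, new_curves: CurveSet) -> ScoreMatrix:
    """Scores of ``new_curves`` on the trained eigenfunctions.

    Centering uses the *training* mean; the curves must live on the model's
    grid.
    """
    if new_curves.grid.shape != model.grid.shape or not np.allclose(
        new_curves.grid, model.grid
    ):
        raise ValueError("grid mismatch; resample the curves onto the training grid first")
    centered = new_curves.values - model.mean_curve
    scores = centered @ (model.eigenfunctions * model.weights).T
    return ScoreMatrix(scores, model.eigenvalues.copy())


def reconstruct(model: FPCAModel, scores: ScoreMatrix | np.ndarray) -> np.ndarray:
    """Curves implied by the scores: x̄(t) + Σ_k ν_ik ξ_k(t); ``(N, T)``."""
    values = scores.values if isinstance(scores, ScoreMatrix) else np.atleast_2d(scores)
    k = values.shape[1]
    if k > model.n_components:
        raise ValueError(
            f"scores have {k} columns but the model holds {model.n_components} components"
        )
    return model.mean_curve + values @ model.eigenfunctions[:k]
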