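"""Penalised B-spline smoothing of raw coefficient functions.

Raw per-time-point estimates are smoothed with cubic B-splines on
uniformly spaced knots and a second-order difference penalty on the
basis coefficients (P-splines). With uniform, unclamped knots the
Greville abscissae are equally spaced, so the penalty null space
contains exactly the constant and linear functions: those are
reproduced unchanged for every penalty weight. The smoother is a linear
operator ``H(lambda) = B (B'B + lambda D'D)^{-1} B'``; its matrix is
returned alongside the smoothed values so downstream variance
propagation stays exact.

The penalty weight is selected per coefficient function by generalised
cross-validation over a fixed logarithmic grid, which keeps selection
deterministic for a given input.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import linalg
from scipy.interpolate import BSpline

from .data import TimeGrid

__all__ = ["SmootherSpec", "basis_matrix", "smoother_matrix", "select_lambda", "smooth_matrix"]

DEFAULT_LAMBDA_GRID = np.logspace(-6.0, 8.0, 57)


@dataclasses.dataclass
class SmootherSpec:
    """Penalised B-spline description.

    Parameters
    ----------
    degree : spline degree (3 = cubic).
    n_basis : number of basis functions K; defaults to ``min(ceil(S/2), 30)``
        when built via :meth:`for_grid`.
    penalty_order : order of the difference penalty (2 penalises curvature).
    lam : penalty weight, a nonnegative number or ``"auto"`` (GCV).
    """

    degree: int = 3
    n_basis: int | None = None
    penalty_order: int = 2
    lam: float | str = "auto"
    lambda_grid: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_LAMBDA_GRID.copy()
    )

    @classmethod
    def for_grid(cls, grid_len: int, **kw) -> "SmootherSpec":
        spec = cls(**kw)
        if spec.n_basis is None:
            spec.n_basis = max(min(int(np.ceil(grid_len / 2)), 30), spec.degree + 1)
        return spec


def basis_matrix(x: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    """Uniform-knot B-spline basis evaluated at x (shape len(x) x n_basis)."""
    x = np.asarray(x, dtype=float)
    if n_basis < degree + 1:
        raise ValueError(f"need at least {degree + 1} basis functions")
    xmin, xmax = x.min(), x.max()
    h = (xmax - xmin) / (n_basis - degree)
    knots = xmin + (np.arange(n_basis + degree + 1) - degree) * h
    B = np.empty((x.size, n_basis))
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        B[:, j] = BSpline(knots, c, degree, extrapolate=False)(x)
    # right endpoint of the base interval is defined by left-continuity
    B[np.isnan(B)] = 0.0
    end = np.isclose(x, xmax)
    if end.any():
        for j in range(n_basis):
            c = np.zeros(n_basis)
            c[j] = 1.0
            B[end, j] = BSpline(knots, c, degree, extrapolate=True)(x[end])
    return B


def _difference_penalty(n_basis: int, order: int) -> np.ndarray:
    D = np.eye(n_basis)
    for _ in range(order):
        D = np.diff(D, axis=0)
    return D


def smoother_matrix(grid: TimeGrid, spec: SmootherSpec, lam: float) -> np.ndarray:
    """The S x S linear smoother implied by (basis, penalty, lambda)."""
    S = grid.n_points
    if spec.n_basis is None:
        raise ValueError("SmootherSpec.n_basis unset; use SmootherSpec.for_grid")
    if S < spec.n_basis:
        raise ValueError(
            f"grid has {S} points but basis has {spec.n_basis} functions; reduce n_basis"
        )
    B = basis_matrix(grid.points, spec.n_basis, spec.degree)
    D = _difference_penalty(spec.n_basis, spec.penalty_order)
    P = D.T @ D
    M = B.T @ B + lam * P
    H = B @ linalg.solve(M, B.T, assume_a="pos")
    return H


def _gcv_curve(raw: np.ndarray, B: np.ndarray, P: np.ndarray, lams: np.ndarray):
    S = raw.size
    BtB = B.T @ B
    Bty = B.T @ raw
    scores = np.empty(lams.size)
    for i, lam in enumerate(lams):
        M = BtB + lam * P
        cf = linalg.cho_factor(M, check_finite=False)
        coef = linalg.cho_solve(cf, Bty, check_finite=False)
        fitted = B @ coef
        # tr(H) = tr(M^-1 B'B)
        tr = float(np.trace(linalg.cho_solve(cf, BtB, check_finite=False)))
        rss = float(np.sum((raw - fitted) ** 2))
        denom = max(S - tr, 1e-10)
        scores[i] = S * rss / denom**2
    return scores


def select_lambda(raw: np.ndarray, grid: TimeGrid, spec: SmootherSpec):
    """GCV-optimal penalty weight over the spec's fixed logarithmic grid.

    Returns ``(lam, scores)`` where ``scores`` is the GCV criterion on the
    grid. A degenerate (constant) input returns the largest grid value
    with a warning; constants are reproduced exactly for every lambda, so
    the output is unaffected.
    """
    raw = np.asarray(raw, dtype=float)
    if spec.n_basis is None or raw.size < spec.n_basis:
        raise ValueError("need S >= n_basis (build spec with SmootherSpec.for_grid)")
    lams = np.asarray(spec.lambda_grid, dtype=float)
    if np.ptp(raw) == 0.0:
        warnings.warn("constant input to select_lambda; returning largest grid lambda")
        return float(lams[-1]), np.zeros_like(lams)
    B = basis_matrix(grid.points, spec.n_basis, spec.degree)
    D = _difference_penalty(spec.n_basis, spec.penalty_order)
    scores = _gcv_curve(raw, B, D.T @ D, lams)
    return float(lams[int(np.argmin(scores))]), scores


def select_lambda_multi(curves: np.ndarray, grid: TimeGrid, spec: SmootherSpec):
    """One GCV penalty for a bundle of curves sharing a smoother.

    ``curves`` is (n_curves, S); the criterion sums squared residuals over
    the bundle. Used to stabilise covariance-surface smoothing, where every
    row/column of the surface is a replicate curve.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    S = curves.shape[1]
    lams = np.asarray(spec.lambda_grid, dtype=float)
    if np.ptp(curves) == 0.0:
        return float(lams[-1])
    B = basis_matrix(grid.points, spec.n_basis, spec.degree)
    D = _difference_penalty(spec.n_basis, spec.penalty_order)
    P = D.T @ D
    BtB = B.T @ B
    BtY = B.T @ curves.T
    best, best_lam = np.inf, lams[-1]
    for lam in lams:
        cf = linalg.cho_factor(BtB + lam * P, check_finite=False)
        fitted = B @ linalg.cho_solve(cf, BtY, check_finite=False)
        tr = float(np.trace(linalg.cho_solve(cf, BtB, check_finite=False)))
        rss = float(np.sum((curves.T - fitted) ** 2))
        score = S * rss / max(S - tr, 1e-10) ** 2
        if score < best:
            best, best_lam = score, lam
    return float(best_lam)


def smooth_matrix(raw_matrix: np.ndarray, grid: TimeGrid, spec: SmootherSpec):
    """Smooth each column of an S x p raw-coefficient matrix.

    One penalty weight is selected per column (unless the spec fixes
    ``lam``). Returns ``(smoothed, smoothers, lambdas)`` with one S x S
    smoother matrix per column; ``smoothed[:, k]`` equals
    ``smoothers[k] @ raw_matrix[:, k]`` exactly.
    """
    raw_matrix = np.atleast_2d(np.asarray(raw_matrix, dtype=float))
    if raw_matrix.shape[0] == 1 and grid.n_points > 1:
        raw_matrix = raw_matrix.T
    S, p = raw_matrix.shape
    if S != grid.n_points:
        raise ValueError("raw matrix rows must match grid length")
    smoothed = np.empty_like(raw_matrix)
    smoothers, lambdas = [], []
    for k in range(p):
        if spec.lam == "auto":
            lam, _ = select_lambda(raw_matrix[:, k], grid, spec)
        else:
            lam = float(spec.lam)
        H = smoother_matrix(grid, spec, lam)
        smoothers.append(H)
        lambdas.append(lam)
        smoothed[:, k] = H @ raw_matrix[:, k]
    return smoothed, smoothers, lambdas
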