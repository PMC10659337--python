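"""Gaussian linear mixed model engine, fitted independently at every time-point.

Each column ``Y(s)`` of the functional outcome is modelled as

    Y(s) = X beta(s) + sum_g Z_g gamma_g(s) + eps(s),

with ``gamma_{g,l}(s) ~ N(0, Sigma_g(s))`` i.i.d. across the levels ``l``
of grouping factor ``g`` and ``eps(s) ~ N(0, sigma^2(s) I)``. Variance
components are profiled: the relative covariances ``Sigma_g / sigma^2``
are parameterised by their Cholesky factors (guaranteeing positive
semi-definiteness), the marginal covariance is inverted through the
Woodbury identity on the stacked random-effect design, and ``sigma^2``
and ``beta`` have closed forms given the Cholesky parameters. REML is the
default criterion; AIC/BIC are always reported on the ML likelihood
evaluated at the fitted components so that models are compared on a
single convention.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg, optimize

from .data import FunctionalDataset
from .formula import DesignMatrices

__all__ = ["PointwiseFit", "ConvergenceError", "fit_single", "fit_all"]

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    pass


@dataclasses.dataclass
class PointwiseFit:
    """Result of one per-time-point LMM fit."""

    s_index: int
    beta_raw: np.ndarray          # p
    cov_beta: np.ndarray          # p x p, model based
    varcomps: list[np.ndarray]    # Sigma_g per random group (q_g x q_g)
    sigma2: float                 # residual variance
    blups: list[np.ndarray]       # per group: (n_levels, q_g)
    residuals: np.ndarray         # conditional residuals, length n_used
    residuals_marginal: np.ndarray
    row_mask: np.ndarray          # bool, which dataset rows entered the fit
    hat: np.ndarray               # p x n_used GLS hat matrix (beta = hat @ y)
    loglik: float                 # at the fitted criterion (REML or ML)
    loglik_ml: float              # ML criterion at fitted components
    aic: float
    bic: float
    theta: np.ndarray             # relative-Cholesky parameters at optimum
    converged: bool
    n_obs: int
    method: str


def _theta_layout(design: DesignMatrices):
    """Slices of the packed Cholesky parameter vector, one per random group."""
    slices, sizes, start = [], [], 0
    for blk in design.random_blocks:
        m = blk.q * (blk.q + 1) // 2
        slices.append(slice(start, start + m))
        sizes.append(blk.q)
        start += m
    return slices, sizes, start


def _unpack_chol(theta_g: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.tril_indices(q)] = theta_g
    return L


class _ColumnProblem:
    """Sufficient statistics for one outcome column; shared pieces precomputed."""

    def __init__(self, X, U, blocks_meta, y, method):
        self.X, self.U = X, U
        self.blocks_meta = blocks_meta  # list of (q, n_levels)
        self.n, self.p = X.shape
        self.method = method
        self.XtX = X.T @ X
        self.UtX = U.T @ X if U is not None else None
        self.UtU = U.T @ U if U is not None else None
        # single-group designs have a level-block-diagonal U'U, so the
        # Woodbury core factorises per level; precompute the stacked blocks
        self.single = U is not None and len(blocks_meta) == 1
        if self.single:
            q, L = blocks_meta[0]
            self._q, self._L = q, L
            self.Bl = np.stack(
                [self.UtU[l * q : (l + 1) * q, l * q : (l + 1) * q] for l in range(L)]
            )
            self.UXl = self.UtX.reshape(L, q, self.p)
        self.set_y(y)

    def set_y(self, y):
        self.y = y
        self.Xty = self.X.T @ y
        self.yty = float(y @ y)
        self.Uty = self.U.T @ y if self.U is not None else None
        if getattr(self, "single", False):
            self.Uyl = self.Uty.reshape(self._L, self._q)

    def _lambda(self, theta, slices):
        """Block-diagonal relative Cholesky factor expanded over levels."""
        Q = self.U.shape[1]
        Lam = np.zeros((Q, Q))
        off = 0
        for (q, n_lev), sl in zip(self.blocks_meta, slices):
            Lg = _unpack_chol(theta[sl], q)
            for _ in range(n_lev):
                Lam[off : off + q, off : off + q] = Lg
                off += q
        return Lam

    def solve(self, theta, slices, force_generic=False):
        """Profiled quantities at the given relative-Cholesky parameters."""
        n, p = self.n, self.p
        if self.U is None or self.U.shape[1] == 0:
            XtViX, XtViy, ytViy = self.XtX, self.Xty, self.yty
            logdetM = 0.0
            Lam = cf = None
        elif self.single and not force_generic:
            q = self._q
            Lg = _unpack_chol(theta, q)
            A = np.einsum("ba,lbc,cd->lad", Lg, self.Bl, Lg)
            M = A + np.eye(q)[None]
            sign, logdets = np.linalg.slogdet(M)
            if np.any(sign <= 0):
                raise ConvergenceError("indefinite Woodbury core")
            logdetM = float(logdets.sum())
            AtX = np.einsum("ba,lbp->lap", Lg, self.UXl)
            Aty = np.einsum("ba,lb->la", Lg, self.Uyl)
            MiAtX = np.linalg.solve(M, AtX)
            MiAty = np.linalg.solve(M, Aty[..., None])[..., 0]
            XtViX = self.XtX - np.einsum("lap,laq->pq", AtX, MiAtX)
            XtViy = self.Xty - np.einsum("lap,la->p", AtX, MiAty)
            ytViy = self.yty - float(np.einsum("la,la->", Aty, MiAty))
            Lam = cf = None
        else:
            Lam = self._lambda(theta, slices)
            AtA = Lam.T @ self.UtU @ Lam
            M = AtA + np.eye(AtA.shape[0])
            cf = linalg.cho_factor(M, lower=True, check_finite=False)
            logdetM = 2.0 * np.sum(np.log(np.diag(cf[0])))
            AtX = Lam.T @ self.UtX
            Aty = Lam.T @ self.Uty
            MiAtX = linalg.cho_solve(cf, AtX, check_finite=False)
            MiAty = linalg.cho_solve(cf, Aty, check_finite=False)
            XtViX = self.XtX - AtX.T @ MiAtX
            XtViy = self.Xty - AtX.T @ MiAty
            ytViy = self.yty - self.Uty @ Lam @ MiAty
        try:
            cX = linalg.cho_factor(XtViX, check_finite=False)
        except linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular weighted cross-product: {exc}")
        beta = linalg.cho_solve(cX, XtViy, check_finite=False)
        logdetXtViX = 2.0 * np.sum(np.log(np.diag(cX[0])))
        rss = max(ytViy - beta @ XtViy, 1e-300)
        if self.method == "REML":
            sigma2 = rss / (n - p)
            neg2ll = (
                (n - p) * (np.log(sigma2) + _LOG2PI)
                + logdetM
                + logdetXtViX
                + (n - p)
            )
        else:
            sigma2 = rss / n
            neg2ll = n * (np.log(sigma2) + _LOG2PI) + logdetM + n
        return {
            "beta": beta,
            "sigma2": sigma2,
            "neg2ll": neg2ll,
            "logdetM": logdetM,
            "cho_XtViX": cX,
            "Lam": Lam,
            "cho_M": cf,
            "rss": rss,
        }

    def objective(self, theta, slices):
        try:
            return self.solve(theta, slices)["neg2ll"]
        except (ConvergenceError, linalg.LinAlgError, FloatingPointError):
            return 1e12

    def ml_loglik(self, theta, slices):
        """ML criterion at the given components (used for AIC/BIC)."""
        n = self.n
        if self.U is None or self.U.shape[1] == 0:
            sol = self.solve(theta, slices)
            rss_ml = sol["rss"]
            logdetM = 0.0
        else:
            sol = self.solve(theta, slices)
            rss_ml = sol["rss"]
            logdetM = sol["logdetM"]
        sigma2_ml = rss_ml / n
        return -0.5 * (n * (np.log(sigma2_ml) + _LOG2PI) + logdetM + n)


def _finalize(problem: _ColumnProblem, design, theta, slices, s_index, row_mask,
              converged, method):
    sol = problem.solve(theta, slices, force_generic=True)
    n, p = problem.n, problem.p
    beta = sol["beta"]
    sigma2 = sol["sigma2"]
    cov_beta = sol["sigma2"] * linalg.cho_solve(
        sol["cho_XtViX"], np.eye(p), check_finite=False
    )
    cov_beta = 0.5 * (cov_beta + cov_beta.T)

    # GLS hat matrix H with beta = H y: H = (X'V~^-1 X)^-1 X'V~^-1
    X, U = problem.X, problem.U
    if U is None or U.shape[1] == 0:
        XtVi = X.T
    else:
        Lam, cf = sol["Lam"], sol["cho_M"]
        AtX = Lam.T @ problem.UtX
        XtVi = X.T - (linalg.cho_solve(cf, AtX, check_finite=False)).T @ Lam.T @ U.T
    hat = linalg.cho_solve(sol["cho_XtViX"], XtVi, check_finite=False)

    resid_marg = problem.y - X @ beta
    varcomps, blups = [], []
    if U is not None and U.shape[1] > 0:
        Lam, cf = sol["Lam"], sol["cho_M"]
        Utr = problem.Uty - problem.UtX @ beta
        Atr = Lam.T @ Utr
        # gamma_hat = Lam Lam' U' Vbar^-1 r  (relative scale cancels sigma^2)
        UtVir = Utr - problem.UtU @ Lam @ linalg.cho_solve(cf, Atr, check_finite=False)
        gam = Lam @ Lam.T @ UtVir
        off = 0
        for blk, sl in zip(design.random_blocks, slices):
            Lg = _unpack_chol(theta[sl], blk.q)
            varcomps.append(sigma2 * (Lg @ Lg.T))
            g = gam[off : off + blk.q * blk.n_levels].reshape(blk.n_levels, blk.q)
            blups.append(g)
            off += blk.q * blk.n_levels
        resid_cond = resid_marg - U @ gam
    else:
        resid_cond = resid_marg.copy()

    ll = -0.5 * sol["neg2ll"]
    ll_ml = problem.ml_loglik(theta, slices)
    k = p + theta.size + 1
    aic = -2.0 * ll_ml + 2.0 * k
    bic = -2.0 * ll_ml + k * np.log(n)
    return PointwiseFit(
        s_index=s_index,
        beta_raw=beta,
        cov_beta=cov_beta,
        varcomps=varcomps,
        sigma2=float(sigma2),
        blups=blups,
        residuals=resid_cond,
        residuals_marginal=resid_marg,
        row_mask=row_mask,
        hat=hat,
        loglik=float(ll),
        loglik_ml=float(ll_ml),
        aic=float(aic),
        bic=float(bic),
        theta=theta.copy(),
        converged=converged,
        n_obs=n,
        method=method,
    )


def _default_start(design: DesignMatrices) -> np.ndarray:
    slices, sizes, total = _theta_layout(design)
    theta = np.zeros(total)
    for q, sl in zip(sizes, slices):
        L = 0.5 * np.eye(q)
        theta[sl] = L[np.tril_indices(q)]
    return theta


def _optimize_theta(problem, slices, theta0):
    """Minimise the (restricted) deviance; deterministic multi-start fallback."""
    if theta0.size == 0:
        return theta0, True
    best = None
    for scale in (1.0, 0.1, 10.0):
        start = theta0 * scale if scale != 1.0 else theta0
        res = optimize.minimize(
            problem.objective,
            start,
            args=(slices,),
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            return best.x, True
    if best is not None and np.isfinite(best.fun):
        return best.x, False
    raise ConvergenceError("variance-component optimisation failed")


def _column_data(dataset: FunctionalDataset, design: DesignMatrices, s_index: int):
    y = dataset.Y[:, s_index]
    mask = np.isfinite(y)
    X = design.X[mask]
    y = y[mask]
    U = None
    blocks_meta = []
    if design.random_blocks:
        U = np.hstack([blk.Z[mask] for blk in design.random_blocks])
        blocks_meta = [(blk.q, blk.n_levels) for blk in design.random_blocks]
    return X, U, blocks_meta, y, mask


def fit_vector(
    y: np.ndarray,
    design: DesignMatrices,
    method: str = "REML",
    start: np.ndarray | None = None,
    s_index: int = 0,
) -> PointwiseFit:
    """Fit the mixed model to a plain outcome vector (scalar-LMM path)."""
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    X = design.X[mask]
    yv = y[mask]
    U = None
    blocks_meta = []
    if design.random_blocks:
        U = np.hstack([blk.Z[mask] for blk in design.random_blocks])
        blocks_meta = [(blk.q, blk.n_levels) for blk in design.random_blocks]
    return _fit_masked(X, U, blocks_meta, yv, mask, design, method, start, s_index)


def _fit_masked(X, U, blocks_meta, y, mask, design, method, start, s_index):
    qtot = sum(q * nl for q, nl in blocks_meta)
    if X.shape[0] < X.shape[1]:
        raise ConvergenceError(
            f"column {s_index}: fewer rows ({X.shape[0]}) than fixed-effect columns"
        )
    if X.shape[0] < X.shape[1] + qtot:
        raise ConvergenceError(
            f"column {s_index}: not enough observations for the random-effect dimension"
        )
    problem = _ColumnProblem(X, U, blocks_meta, y, method)
    slices, _, total = _theta_layout(design)
    theta0 = start if start is not None else _default_start(design)
    theta, ok = _optimize_theta(problem, slices, np.asarray(theta0, dtype=float))
    return _finalize(problem, design, theta, slices, s_index, mask, ok, method)


def fit_single(
    dataset: FunctionalDataset,
    design: DesignMatrices,
    s_index: int,
    method: str = "REML",
    start: np.ndarray | None = None,
) -> PointwiseFit:
    """Fit the LMM to a single time-point column."""
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    X, U, blocks_meta, y, mask = _column_data(dataset, design, s_index)
    return _fit_masked(X, U, blocks_meta, y, mask, design, method, start, s_index)


def fit_all(
    dataset: FunctionalDataset,
    design: DesignMatrices,
    method: str = "REML",
    workers: int = 1,
) -> list[PointwiseFit]:
    """Fit every column of the functional outcome.

    Column 0 is fitted from the common default start; every other column
    starts from column 0's solution. Results are therefore identical for
    any worker count and any execution order. Columns whose optimiser
    fails even after the deterministic restarts are flagged and their
    ``beta_raw`` / ``cov_beta`` linearly interpolated from the nearest
    converged neighbours (they are excluded from covariance estimation
    downstream). More than 20% failed columns is an error.
    """
    S = dataset.n_timepoints
    first = fit_single(dataset, design, 0, method=method)
    start = first.theta

    def _one(s):
        try:
            return fit_single(dataset, design, s, method=method, start=start)
        except ConvergenceError:
            return None

    if workers and workers > 1:
        from joblib import Parallel, delayed

        rest = Parallel(n_jobs=workers)(delayed(_one)(s) for s in range(1, S))
    else:
        rest = [_one(s) for s in range(1, S)]
    fits: list = [first] + list(rest)

    failed = [s for s, f in enumerate(fits) if f is None or not f.converged]
    if len(failed) > 0.2 * S:
        raise ConvergenceError(
            f"{len(failed)}/{S} columns failed to converge; simplify the model"
        )
    good = [s for s, f in enumerate(fits) if f is not None and f.converged]
    for s in failed:
        if fits[s] is not None:
            continue  # flagged non-converged but usable estimates kept
        lo = max((g for g in good if g < s), default=None)
        hi = min((g for g in good if g > s), default=None)
        if lo is None or hi is None:
            src = fits[hi if lo is None else lo]
            beta, cov = src.beta_raw, src.cov_beta
        else:
            w = (s - lo) / (hi - lo)
            beta = (1 - w) * fits[lo].beta_raw + w * fits[hi].beta_raw
            cov = (1 - w) * fits[lo].cov_beta + w * fits[hi].cov_beta
        proto = fits[lo if lo is not None else hi]
        fits[s] = dataclasses.replace(
            proto,
            s_index=s,
            beta_raw=beta,
            cov_beta=cov,
            converged=False,
        )
    return fits
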