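"""Cross-time covariance of coefficient functions, and confidence bands.

The pointwise engine treats every time-point separately, so it cannot say
how the estimation errors of ``beta_hat(s1)`` and ``beta_hat(s2)`` covary —
yet that covariance is exactly what a simultaneous (joint) band needs.
Here it is estimated by a method-of-moments construction that remains
valid under nested random-effect specifications:

1. For every pair of time-points, the cross-covariances of the
   random-effect vectors ``G_g(s1, s2) = Cov(gamma_g(s1), gamma_g(s2))``
   and of the residual curves ``R(s1, s2)`` are identified from moment
   equations in the *marginal* residual cross-products (block sums
   ``Z_g' e(s1) e(s2)' Z_g`` and the elementwise product sum
   ``sum_i e_i(s1) e_i(s2)``). The moment equations form one small linear
   system, assembled once from the random-effect designs, that is solved
   simultaneously for all time-point pairs.
2. The covariance of the raw GLS estimators follows from the sandwich
   ``Cov(b(s1), b(s2)) = H(s1) Cov(Y(s1), Y(s2)) H(s2)'`` with ``H(s)``
   the per-column GLS hat matrix.
3. Smoothing is linear, so the covariance of the smoothed coefficient
   function is the raw surface pre/post-multiplied by the smoother
   matrix. The result is symmetrised and projected to the nearest
   positive semi-definite matrix by truncating negative eigenvalues;
   its diagonal defines the pointwise standard errors.

The joint multiplier is the empirical ``level`` quantile of
``max_s |Z_s| / sqrt(cov[s,s])`` over draws of ``Z ~ N(0, cov)``, clipped
from below at the pointwise normal quantile so the joint band always
contains the pointwise band.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import lmm, smoothing
from .data import FunctionalDataset
from .formula import DesignMatrices, ModelFormula, build_design

__all__ = [
    "CoefficientBand",
    "ModelInformation",
    "estimate_beta_covariance",
    "joint_multiplier",
    "build_bands",
    "significant_intervals",
    "cluster_bootstrap_bands",
    "model_information",
]

DEFAULT_NSIM_JOINT = 10_000
DEFAULT_JOINT_SEED = 20_240_915  # fixed constant, recorded in output metadata


@dataclasses.dataclass
class CoefficientBand:
    """Smoothed coefficient function with pointwise and joint 95% bands."""

    name: str
    time: np.ndarray
    estimate: np.ndarray
    se: np.ndarray
    pw_level: float
    joint_level: float
    q_joint: float
    pw_bounds: np.ndarray     # S x 2
    joint_bounds: np.ndarray  # S x 2
    cov_full: np.ndarray | None = None
    degenerate: np.ndarray | None = None  # bool mask where se == 0


def _scatter_rows(values: np.ndarray, mask: np.ndarray, n: int, axis: int = 0):
    if mask.all():
        return values
    out_shape = list(values.shape)
    out_shape[axis] = n
    out = np.zeros(out_shape)
    idx = [slice(None)] * values.ndim
    idx[axis] = mask
    out[tuple(idx)] = values
    return out


def _moment_system(Zt_list: list[np.ndarray], blocks, n: int, p: int):
    """Coefficient matrix of the moment equations (independent of s).

    ``Zt_list`` holds the OLS-projected block designs ``P0 Z_g`` (with
    ``P0 = I - X (X'X)^-1 X'``). Working in the projected space removes
    the fixed-effect estimation from the moment equations exactly: the
    statistics ``Z_g' P0 Y(s)`` have mean zero, and their second moments
    are linear in the unknown ``G_g(s1, s2)`` and ``R(s1, s2)`` with the
    coefficients assembled here. The projection couples levels, so all
    level pairs contribute.
    """
    sizes = [blk.q**2 for blk in blocks]
    m = sum(sizes) + 1
    A = np.zeros((m, m))
    offs = np.cumsum([0] + sizes)
    for gi, bg in enumerate(blocks):
        rows = slice(offs[gi], offs[gi + 1])
        for hi, bh in enumerate(blocks):
            cols = slice(offs[hi], offs[hi + 1])
            M = Zt_list[gi].T @ Zt_list[hi]  # (Lg qg) x (Lh qh)
            acc = np.zeros((bg.q**2, bh.q**2))
            for l in range(bg.n_levels):
                for lp in range(bh.n_levels):
                    C = M[l * bg.q : (l + 1) * bg.q, lp * bh.q : (lp + 1) * bh.q]
                    if not C.any():
                        continue
                    acc += np.kron(C, C)
            A[rows, cols] = acc
        M = Zt_list[gi].T @ Zt_list[gi]
        Sg = np.zeros((bg.q, bg.q))
        for l in range(bg.n_levels):
            Sg += M[l * bg.q : (l + 1) * bg.q, l * bg.q : (l + 1) * bg.q]
        A[rows, -1] = Sg.reshape(-1)
        A[-1, offs[gi] : offs[gi + 1]] = Sg.reshape(-1)
    A[-1, -1] = n - p
    return A, offs


def _surface_smoother(grid, G_surfaces) -> np.ndarray:
    """Shared P-spline smoother for the random-effect covariance surfaces."""
    spec = smoothing.SmootherSpec.for_grid(grid.n_points)
    curves = np.vstack([G.reshape(-1, grid.n_points) for G in G_surfaces])
    lam = smoothing.select_lambda_multi(curves, grid, spec)
    return smoothing.smoother_matrix(grid, spec, lam)


def estimate_beta_covariance(
    fits: list[lmm.PointwiseFit],
    smoothers: list[np.ndarray] | None,
    design: DesignMatrices,
    dataset: FunctionalDataset,
    return_components: bool = False,
):
    """Method-of-moments S x S covariance of each smoothed coefficient function.

    ``smoothers`` is one S x S smoother matrix per fixed-effect coefficient
    (or None for the identity, i.e. the covariance of the raw estimators).
    Columns flagged non-convergent are excluded from the moment equations;
    their rows/columns of the surface use interpolated hat matrices.
    Returns a list of symmetrised, PSD-projected S x S matrices.
    """
    S = len(fits)
    n = dataset.n_trials
    p = design.p
    converged = np.array([f.converged for f in fits])
    if not converged.any():
        raise RuntimeError("no converged columns; covariance unavailable")

    # OLS-projected outcome: E0 = P0 Y with P0 = I - X (X'X)^-1 X'.
    # Missing samples are zero-filled (their rows were excluded from the
    # per-column fits; at typical missingness this is a second-order effect).
    X = design.X
    Yf = np.nan_to_num(dataset.Y, nan=0.0)
    pinvX = np.linalg.pinv(X)
    E = Yf - X @ (pinvX @ Yf)
    if not np.isfinite(E).all():
        raise RuntimeError("non-finite residual cross-products")

    # full-row GLS hat matrices (p x n per column)
    hats = np.zeros((S, p, n))
    for s, f in enumerate(fits):
        hats[s][:, f.row_mask] = f.hat

    blocks = design.random_blocks
    if blocks:
        Zt_list = [blk.Z - X @ (pinvX @ blk.Z) for blk in blocks]
        A, offs = _moment_system(Zt_list, blocks, n, p)
        stats_rows = []
        for bg, Zt in zip(blocks, Zt_list):
            W = (Zt.T @ Yf).reshape(bg.n_levels, bg.q, S)
            # T_g(s1,s2)[a,b] = sum_l W[l,a,s1] W[l,b,s2]
            T = np.einsum("las,lbt->abst", W, W)
            stats_rows.append(T.reshape(bg.q**2, S * S))
        stats_rows.append((E.T @ E).reshape(1, S * S))
        Tall = np.vstack(stats_rows)
        Uhat = np.linalg.lstsq(A, Tall, rcond=None)[0]
        G_surfaces = [
            Uhat[offs[g] : offs[g + 1]].reshape(bg.q, bg.q, S, S)
            for g, bg in enumerate(blocks)
        ]
        R_surface = Uhat[-1].reshape(S, S)
        G_surfaces_raw = G_surfaces
        if S >= 8:
            # The random-effect surfaces are estimated from as many
            # cross-products as there are grouping levels, so they are far
            # noisier than the residual surface; smooth them bivariately
            # (P-spline sandwich, GCV-selected penalty) before assembly.
            Hb = _surface_smoother(dataset.grid, G_surfaces)
            G_surfaces = [
                np.einsum("su,abuv,tv->abst", Hb, G, Hb) for G in G_surfaces
            ]
    else:
        G_surfaces = []
        G_surfaces_raw = []
        # no random effects: residual cross-covariance averaged over rows
        R_surface = (E.T @ E) / max(n - p, 1)

    covs = []
    components = []
    v_model = np.array([[f.cov_beta[k, k] for f in fits] for k in range(p)])
    for k in range(p):
        Hk = hats[:, k, :]  # S x n
        R_part = R_surface * (Hk @ Hk.T)
        C = R_part.copy()
        C_mult = R_part.copy()  # unsmoothed-surface version for the multiplier
        for bg, G, Graw in zip(blocks, G_surfaces, G_surfaces_raw):
            Rk = (Hk @ bg.Z).reshape(S, bg.n_levels, bg.q)
            K = np.einsum("sla,tlb->abst", Rk, Rk)
            C = C + np.einsum("abst,abst->st", G, K)
            C_mult = C_mult + np.einsum("abst,abst->st", Graw, K)
        # Variance-noise model for the max-t multiplier. In a balanced
        # cluster design the model-based variance of a coefficient behaves
        # like max(between-cluster sample variance, residual floor) over the
        # cluster count: a Wishart field with (clusters - 1) degrees of
        # freedom — correlated along the grid like the raw coefficient
        # covariance — truncated from below at the residual-variance share
        # (the REML zero-boundary on the random-effect component).
        if blocks:
            df_k = max(min(bg.n_levels for bg in blocks) - 1, 1)
            dC = np.clip(np.diag(C_mult), 1e-12, None)
            floor = np.clip(np.diag(R_part) / dC, 0.0, 1.0)
            dd = np.sqrt(dC)
            pc = C_mult / np.outer(dd, dd)
            pc = np.clip(0.5 * (pc + pc.T), -1.0, 1.0)
            np.fill_diagonal(pc, 1.0)
            components.append({"df": df_k, "floor_share": floor, "corr": pc})
        else:
            components.append(None)
        if blocks:
            # Anchor the scale to the model-based (REML) per-column variances:
            # the moment estimates identify the cross-time-point *correlation*
            # well, but their diagonal is far noisier than the constrained
            # likelihood-based variances when there are few grouping levels.
            d = np.diag(C).copy()
            ok = d > 0
            fac = np.ones(S)
            fac[ok] = np.sqrt(v_model[k, ok] / d[ok])
            C = C * np.outer(fac, fac)
        target = None
        if smoothers is not None:
            Hs = smoothers[k]
            trC = float(np.trace(C))
            C = Hs @ C @ Hs.T
            if blocks and trC > 0:
                # Stabilised diagonal for the smoothed estimator: the
                # model-based variances scaled by one global smoothing
                # reduction factor. Pointwise reduction factors inherit the
                # correlation-surface noise and produce spurious dips in the
                # standard errors; the trace ratio is stable and, with
                # autocorrelated raw estimates, close to the true reduction.
                r = min(max(float(np.trace(C)) / trC, 0.0), 1.0)
                target = v_model[k] * r
        C = 0.5 * (C + C.T)
        w, V = np.linalg.eigh(C)
        w = np.clip(w, 0.0, None)
        C = (V * w) @ V.T
        C = 0.5 * (C + C.T)
        if target is not None:
            d = np.diag(C).copy()
            ok = d > 0
            fac = np.zeros(S)
            fac[ok] = np.sqrt(target[ok] / d[ok])
            C = C * np.outer(fac, fac)
        covs.append(C)
    if return_components:
        return covs, components
    return covs


def joint_multiplier(
    cov: np.ndarray,
    level: float = 0.95,
    n_sim: int = DEFAULT_NSIM_JOINT,
    seed: int = DEFAULT_JOINT_SEED,
    var_components=None,
) -> float:
    """Simultaneous critical value from the max-standardised-deviation law.

    Empirical ``level`` quantile of ``max_s |Z_s|/sqrt(cov[s,s])`` over
    ``n_sim`` draws ``Z ~ N(0, cov)`` (numpy Generator ``PCG64`` seeded with
    ``seed``), clipped from below at the pointwise normal quantile.
    Invariant to positive rescaling of ``cov``.

    ``var_components``, when given, is a dict describing the sampling noise
    of the standard-error field, with keys ``df`` (degrees of freedom of
    the between-cluster variance, typically clusters - 1),
    ``floor_share`` (per-time-point share of the variance coming from the
    residual floor — the REML zero-boundary), and ``corr`` (grid
    correlation of the underlying effect curves, or None for a global
    scale). Each Gaussian draw is then divided by
    ``sqrt(max(W(s), floor_share(s)))`` where ``W`` is a Wishart-type
    field (mean of ``df`` squared correlated Gaussian curves). This max-t
    analogue widens the band to reflect variance-estimation noise when
    grouping levels are few, while the floor reproduces the truncation of
    the variance estimate at its residual component.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")
    cov = np.asarray(cov, dtype=float)
    d = np.diag(cov).copy()
    keep = d > 0
    if not keep.all():
        warnings.warn("zero-variance time-points excluded from joint multiplier")
    z = stats.norm.ppf(0.5 + level / 2.0)
    if not keep.any():
        return float(z)
    sub = cov[np.ix_(keep, keep)]
    sd = np.sqrt(np.diag(sub))
    corr = sub / np.outer(sd, sd)
    corr = 0.5 * (corr + corr.T)
    w, V = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    keep_w = w > 1e-10 * max(w.max(), 1.0)
    root = V[:, keep_w] * np.sqrt(w[keep_w])
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_sim, root.shape[1])) @ root.T
    if var_components:
        Sk = int(keep.sum())
        df = int(var_components["df"])
        floor = np.asarray(var_components.get("floor_share", 0.0), dtype=float)
        floor = (floor[keep] if floor.ndim else np.full(Sk, float(floor)))
        comp_corr = var_components.get("corr")
        if comp_corr is None:
            W = np.repeat(rng.chisquare(df, size=n_sim)[:, None] / df, Sk, axis=1)
        else:
            cc = np.asarray(comp_corr, dtype=float)[np.ix_(keep, keep)]
            wc, Vc = np.linalg.eigh(0.5 * (cc + cc.T))
            wc = np.clip(wc, 0.0, None)
            kc = wc > 1e-10 * max(wc.max(), 1.0)
            rootc = Vc[:, kc] * np.sqrt(wc[kc])
            g = rng.standard_normal((n_sim * df, rootc.shape[1])) @ rootc.T
            W = np.mean(g.reshape(n_sim, df, Sk) ** 2, axis=1)
        denom2 = np.maximum(W, floor[None, :])
        draws = draws / np.sqrt(np.clip(denom2, 1e-12, None))
    maxdev = np.max(np.abs(draws), axis=1)
    q = float(np.quantile(maxdev, level))
    return float(max(q, z))


def build_bands(
    estimate: np.ndarray,
    cov: np.ndarray,
    level: float,
    q_joint: float,
    name: str = "coef",
    time: np.ndarray | None = None,
) -> CoefficientBand:
    """Pointwise and joint bands around a smoothed coefficient function."""
    estimate = np.asarray(estimate, dtype=float)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = stats.norm.ppf(0.5 + level / 2.0)
    pw = np.column_stack([estimate - z * se, estimate + z * se])
    joint = np.column_stack([estimate - q_joint * se, estimate + q_joint * se])
    degenerate = se == 0.0
    if time is None:
        time = np.arange(estimate.size, dtype=float)
    return CoefficientBand(
        name=name,
        time=np.asarray(time, dtype=float),
        estimate=estimate,
        se=se,
        pw_level=level,
        joint_level=level,
        q_joint=float(q_joint),
        pw_bounds=pw,
        joint_bounds=joint,
        cov_full=cov,
        degenerate=degenerate,
    )


def significant_intervals(band: CoefficientBand, which: str = "joint"):
    """Maximal time intervals over which the chosen band excludes zero.

    Returns a list of ``(t_start, t_end)`` pairs in seconds, in time order.
    """
    if which == "joint":
        bounds = band.joint_bounds
    elif which == "pointwise":
        bounds = band.pw_bounds
    else:
        raise ValueError("which must be 'joint' or 'pointwise'")
    excl = (bounds[:, 0] > 0.0) | (bounds[:, 1] < 0.0)
    intervals = []
    start = None
    for i, flag in enumerate(excl):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(band.time[start]), float(band.time[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(band.time[start]), float(band.time[-1])))
    return intervals


@dataclasses.dataclass
class ModelInformation:
    """Aggregate fit criteria over converged columns (shared ML convention)."""

    aic: float
    bic: float
    n_columns: int
    column_set: frozenset

    def assert_comparable(self, other: "ModelInformation"):
        if self.column_set != other.column_set:
            raise ValueError(
                "models were fitted on different converged-column sets "
                f"({sorted(self.column_set ^ other.column_set)} differ); "
                "refit on a common set before comparing AIC/BIC"
            )


def model_information(fits: list[lmm.PointwiseFit]) -> ModelInformation:
    cols = [f.s_index for f in fits if f.converged]
    aic = float(sum(f.aic for f in fits if f.converged))
    bic = float(sum(f.bic for f in fits if f.converged))
    return ModelInformation(aic=aic, bic=bic, n_columns=len(cols), column_set=frozenset(cols))


def cluster_bootstrap_bands(
    dataset: FunctionalDataset,
    formula: ModelFormula,
    B: int = 500,
    seed: int = 0,
    level: float = 0.95,
    center="default",
    spec: smoothing.SmootherSpec | None = None,
    method: str = "REML",
):
    """Cluster bootstrap over subjects: percentile pointwise and max-deviation joint bands.

    Subjects are resampled with replacement (all their trials carried
    along, resampled subjects relabelled so duplicates are distinct
    grouping levels) and the pointwise-fit + smoothing pipeline is refit
    per replicate. Smoothing penalties are fixed at the values selected on
    the original data so replicates differ only through resampling.
    Replicates that draw a single distinct subject are redrawn (count
    reported in the returned log).
    """
    if B < 200:
        raise ValueError("bootstrap needs B >= 200 replicates")
    subjects = pd.unique(dataset.trials["subject"])
    if len(subjects) < 3:
        raise ValueError("cluster bootstrap needs at least 3 subjects")
    design = build_design(formula, dataset.trials, center=center)
    if spec is None:
        spec = smoothing.SmootherSpec.for_grid(dataset.n_timepoints)
    fits = lmm.fit_all(dataset, design, method=method)
    raw = np.column_stack([f.beta_raw for f in fits])  # p x S -> transpose below
    raw = raw.T
    smoothed0, _, lambdas = smoothing.smooth_matrix(raw, dataset.grid, spec)
    fixed_spec = dataclasses.replace(spec)

    rng = np.random.default_rng(seed)
    p = design.p
    S = dataset.n_timepoints
    boot = np.empty((B, S, p))
    redraws = 0
    groups = {s: np.where(dataset.trials["subject"].to_numpy() == s)[0] for s in subjects}
    b = 0
    while b < B:
        draw = rng.choice(subjects, size=len(subjects), replace=True)
        if len(set(draw)) < 2:
            redraws += 1
            continue
        rows, labels = [], []
        for j, s in enumerate(draw):
            idx = groups[s]
            rows.append(idx)
            labels.extend([f"bs{j}"] * idx.size)
        rows = np.concatenate(rows)
        trials = dataset.trials.iloc[rows].reset_index(drop=True)
        trials["subject"] = labels
        ds_b = FunctionalDataset(Y=dataset.Y[rows], grid=dataset.grid, trials=trials)
        try:
            design_b = build_design(formula, trials, center=center)
            fits_b = lmm.fit_all(ds_b, design_b, method=method)
        except (lmm.ConvergenceError, Exception):
            redraws += 1
            if redraws > 10 * B:
                raise RuntimeError("bootstrap: too many failed replicates")
            continue
        raw_b = np.column_stack([f.beta_raw for f in fits_b]).T
        for k in range(p):
            fixed_spec.lam = lambdas[k]
            H = smoothing.smoother_matrix(dataset.grid, fixed_spec, lambdas[k])
            boot[b, :, k] = H @ raw_b[:, k]
        b += 1

    z = stats.norm.ppf(0.5 + level / 2.0)
    bands = []
    alpha = 1.0 - level
    for k in range(p):
        bk = boot[:, :, k]
        est = smoothed0[:, k]
        se = bk.std(axis=0, ddof=1)
        pw = np.column_stack(
            [np.quantile(bk, alpha / 2, axis=0), np.quantile(bk, 1 - alpha / 2, axis=0)]
        )
        sd = np.where(se > 0, se, 1.0)
        maxdev = np.max(np.abs(bk - bk.mean(axis=0)) / sd, axis=1)
        q = max(float(np.quantile(maxdev, level)), z)
        joint = np.column_stack([est - q * se, est + q * se])
        bands.append(
            CoefficientBand(
                name=design.fixed_names[k],
                time=dataset.grid.points,
                estimate=est,
                se=se,
                pw_level=level,
                joint_level=level,
                q_joint=q,
                pw_bounds=pw,
                joint_bounds=joint,
                cov_full=None,
                degenerate=se == 0.0,
            )
        )
    return bands, {"redraws": redraws, "B": B, "seed": seed}
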