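"""Model/results interface for functional linear mixed models.

`FLMM` is constructed from a :class:`~flmm.data.FunctionalDataset` and an
lme4-style formula; :meth:`FLMM.fit` runs the full pipeline — per-time-point
mixed-model fits, penalised-spline smoothing of each coefficient function,
method-of-moments covariance across time-points, and pointwise plus joint
confidence bands — and returns an :class:`FLMMResults` carrying the bands,
random-effect curves, fit criteria and metadata.

    >>> model = FLMM("photometry ~ delay + (delay | id)", dataset)
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import inference, lmm, smoothing
from .data import FunctionalDataset, write_result_tables
from .formula import ModelFormula, build_design, parse_formula

__all__ = ["FLMM", "FLMMResults"]


class FLMM:
    """Functional linear mixed model for trial-structured signal data.

    Parameters
    ----------
    formula : str or ModelFormula
        e.g. ``"photometry ~ delay + (delay | id)"`` — fixed terms plus
        lme4-style random-effect blocks, with ``a/b`` nesting.
    data : FunctionalDataset
        Trial x time signal matrix with trial covariates and time grid.
    center : "default" | bool | dict
        Covariate centering policy (default: mean-center numeric
        covariates, never 0/1 indicators).
    smoother : SmootherSpec, optional
        Penalised B-spline settings; defaults to cubic splines with
        ``K = min(ceil(S/2), 30)`` basis functions and GCV-selected
        penalties.
    """

    def __init__(self, formula, data: FunctionalDataset, center="default", smoother=None):
        self.formula = (
            parse_formula(formula) if isinstance(formula, str) else formula
        )
        # canonical row order: results must not depend on how trials were
        # stored on disk, so all sufficient statistics are accumulated in
        # (subject, session, trial) order
        order = data.trials.sort_values(
            ["subject", "session", "trial"], kind="mergesort"
        ).index.to_numpy()
        self.data = data.subset_rows(order)
        self.center = center
        self.smoother = smoother or smoothing.SmootherSpec.for_grid(data.n_timepoints)
        self.design = build_design(self.formula, self.data.trials, center=center)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        formula,
        signal_prefix: str = "sig",
        time_start: float = 0.0,
        rate: float = 15.0,
        **kw,
    ) -> "FLMM":
        """Build the model from a wide-format DataFrame (see load_wide_csv dialect)."""
        import io

        from .data import load_wide_csv

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        ds = load_wide_csv(buf, signal_prefix=signal_prefix, time_start=time_start, rate=rate)
        return cls(formula, ds, **kw)

    def fit(
        self,
        method: str = "REML",
        alpha: float = 0.05,
        n_sim_joint: int = inference.DEFAULT_NSIM_JOINT,
        seed: int = inference.DEFAULT_JOINT_SEED,
        workers: int = 1,
        smooth_blups: bool = False,
    ) -> "FLMMResults":
        """Run the estimation pipeline and return the fitted results."""
        if not 0.0 < alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        level = 1.0 - alpha
        fits = lmm.fit_all(self.data, self.design, method=method, workers=workers)
        raw = np.column_stack([f.beta_raw for f in fits]).T  # S x p
        if self.data.n_timepoints >= (self.smoother.n_basis or 4):
            smoothed, smoothers, lambdas = smoothing.smooth_matrix(
                raw, self.data.grid, self.smoother
            )
        else:  # grid too short to smooth: identity
            smoothed = raw
            smoothers = [np.eye(self.data.n_timepoints)] * self.design.p
            lambdas = [0.0] * self.design.p
        covs, var_components = inference.estimate_beta_covariance(
            fits, smoothers, self.design, self.data, return_components=True
        )
        bands = []
        for k, name in enumerate(self.design.fixed_names):
            qk = inference.joint_multiplier(
                covs[k],
                level=level,
                n_sim=n_sim_joint,
                seed=(int(seed) + 7919 * k) % (2**31 - 1),
                var_components=var_components[k],
            )
            bands.append(
                inference.build_bands(
                    smoothed[:, k],
                    covs[k],
                    level,
                    qk,
                    name=name,
                    time=self.data.grid.points,
                )
            )

        random_curves = {}
        for g, blk in enumerate(self.design.random_blocks):
            curves = np.stack([f.blups[g] for f in fits], axis=-1)  # levels x q x S
            if smooth_blups:
                for li in range(curves.shape[0]):
                    for qi in range(curves.shape[1]):
                        sm, _, _ = smoothing.smooth_matrix(
                            curves[li, qi][:, None], self.data.grid, self.smoother
                        )
                        curves[li, qi] = sm[:, 0]
            random_curves[blk.grouping] = {
                "levels": blk.levels,
                "terms": blk.term_names,
                "curves": curves,
            }

        info = inference.model_information(fits)
        meta = {
            "formula": str(self.formula),
            "method": method,
            "alpha": alpha,
            "n_sim_joint": n_sim_joint,
            "seed": int(seed),
            "rng": "numpy PCG64",
            "likelihood_convention": "AIC/BIC from ML criterion at fitted components",
            "aic": info.aic,
            "bic": info.bic,
            "n_converged_columns": info.n_columns,
            "n_columns": self.data.n_timepoints,
            "n_trials": self.data.n_trials,
            "smoother": {
                "basis": "uniform cubic B-splines",
                "n_basis": self.smoother.n_basis,
                "penalty_order": self.smoother.penalty_order,
                "selection": "GCV" if self.smoother.lam == "auto" else "fixed",
                "lambdas": [float(l) for l in lambdas],
            },
            "centering": dict(self.design.centering),
            "package_version": _pkg_version,
        }
        return FLMMResults(
            model=self,
            bands=bands,
            random_curves=random_curves,
            fits=fits,
            information=info,
            info=meta,
        )


class FLMMResults:
    """Fitted coefficient functions with uncertainty bands and diagnostics."""

    def __init__(self, model, bands, random_curves, fits, information, info):
        self.model = model
        self.bands = bands
        self.random_curves = random_curves
        self.fits = fits
        self.information = information
        self.info = info

    # -- access -------------------------------------------------------------
    def band(self, name: str) -> inference.CoefficientBand:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(
            f"no coefficient named '{name}'; available: {[b.name for b in self.bands]}"
        )

    @property
    def coef_names(self) -> list[str]:
        return [b.name for b in self.bands]

    def coefficients(self) -> pd.DataFrame:
        out = {"time": self.bands[0].time}
        for b in self.bands:
            out[b.name] = b.estimate
        return pd.DataFrame(out)

    def significant_intervals(self, name: str, which: str = "joint"):
        return inference.significant_intervals(self.band(name), which=which)

    @property
    def aic(self) -> float:
        return self.information.aic

    @property
    def bic(self) -> float:
        return self.information.bic

    # -- output -------------------------------------------------------------
    def summary(self) -> str:
        lines = []
        w = 72
        lines.append("Functional Linear Mixed Model".center(w))
        lines.append("=" * w)
        lines.append(f"Formula:        {self.info['formula']}")
        lines.append(
            f"Trials: {self.info['n_trials']}    Time-points: {self.info['n_columns']}"
            f"    Method: {self.info['method']}"
        )
        lines.append(
            f"AIC: {self.aic:.1f}    BIC: {self.bic:.1f}    "
            f"converged columns: {self.info['n_converged_columns']}/{self.info['n_columns']}"
        )
        lines.append("-" * w)
        lines.append(
            f"{'coefficient':<22}{'max |est|':>10}{'q_joint':>9}  significant (joint)"
        )
        for b in self.bands:
            ivals = inference.significant_intervals(b, "joint")
            txt = ", ".join(f"[{a:.2f}, {c:.2f}]" for a, c in ivals) or "none"
            lines.append(
                f"{b.name:<22}{np.max(np.abs(b.estimate)):>10.3f}{b.q_joint:>9.3f}  {txt}"
            )
        lines.append("=" * w)
        lines.append(
            f"Joint bands: {int(round(self.bands[0].joint_level * 100))}% simultaneous, "
            f"max-deviation multiplier over {self.info['n_sim_joint']} draws "
            f"(seed {self.info['seed']})."
        )
        return "\n".join(lines)

    def to_tables(self, out_dir):
        return write_result_tables(self, out_dir)

    def plot(self, name: str | None = None, **kw):
        from . import plotting

        if name is None:
            return [plotting.plot_coefficient(b, **kw) for b in self.bands]
        return plotting.plot_coefficient(self.band(name), **kw)
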