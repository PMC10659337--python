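"""Windowed trial summaries (AUC) and the scalar baseline analyses.

These are the comparators the functional model is evaluated against: a
window summary per trial (mean amplitude or trapezoidal integral,
optionally baseline-subtracted), a paired t-test on subject-by-condition
means, a scalar linear mixed model with random intercept and slope by
subject, and per-session regressions parameterised so the intercept is
the expected first-trial value.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import simpson

from . import lmm
from .data import FunctionalDataset
from .formula import parse_formula, build_design

__all__ = [
    "WindowSpec",
    "compute_auc",
    "scalar_baselines",
    "ScalarBaselineResult",
    "sessionwise_regression",
]


@dataclasses.dataclass
class WindowSpec:
    """Closed time window (seconds relative to alignment), optional baseline window.

    ``mode`` is ``"mean"`` (average amplitude, computed as the Simpson
    time-integral divided by the window length so the value is stable
    under sampling-rate refinement; default, comparable across windows of
    unequal length) or ``"integral"`` (trapezoidal area).
    """

    main: tuple
    baseline: tuple | None = None
    mode: str = "mean"

    def __post_init__(self):
        a, b = self.main
        if not a < b:
            raise ValueError("window start must precede end")
        if self.baseline is not None and not self.baseline[0] < self.baseline[1]:
            raise ValueError("baseline start must precede end")
        if self.mode not in ("mean", "integral"):
            raise ValueError("mode must be 'mean' or 'integral'")


def _window_value(Y: np.ndarray, grid, interval, mode: str) -> np.ndarray:
    idx = grid.window_indices(*interval)
    if idx.size == 0:
        raise ValueError(f"window {interval} contains no grid points")
    sub = Y[:, idx]
    t = grid.points[idx]
    if mode == "mean":
        if idx.size == 1:
            return sub[:, 0]
        return simpson(sub, x=t, axis=1) / (t[-1] - t[0])
    return np.trapezoid(sub, t, axis=1)


def compute_auc(dataset: FunctionalDataset, spec: WindowSpec) -> np.ndarray:
    """Per-trial window summary; baseline window subtracted when given."""
    val = _window_value(dataset.Y, dataset.grid, spec.main, spec.mode)
    if spec.baseline is not None:
        val = val - _window_value(dataset.Y, dataset.grid, spec.baseline, spec.mode)
    return val


@dataclasses.dataclass
class ScalarBaselineResult:
    t_statistic: float
    t_df: int
    t_pvalue: float
    mean_difference: float
    lmm_estimate: float
    lmm_se: float
    lmm_ci: tuple
    lmm_pvalue: float
    n_subjects_paired: int
    excluded_subjects: list


def scalar_baselines(
    auc: np.ndarray, trials: pd.DataFrame, condition: str, alpha: float = 0.05
) -> ScalarBaselineResult:
    """Paired t-test and scalar LMM on a per-trial summary measure.

    The paired t-test compares subject-by-condition means; subjects seen
    in only one condition are excluded with a warning. The LMM regresses
    the trial-level summary on the binary condition with a random
    intercept and condition slope per subject; the condition effect, its
    Wald CI and p-value are returned.
    """
    df = trials.copy()
    df["_auc"] = np.asarray(auc, dtype=float)
    cond_vals = np.sort(df[condition].unique())
    if cond_vals.size != 2:
        raise ValueError(f"condition '{condition}' must be binary, saw {cond_vals}")
    means = df.groupby(["subject", condition])["_auc"].mean().unstack()
    complete = means.dropna()
    excluded = sorted(set(means.index) - set(complete.index))
    if excluded:
        warnings.warn(f"subjects observed in one condition only excluded: {excluded}")
    if len(complete) < 2:
        raise ValueError("paired t-test needs at least 2 subjects in both conditions")
    a = complete[cond_vals[0]].to_numpy()
    b = complete[cond_vals[1]].to_numpy()
    diffs = b - a
    if np.ptp(diffs) == 0.0:
        # degenerate: no between-subject variability in the difference
        t_stat = 0.0 if diffs[0] == 0.0 else np.sign(diffs[0]) * np.inf
        t_p = 1.0 if diffs[0] == 0.0 else 0.0
        tt = type("TT", (), {"statistic": t_stat, "pvalue": t_p})
    else:
        tt = stats.ttest_rel(b, a)

    formula = parse_formula(f"_auc ~ {condition} + ({condition} | subject)")
    design = build_design(formula, df, center=False)
    fit = lmm.fit_vector(df["_auc"].to_numpy(), design, method="REML")
    k = design.fixed_names.index(condition)
    est = float(fit.beta_raw[k])
    se = float(np.sqrt(fit.cov_beta[k, k]))
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else 1.0
    return ScalarBaselineResult(
        t_statistic=float(tt.statistic),
        t_df=len(complete) - 1,
        t_pvalue=float(tt.pvalue),
        mean_difference=float(np.mean(b - a)),
        lmm_estimate=est,
        lmm_se=se,
        lmm_ci=(est - z * se, est + z * se),
        lmm_pvalue=float(p),
        n_subjects_paired=len(complete),
        excluded_subjects=excluded,
    )


def sessionwise_regression(auc: np.ndarray, trials: pd.DataFrame):
    """Per-session OLS with first-trial intercepts, plus the pooled regression.

    Within each (subject, session) the summary is regressed on
    ``trial - 1``, so the intercept is the expected value on the first
    trial of that session. The pooled fit regresses the summary on the
    cumulative reward number across sessions. Returns
    ``(per_session_frame, pooled)`` where ``pooled`` has keys ``slope``
    and ``intercept``.
    """
    df = trials.copy()
    df["_auc"] = np.asarray(auc, dtype=float)
    if "reward_number" not in df.columns:
        df = df.sort_values(["subject", "session", "trial"])
        df["reward_number"] = df.groupby("subject").cumcount() + 1.0
    recs = []
    for (subj, sess), g in df.groupby(["subject", "session"]):
        if len(g) < 2:
            warnings.warn(f"singleton session ({subj}, {sess}) skipped")
            continue
        x = g["trial"].to_numpy(dtype=float) - 1.0
        y = g["_auc"].to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        recs.append(
            {
                "subject": subj,
                "session": sess,
                "slope": float(slope),
                "first_trial_intercept": float(intercept),
                "n_trials": len(g),
            }
        )
    per_session = pd.DataFrame(recs)
    x = df["reward_number"].to_numpy(dtype=float)
    y = df["_auc"].to_numpy()
    pslope, pintercept = np.polyfit(x, y, 1)
    pooled = {"slope": float(pslope), "intercept": float(pintercept)}
    return per_session, pooled
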