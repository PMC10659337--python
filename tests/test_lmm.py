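import numpy as np
import pandas as pd
import pytest

import flmm
from flmm import lmm
from flmm.data import FunctionalDataset, TimeGrid
from flmm.formula import build_design, parse_formula


def _one_way(g=6, m=8, sd_between=1.3, sd_within=0.9, seed=0):
    """Balanced one-way random-intercept data with its trial table."""
    rng = np.random.default_rng(seed)
    rows, y = [], []
    for i in range(g):
        b = rng.normal(0, sd_between)
        for j in range(m):
            rows.append((f"s{i+1}", 1, j + 1))
            y.append(2.0 + b + rng.normal(0, sd_within))
    trials = pd.DataFrame(rows, columns=["subject", "session", "trial"])
    return np.asarray(y), trials


def test_balanced_one_way_matches_closed_form_reml():
    """Between = (MSB - MSW)/m, within = MSW for the balanced one-way layout."""
    g, m = 6, 8
    y, trials = _one_way(g, m)
    design = build_design(parse_formula("y ~ 1 + (1 | subject)"), trials)
    fit = lmm.fit_vector(y, design)
    means = y.reshape(g, m).mean(axis=1)
    grand = y.mean()
    msb = m * np.sum((means - grand) ** 2) / (g - 1)
    msw = np.sum((y.reshape(g, m) - means[:, None]) ** 2) / (g * (m - 1))
    assert fit.sigma2 == pytest.approx(msw, rel=1e-5)
    assert fit.varcomps[0][0, 0] == pytest.approx(max((msb - msw) / m, 0.0), rel=1e-4)
    assert fit.beta_raw[0] == pytest.approx(grand, rel=1e-8)


def test_zero_between_group_variability_collapses_to_ols():
    rng = np.random.default_rng(1)
    rows, y = [], []
    x_all = []
    for i in range(5):
        for j in range(20):
            x = rng.normal()
            rows.append((f"s{i+1}", 1, j + 1, x))
            y.append(1.0 + 0.5 * x + rng.normal(0, 0.4))
            x_all.append(x)
    trials = pd.DataFrame(rows, columns=["subject", "session", "trial", "x"])
    y = np.asarray(y)
    design = build_design(parse_formula("y ~ x + (1 | subject)"), trials, center=False)
    fit = lmm.fit_vector(y, design)
    X = np.column_stack([np.ones(len(y)), x_all])
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    np.testing.assert_allclose(fit.beta_raw, ols, atol=1e-4)


def test_local_optimality_of_reml_solution():
    """Perturbing each fitted component by ±10% never improves the criterion."""
    y, trials = _one_way(seed=3)
    design = build_design(parse_formula("y ~ 1 + (1 | subject)"), trials)
    fit = lmm.fit_vector(y, design)
    from flmm.lmm import _ColumnProblem, _theta_layout

    prob = _ColumnProblem(design.X, design.random_blocks[0].Z, [(1, 6)], y, "REML")
    slices, _, _ = _theta_layout(design)
    base = prob.objective(fit.theta, slices)
    for j in range(fit.theta.size):
        for f in (0.9, 1.1):
            th = fit.theta.copy()
            th[j] *= f
            assert prob.objective(th, slices) >= base - 1e-6


def test_matches_statsmodels_mixedlm():
    """Cross-implementation oracle: random intercept + slope vs MixedLM."""
    smf = pytest.importorskip("statsmodels.formula.api")
    rng = np.random.default_rng(42)
    rows = []
    for i in range(20):
        g0, g1 = rng.normal(0, 1.5), rng.normal(0, 1.0)
        for j in range(40):
            x = rng.normal()
            rows.append((f"s{i+1}", 1, j + 1, x,
                         1.0 + g0 + (0.5 + g1) * x + rng.normal(0, 0.8)))
    df = pd.DataFrame(rows, columns=["subject", "session", "trial", "x", "y"])
    design = build_design(parse_formula("y ~ x + (x | subject)"), df, center=False)
    fit = lmm.fit_vector(df["y"].to_numpy(), design)
    md = smf.mixedlm("y ~ x", df, groups=df["subject"], re_formula="~x")
    ref = md.fit(reml=True, method=["lbfgs"], maxiter=2000)
    for _ in range(2):  # polish to the optimum so the oracle itself converges
        ref = md.fit(reml=True, method=["bfgs"], start_params=ref.params,
                     maxiter=2000, gtol=1e-10)
    np.testing.assert_allclose(fit.beta_raw, ref.fe_params.values, rtol=1e-4)
    np.testing.assert_allclose(
        np.sqrt(np.diag(fit.cov_beta)), ref.bse_fe.values, rtol=1e-4
    )
    # variance components agree less tightly: the restricted likelihood is
    # much flatter in them than in the fixed effects
    np.testing.assert_allclose(fit.varcomps[0], ref.cov_re.values, rtol=5e-2)
    assert fit.sigma2 == pytest.approx(ref.scale, rel=1e-3)


def test_intercept_only_no_random_effects():
    rng = np.random.default_rng(5)
    y = rng.normal(size=40)
    trials = pd.DataFrame(
        {"subject": ["s1"] * 40, "session": 1, "trial": np.arange(1, 41)}
    )
    design = build_design(parse_formula("y ~ 1"), trials)
    fit = lmm.fit_vector(y, design)
    assert fit.beta_raw[0] == pytest.approx(y.mean())
    assert fit.cov_beta[0, 0] == pytest.approx(np.var(y, ddof=1) / 40)


def test_fit_all_deterministic_across_workers(small_dataset):
    ds, _ = small_dataset
    design = build_design(parse_formula("photometry ~ delay + (delay | id)"), ds.trials)
    f1 = lmm.fit_all(ds, design, workers=1)
    f2 = lmm.fit_all(ds, design, workers=2)
    b1 = np.array([f.beta_raw for f in f1])
    b2 = np.array([f.beta_raw for f in f2])
    np.testing.assert_array_equal(b1, b2)


def test_single_timepoint_fit_all_equals_fit_single(toy_dataset):
    ds1 = FunctionalDataset(
        Y=toy_dataset.Y[:, :1],
        grid=TimeGrid(points=toy_dataset.grid.points[:1], rate=toy_dataset.grid.rate),
        trials=toy_dataset.trials,
    )
    design = build_design(parse_formula("y ~ delay + (1 | subject)"), ds1.trials)
    all_fits = lmm.fit_all(ds1, design)
    single = lmm.fit_single(ds1, design, 0)
    assert len(all_fits) == 1
    np.testing.assert_allclose(all_fits[0].beta_raw, single.beta_raw, atol=1e-10)
    assert all_fits[0].aic == pytest.approx(single.aic)


def test_blups_sum_to_zero_in_balanced_design():
    y, trials = _one_way(seed=11)
    design = build_design(parse_formula("y ~ 1 + (1 | subject)"), trials)
    fit = lmm.fit_vector(y, design)
    assert abs(fit.blups[0].sum()) < 1e-6 * max(abs(fit.blups[0]).max(), 1.0)


def test_psd_invariants(small_dataset):
    ds, _ = small_dataset
    design = build_design(parse_formula("photometry ~ delay + (delay | id)"), ds.trials)
    fit = lmm.fit_single(ds, design, 10)
    w = np.linalg.eigvalsh(fit.cov_beta)
    assert w.min() >= -1e-10
    for vc in fit.varcomps:
        assert np.linalg.eigvalsh(vc).min() >= -1e-10
    assert fit.sigma2 > 0


def test_too_few_rows_is_error():
    """Missing samples can leave a column with fewer rows than coefficients."""
    rng = np.random.default_rng(0)
    trials = pd.DataFrame(
        {"subject": ["a"] * 10, "session": 1, "trial": np.arange(1, 11),
         "x": rng.normal(size=10), "x2": rng.normal(size=10),
         "x3": rng.normal(size=10)}
    )
    design = build_design(parse_formula("y ~ x + x2 + x3"), trials, center=False)
    y = np.full(10, np.nan)
    y[:2] = [0.1, 0.2]
    with pytest.raises(lmm.ConvergenceError, match="fewer rows"):
        lmm.fit_vector(y, design)


def test_noise_covariate_increases_bic():
    """Adding a pure-noise fixed covariate raises aggregate BIC in most draws."""
    from flmm.inference import model_information

    wins = 0
    R = 60
    for r in range(R):
        rng = np.random.default_rng(100 + r)
        y, trials = _one_way(g=5, m=8, seed=200 + r)
        trials = trials.copy()
        trials["junk"] = rng.normal(size=len(trials))
        grid = TimeGrid.regular(0.0, 1, 15.0)
        ds = FunctionalDataset(Y=y[:, None], grid=grid, trials=trials)
        d0 = build_design(parse_formula("y ~ 1 + (1 | subject)"), trials)
        d1 = build_design(parse_formula("y ~ junk + (1 | subject)"), trials)
        i0 = model_information(lmm.fit_all(ds, d0))
        i1 = model_information(lmm.fit_all(ds, d1))
        i0.assert_comparable(i1)
        wins += i1.bic > i0.bic
    assert wins >= 0.9 * R
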