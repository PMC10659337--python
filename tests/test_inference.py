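import numpy as np
import pandas as pd
import pytest
from scipy import stats

import flmm
from flmm import inference, lmm, smoothing
from flmm.data import FunctionalDataset, TimeGrid
from flmm.formula import build_design, parse_formula


# ---------------------------------------------------------------------------
# joint multiplier


def test_multiplier_single_point_is_normal_quantile():
    q = inference.joint_multiplier(np.array([[2.0]]), 0.95, n_sim=100_000, seed=1)
    assert q == pytest.approx(1.959964, abs=0.02)


def test_multiplier_perfect_correlation_is_normal_quantile():
    cov = np.ones((20, 20))  # rank one, equal variances
    q = inference.joint_multiplier(cov, 0.95, n_sim=100_000, seed=2)
    assert q == pytest.approx(1.959964, abs=0.02)


def test_multiplier_independent_matches_closed_form():
    S = 10
    q = inference.joint_multiplier(np.eye(S), 0.95, n_sim=200_000, seed=3)
    expected = stats.norm.ppf((1.0 + 0.95 ** (1.0 / S)) / 2.0)
    assert q == pytest.approx(expected, abs=0.03)


def test_multiplier_scale_invariant():
    rng = np.random.default_rng(4)
    A = rng.normal(size=(15, 15))
    cov = A @ A.T
    q1 = inference.joint_multiplier(cov, 0.95, n_sim=5000, seed=5)
    q2 = inference.joint_multiplier(37.5 * cov, 0.95, n_sim=5000, seed=5)
    assert q1 == pytest.approx(q2, rel=1e-9)


def test_multiplier_validations():
    with pytest.raises(ValueError, match="n_sim"):
        inference.joint_multiplier(np.eye(3), 0.95, n_sim=10, seed=0)
    with pytest.raises(ValueError, match="level"):
        inference.joint_multiplier(np.eye(3), 1.5, n_sim=2000, seed=0)
    with pytest.warns(UserWarning, match="zero-variance"):
        cov = np.diag([1.0, 0.0, 1.0])
        q = inference.joint_multiplier(cov, 0.95, n_sim=2000, seed=0)
    assert q >= 1.959


def test_multiplier_with_variance_noise_model_is_wider():
    cov = np.eye(12)
    q0 = inference.joint_multiplier(cov, 0.95, n_sim=20_000, seed=6)
    qt = inference.joint_multiplier(
        cov, 0.95, n_sim=20_000, seed=6,
        var_components={"df": 5, "floor_share": np.zeros(12), "corr": None},
    )
    assert qt > q0


# ---------------------------------------------------------------------------
# bands


def test_band_arithmetic():
    est = np.zeros(5)
    cov = np.eye(5)
    band = inference.build_bands(est, cov, 0.95, q_joint=2.5)
    np.testing.assert_allclose(band.joint_bounds[:, 0], -2.5)
    np.testing.assert_allclose(band.joint_bounds[:, 1], 2.5)
    np.testing.assert_allclose(
        band.pw_bounds[:, 1] - band.pw_bounds[:, 0], 2 * 1.959964, rtol=1e-5
    )
    width_ratio = (band.joint_bounds[:, 1] - band.joint_bounds[:, 0]) / (
        band.pw_bounds[:, 1] - band.pw_bounds[:, 0]
    )
    np.testing.assert_allclose(width_ratio, 2.5 / 1.959964, rtol=1e-6)


def test_zero_se_degenerates_to_point_estimate():
    cov = np.diag([1.0, 0.0, 1.0])
    band = inference.build_bands(np.array([1.0, 2.0, 3.0]), cov, 0.95, 2.0)
    assert band.degenerate[1]
    assert band.joint_bounds[1, 0] == band.joint_bounds[1, 1] == 2.0


@pytest.mark.parametrize(
    "lower_sig, expected",
    [
        ([(10, 20)], [(10, 20)]),
        ([], []),
        ([(3, 5), (12, 14)], [(3, 5), (12, 14)]),
    ],
)
def test_significant_interval_extraction(lower_sig, expected):
    S = 30
    time = np.arange(S, dtype=float)
    lower = -np.ones(S)
    upper = np.ones(S)
    for a, b in lower_sig:
        lower[a : b + 1] = 0.5  # band excludes zero on [a, b]
    band = inference.CoefficientBand(
        name="c", time=time, estimate=np.zeros(S), se=np.ones(S),
        pw_level=0.95, joint_level=0.95, q_joint=2.0,
        pw_bounds=np.column_stack([lower, upper]),
        joint_bounds=np.column_stack([lower, upper]),
    )
    got = inference.significant_intervals(band, "joint")
    assert got == [(float(a), float(b)) for a, b in expected]


# ---------------------------------------------------------------------------
# method-of-moments covariance


def _iid_dataset(n=300, S=8, seed=0):
    rng = np.random.default_rng(seed)
    trials = pd.DataFrame(
        {"subject": ["s1"] * n, "session": 1, "trial": np.arange(1, n + 1),
         "x": rng.normal(size=n)}
    )
    Y = 0.5 + trials["x"].to_numpy()[:, None] * 0.3 + rng.normal(size=(n, S))
    grid = TimeGrid.regular(0.0, S, 15.0)
    return FunctionalDataset(Y=Y, grid=grid, trials=trials)


def test_no_random_effects_diagonal_matches_pointwise():
    """Independent homoskedastic errors, identity smoother: MoM diagonal
    equals the per-column OLS covariance and off-diagonals are near zero."""
    ds = _iid_dataset()
    design = build_design(parse_formula("y ~ x"), ds.trials, center=False)
    fits = lmm.fit_all(ds, design)
    covs = inference.estimate_beta_covariance(fits, None, design, ds)
    S = ds.n_timepoints
    for k in range(2):
        diag = np.diag(covs[k])
        model = np.array([f.cov_beta[k, k] for f in fits])
        np.testing.assert_allclose(diag, model, rtol=1e-6)
        off = covs[k][~np.eye(S, dtype=bool)]
        # zero-mean cross-column covariances: 3 MC SEs of 0
        assert np.abs(off).max() < 3.5 * model.max() / np.sqrt(300 / 3)


def test_subject_intercept_induces_distant_correlation():
    """A subject random intercept constant in s makes beta_0 estimates
    correlated across distant time-points; MoM recovers it near the truth."""
    rng = np.random.default_rng(1)
    S, n_sub, T = 8, 40, 25
    sd_b, sd_e = 1.0, 0.7
    rows, Y = [], []
    for i in range(n_sub):
        b = rng.normal(0, sd_b)
        for j in range(T):
            rows.append((f"s{i+1}", 1, j + 1))
            Y.append(b + rng.normal(0, sd_e, size=S))
    trials = pd.DataFrame(rows, columns=["subject", "session", "trial"])
    ds = FunctionalDataset(Y=np.asarray(Y), grid=TimeGrid.regular(0, S, 15.0), trials=trials)
    design = build_design(parse_formula("y ~ 1 + (1 | subject)"), trials)
    fits = lmm.fit_all(ds, design)
    covs = inference.estimate_beta_covariance(fits, None, design, ds)
    C = covs[0]
    corr_far = C[0, S - 1] / np.sqrt(C[0, 0] * C[S - 1, S - 1])
    # truth: Var(beta0) ~ sd_b^2/n + sd_e^2/(nT); distant corr = share of sd_b^2/n
    truth = (sd_b**2 / n_sub) / (sd_b**2 / n_sub + sd_e**2 / (n_sub * T))
    assert corr_far > 0.5
    assert corr_far == pytest.approx(truth, abs=0.15)


def test_covariance_is_symmetric_psd(small_dataset):
    ds, _ = small_dataset
    design = build_design(parse_formula("photometry ~ delay + (delay | id)"), ds.trials)
    fits = lmm.fit_all(ds, design)
    raw = np.column_stack([f.beta_raw for f in fits]).T
    spec = smoothing.SmootherSpec.for_grid(ds.n_timepoints)
    _, smoothers, _ = smoothing.smooth_matrix(raw, ds.grid, spec)
    covs = inference.estimate_beta_covariance(fits, smoothers, design, ds)
    for C in covs:
        np.testing.assert_array_equal(C, C.T)
        assert np.linalg.eigvalsh(C).min() >= -1e-10


# ---------------------------------------------------------------------------
# model information and bootstrap


def test_information_comparison_guard():
    a = inference.ModelInformation(aic=1.0, bic=2.0, n_columns=3, column_set=frozenset({0, 1, 2}))
    b = inference.ModelInformation(aic=1.0, bic=2.0, n_columns=2, column_set=frozenset({0, 1}))
    with pytest.raises(ValueError, match="different converged-column sets"):
        a.assert_comparable(b)


def test_bootstrap_validations(toy_dataset):
    mf = parse_formula("photometry ~ delay")
    with pytest.raises(ValueError, match="B >= 200"):
        inference.cluster_bootstrap_bands(toy_dataset, mf, B=2, seed=0)
    with pytest.raises(ValueError, match="3 subjects"):
        inference.cluster_bootstrap_bands(toy_dataset, mf, B=200, seed=0)


def test_bootstrap_deterministic_and_near_analytic():
    """Same seed gives identical bands; widths are near the analytic bands."""
    truth = flmm.delay_template(n_subjects=10, trials_per_session=6,
                                grid=TimeGrid.regular(-0.5, 12, 15.0))
    ds, _ = flmm.generate_functional(truth, 77)
    mf = parse_formula("photometry ~ delay + (1 | subject)")
    bands1, log1 = inference.cluster_bootstrap_bands(ds, mf, B=200, seed=9)
    bands2, _ = inference.cluster_bootstrap_bands(ds, mf, B=200, seed=9)
    for b1, b2 in zip(bands1, bands2):
        np.testing.assert_array_equal(b1.joint_bounds, b2.joint_bounds)
    res = flmm.FLMM("photometry ~ delay + (1 | subject)", ds).fit(seed=9)
    k = res.coef_names.index("delay")
    wa = np.mean(res.bands[k].pw_bounds[:, 1] - res.bands[k].pw_bounds[:, 0])
    wb = np.mean(bands1[k].pw_bounds[:, 1] - bands1[k].pw_bounds[:, 0])
    assert wb == pytest.approx(wa, rel=0.35)
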