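import dataclasses

import numpy as np
import pytest

import flmm
from flmm import simulate
from flmm.data import TimeGrid


def test_noiseless_limit_reproduces_mean_model():
    grid = TimeGrid.regular(-1.0, 20, 15.0)
    t = grid.points
    S = grid.n_points
    zero = np.zeros((S, S))
    truth = simulate.SimTruth(
        grid=grid,
        beta={"1": simulate.bump(t, 1.0, 0.2, 0.3), "delay": simulate.bump(t, 0.5, 0.5, 0.2)},
        Sigma_gamma={},
        Sigma_eps_base=[zero],
        eps_scale=5.0,
        n_subjects=3,
        n_sessions=2,
        trials_per_session=4,
    )
    ds, _ = simulate.generate_functional(truth, seed=0)
    x = ds.trials["delay"].to_numpy()
    expected = truth.beta["1"][None, :] + x[:, None] * truth.beta["delay"][None, :]
    np.testing.assert_array_equal(ds.Y, expected)


def test_random_curve_moments_match_target_covariance():
    """Empirical covariance of many drawn subject curves matches the target."""
    grid = TimeGrid.regular(0.0, 10, 15.0)
    C = simulate.default_covariances(grid, "squared-exponential", 0.5, 0.4)
    truth = simulate.SimTruth(
        grid=grid,
        beta={"1": np.zeros(10)},
        Sigma_gamma={"1": C},
        Sigma_eps_base=[np.zeros((10, 10))],
        n_subjects=2000,
        n_sessions=1,
        trials_per_session=1,
        condition=None,
    )
    _, lat = simulate.generate_functional(truth, seed=3)
    g = lat["gammas"]["1"]
    emp = np.cov(g.T)
    mc_se = C[0, 0] * np.sqrt(2.0 / 2000)
    assert np.abs(emp - C).max() < 3.5 * mc_se


def test_base_index_rule():
    rng = np.random.default_rng(0)
    # n <= M: a permutation subset, no repeats
    for _ in range(20):
        idx = simulate.assign_base_indices(5, 7, rng)
        assert len(set(idx.tolist())) == 5
        assert set(idx.tolist()) <= set(range(7))
    # n > M: first M are the identity, remainder drawn without replacement
    for _ in range(20):
        idx = simulate.assign_base_indices(10, 7, rng)
        np.testing.assert_array_equal(idx[:7], np.arange(7))
        extra = idx[7:]
        assert len(set(extra.tolist())) == 3
        assert set(extra.tolist()) <= set(range(7))


def test_error_covariance_scale_factor():
    truth = flmm.delay_template()
    for m in range(truth.n_base):
        used = truth.eps_covariance(m)
        ratio = np.trace(used) / np.trace(truth.Sigma_eps_base[m])
        assert ratio == pytest.approx(5.0, abs=1e-12)


def test_generator_defaults_match_design_constants():
    truth = flmm.delay_template()
    assert truth.trials_per_session == 100
    assert truth.grid.rate == 15.0
    assert truth.eps_scale == 5.0
    assert truth.n_base == 7
    cfg = simulate.EventConfig()
    assert cfg.iri_mean == 14.0


def test_trial_events_counters_and_iri():
    cfg = simulate.EventConfig()
    tab = simulate.generate_trial_events(cfg, n_sessions=3, trials_per_session=100, seed=5)
    np.testing.assert_array_equal(tab["reward_number"], np.arange(1, 301))
    np.testing.assert_array_equal(tab["trial_number"], np.tile(np.arange(1, 101), 3))
    np.testing.assert_array_equal(tab["session_number"], np.repeat([1, 2, 3], 100))
    tab2 = simulate.generate_trial_events(cfg, 3, 100, seed=5)
    np.testing.assert_array_equal(tab["iri"], tab2["iri"])
    big = simulate.generate_trial_events(cfg, 1, 100_000, seed=6)
    se = 14.0 / np.sqrt(100_000)
    assert abs(big["iri"].mean() - 14.0) < 3 * se


def test_seed_changes_draws_not_structure():
    truth = flmm.delay_template(n_subjects=3, trials_per_session=5)
    d1, _ = simulate.generate_functional(truth, 1)
    d2, _ = simulate.generate_functional(truth, 2)
    assert d1.Y.shape == d2.Y.shape
    assert d1.trials.equals(d2.trials)
    assert not np.allclose(d1.Y, d2.Y)
    d1b, _ = simulate.generate_functional(truth, 1)
    np.testing.assert_array_equal(d1.Y, d1b.Y)


def test_covariance_family_limits():
    grid = TimeGrid.regular(0.0, 12, 15.0)
    tiny = simulate.default_covariances(grid, "squared-exponential", 2.0, (1 / 15.0) / 100)
    np.testing.assert_allclose(tiny, 2.0 * np.eye(12), atol=1e-6)
    for fam in ("squared-exponential", "AR1"):
        C = simulate.default_covariances(grid, fam, 3.0, 0.4)
        np.testing.assert_array_equal(C, C.T)
        np.testing.assert_allclose(np.diag(C / 3.0), np.ones(12))
        assert np.linalg.eigvalsh(C).min() >= -1e-10
    with pytest.raises(ValueError):
        simulate.default_covariances(grid, "squared-exponential", -1.0, 0.4)


def test_mean_model_law_of_large_numbers():
    truth = flmm.delay_template(n_subjects=6, trials_per_session=80)
    ds, _ = simulate.generate_functional(truth, seed=9)
    long = ds.trials["delay"].to_numpy() == 1.0
    diff = ds.Y[long].mean(axis=0) - ds.Y[~long].mean(axis=0)
    bt = truth.beta["delay"]
    n_per = long.sum()
    var = (truth.Sigma_gamma["delay"][0, 0] / truth.n_subjects
           + 2 * 5 * 0.55 / n_per)
    assert np.abs(diff - bt).max() < 4 * np.sqrt(var)


def test_simpsons_pooled_slope_positive():
    """Pooled summary regression recovers a positive slope in nearly all draws."""
    from flmm.summaries import WindowSpec, compute_auc, sessionwise_regression

    wins = 0
    R = 100
    for r in range(R):
        ds, truth = flmm.simpsons_template(seed=r)
        auc = compute_auc(ds, WindowSpec(main=(0.0, 1.5), mode="mean"))
        _, pooled = sessionwise_regression(auc, ds.trials)
        wins += pooled["slope"] > 0
    assert wins >= 0.95 * R


def test_simpsons_requires_opposite_signs():
    with pytest.raises(ValueError, match="opposite signs"):
        flmm.simpsons_template(between_slope=0.4, within_slope=0.1, seed=0)


def test_recovery_improves_with_sample_size():
    """Integrated squared error of the recovered condition effect shrinks
    as the number of subjects grows (averaged over replicates)."""
    ise = {}
    for n in (4, 7, 14):
        errs = []
        for r in range(6):
            truth = flmm.delay_template(n_subjects=n, trials_per_session=12)
            ds, _ = simulate.generate_functional(truth, seed=1000 * n + r)
            res = flmm.FLMM("photometry ~ delay + (delay | id)", ds).fit(
                seed=r, n_sim_joint=1000
            )
            err = res.band("delay").estimate - truth.beta["delay"]
            errs.append(np.mean(err**2))
        ise[n] = np.mean(errs)
    assert ise[14] < ise[4]
    assert ise[14] < ise[7] * 1.5
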