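"""Calibration model: recovery, least-squares oracle, prediction contract."""

import numpy as np
import pytest

from isomanure.calibration import (
    CalibrationParams,
    CalibrationPosterior,
    fit_calibration,
    fit_calibration_ols,
    predict_d15n,
)
from isomanure.io_config import MCMCConfig, ModernObservation, PriorConfig, RunConfig
from isomanure.synthetic import generate_modern


def _cfg(seed=7, **kw):
    return RunConfig(mcmc=MCMCConfig(chains=2, warmup=300, draws=400, seed=seed), **kw)


def test_noiseless_recovery(calib_params):
    """Data exactly on three parallel lines pin the posterior means."""
    truth = CalibrationParams(2.0, 5.0, 8.0, -1.5, 1e-9)
    modern = generate_modern(truth, 15, seed=1)
    post = fit_calibration(modern, _cfg())
    est = post.mean_params()
    assert est.beta_low == pytest.approx(2.0, abs=0.05)
    assert est.beta_med == pytest.approx(5.0, abs=0.05)
    assert est.beta_high == pytest.approx(8.0, abs=0.05)
    assert float(np.mean(post.lam)) == pytest.approx(-1.5, abs=0.05)


def test_posterior_mean_matches_ols_under_flat_priors():
    """Small-table posterior means equal the least-squares fit when the
    prior is effectively flat (Monte-Carlo error only)."""
    # residuals are tiny so the posterior stays far from the ordering
    # boundary and the truncated prior does not shift the means
    rows = [
        ModernObservation(2.0 - 1.4 * np.log(400) + 0.04, 400, 1),
        ModernObservation(2.0 - 1.4 * np.log(700) - 0.04, 700, 1),
        ModernObservation(5.0 - 1.4 * np.log(380) + 0.05, 380, 2),
        ModernObservation(5.0 - 1.4 * np.log(650) - 0.05, 650, 2),
        ModernObservation(8.0 - 1.4 * np.log(420) + 0.03, 420, 3),
        ModernObservation(8.0 - 1.4 * np.log(600) - 0.03, 600, 3),
    ]
    flat = PriorConfig(beta_scale=1e4, lambda_scale=1e4, sigma_scale=1e4)
    cfg = RunConfig(mcmc=MCMCConfig(chains=2, warmup=500, draws=3000, seed=5), priors=flat)
    post = fit_calibration(rows, cfg)
    ols = fit_calibration_ols(rows)
    est = post.mean_params()
    assert est.beta_low == pytest.approx(ols.params.beta_low, abs=0.1)
    assert est.beta_med == pytest.approx(ols.params.beta_med, abs=0.1)
    assert est.beta_high == pytest.approx(ols.params.beta_high, abs=0.1)
    assert float(np.mean(post.lam)) == pytest.approx(ols.params.lam, abs=0.03)


def test_interval_coverage_on_simulated_tables():
    """90% credible intervals cover the generator values at near-nominal
    rate over seeded replicates (n = 500 per table)."""
    truth = CalibrationParams(2.0, 5.0, 8.0, -1.5, 0.8)
    names = ["beta_low", "beta_med", "beta_high", "lam", "sigma"]
    hits = {k: 0 for k in names}
    reps = 40
    for seed in range(reps):
        modern = generate_modern(truth, 167, seed=seed)
        post = fit_calibration(
            modern, RunConfig(mcmc=MCMCConfig(chains=2, warmup=150, draws=250, seed=seed))
        )
        draws = {
            "beta_low": post.beta[:, 0],
            "beta_med": post.beta[:, 1],
            "beta_high": post.beta[:, 2],
            "lam": post.lam,
            "sigma": post.sigma,
        }
        for k in names:
            lo, hi = np.quantile(draws[k], [0.05, 0.95])
            hits[k] += lo <= getattr(truth, k) <= hi
    for k in names:
        assert hits[k] / reps >= 0.775, (k, hits)


def test_absent_level_is_named():
    rows = [ModernObservation(3.0, 500, 1)] * 3 + [ModernObservation(5.0, 500, 2)] * 3
    with pytest.raises(ValueError, match="high"):
        fit_calibration(rows, _cfg())


@pytest.mark.parametrize(
    "params,level,rain,expected",
    [
        (CalibrationParams(2.0, 5.0, 8.0, 0.0, 1.0), "medium", 123.0, 5.0),
        (CalibrationParams(2.0, 5.0, 8.0, -1.0, 1.0), "low", np.e, 1.0),
    ],
)
def test_predict_trivials(params, level, rain, expected):
    assert predict_d15n(params, level, rain) == pytest.approx(expected)


def test_predict_consistent_with_noiseless_fit():
    truth = CalibrationParams(2.0, 5.0, 8.0, -1.5, 1e-9)
    modern = generate_modern(truth, 15, seed=2)
    est = fit_calibration(modern, _cfg()).mean_params()
    want = 8.0 - 1.5 * np.log(400.0)
    assert predict_d15n(est, "high", 400.0) == pytest.approx(want, abs=0.05)


def test_predict_rejects_bad_inputs(calib_params):
    with pytest.raises(ValueError):
        predict_d15n(calib_params, "low", -5.0)
    with pytest.raises(Exception):
        predict_d15n(calib_params, "very-high", 500.0)


def test_zero_slope_degenerates_to_group_means():
    """With lambda pinned near zero by the data the level means drive the fit."""
    rng = np.random.default_rng(8)
    rows = []
    for m, mu in enumerate((2.0, 5.0, 8.0), start=1):
        for _ in range(60):
            rows.append(
                ModernObservation(mu + 0.5 * rng.standard_normal(), rng.uniform(300, 900), m)
            )
    post = fit_calibration(rows, _cfg(seed=4))
    grp = [np.mean([r.d15n for r in rows if r.level == m]) for m in (1, 2, 3)]
    est = post.mean_params()
    lam_term = float(np.mean(post.lam)) * np.log(550.0)
    for b, g in zip((est.beta_low, est.beta_med, est.beta_high), grp):
        # intercept + slope*log(rain) near the data centre matches group mean
        assert b + lam_term == pytest.approx(g, abs=0.25)


def test_ordering_constraint_enforced():
    with pytest.raises(ValueError):
        CalibrationParams(5.0, 2.0, 8.0, -1.0, 1.0)


def test_convergence_flag_and_draw_count(small_scenario):
    _, _, _, modern = small_scenario
    cfg = _cfg(seed=13)
    post = fit_calibration(modern, cfg)
    assert len(post) == cfg.mcmc.chains * cfg.mcmc.draws
    assert post.converged
    assert max(post.rhat.values()) <= 1.01


def test_from_params_plugin_posterior(calib_params):
    post = CalibrationPosterior.from_params(calib_params, n=4)
    assert len(post) == 4
    assert np.allclose(post.beta[0], calib_params.beta)
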