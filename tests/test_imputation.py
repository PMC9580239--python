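"""Level imputation: quadrature oracle, degenerate limits, monotonicity."""

import numpy as np
import pytest
from scipy import integrate, stats

from isomanure.calibration import CalibrationParams, CalibrationPosterior
from isomanure.imputation import (
    ManuringPosterior,
    charring_correct,
    impute_levels,
    level_log_probs,
    map_assign,
)
from isomanure.io_config import ArchSample, RunConfig


def _sample(d15n, rain_min, rain_max, sid="s1"):
    return ArchSample(sid, "r", "A", "p", 3000.0, 10.0, d15n, rain_min, rain_max)


def test_charring_correct_contract():
    assert charring_correct(6.0, 0.0) == 6.0
    assert charring_correct(6.0, 0.3) == pytest.approx(5.7)
    assert charring_correct(charring_correct(6.0, 0.3), -0.3) == pytest.approx(6.0)
    with pytest.raises(ValueError):
        charring_correct(float("nan"), 0.0)


def test_degenerate_noise_pins_the_level():
    params = CalibrationParams(2.0, 5.0, 8.0, -1.5, 0.01)
    z = 5.0 - 1.5 * np.log(500.0)
    (post,) = impute_levels([_sample(z, 500, 500)], params)
    assert post.p_med > 0.999


def test_midpoint_symmetry_between_adjacent_levels():
    """d15n exactly between the low and medium lines at a point rainfall
    splits the posterior evenly; a far-away high line gets nothing."""
    params = CalibrationParams(2.0, 3.0, 30.0, 0.0, 0.25)
    (post,) = impute_levels([_sample(2.5, 500, 500)], params)
    assert post.p_low == pytest.approx(0.5, abs=1e-6)
    assert post.p_med == pytest.approx(0.5, abs=1e-6)
    assert post.p_high < 1e-6


def test_matches_dense_quadrature_oracle():
    """Monte-Carlo/Gauss-Legendre imputation agrees with brute-force
    numerical integration of the rainfall prior to 3 decimals."""
    params = CalibrationParams(2.0, 5.0, 8.0, -1.5, 0.9)
    z_vals = [3.0, 4.4, 6.1]
    samples = [_sample(z, 400, 600, sid=f"s{k}") for k, z in enumerate(z_vals)]
    posts = impute_levels(samples, params, RunConfig())

    for z, post in zip(z_vals, posts):
        weights = []
        for m in range(3):
            f = lambda r: stats.norm.pdf(z, params.beta[m] - 1.5 * np.log(r), 0.9) / 200.0
            weights.append(integrate.quad(f, 400.0, 600.0, limit=200)[0])
        expected = np.array(weights) / sum(weights)
        assert np.allclose(post.p, expected, atol=1e-3)
        # MAP assignment agrees with the oracle argmax
        assert map_assign(post) == int(np.argmax(expected)) + 1


def test_calibration_draw_averaging_matches_manual_mean(calib_params):
    """`draws` mode averages per-draw *likelihoods* (not normalized
    posteriors) before normalising, matching a manual mixture."""
    rng = np.random.default_rng(5)
    S = 50
    post = CalibrationPosterior(
        beta=calib_params.beta + 0.2 * rng.standard_normal((S, 3)),
        lam=-1.5 + 0.1 * rng.standard_normal(S),
        sigma=np.abs(1.0 + 0.1 * rng.standard_normal(S)),
    )
    sample = _sample(4.2, 450, 550)
    (got,) = impute_levels([sample], post, RunConfig())
    per_draw = np.array(
        [
            np.exp(
                level_log_probs(
                    [sample],
                    CalibrationParams(
                        *post.beta[s], lam=float(post.lam[s]), sigma=float(post.sigma[s])
                    ),
                    RunConfig(),
                )[0]
                + _lognorm(sample, post, s)
            )
            for s in range(S)
        ]
    )
    manual = per_draw.sum(axis=0)
    manual /= manual.sum()
    assert np.allclose(got.p, manual, atol=1e-10)


def _lognorm(sample, post, s):
    """Normalising constant of draw s's level posterior (its total
    emission likelihood), needed to reconstruct the mixture weights."""
    from isomanure.imputation import emission_log_matrix, rainfall_quadrature
    from scipy.special import logsumexp

    lognodes, logw = rainfall_quadrature(
        [sample.rain_min_mm], [sample.rain_max_mm], RunConfig().rainfall_grid
    )
    L = emission_log_matrix(
        np.array([sample.d15n]), lognodes, logw,
        post.beta[s], post.lam[s], float(post.sigma[s]),
    )
    return logsumexp(L[0])


def test_map_assign_tie_breaks_to_lower_level():
    assert map_assign(ManuringPosterior("x", 0.2, 0.7, 0.1)) == 2
    assert map_assign(ManuringPosterior("x", 0.5, 0.5, 0.0)) == 1
    assert map_assign(ManuringPosterior("x", 0.0, 0.5, 0.5)) == 2


def test_probability_vector_validation():
    with pytest.raises(ValueError):
        ManuringPosterior("x", 0.5, 0.6, 0.2)
    with pytest.raises(ValueError):
        ManuringPosterior("x", -0.1, 0.6, 0.5)


def test_increasing_d15n_never_decreases_p_high(calib_params):
    """Stochastic monotonicity of the level posterior in the isotope value."""
    grid = np.linspace(1.0, 10.0, 25)
    samples = [_sample(z, 420, 580, sid=f"g{k}") for k, z in enumerate(grid)]
    posts = impute_levels(samples, calib_params, RunConfig())
    p_high = np.array([p.p_high for p in posts])
    assert np.all(np.diff(p_high) >= -1e-12)


def test_wider_rainfall_range_does_not_sharpen_on_average(calib_params):
    """Averaged over simulated samples, widening the rainfall prior cannot
    reduce the entropy of the level posterior."""
    rng = np.random.default_rng(11)
    z = rng.uniform(1.0, 9.0, size=60)
    narrow = [_sample(zi, 480, 520, sid=f"n{k}") for k, zi in enumerate(z)]
    wide = [_sample(zi, 300, 700, sid=f"w{k}") for k, zi in enumerate(z)]

    def mean_entropy(posts):
        P = np.array([p.p for p in posts])
        return float(-(P * np.log(np.clip(P, 1e-12, None))).sum(axis=1).mean())

    cfg = RunConfig()
    assert mean_entropy(impute_levels(wide, calib_params, cfg)) >= (
        mean_entropy(impute_levels(narrow, calib_params, cfg)) - 1e-6
    )


def test_zero_likelihood_names_the_sample():
    params = CalibrationParams(2.0, 5.0, 8.0, 0.0, 1e-300)
    with pytest.raises(ValueError, match="bad-sample"):
        impute_levels([_sample(100.0, 500, 500, sid="bad-sample")], params)
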