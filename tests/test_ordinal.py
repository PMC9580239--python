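"""Proportional-odds model: closed forms, likelihood oracle, ML recovery."""

import numpy as np
import pytest
from scipy.special import expit, logit

import isomanure as im
from isomanure.io_config import RunConfig
from isomanure.ordinal import (
    Design,
    POParams,
    build_design,
    cumulative_logprobs,
    fit_po_wald,
    po_cumulative_prob,
    po_loglik,
)


def _flat_design(n, x_size=None, x_date=None, site_idx=None, sites=None):
    return Design(
        x_size=np.zeros(n) if x_size is None else np.asarray(x_size, float),
        x_date=np.zeros(n) if x_date is None else np.asarray(x_date, float),
        site_idx=np.zeros(n, int) if site_idx is None else np.asarray(site_idx, int),
        sites=sites or ["s0"],
        size_transform="identity",
        size_center=0.0,
        date_center=0.0,
        date_scale=1.0,
    )


def test_cumulative_prob_logit_zero():
    p = POParams(alpha1=0.0, alpha2=1.0, gamma=0.0, tau=0.0)
    assert po_cumulative_prob(p, 0.0, 0.0, "s0", "low") == pytest.approx(0.5)
    assert po_cumulative_prob(p, 3.0, -2.0, "s0", "high") == 1.0


def test_cumulative_prob_direct_inverse_logit():
    p = POParams(alpha1=-1.0, alpha2=1.0, gamma=0.5, tau=0.0)
    # linear predictor 0.5 at x_size = 1
    assert po_cumulative_prob(p, 1.0, 0.0, "s0", "low") == pytest.approx(expit(-1.5))
    assert po_cumulative_prob(p, 1.0, 0.0, "s0", "medium") == pytest.approx(expit(0.5))
    probs = np.exp(cumulative_logprobs(-1.0, 1.0, np.array([0.5])))[0]
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)


def test_negative_gamma_makes_cumprob_rise_with_size():
    p = POParams(alpha1=-1.0, alpha2=1.0, gamma=-0.5, tau=0.0)
    sizes = np.linspace(-2, 4, 9)
    vals = [po_cumulative_prob(p, x, 0.0, "s0", "low") for x in sizes]
    assert np.all(np.diff(vals) > 0)


def test_category_probs_sum_to_one_everywhere():
    rng = np.random.default_rng(3)
    eta = rng.normal(0, 5, size=500)
    for a1, a2 in ((-2.0, -1.0), (-0.5, 0.5), (1.0, 4.0)):
        p = np.exp(cumulative_logprobs(a1, a2, eta))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)


def test_loglik_uniform_categories():
    d = _flat_design(1)
    p = POParams(alpha1=float(logit(1 / 3)), alpha2=float(logit(2 / 3)), gamma=0.0, tau=0.0)
    assert po_loglik(p, [2], d) == pytest.approx(np.log(1 / 3))


def test_loglik_matches_brute_force_sum():
    d = _flat_design(3, x_size=[0.0, 1.0, -1.0], site_idx=[0, 0, 1], sites=["a", "b"])
    p = POParams(alpha1=-0.7, alpha2=0.9, gamma=-0.4, tau=0.0, u={"a": 0.2, "b": -0.1})
    levels = [1, 3, 2]
    manual = 0.0
    for lv, x, site in zip(levels, d.x_size, ["a", "a", "b"]):
        e = -0.4 * x + p.u[site]
        c1, c2 = expit(-0.7 - e), expit(0.9 - e)
        probs = [c1, c2 - c1, 1 - c2]
        manual += np.log(probs[lv - 1])
    assert po_loglik(p, levels, d) == pytest.approx(manual, abs=1e-12)

    # additivity: duplicating an observation doubles its contribution
    d2 = _flat_design(4, x_size=[0.0, 1.0, -1.0, 1.0], site_idx=[0, 0, 1, 0], sites=["a", "b"])
    extra = po_loglik(p, levels + [3], d2) - po_loglik(p, levels, d)
    e = -0.4 * 1.0 + 0.2
    assert extra == pytest.approx(np.log(1 - expit(0.9 - e)), abs=1e-12)


def test_loglik_invariant_under_site_relabeling():
    rng = np.random.default_rng(9)
    n = 40
    site_idx = rng.integers(0, 4, n)
    levels = list(rng.integers(1, 4, n))
    x = rng.normal(size=n)
    d1 = _flat_design(n, x_size=x, site_idx=site_idx, sites=["a", "b", "c", "d"])
    # same sites listed in a different order; indices remapped to match
    new_sites = ["c", "a", "d", "b"]
    remap = {old: new_sites.index(name) for old, name in enumerate(["a", "b", "c", "d"])}
    d2 = _flat_design(
        n,
        x_size=x,
        site_idx=[remap[s] for s in site_idx],
        sites=new_sites,
    )
    u_vals = {"a": 0.3, "b": -0.2, "c": 0.1, "d": 0.0}
    p = POParams(alpha1=-1.0, alpha2=1.0, gamma=-0.3, tau=0.0, u=u_vals)
    assert po_loglik(p, levels, d1) == pytest.approx(po_loglik(p, levels, d2), abs=1e-10)


def test_intercept_only_closed_form_cutpoints():
    """Counts (25, 50, 25) give ML cutpoints logit(1/4) and logit(3/4)."""
    levels = [1] * 25 + [2] * 50 + [3] * 25
    d = _flat_design(100)
    fit = fit_po_wald(levels, d, RunConfig(), include_size=False, include_date=False,
                      random_effects=False)
    assert fit.alpha1 == pytest.approx(float(logit(0.25)), abs=1e-4)
    assert fit.alpha2 == pytest.approx(float(logit(0.75)), abs=1e-4)
    assert fit.converged


def test_fixed_effects_fit_matches_statsmodels():
    """The sigma_u -> 0 limit agrees with an independent fixed-effects
    cumulative-logit implementation."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    spec = im.synthetic.simple_scenario(n_sites=6, n_per_site=40, gamma=-0.5,
                                        sigma_u=0.0, seed=17)
    arch, truth = im.generate_arch(spec)
    d = build_design(arch, RunConfig())
    fit = fit_po_wald(list(truth["levels"]), d, RunConfig(), random_effects=False)
    sm = OrderedModel(
        np.asarray(truth["levels"]),
        np.column_stack([d.x_size, d.x_date]),
        distr="logit",
    ).fit(method="bfgs", disp=False)
    assert fit.gamma == pytest.approx(sm.params[0], abs=1e-3)
    assert fit.tau == pytest.approx(sm.params[1], abs=1e-3)
    assert fit.alpha1 == pytest.approx(sm.params[2], abs=1e-3)
    assert fit.se["gamma"] == pytest.approx(sm.bse[0], rel=0.05)


def test_mixed_fit_recovers_gamma_with_wald_coverage():
    """gamma_hat's 95% Wald interval covers the generator value at
    near-nominal rate over seeded replicates."""
    hits = 0
    reps = 12
    for seed in range(reps):
        spec = im.synthetic.simple_scenario(
            n_sites=10, n_per_site=30, gamma=-0.5, sigma_u=0.5, seed=seed
        )
        arch, truth = im.generate_arch(spec)
        d = build_design(arch, RunConfig())
        fit = fit_po_wald(list(truth["levels"]), d, RunConfig())
        hits += abs(fit.gamma + 0.5) < 1.96 * fit.se["gamma"]
    assert hits >= 9


def test_mixed_likelihood_converges_to_fixed_as_sigma_u_vanishes():
    spec = im.synthetic.simple_scenario(n_sites=4, n_per_site=10, gamma=-0.3, seed=2)
    arch, truth = im.generate_arch(spec)
    d = build_design(arch, RunConfig())
    from isomanure.ordinal import _marginal_negll

    x, w = np.polynomial.hermite.hermgauss(25)
    gh = (x, np.log(w) - 0.5 * np.log(np.pi))
    lv = truth["levels"] - 1
    pv_fixed = np.array([-1.0, np.log(2.0), -0.3, 0.1])
    fixed = _marginal_negll(pv_fixed, lv, d, True, True, False, gh)
    mixed = _marginal_negll(
        np.concatenate([pv_fixed, [np.log(1e-8)]]), lv, d, True, True, True, gh
    )
    assert mixed == pytest.approx(fixed, abs=1e-6)


def test_requires_two_distinct_levels():
    d = _flat_design(10)
    with pytest.raises(ValueError):
        fit_po_wald([2] * 10, d, RunConfig())


def test_single_site_falls_back_to_fixed_intercept():
    levels = [1] * 10 + [2] * 12 + [3] * 8
    d = _flat_design(30, x_size=np.linspace(-1, 1, 30))
    fit = fit_po_wald(levels, d, RunConfig())
    assert not fit.used_random_effects
    assert fit.sigma_u is None


def test_unknown_site_requires_marginal_mode():
    p = POParams(alpha1=-1.0, alpha2=1.0, gamma=-0.5, tau=0.0,
                 u={"a": 0.1}, sigma_u=0.4)
    with pytest.raises(KeyError):
        po_cumulative_prob(p, 0.0, 0.0, "unseen", "low")
    val = po_cumulative_prob(p, 0.0, 0.0, "unseen", "low", marginal=True, n_mc=20000)
    # MC-marginalised probability sits near the sigma_u-smoothed value
    u = np.random.default_rng(0).normal(0, 0.4, 20000)
    assert val == pytest.approx(float(np.mean(expit(-1.0 - u))), abs=0.01)
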