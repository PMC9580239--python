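"""Cut, full-Bayes and semi-modular inference across the two modules.

Module one (imputation) links the modern calibration model θ =
(beta_low, beta_med, beta_high, lambda, sigma) to the archaeological
grain δ15N values z through latent manuring levels M, with a uniform
rainfall prior on each sample's range integrated out by quadrature.
Module two (analysis) is the proportional-odds regression p(M | φ) with
φ = (alpha, gamma, tau, u, sigma_u).

The SMI power posterior raises the analysis-module likelihood to the
influence η ∈ [0, 1]:

    p_η(θ, M, φ̃) ∝ p(θ) p(modern | θ) Π_i p(z_i | M_i, θ) p(M_i | φ̃)^η p(φ̃)

and a second stage draws the reported analysis parameters φ from their
full conditional p(φ | M) for each sampled completed dataset. η = 0 is
the cut posterior (Bayesian multiple imputation: level assignment
receives no feedback from the settlement-size model), η = 1 the full
joint posterior. η is chosen by maximizing the expected log pointwise
predictive density (ELPD) of the observed δ15N values, estimated by
Pareto-smoothed importance-sampling leave-one-out.

Evidence for a directional size effect is reported as posterior sign
odds of gamma, which equal the one-sided Bayes factor under the
symmetric prior on gamma.

Sampling is Metropolis-within-Gibbs: a random-walk update on θ, exact
Gibbs on the discrete levels, and componentwise random-walk updates on
φ (site random effects are updated jointly since they are conditionally
independent given the rest). Proposal scales adapt during warmup only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .calibration import CalibrationParams, CalibrationPosterior
from .imputation import emission_log_matrix, rainfall_quadrature
from .io_config import MCMCConfig, PriorConfig, RunConfig
from .ordinal import Design, build_design, cumulative_logprobs, level_logprob

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)
PSIS_K_THRESHOLD = 0.7


@dataclass
class SMIConfig:
    """Influence setting for one semi-modular run."""

    eta: float
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    direction: str = "negative"

    def __post_init__(self):
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError(f"eta must lie in [0, 1], got {self.eta}")


@dataclass
class TwoModuleData:
    """Archaeological samples plus (optionally) the modern calibration table.

    When the modern table is supplied the θ updates use its exact
    likelihood; otherwise θ is anchored by a multivariate-normal
    approximation to the supplied calibration posterior draws.
    """

    arch: list
    modern: list | None = None


@dataclass
class POModelSpec:
    """Which analysis-model components are active in the Bayesian fits."""

    include_size: bool = True
    include_date: bool = True
    random_effects: bool = True
    fixed_alpha: tuple | None = None

    @classmethod
    def from_config(cls, config: RunConfig) -> "POModelSpec":
        return cls(include_date=config.include_date, random_effects=config.random_effects)


@dataclass
class PosteriorSamples:
    """Pooled posterior draws from a cut, SMI or full-Bayes run.

    All arrays are aligned on the first (draw) axis. ``gamma`` etc. are
    the reported analysis parameters (stage-two draws for cut/SMI,
    stage-one draws for the full posterior); ``levels`` are 1-based
    manuring levels; θ draws are repeated to match when stage two emits
    several φ draws per completed dataset.
    """

    eta: float
    gamma: np.ndarray
    tau: np.ndarray
    alpha: np.ndarray
    u: np.ndarray
    sigma_u: np.ndarray
    levels: np.ndarray
    theta_beta: np.ndarray
    theta_lam: np.ndarray
    theta_sigma: np.ndarray
    sites: list
    diagnostics: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        n = len(self.gamma)
        for name in ("tau", "sigma_u", "levels", "alpha", "u", "theta_beta"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"draw array {name!r} not aligned with gamma")
        if not np.isin(self.levels, [1, 2, 3]).all():
            raise ValueError("level draws must be valid categories 1/2/3")

    @property
    def n_draws(self) -> int:
        return len(self.gamma)


@dataclass
class ELPDCurve:
    """ELPD against the influence parameter, with the maximizing η."""

    etas: list
    elpd: list
    elpd_se: list
    eta_star: float
    pareto_k_frac: list = field(default_factory=list)

    def __post_init__(self):
        best = int(np.argmax(self.elpd))
        if self.etas[best] != self.eta_star:
            raise ValueError("eta_star must attain the maximum ELPD on the grid")


@dataclass
class BayesFactorResult:
    """One-sided posterior sign odds on gamma (= Bayes factor here)."""

    bf: float
    n_draws: int
    direction: str
    capped: bool = False


# ---------------------------------------------------------------------------
# data preparation


class _Prepared:
    """Precomputed arrays shared by every sampler on one dataset."""

    def __init__(self, data, calib, config: RunConfig):
        if isinstance(data, TwoModuleData):
            arch, modern = data.arch, data.modern
        else:
            arch, modern = list(data), None
        self.arch = arch
        self.n = len(arch)
        self.config = config
        self.design: Design = build_design(arch, config)
        from .imputation import charring_correct

        self.d15n = np.array([charring_correct(s.d15n, config.charring_offset) for s in arch])
        self.lognodes, self.logw = rainfall_quadrature(
            [s.rain_min_mm for s in arch],
            [s.rain_max_mm for s in arch],
            config.rainfall_grid,
        )
        self.fixed_theta = isinstance(calib, CalibrationParams)
        if self.fixed_theta:
            self.center = 0.0
            self.theta0 = np.concatenate(
                [calib.beta, [float(np.asarray(calib.lam))], [np.log(calib.sigma)]]
            )
            self.modern = None
            self.mvn = None
            return
        if len(calib) == 0:
            raise ValueError("calibration posterior is empty")
        if modern is not None:
            lograin = np.log([o.rainfall_mm for o in modern])
            self.center = float(lograin.mean())
            self.mod_d15n = np.array([o.d15n for o in modern])
            self.mod_lograin_c = lograin - self.center
            self.mod_level = np.array([o.level for o in modern]) - 1
            self.modern = True
            self.mvn = None
        else:
            self.center = float(np.mean(self.lognodes))
            self.modern = None
            # MVN approximation to the calibration posterior in centered coords
            draws = np.column_stack(
                [
                    calib.beta + calib.lam[:, None] * self.center,
                    calib.lam,
                    np.log(calib.sigma),
                ]
            )
            mu = draws.mean(axis=0)
            cov = np.cov(draws.T) + 1e-10 * np.eye(5)
            self.mvn = (mu, np.linalg.inv(cov))
        # start: centered posterior mean
        p = calib.mean_params()
        lam0 = float(np.mean(np.atleast_1d(np.asarray(p.lam))))
        self.theta0 = np.concatenate(
            [p.beta + lam0 * self.center, [lam0], [np.log(p.sigma)]]
        )

    # θ is stored as (b1c, b2c, b3c, lam, log_sigma) with betas on the
    # centered log-rainfall scale (decorrelates intercepts and slope)

    def theta_uncentered(self, tv: np.ndarray):
        beta = tv[:3] - tv[3] * self.center
        return beta, tv[3], math.exp(tv[4])

    def emission(self, tv: np.ndarray) -> np.ndarray:
        beta, lam, sigma = self.theta_uncentered(tv)
        return emission_log_matrix(self.d15n, self.lognodes, self.logw, beta, lam, sigma)

    def theta_logprior(self, tv: np.ndarray, priors: PriorConfig) -> float:
        if not (tv[0] < tv[1] < tv[2]):
            return -np.inf
        if self.mvn is not None:
            mu, prec = self.mvn
            d = tv - mu
            return -0.5 * float(d @ prec @ d)
        beta, lam, sigma = self.theta_uncentered(tv)
        lp = (
            float(np.sum(_nlogpdf(beta, priors.beta_scale)))
            + _nlogpdf(lam, priors.lambda_scale)
            + _hnlogpdf(sigma, priors.sigma_scale)
            + tv[4]
        )
        if self.modern:
            mu = tv[self.mod_level] + lam * self.mod_lograin_c
            z = (self.mod_d15n - mu) / sigma
            lp += float(np.sum(-0.5 * z * z - tv[4] - 0.5 * _LOG_2PI))
        return float(lp)


# ---------------------------------------------------------------------------
# φ state and componentwise updates


def _nlogpdf(x, scale):
    """Normal(0, scale) log density up to nothing — exact, fast scalar/array."""
    return -0.5 * (x / scale) ** 2 - math.log(scale) - 0.5 * _LOG_2PI


def _hnlogpdf(s, scale):
    """Half-normal(scale) log density for s > 0."""
    return 0.5 * math.log(2.0 / math.pi) - math.log(scale) - 0.5 * (s / scale) ** 2


class _PhiState:
    def __init__(self, alpha, gamma, tau, u, log_sigma_u, design: Design):
        self.alpha = np.asarray(alpha, dtype=float).copy()
        self.gamma = float(gamma)
        self.tau = float(tau)
        self.u = np.asarray(u, dtype=float).copy()
        self.log_sigma_u = float(log_sigma_u)
        self.design = design
        self.refresh_eta()

    def refresh_eta(self):
        d = self.design
        self.e = self.gamma * d.x_size + self.tau * d.x_date + self.u[d.site_idx]

    def copy(self) -> "_PhiState":
        return _PhiState(self.alpha, self.gamma, self.tau, self.u, self.log_sigma_u, self.design)

    def level_logprobs_all(self) -> np.ndarray:
        return cumulative_logprobs(self.alpha[0], self.alpha[1], self.e)


def _init_phi(prep: _Prepared, spec: POModelSpec, M_idx: np.ndarray) -> _PhiState:
    freqs = np.bincount(M_idx, minlength=3) / len(M_idx)
    c1 = float(np.clip(freqs[0], 0.05, 0.9))
    c2 = float(np.clip(freqs[0] + freqs[1], c1 + 0.05, 0.95))
    if spec.fixed_alpha is not None:
        alpha = np.asarray(spec.fixed_alpha, dtype=float)
    else:
        alpha = np.array([np.log(c1 / (1 - c1)), np.log(c2 / (1 - c2))])
    lsu = np.log(0.3) if spec.random_effects else -np.inf
    return _PhiState(alpha, 0.0, 0.0, np.zeros(prep.design.n_sites), lsu, prep.design)


def _default_phi_scales(spec: POModelSpec) -> dict:
    return {"a1": 0.3, "a2": 0.3, "gamma": 0.3, "tau": 0.3, "u": 0.4, "lsu": 0.5}


def _phi_sweep(
    rng,
    phi: _PhiState,
    M_idx: np.ndarray,
    weight: float,
    priors: PriorConfig,
    spec: POModelSpec,
    scales: dict,
    acc: dict,
) -> None:
    """One componentwise Metropolis sweep on φ given levels M.

    ``weight`` multiplies the module-two log likelihood (η in stage one,
    1 in stage two and in the joint sampler); priors stay untempered.
    """
    d = phi.design
    a1, a2 = phi.alpha

    def loglik(alpha1, alpha2, e) -> float:
        return float(level_logprob(alpha1, alpha2, e, M_idx).sum())

    ll_cur = loglik(a1, a2, phi.e)

    if spec.fixed_alpha is None:
        prop = a1 + scales["a1"] * rng.standard_normal()
        acc["a1"][1] += 1
        if prop < a2:
            delta = weight * (loglik(prop, a2, phi.e) - ll_cur) + (
                _nlogpdf(prop, priors.alpha_scale) - _nlogpdf(a1, priors.alpha_scale)
            )
            if math.log(rng.uniform()) < delta:
                a1 = prop
                phi.alpha[0] = a1
                ll_cur = loglik(a1, a2, phi.e)
                acc["a1"][0] += 1
        prop = a2 + scales["a2"] * rng.standard_normal()
        acc["a2"][1] += 1
        if prop > a1:
            delta = weight * (loglik(a1, prop, phi.e) - ll_cur) + (
                _nlogpdf(prop, priors.alpha_scale) - _nlogpdf(a2, priors.alpha_scale)
            )
            if math.log(rng.uniform()) < delta:
                a2 = prop
                phi.alpha[1] = a2
                ll_cur = loglik(a1, a2, phi.e)
                acc["a2"][0] += 1

    if spec.include_size:
        prop = phi.gamma + scales["gamma"] * rng.standard_normal()
        e_prop = phi.e + (prop - phi.gamma) * d.x_size
        delta = weight * (loglik(a1, a2, e_prop) - ll_cur) + (
            _nlogpdf(prop, priors.coef_scale) - _nlogpdf(phi.gamma, priors.coef_scale)
        )
        acc["gamma"][1] += 1
        if math.log(rng.uniform()) < delta:
            phi.gamma = prop
            phi.e = e_prop
            ll_cur = loglik(a1, a2, phi.e)
            acc["gamma"][0] += 1

    if spec.include_date:
        prop = phi.tau + scales["tau"] * rng.standard_normal()
        e_prop = phi.e + (prop - phi.tau) * d.x_date
        delta = weight * (loglik(a1, a2, e_prop) - ll_cur) + (
            _nlogpdf(prop, priors.coef_scale) - _nlogpdf(phi.tau, priors.coef_scale)
        )
        acc["tau"][1] += 1
        if math.log(rng.uniform()) < delta:
            phi.tau = prop
            phi.e = e_prop
            ll_cur = loglik(a1, a2, phi.e)
            acc["tau"][0] += 1

    if spec.random_effects and d.n_sites > 0:
        sigma_u = math.exp(phi.log_sigma_u)
        prop_u = phi.u + scales["u"] * rng.standard_normal(d.n_sites)
        e_prop = phi.e + (prop_u - phi.u)[d.site_idx]
        lp_cur = level_logprob(a1, a2, phi.e, M_idx)
        lp_prop = level_logprob(a1, a2, e_prop, M_idx)
        site_delta = weight * np.bincount(
            d.site_idx, weights=lp_prop - lp_cur, minlength=d.n_sites
        )
        site_delta += _nlogpdf(prop_u, sigma_u) - _nlogpdf(phi.u, sigma_u)
        accept = np.log(rng.uniform(size=d.n_sites)) < site_delta
        if np.any(accept):
            delta_u = np.where(accept, prop_u - phi.u, 0.0)
            phi.u = phi.u + delta_u
            phi.e = phi.e + delta_u[d.site_idx]
        acc["u"][0] += int(accept.sum())
        acc["u"][1] += d.n_sites

        # sigma_u only touches the u prior and its own prior
        prop = phi.log_sigma_u + scales["lsu"] * rng.standard_normal()
        s_cur, s_prop = math.exp(phi.log_sigma_u), math.exp(prop)
        delta = (
            float(np.sum(_nlogpdf(phi.u, s_prop)) - np.sum(_nlogpdf(phi.u, s_cur)))
            + _hnlogpdf(s_prop, priors.sigma_u_scale)
            - _hnlogpdf(s_cur, priors.sigma_u_scale)
            + prop
            - phi.log_sigma_u
        )
        acc["lsu"][1] += 1
        if math.log(rng.uniform()) < delta:
            phi.log_sigma_u = prop
            acc["lsu"][0] += 1


def _adapt(scales: dict, acc: dict, keys, target: float = 0.44) -> None:
    for k in keys:
        a, n = acc[k]
        if n == 0:
            continue
        rate = a / n
        if rate > target + 0.08:
            scales[k] *= 1.2
        elif rate < target - 0.12:
            scales[k] /= 1.2
        acc[k][0] = acc[k][1] = 0


def _fresh_acc() -> dict:
    return {k: [0, 0] for k in ("a1", "a2", "gamma", "tau", "u", "lsu", "theta")}


# ---------------------------------------------------------------------------
# stage-one samplers


def _sample_levels(rng, logits: np.ndarray) -> np.ndarray:
    g = rng.gumbel(size=logits.shape)
    return np.argmax(logits + g, axis=1)


def _theta_step(rng, prep: _Prepared, tv, L, t_prior, M_idx, scales, acc, priors):
    """Joint random-walk Metropolis update of θ; returns new state."""
    step = scales["theta"] * np.array([1.0, 1.0, 1.0, 0.7, 0.5])
    prop = tv + step * rng.standard_normal(5)
    lp_prop = prep.theta_logprior(prop, priors)
    acc["theta"][1] += 1
    if not np.isfinite(lp_prop):
        return tv, L, t_prior
    L_prop = prep.emission(prop)
    idx = np.arange(prep.n)
    delta = (lp_prop + L_prop[idx, M_idx].sum()) - (t_prior + L[idx, M_idx].sum())
    if math.log(rng.uniform()) < delta:
        acc["theta"][0] += 1
        return prop, L_prop, lp_prop
    return tv, L, t_prior


def _run_power_stage1(
    prep: _Prepared,
    config: RunConfig,
    eta: float,
    spec: POModelSpec,
    seed_seq: np.random.SeedSequence,
):
    """Power-posterior MCMC on (θ, M, φ̃); returns per-chain records."""
    mc = config.mcmc
    priors = config.priors
    chains = []
    for cseed in seed_seq.spawn(mc.chains):
        rng = np.random.default_rng(cseed)
        tv = prep.theta0 + 0.01 * rng.standard_normal(5)
        tv[:3] = np.sort(tv[:3])
        L = prep.emission(tv)
        t_prior = prep.theta_logprior(tv, priors)
        M_idx = _sample_levels(rng, L)
        phi = _init_phi(prep, spec, M_idx)
        scales = _default_phi_scales(spec)
        scales["theta"] = 0.1
        acc = _fresh_acc()
        n_iter = mc.warmup + mc.draws * mc.thin
        rec = {"theta": [], "M": [], "phi": []}
        for it in range(n_iter):
            if not prep.fixed_theta:
                tv, L, t_prior = _theta_step(
                    rng, prep, tv, L, t_prior, M_idx, scales, acc, priors
                )
            logits = L if eta == 0.0 else L + eta * phi.level_logprobs_all()
            M_idx = _sample_levels(rng, logits)
            if eta > 0.0:
                _phi_sweep(rng, phi, M_idx, eta, priors, spec, scales, acc)
            if it < mc.warmup:
                if (it + 1) % 25 == 0:
                    _adapt(scales, acc, ("a1", "a2", "gamma", "tau", "u", "lsu"))
                    _adapt(scales, acc, ("theta",), target=0.25)
            elif (it - mc.warmup + 1) % mc.thin == 0:
                rec["theta"].append(tv.copy())
                rec["M"].append(M_idx.copy())
                rec["phi"].append(
                    (phi.alpha.copy(), phi.gamma, phi.tau, phi.u.copy(), phi.log_sigma_u)
                )
        rec["scales"] = scales
        rec["acc"] = acc
        chains.append(rec)
    return chains


def _run_module_one_stage1(
    prep: _Prepared, config: RunConfig, seed_seq: np.random.SeedSequence
):
    """Module-one sampler for the cut posterior: MCMC on (θ, M) only.

    The target is p(θ | modern) Π_i (1/3) p(z_i | M_i, θ) — the
    imputation model with a uniform level prior and no analysis-stage
    feedback of any kind.
    """
    mc = config.mcmc
    priors = config.priors
    chains = []
    for cseed in seed_seq.spawn(mc.chains):
        rng = np.random.default_rng(cseed)
        tv = prep.theta0 + 0.01 * rng.standard_normal(5)
        tv[:3] = np.sort(tv[:3])
        L = prep.emission(tv)
        t_prior = prep.theta_logprior(tv, priors)
        M_idx = _sample_levels(rng, L)
        scales = {"theta": 0.1}
        acc = _fresh_acc()
        n_iter = mc.warmup + mc.draws * mc.thin
        rec = {"theta": [], "M": []}
        for it in range(n_iter):
            if not prep.fixed_theta:
                tv, L, t_prior = _theta_step(
                    rng, prep, tv, L, t_prior, M_idx, scales, acc, priors
                )
            M_idx = _sample_levels(rng, L)
            if it < mc.warmup:
                if (it + 1) % 25 == 0:
                    _adapt(scales, acc, ("theta",), target=0.25)
            elif (it - mc.warmup + 1) % mc.thin == 0:
                rec["theta"].append(tv.copy())
                rec["M"].append(M_idx.copy())
        rec["acc"] = acc
        chains.append(rec)
    return chains


# ---------------------------------------------------------------------------
# stage two: φ | M chainlets


def _stage2_chainlets(
    prep: _Prepared,
    config: RunConfig,
    spec: POModelSpec,
    M_draws: np.ndarray,
    theta_draws: np.ndarray,
    seed_seq: np.random.SeedSequence,
    phi_inits: list | None = None,
):
    """Sample φ from p(φ | M) for each completed dataset and pool.

    One chainlet per completed dataset; proposal scales are pre-adapted
    on a pilot chainlet and then frozen so the pooled draws are
    exchangeable across datasets. Chainlets warm-start from the previous
    chainlet's end state (or the matching stage-one φ̃ draw when given).
    """
    mc = config.mcmc
    priors = config.priors
    rng = np.random.default_rng(seed_seq.spawn(1)[0])
    n_imp = M_draws.shape[0]

    # pilot adaptation
    phi = _init_phi(prep, spec, M_draws[0])
    scales = _default_phi_scales(spec)
    acc = _fresh_acc()
    for it in range(max(4 * mc.stage2_warmup, 200)):
        _phi_sweep(rng, phi, M_draws[0], 1.0, priors, spec, scales, acc)
        if (it + 1) % 25 == 0:
            _adapt(scales, acc, ("a1", "a2", "gamma", "tau", "u", "lsu"))

    out = {"alpha": [], "gamma": [], "tau": [], "u": [], "sigma_u": [], "rep": []}
    acc = _fresh_acc()
    carry = phi
    for k in range(n_imp):
        M_idx = M_draws[k]
        if phi_inits is not None:
            a, g, t, u, lsu = phi_inits[k]
            carry = _PhiState(a, g, t, u, lsu, prep.design)
        chain = carry
        for _ in range(mc.stage2_warmup):
            _phi_sweep(rng, chain, M_idx, 1.0, priors, spec, scales, acc)
        for j in range(mc.stage2_draws):
            for _ in range(mc.stage2_thin):
                _phi_sweep(rng, chain, M_idx, 1.0, priors, spec, scales, acc)
            out["alpha"].append(chain.alpha.copy())
            out["gamma"].append(chain.gamma)
            out["tau"].append(chain.tau)
            out["u"].append(chain.u.copy())
            out["sigma_u"].append(math.exp(chain.log_sigma_u))
            out["rep"].append(k)
        carry = chain

    rep = np.array(out["rep"])
    return {
        "alpha": np.array(out["alpha"]),
        "gamma": np.array(out["gamma"]),
        "tau": np.array(out["tau"]),
        "u": np.array(out["u"]),
        "sigma_u": np.array(out["sigma_u"]),
        "levels": M_draws[rep] + 1,
        "theta": theta_draws[rep],
        "acc": acc,
        "scales": scales,
    }


def _pool_stage1(chains, keys=("theta", "M")):
    pooled = {k: np.array(sum((c[k] for c in chains), [])) for k in keys}
    return pooled


def _select_imputations(n_total: int, n_imp: int) -> np.ndarray:
    n_imp = min(n_imp, n_total)
    return np.unique(np.linspace(0, n_total - 1, n_imp).round().astype(int))


def _theta_draws_uncentered(prep: _Prepared, theta: np.ndarray):
    beta = theta[:, :3] - theta[:, 3:4] * prep.center
    return beta, theta[:, 3], np.exp(theta[:, 4])


def _split_rhat_1d(per_chain: np.ndarray) -> float:
    """Split-chain R-hat for a (chains, draws) array of one scalar."""
    import arviz as az

    half = per_chain.shape[1] // 2
    if half < 2:
        return float("nan")
    arr = np.concatenate([per_chain[:, :half], per_chain[:, half : 2 * half]], axis=0)
    return float(az.rhat(az.convert_to_dataset(arr))["x"].values)


def sample_cut_posterior(
    data, calib, config: RunConfig | None = None, model_spec: POModelSpec | None = None
) -> PosteriorSamples:
    """The cut posterior (Bayesian multiple imputation).

    Stage one draws (θ, M) from the imputation module alone — a uniform
    prior over levels and no feedback from the settlement-size model.
    Stage two draws the analysis parameters φ given each completed set
    of imputed levels and pools across completed datasets.
    """
    config = config or RunConfig()
    spec = model_spec or POModelSpec.from_config(config)
    prep = _Prepared(data, calib, config)
    seed_seq = np.random.SeedSequence(config.mcmc.seed)
    s1_seq, s2_seq = seed_seq.spawn(2)
    chains = _run_module_one_stage1(prep, config, s1_seq)
    pooled = _pool_stage1(chains)
    sel = _select_imputations(len(pooled["M"]), config.mcmc.n_imputations)
    s2 = _stage2_chainlets(prep, config, spec, pooled["M"][sel], pooled["theta"][sel], s2_seq)
    beta, lam, sigma = _theta_draws_uncentered(prep, s2["theta"])
    diag = _diagnostics(chains, s2, key_theta=True)
    return PosteriorSamples(
        eta=0.0,
        gamma=s2["gamma"],
        tau=s2["tau"],
        alpha=s2["alpha"],
        u=s2["u"],
        sigma_u=s2["sigma_u"],
        levels=s2["levels"],
        theta_beta=beta,
        theta_lam=lam,
        theta_sigma=sigma,
        sites=prep.design.sites,
        diagnostics=diag,
        seed=config.mcmc.seed,
    )


def sample_smi_posterior(
    data,
    calib,
    config: RunConfig | None = None,
    eta: float = 0.5,
    model_spec: POModelSpec | None = None,
) -> PosteriorSamples:
    """Semi-modular posterior at influence η.

    Stage one samples the power posterior over (θ, M, φ̃) with the
    analysis likelihood tempered by η; stage two redraws the reported
    analysis parameters from their full conditional given the imputed
    levels. η = 0 targets the cut posterior, η = 1 the full joint.
    """
    config = config or RunConfig()
    if not (0.0 <= eta <= 1.0):
        raise ValueError(f"eta must lie in [0, 1], got {eta}")
    spec = model_spec or POModelSpec.from_config(config)
    prep = _Prepared(data, calib, config)
    seed_seq = np.random.SeedSequence(config.mcmc.seed)
    s1_seq, s2_seq = seed_seq.spawn(2)
    chains = _run_power_stage1(prep, config, eta, spec, s1_seq)
    pooled = _pool_stage1(chains)
    phis = sum((c["phi"] for c in chains), [])
    sel = _select_imputations(len(pooled["M"]), config.mcmc.n_imputations)
    phi_inits = [phis[i] for i in sel] if eta > 0 else None
    s2 = _stage2_chainlets(
        prep, config, spec, pooled["M"][sel], pooled["theta"][sel], s2_seq, phi_inits
    )
    beta, lam, sigma = _theta_draws_uncentered(prep, s2["theta"])
    diag = _diagnostics(chains, s2, key_theta=not prep.fixed_theta, eta=eta)
    return PosteriorSamples(
        eta=eta,
        gamma=s2["gamma"],
        tau=s2["tau"],
        alpha=s2["alpha"],
        u=s2["u"],
        sigma_u=s2["sigma_u"],
        levels=s2["levels"],
        theta_beta=beta,
        theta_lam=lam,
        theta_sigma=sigma,
        sites=prep.design.sites,
        diagnostics=diag,
        seed=config.mcmc.seed,
    )


def sample_full_posterior(
    data, calib, config: RunConfig | None = None, model_spec: POModelSpec | None = None
) -> PosteriorSamples:
    """The directly-specified joint Bayesian posterior.

    A single Metropolis-within-Gibbs chain over (θ, M, φ) in which the
    level updates use the analysis model at full strength and φ is the
    reported parameter — no auxiliary copy and no second stage.
    """
    config = config or RunConfig()
    spec = model_spec or POModelSpec.from_config(config)
    prep = _Prepared(data, calib, config)
    mc = config.mcmc
    priors = config.priors
    seed_seq = np.random.SeedSequence(mc.seed)
    recs = []
    for cseed in seed_seq.spawn(mc.chains):
        rng = np.random.default_rng(cseed)
        tv = prep.theta0 + 0.01 * rng.standard_normal(5)
        tv[:3] = np.sort(tv[:3])
        L = prep.emission(tv)
        t_prior = prep.theta_logprior(tv, priors)
        M_idx = _sample_levels(rng, L)
        phi = _init_phi(prep, spec, M_idx)
        scales = _default_phi_scales(spec)
        scales["theta"] = 0.1
        acc = _fresh_acc()
        rec = {"theta": [], "M": [], "phi": []}
        for it in range(mc.warmup + mc.draws * mc.thin):
            if not prep.fixed_theta:
                tv, L, t_prior = _theta_step(
                    rng, prep, tv, L, t_prior, M_idx, scales, acc, priors
                )
            M_idx = _sample_levels(rng, L + phi.level_logprobs_all())
            _phi_sweep(rng, phi, M_idx, 1.0, priors, spec, scales, acc)
            if it < mc.warmup:
                if (it + 1) % 25 == 0:
                    _adapt(scales, acc, ("a1", "a2", "gamma", "tau", "u", "lsu"))
                    _adapt(scales, acc, ("theta",), target=0.25)
            elif (it - mc.warmup + 1) % mc.thin == 0:
                rec["theta"].append(tv.copy())
                rec["M"].append(M_idx.copy())
                rec["phi"].append(
                    (phi.alpha.copy(), phi.gamma, phi.tau, phi.u.copy(), phi.log_sigma_u)
                )
        rec["acc"] = acc
        recs.append(rec)

    pooled = _pool_stage1(recs)
    phis = sum((c["phi"] for c in recs), [])
    alpha = np.array([p[0] for p in phis])
    gamma = np.array([p[1] for p in phis])
    tau = np.array([p[2] for p in phis])
    u = np.array([p[3] for p in phis])
    sigma_u = np.exp([p[4] for p in phis])
    beta, lam, sigma = _theta_draws_uncentered(prep, pooled["theta"])
    gamma_chains = np.array(
        [[p[1] for p in c["phi"]] for c in recs]
    )
    diag = {
        "rhat_gamma": _split_rhat_1d(gamma_chains),
        "accept": {k: v[0] / max(v[1], 1) for k, v in recs[0]["acc"].items()},
    }
    return PosteriorSamples(
        eta=1.0,
        gamma=gamma,
        tau=tau,
        alpha=alpha,
        u=u,
        sigma_u=np.asarray(sigma_u),
        levels=pooled["M"] + 1,
        theta_beta=beta,
        theta_lam=lam,
        theta_sigma=sigma,
        sites=prep.design.sites,
        diagnostics=diag,
        seed=mc.seed,
    )


def _diagnostics(chains, s2, key_theta: bool, eta: float | None = None) -> dict:
    diag = {"stage2_accept": {k: v[0] / max(v[1], 1) for k, v in s2["acc"].items()}}
    if key_theta and chains and len(chains[0].get("theta", [])) > 1:
        sig = np.array([[t[4] for t in c["theta"]] for c in chains])
        diag["rhat_log_sigma_theta"] = _split_rhat_1d(sig)
    if eta is not None and eta > 0 and chains and chains[0].get("phi"):
        g = np.array([[p[1] for p in c["phi"]] for c in chains])
        diag["rhat_gamma_tilde"] = _split_rhat_1d(g)
    return diag


# ---------------------------------------------------------------------------
# ELPD and η selection


def pointwise_loglik(samples: PosteriorSamples, data, config: RunConfig | None = None) -> np.ndarray:
    """Per-draw, per-sample log predictive density of the δ15N values.

    ll[s, i] = log Σ_m p(m | φ_s, x_i) p(z_i | m, θ_s), the analysis
    model marginalizing the latent level — the observed-outcome
    predictive the η selection targets.
    """
    config = config or RunConfig()
    arch = data.arch if isinstance(data, TwoModuleData) else list(data)
    prep = _Prepared(arch, CalibrationParams(0.0, 1.0, 2.0, 0.0, 1.0), config)
    d = prep.design
    S = samples.n_draws
    n = prep.n
    ll = np.empty((S, n))
    for s in range(S):
        L = emission_log_matrix(
            prep.d15n,
            prep.lognodes,
            prep.logw,
            samples.theta_beta[s],
            samples.theta_lam[s],
            float(samples.theta_sigma[s]),
        )
        e = (
            samples.gamma[s] * d.x_size
            + samples.tau[s] * d.x_date
            + samples.u[s][d.site_idx]
        )
        lp = cumulative_logprobs(samples.alpha[s, 0], samples.alpha[s, 1], e)
        ll[s] = logsumexp(L + lp, axis=1)
    return ll


def elpd_from_loglik(ll: np.ndarray):
    """PSIS-LOO ELPD from a (draws, obs) pointwise log-likelihood matrix."""
    import arviz as az

    lw, khat = az.psislw(-ll.T)
    elpd_i = logsumexp(ll.T + np.asarray(lw), axis=1)
    khat = np.asarray(khat)
    n = ll.shape[1]
    se = float(np.sqrt(n * np.var(elpd_i)))
    return float(elpd_i.sum()), se, khat


def elpd_curve(
    data,
    calib,
    config: RunConfig | None = None,
    eta_grid: Sequence[float] | None = None,
) -> ELPDCurve:
    """ELPD of the observed δ15N values across an η grid.

    Each η is fitted by :func:`sample_smi_posterior` and scored by
    importance-sampling leave-one-out on the pointwise predictive
    density. Observations with Pareto-k above 0.7 are reported per η;
    a high fraction warrants a k-fold rerun (``kfold_elpd``).
    """
    config = config or RunConfig()
    etas = list(config.eta_grid if eta_grid is None else eta_grid)
    if len(etas) == 0:
        raise ValueError("eta grid is empty")
    elpds, ses, kfracs = [], [], []
    for eta in etas:
        samples = sample_smi_posterior(data, calib, config, eta=eta)
        ll = pointwise_loglik(samples, data, config)
        e, se, khat = elpd_from_loglik(ll)
        kbad = float(np.mean(khat > PSIS_K_THRESHOLD))
        if kbad > 0:
            logger.warning(
                "eta=%.2f: %.0f%% of observations have Pareto-k > %.1f",
                eta,
                100 * kbad,
                PSIS_K_THRESHOLD,
            )
        elpds.append(e)
        ses.append(se)
        kfracs.append(kbad)
    star = etas[int(np.argmax(elpds))]
    return ELPDCurve(etas=etas, elpd=elpds, elpd_se=ses, eta_star=star, pareto_k_frac=kfracs)


def kfold_elpd(data, calib, config: RunConfig, eta: float, k: int = 5) -> float:
    """K-fold cross-validated ELPD — the fallback when PSIS is unstable.

    Refits the SMI posterior with each fold's δ15N contribution removed
    from the imputation likelihood (the held-out samples keep uniform
    level probabilities) and scores the held-out predictive density.
    """
    arch = data.arch if isinstance(data, TwoModuleData) else list(data)
    modern = data.modern if isinstance(data, TwoModuleData) else None
    n = len(arch)
    rng = np.random.default_rng(config.mcmc.seed)
    folds = rng.permutation(n) % k
    total = 0.0
    for fold in range(k):
        keep = [s for s, f in zip(arch, folds) if f != fold]
        held = [s for s, f in zip(arch, folds) if f == fold]
        sub = TwoModuleData(keep, modern)
        samples = sample_smi_posterior(sub, calib, config, eta=eta)
        ll = _heldout_loglik(samples, keep, held, config)
        total += float(logsumexp(ll, axis=0).sum() - ll.shape[1] * np.log(ll.shape[0]))
    return total


def _heldout_loglik(samples: PosteriorSamples, keep, held, config: RunConfig) -> np.ndarray:
    """Predictive log density of held-out samples; sites unseen during
    fitting get a random effect drawn from its prior per posterior draw."""
    prep = _Prepared(held, CalibrationParams(0.0, 1.0, 2.0, 0.0, 1.0), config)
    fit_design = build_design(keep, config)
    x_size = fit_design.transform_size([s.size_ha for s in held])
    x_date = (
        np.array([s.date_calBC for s in held]) - fit_design.date_center
    ) / fit_design.date_scale
    site_of = [s.site for s in held]
    rng = np.random.default_rng(samples.seed or 0)
    S = samples.n_draws
    ll = np.empty((S, len(held)))
    lookup = {name: j for j, name in enumerate(samples.sites)}
    for s in range(S):
        L = emission_log_matrix(
            prep.d15n, prep.lognodes, prep.logw,
            samples.theta_beta[s], samples.theta_lam[s], float(samples.theta_sigma[s]),
        )
        u = np.array(
            [
                samples.u[s][lookup[name]]
                if name in lookup
                else rng.normal(0, samples.sigma_u[s])
                for name in site_of
            ]
        )
        e = samples.gamma[s] * x_size + samples.tau[s] * x_date + u
        lp = cumulative_logprobs(samples.alpha[s, 0], samples.alpha[s, 1], e)
        ll[s] = logsumexp(L + lp, axis=1)
    return ll


# ---------------------------------------------------------------------------
# Bayes factors


def bayes_factor(samples: PosteriorSamples, direction: str | None = None) -> BayesFactorResult:
    """One-sided posterior sign odds on the settlement-size effect.

    With the symmetric prior on gamma these posterior odds equal the
    Bayes factor for the sign hypothesis. A zero denominator caps the
    estimate at the draw count (a lower bound).
    """
    direction = direction or "negative"
    if direction not in ("negative", "positive"):
        raise ValueError(f"unknown direction {direction!r}")
    g = samples.gamma
    n = len(g)
    if n < 1000:
        logger.warning("bayes_factor on %d draws; >= 1000 recommended", n)
    n_neg = int(np.sum(g < 0))
    n_pos = int(np.sum(g > 0))
    num, den = (n_neg, n_pos) if direction == "negative" else (n_pos, n_neg)
    if den == 0:
        return BayesFactorResult(bf=float(n), n_draws=n, direction=direction, capped=True)
    return BayesFactorResult(bf=num / den, n_draws=n, direction=direction, capped=False)
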