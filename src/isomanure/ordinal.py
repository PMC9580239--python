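"""Mixed-effects proportional-odds regression of manuring level.

The analysis-stage model: for sample i at site s(i) with transformed
size covariate x_size and standardized date x_date,

    P(M_i <= m) = expit(alpha_m - (gamma*x_size_i + tau*x_date_i + u_s(i)))
    u_s ~ Normal(0, sigma_u^2),   alpha_1 < alpha_2

so a *negative* gamma means larger settlements shift probability toward
lower manuring levels (cumulative probabilities of "low or lower" and
"medium or lower" rise with size). Maximum likelihood integrates the
site intercepts by Gauss-Hermite quadrature; the Wald test on gamma is
one-sided in the configured direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .io_config import ArchSample, RunConfig, level_to_code

_GH_NODES = 25


@dataclass
class Design:
    """Model-scale covariates and site grouping for a set of samples.

    ``x_size`` is raw or log hectares minus its sample mean, ``x_date``
    is the centered/scaled date (older = larger). The stored transform
    state lets new size values (e.g. a plotting grid) be mapped onto the
    same scale.
    """

    x_size: np.ndarray
    x_date: np.ndarray
    site_idx: np.ndarray
    sites: list
    size_transform: str
    size_center: float
    date_center: float
    date_scale: float

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def transform_size(self, size_ha) -> np.ndarray:
        s = np.asarray(size_ha, dtype=float)
        x = np.log(s) if self.size_transform == "log" else s
        return x - self.size_center


def build_design(samples: Sequence[ArchSample], config: RunConfig | None = None) -> Design:
    """Build the covariate design shared by the generator and all fitters.

    Centering the size covariate and standardizing date changes only the
    cutpoints, not gamma or tau, but greatly improves conditioning.
    """
    config = config or RunConfig()
    size = np.array([s.size_ha for s in samples], dtype=float)
    date = np.array([s.date_calBC for s in samples], dtype=float)
    xs = np.log(size) if config.size_transform == "log" else size
    size_center = float(xs.mean())
    date_center = float(date.mean())
    date_scale = float(date.std()) or 1.0
    sites = sorted({s.site for s in samples})
    lookup = {name: k for k, name in enumerate(sites)}
    return Design(
        x_size=xs - size_center,
        x_date=(date - date_center) / date_scale,
        site_idx=np.array([lookup[s.site] for s in samples]),
        sites=sites,
        size_transform=config.size_transform,
        size_center=size_center,
        date_center=date_center,
        date_scale=date_scale,
    )


@dataclass(frozen=True)
class POParams:
    """Point values of the proportional-odds model."""

    alpha1: float
    alpha2: float
    gamma: float
    tau: float
    u: dict = field(default_factory=dict)
    sigma_u: float = 0.0

    def __post_init__(self):
        if not (self.alpha1 < self.alpha2):
            raise ValueError(f"require alpha1 < alpha2, got ({self.alpha1}, {self.alpha2})")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be nonnegative")


def cumulative_logprobs(alpha1, alpha2, eta_lin):
    """Log category probabilities, shape ``eta_lin.shape + (3,)``.

    Probabilities are clipped at 1e-300 before logging; an exactly-zero
    category therefore maps to a log probability of about -690, which
    the likelihood treats as effectively -inf.
    """
    eta = np.asarray(eta_lin, dtype=float)
    c1 = expit(alpha1 - eta)
    c2 = expit(alpha2 - eta)
    p = np.stack([c1, c2 - c1, 1.0 - c2], axis=-1)
    return np.log(np.clip(p, 1e-300, None))


def level_logprob(alpha1, alpha2, eta_lin, level_idx):
    """Log probability of the assigned level (0-based) per observation."""
    lp = cumulative_logprobs(alpha1, alpha2, eta_lin)
    return np.take_along_axis(lp, np.asarray(level_idx)[..., None], axis=-1)[..., 0]


def po_cumulative_prob(
    params: POParams,
    x_size: float,
    x_date: float,
    site,
    m,
    marginal: bool = False,
    n_mc: int = 2000,
    rng=None,
) -> float:
    """P(level <= m) at model-scale covariates for one site.

    ``m`` is "low"/"medium"/"high" or 1/2/3; P(<= high) is identically 1.
    Unknown sites raise unless ``marginal`` is set, in which case the
    random effect is integrated over Normal(0, sigma_u^2) by Monte Carlo.
    """
    code = level_to_code(m)
    if code == 3:
        return 1.0
    eta = params.gamma * x_size + params.tau * x_date
    alpha_m = params.alpha1 if code == 1 else params.alpha2
    if marginal:
        rng = rng or np.random.default_rng(0)
        u = rng.normal(0.0, params.sigma_u, size=n_mc) if params.sigma_u > 0 else np.zeros(1)
        return float(np.mean(expit(alpha_m - (eta + u))))
    if site in params.u:
        u_site = params.u[site]
    elif not params.u and params.sigma_u == 0.0:
        u_site = 0.0
    else:
        raise KeyError(
            f"no random effect supplied for site {site!r}; pass marginal=True to integrate"
        )
    return float(expit(alpha_m - (eta + u_site)))


def po_loglik(
    params: POParams,
    levels: Sequence[int],
    design: Design,
) -> float:
    """Log likelihood of assigned levels given fixed parameters.

    Random effects are taken at their supplied values (conditional
    likelihood); missing sites default to u = 0. Zero-probability
    categories give -inf.
    """
    level_idx = np.array([level_to_code(v) for v in levels]) - 1
    u = np.array([params.u.get(s, 0.0) for s in design.sites])
    eta = params.gamma * design.x_size + params.tau * design.x_date + u[design.site_idx]
    lp = level_logprob(params.alpha1, params.alpha2, eta, level_idx)
    total = float(lp.sum())
    return -np.inf if total <= len(level_idx) * np.log(1e-299) else total


@dataclass
class WaldFit:
    """Maximum-likelihood proportional-odds fit with a one-sided Wald test."""

    alpha1: float
    alpha2: float
    gamma: float | None
    tau: float | None
    sigma_u: float | None
    se: dict
    z: float | None
    p_one_sided: float | None
    direction: str
    converged: bool
    loglik: float
    n_obs: int
    used_random_effects: bool

    def params(self) -> POParams:
        return POParams(
            alpha1=self.alpha1,
            alpha2=self.alpha2,
            gamma=self.gamma or 0.0,
            tau=self.tau or 0.0,
            sigma_u=self.sigma_u or 0.0,
        )


def _marginal_negll(
    pv: np.ndarray,
    level_idx: np.ndarray,
    design: Design,
    include_size: bool,
    include_date: bool,
    random_effects: bool,
    gh: tuple,
) -> float:
    k = 0
    a1 = pv[k]; k += 1
    a2 = a1 + np.exp(pv[k]); k += 1
    gamma = pv[k] if include_size else 0.0
    k += include_size
    tau = pv[k] if include_date else 0.0
    k += include_date
    eta = gamma * design.x_size + tau * design.x_date
    if not random_effects:
        return -float(level_logprob(a1, a2, eta, level_idx).sum())
    sigma_u = np.exp(pv[k])
    nodes, logw = gh
    shift = np.sqrt(2.0) * sigma_u * nodes  # (K,)
    lp = level_logprob(a1, a2, eta[:, None] + shift[None, :], level_idx[:, None])  # (n, K)
    acc = np.zeros((design.n_sites, len(nodes)))
    np.add.at(acc, design.site_idx, lp)
    from scipy.special import logsumexp

    site_ll = logsumexp(acc + logw[None, :], axis=1)
    return -float(site_ll.sum())


def fit_po_wald(
    levels: Sequence[int],
    design: Design,
    config: RunConfig | None = None,
    include_size: bool = True,
    include_date: bool | None = None,
    random_effects: bool | None = None,
) -> WaldFit:
    """Fit the proportional-odds model by marginal maximum likelihood.

    Site random intercepts are integrated out by 25-node Gauss-Hermite
    quadrature. With fewer than two sites (or ``random_effects=False``)
    the fixed-intercept model is fitted instead. Non-convergence or a
    non-invertible Hessian flags the result rather than failing silently.
    """
    config = config or RunConfig()
    include_date = config.include_date if include_date is None else include_date
    random_effects = config.random_effects if random_effects is None else random_effects
    level_idx = np.array([level_to_code(v) for v in levels]) - 1
    if len(np.unique(level_idx)) < 2:
        raise ValueError("need at least 2 distinct manuring levels to fit")
    if design.n_sites < 2:
        random_effects = False

    x, w = np.polynomial.hermite.hermgauss(_GH_NODES)
    gh = (x, np.log(w) - 0.5 * np.log(np.pi))

    # start: cutpoints from marginal level frequencies, effects at zero
    freqs = np.bincount(level_idx, minlength=3) / len(level_idx)
    c1 = np.clip(freqs[0], 0.02, 0.96)
    c2 = np.clip(freqs[0] + freqs[1], c1 + 0.02, 0.98)
    start = [np.log(c1 / (1 - c1)), np.log(np.log(c2 / (1 - c2)) - np.log(c1 / (1 - c1)))]
    if include_size:
        start.append(0.0)
    if include_date:
        start.append(0.0)
    if random_effects:
        start.append(np.log(0.5))
    start = np.array(start)

    args = (level_idx, design, include_size, include_date, random_effects, gh)
    res = optimize.minimize(
        _marginal_negll, start, args=args, method="BFGS",
        options={"gtol": 1e-6, "maxiter": 500},
    )
    # polish: finite-difference BFGS can stall on nearly-flat marginals
    polish = optimize.minimize(
        _marginal_negll, res.x, args=args, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
    )
    opt_ok = bool(res.success or polish.success)
    if polish.fun < res.fun:
        res = polish
    pv = res.x

    from statsmodels.tools.numdiff import approx_hess

    H = approx_hess(pv, _marginal_negll, args=args)
    converged = opt_ok
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) <= 0):
            converged = False
    except np.linalg.LinAlgError:
        cov = np.full((len(pv), len(pv)), np.nan)
        converged = False

    k = 0
    a1 = pv[k]
    se_a1 = np.sqrt(abs(cov[k, k]))
    k += 1
    a2 = a1 + np.exp(pv[k])
    g = np.array([1.0, np.exp(pv[k])])
    se_a2 = float(np.sqrt(abs(g @ cov[:2, :2] @ g)))
    k += 1
    gamma = tau = sigma_u = None
    se = {"alpha1": float(se_a1), "alpha2": se_a2}
    z = p = None
    if include_size:
        gamma = float(pv[k])
        se["gamma"] = float(np.sqrt(abs(cov[k, k])))
        if se["gamma"] > 0:
            z = gamma / se["gamma"]
            p = float(stats.norm.cdf(z) if config.direction == "negative" else stats.norm.sf(z))
        k += 1
    if include_date:
        tau = float(pv[k])
        se["tau"] = float(np.sqrt(abs(cov[k, k])))
        k += 1
    if random_effects:
        sigma_u = float(np.exp(pv[k]))
        se["sigma_u"] = float(sigma_u * np.sqrt(abs(cov[k, k])))

    return WaldFit(
        alpha1=float(a1),
        alpha2=float(a2),
        gamma=gamma,
        tau=tau,
        sigma_u=sigma_u,
        se=se,
        z=None if z is None else float(z),
        p_one_sided=p,
        direction=config.direction,
        converged=converged,
        loglik=-float(res.fun),
        n_obs=len(level_idx),
        used_random_effects=random_effects,
    )
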