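# Methods

This note documents the statistical models, priors, numerical choices
and validation scope of `isomanure`. Nothing here reports an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Two-module structure

The inference couples two models through the latent ordinal manuring
level M_i ∈ {low, medium, high} of each archaeological grain sample.

**Module one (imputation / measurement).** The calibration model for
grain δ15N (‰ vs AIR) given manuring level and mean annual rainfall
r (mm/yr):

    z ~ Normal(β_m + λ·log r, σ),  β_low < β_med < β_high.

Modern samples with known levels identify (β, λ, σ); archaeological
samples contribute through the same density with M_i latent and r_i
uniform on the sample's past-rainfall range [r_min, r_max]. The
rainfall integral uses Gauss–Legendre quadrature (15 nodes by default;
exact for point ranges, and the affine map cancels the 1/(b−a)
normalisation so weights are range-free). The ordering constraint on
the intercepts is essential: without it, level labels are
unidentifiable once levels are latent.

A configuration switch (`per_level_slope`) relaxes the common slope to
per-level slopes; the parallel-line form is the parsimonious default.

**Module two (analysis).** Mixed-effects proportional odds:

    P(M_i ≤ m) = logit⁻¹(α_m − (γ·x_size + τ·x_date + u_s)),
    u_s ~ Normal(0, σ_u²),  α_1 < α_2.

The sign convention makes γ < 0 mean "larger settlements, less
manure", so cumulative-probability curves *rise* with size under
extensification. The size covariate is raw hectares or log-hectares
(`size_transform`); the date covariate is centred and scaled. Both the
synthetic generator and every fitter build covariates through the same
`build_design` routine, so transform and centring can never drift
apart; centring changes only the cutpoints, never γ or τ.

The packaged synthetic scenarios default to `size_transform="log"`:
published settlement sizes span 0.1–130 ha, and on the raw-hectare
scale any non-negligible γ drives category probabilities to 0/1 for
most of that range, which no ordinal dataset of realistic size can
support.

## Inference strategies

* **Single imputation**: most-probable level per sample from the
  calibration posterior (ties break toward the *lower* level —
  conservative about claiming intensive management), then marginal
  maximum likelihood for the proportional-odds model with site
  intercepts integrated by 25-node Gauss–Hermite quadrature. The GH
  marginal likelihood was verified against adaptive numerical
  integration to 12 digits. Standard errors come from the numerical
  Hessian (delta method for transformed coordinates); the Wald test on
  γ is one-sided in the configured direction. Below two sites, or on
  request, the fixed-intercept model is fitted instead; that limit
  reproduces `statsmodels`' `OrderedModel` to 3–4 decimals.

* **Cut posterior / Bayesian multiple imputation**: stage one samples
  p(θ, M | modern, arch δ15N) under a *uniform* level prior — the
  imputation module alone, with no feedback from the settlement-size
  model; stage two draws the analysis parameters φ = (α, γ, τ, u, σ_u)
  from p(φ | M) for each completed level dataset and pools. One
  stage-two chainlet runs per completed dataset with frozen,
  pilot-adapted proposal scales, so pooled draws are exchangeable
  across datasets.

* **Semi-modular inference**: stage one targets the power posterior

      p_η(θ, M, φ̃) ∝ p(θ) p(modern|θ) Π_i p(z_i|M_i, θ) p(M_i|φ̃)^η p(φ̃)

  (likelihood tempered, priors untempered), stage two redraws the
  reported φ | M exactly as in the cut sampler. At η = 0 the tempered
  factor is constant, reproducing the cut target; at η = 1 stage one is
  the joint posterior and stage two its full conditional, reproducing
  full Bayes. Both boundary identities are verified distributionally in
  the test suite against independent code paths (the module-one
  sampler; a directly-specified joint sampler).

* **η selection**: expected log pointwise predictive density of the
  *observed* outcome — the archaeological δ15N values, with the latent
  level marginalised through the analysis model:
  p(z_i | θ, φ) = Σ_m p(m|φ, x_i) p(z_i|m, θ) — estimated by
  Pareto-smoothed importance-sampling leave-one-out (`arviz.psislw`).
  Observations with Pareto k > 0.7 trigger a per-point warning; a
  K-fold refit (`kfold_elpd`) is available when PSIS is unstable.
  δ15N is the only observed outcome (levels are latent), which is why
  it is the predictive target.

* **Bayes factors**: the posterior sign proportion
  #(γ in direction)/#(γ against). Under the symmetric normal prior on
  γ this ratio equals the one-sided Bayes factor. A zero denominator
  returns the draw count as a *lower bound* with `capped=True`;
  comparisons between two capped values are censored and are reported
  as such rather than resolved arbitrarily.

## Priors and defaults

| parameter | prior | default scale | rationale |
|---|---|---|---|
| β_m | Normal(0, 10 ‰), ordered | 10 | weakly informative; data span ~2–12 ‰ |
| λ | Normal(0, 10) | 10 | slope magnitude is O(1) ‰ per log-mm |
| σ | half-Normal(5 ‰) | 5 | residuals are ~1 ‰ |
| α_1 < α_2 | Normal(0, 5), ordered | 5 | cutpoints on the logit scale |
| γ, τ | Normal(0, 2.5) | 2.5 | symmetric about 0 so sign odds = Bayes factor; covariates are centred/scaled |
| σ_u | half-Normal(1) | 1 | site heterogeneity on the logit scale |

MCMC defaults: 2 chains, 500 warmup, 500 retained draws, 250 completed
datasets with 4 stage-two draws each. The charring correction is an
additive offset, default 0 because published archaeological values are
already charring-corrected; it is configurable for raw inputs.

## Samplers and numerics

The calibration posterior uses a blocked Gibbs sampler: coefficients
given σ are an exact multivariate-normal draw (conditional conjugacy,
with rejection under the ordering constraint), and log σ is drawn from
its one-dimensional conditional by inverse-CDF on a 256-point grid.
Successive draws are nearly independent; split-chain R̂ ≤ 1.01 is
checked per parameter and a violation flags the result and logs a
warning rather than failing.

The two-module samplers are Metropolis-within-Gibbs: a joint
random-walk update on θ (betas internally re-expressed against centred
log-rainfall, which removes the intercept–slope ridge), exact Gibbs on
the discrete levels via the Gumbel-argmax trick, and componentwise
random-walk updates on φ, with all site intercepts updated in one
vectorised step (they are conditionally independent given the rest).
Proposal scales adapt toward standard acceptance targets during warmup
only. Emission densities are computed in log space throughout; an
exactly-zero category probability contributes −∞ and is flagged, never
silently clipped into a finite value.

Degenerate inputs: point rainfall ranges collapse the quadrature to a
single node; a sample whose δ15N has zero likelihood under every level
raises an error naming the sample; fewer than two observed level
categories is a fit error; a single site disables random effects.

## What the synthetic studies show — and do not

The generator emulates the structure the analysis assumes: modern
values scattered around parallel level lines (defaults β = 2/5/8 ‰,
λ = −1.5, σ = 1.0 ‰ — fixture conventions producing realistic 2–12 ‰
spans, not empirical estimates), archaeological levels drawn from the
proportional-odds model over published site covariates, true rainfall
uniform in the site range, and hidden truth saved for recovery checks.
A triangular rainfall emitter is available to create deliberate
prior–generator mismatch, the model-error regime semi-modular
inference is designed for.

Passing tests therefore establish internal correctness — the samplers
hit their targets (verified against brute-force enumeration on a toy
where the posterior is an exhaustively computable 729-term mixture),
the estimators recover generator truth with near-nominal interval
coverage, and the feedback mechanism concentrates evidence — under a
*correctly specified* generator. They do not establish behaviour under
the kinds of misspecification real assemblages carry (taxon effects,
non-uniform rainfall error, charring heterogeneity), nor do they
reproduce published coefficients, which would require the original
supplementary data tables as input. The pipeline accepts such tables
through the documented CSV schema.

Two quantitative caveats from the validation runs are worth stating.
First, under a well-specified generator the ELPD–η curve is flat to
within a fraction of its standard error, so the selected η* varies
between replicates; this is expected — modular tempering matters when
the model is wrong, and here it is right. Second, with the strong
settlement-size effect (γ = −0.5 over a seven-unit log-size span) both
the cut and the SMI posteriors can place essentially no mass on γ > 0,
in which case both sign-odds Bayes factors are reported as capped
lower bounds and their comparison is censored; the feedback effect is
then visible instead in the posterior means, which sit further into
the negative tail under SMI than under the cut in most replicates
(the acceptance script measures this as
`antidilution_smi_mean_more_negative_frac`).

## Problem sizes

Validation workloads are sized for a single CPU: two-site/30-sample
boundary datasets, a six-sample enumeration toy, and a recovery grid of
24 replicates at n = 248 (the three regional site layouts pooled, 8
samples per site/phase cell) with a three-point η grid and shortened
chains. The full acceptance sweep completes in roughly ten minutes;
the unit suite in about one.
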