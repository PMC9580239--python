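# isomanure

Infer how intensively past farmers manured their cereals — and how that
intensity changed with settlement size — from the nitrogen isotope
composition of charred archaeological grain.

Manure raises the δ15N of soil and of the crops grown on it, so the
δ15N of a charred cereal grain carries a signal of manuring rate; but
aridity also raises plant δ15N, so the signal must be read against the
local rainfall. `isomanure` implements the full inferential chain from
grain δ15N values to an ordinal manuring intensity (low < medium <
high) and from there to settlement-scale effects, for archaeobotanists
and archaeological scientists working with crop stable-isotope
assemblages.

## The models

**Calibration (measurement model).** Modern cereal grains grown under
known manuring regimes follow parallel lines in log rainfall:

    δ15N ~ Normal(β_m + λ·log r, σ),   β_low < β_med < β_high

with level intercepts β_m (‰), a common rainfall slope λ (‰ per
log-mm, empirically negative) and residual scale σ. Archaeological
samples carry a past-rainfall *range* per site/phase (built from
speleothem δ18O or pollen-derived anomalies, see `isomanure.rainfall`),
which enters as a uniform prior integrated out by quadrature.

**Analysis (proportional-odds model).** The latent manuring level M of
sample *i* at site *s(i)* follows a mixed-effects cumulative-logit
regression on settlement size and date:

    P(M_i ≤ m) = logit⁻¹( α_m − (γ·size_i + τ·date_i + u_s(i)) ),
    u_s ~ Normal(0, σ_u²)

so γ < 0 means larger settlements manure less — the isotopic signature
of agricultural *extensification*.

**Linking the two.** Because the levels are latent, how much the
analysis model is allowed to inform them matters. Three strategies of
increasing sophistication are provided:

1. **Single imputation** — assign each sample its most probable level,
   then a one-sided Wald test on γ (`fit_po_wald`).
2. **Bayesian multiple imputation / the cut posterior** — propagate
   level uncertainty but allow *no* feedback from the size model into
   level assignment (`sample_cut_posterior`). Robust, but it dilutes
   effect estimates toward zero.
3. **Semi-modular inference (SMI)** — a family of posteriors indexed by
   an influence parameter η ∈ [0, 1] that tempers the analysis-model
   likelihood in the imputation stage: η = 0 is the cut posterior, η = 1
   the full joint Bayesian posterior (`sample_smi_posterior`). η is
   chosen by maximizing the expected log pointwise predictive density
   (ELPD) of the observed δ15N values via PSIS-LOO (`elpd_curve`).

Evidence for a directional size effect is reported as posterior sign
odds on γ, which equal the one-sided **Bayes factor** under the
symmetric prior used for γ (`bayes_factor`).

All samplers are seeded Metropolis-within-Gibbs routines built for this
two-module structure; there is no external probabilistic-programming
dependency.

## Worked example

Simulate an Aegean-like study (published site sizes, dates and
present-day rainfall; known generator truth γ = −0.5), fit the
calibration, and compare cut against SMI:

```python
import dataclasses
from isomanure import (
    fit_calibration, generate_arch, generate_modern, preset_table1,
    bayes_factor, sample_cut_posterior, sample_smi_posterior, elpd_curve,
)
from isomanure.io_config import MCMCConfig, RunConfig
from isomanure.smi import TwoModuleData

spec = dataclasses.replace(
    preset_table1("aegean", n_per_phase=8), gamma=-0.5, sigma_u=0.5, seed=11,
)
arch, truth = generate_arch(spec)
modern = generate_modern(spec.calib, n_per_level=30, seed=12)

cfg = RunConfig(
    eta_grid=[0.0, 0.5, 1.0],
    mcmc=MCMCConfig(chains=2, warmup=300, draws=400, seed=13,
                    n_imputations=200, stage2_draws=4),
)
calib = fit_calibration(modern, cfg)
data = TwoModuleData(arch, modern)

cut = sample_cut_posterior(data, calib, cfg)
curve = elpd_curve(data, calib, cfg)
smi = sample_smi_posterior(data, calib, cfg, eta=curve.eta_star)
```

which prints (seeded, reproducible):

```
calibration: lambda = -1.54 permil per log-mm (truth -1.50)
eta* = 1.0  (ELPD {0.0: -191.6, 0.5: -191.0, 1.0: -190.9})
cut  posterior: gamma = -0.553 +/- 0.208, BF(negative) = 199.0
SMI  posterior: gamma = -0.751 +/- 0.250, BF(negative) = 799.0
```

The calibration slope is recovered; predictive tuning selects full
feedback (η* = 1); and SMI strengthens both the effect estimate and the
one-sided evidence relative to the cut posterior — the anti-dilution
behaviour that motivates semi-modular inference. Figure-style
cumulative-probability-vs-size curves with credible bands come from
`isomanure.reporting.probability_curves`.

The same pipeline is scriptable from a shell (`isomanure simulate`,
`calibrate`, `impute`, `fit-si`, `fit-bmi`, `fit-smi`, `report`); real
data enter as two CSV tables documented in `isomanure.io_config`.

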