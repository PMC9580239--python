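import numpy as np
import pytest

from isomanure.calibration import CalibrationParams
from isomanure.io_config import MCMCConfig, RunConfig
from isomanure.synthetic import generate_arch, generate_modern, simple_scenario


@pytest.fixture
def calib_params():
    return CalibrationParams(beta_low=2.0, beta_med=5.0, beta_high=8.0, lam=-1.5, sigma=1.0)


@pytest.fixture
def quick_config():
    """Short-chain settings for unit tests."""
    return RunConfig(
        mcmc=MCMCConfig(
            chains=2, warmup=200, draws=200, seed=7,
            n_imputations=60, stage2_warmup=50, stage2_draws=3, stage2_thin=3,
        )
    )


@pytest.fixture
def small_scenario():
    spec = simple_scenario(n_sites=5, n_per_site=12, gamma=-0.5, sigma_u=0.4, seed=21)
    arch, truth = generate_arch(spec)
    modern = generate_modern(spec.calib, 25, seed=22)
    return spec, arch, truth, modern
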