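"""Shared builders for posterior-draw fixtures."""

import numpy as np

from isomanure.smi import PosteriorSamples


def samples_with_gamma(gamma_draws, eta=0.5):
    """A minimal PosteriorSamples whose gamma draws are as given."""
    g = np.asarray(gamma_draws, dtype=float)
    S = len(g)
    return PosteriorSamples(
        eta=eta,
        gamma=g,
        tau=np.zeros(S),
        alpha=np.tile([-1.0, 1.0], (S, 1)),
        u=np.zeros((S, 1)),
        sigma_u=np.full(S, 0.3),
        levels=np.ones((S, 4), dtype=int),
        theta_beta=np.tile([2.0, 5.0, 8.0], (S, 1)),
        theta_lam=np.full(S, -1.5),
        theta_sigma=np.ones(S),
        sites=["a"],
    )
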