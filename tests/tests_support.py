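"""Shared helpers for the test suite."""

import numpy as np

from sevocea.bayes import PosteriorDraws


def crafted_draws(b17, b27, sigma11=1.0):
    """PosteriorDraws with specified treatment-coefficient draws, zeros elsewhere."""
    b17 = np.asarray(b17, float)
    b27 = np.asarray(b27, float)
    m = len(b17)
    beta_cost = np.zeros((m, 7))
    beta_cost[:, 6] = b17
    beta_eff = np.zeros((m, 7))
    beta_eff[:, 6] = b27
    sigma = np.tile(np.diag([sigma11, 1.0]), (m, 1, 1))
    return PosteriorDraws(beta_cost=beta_cost, beta_eff=beta_eff, sigma=sigma)
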