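"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import midfield as mf
from midfield import cells as mc


@pytest.fixture(scope="session")
def white_noise_quadratic():
    """White-noise stimuli + 1D quadratic-gain cell (8x8, 2 lags, D=128)."""
    stim = mf.generate_white_noise(12000, 8, 8, seed=3)
    emb = mf.embed_spatiotemporal(stim, 2)
    cell = mc.make_quadratic_cell(8, 8, 2, gamma=0.5)
    rates = mc.rates_on(cell, emb.matrix)
    y = mc.simulate_spikes(rates, seed=4)
    return {"X": emb.matrix, "y": y, "cell": cell, "rates": rates}


@pytest.fixture(scope="session")
def white_noise_or():
    """White-noise stimuli + 2D OR-threshold quadrature-Gabor cell."""
    stim = mf.generate_white_noise(12000, 8, 8, seed=3)
    emb = mf.embed_spatiotemporal(stim, 2)
    cell = mc.make_or_cell(8, 8, 2)
    rates = mc.rates_on(cell, emb.matrix)
    y = mc.simulate_spikes(rates, seed=5, family="or_threshold")
    return {"X": emb.matrix, "y": y, "cell": cell, "rates": rates}


@pytest.fixture(scope="session")
def naturalistic_small():
    """Small naturalistic-surrogate ensemble (6x6, 2 lags)."""
    stim = mf.generate_naturalistic(5000, 6, 6, seed=7)
    emb = mf.embed_spatiotemporal(stim, 2)
    return {"stim": stim, "X": emb.matrix}
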