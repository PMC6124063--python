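"""Shared fixtures: small reusable states for the unit suites."""

import numpy as np
import pytest

from auxregion import ParticleEnsemble, PDEField


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def flat_field():
    """Uniform density 250 on the canonical PDE subdomain (-1, 0)."""
    return PDEField(x_lo=-1.0, h_p=0.01, values=np.full(100, 250.0))


@pytest.fixture
def unit_ensemble(rng):
    """250 uniform particles on the canonical Brownian subdomain (0, 1)."""
    return ParticleEnsemble(rng.uniform(0.0, 1.0, 250), np.array([0.0]),
                            np.array([1.0]))
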