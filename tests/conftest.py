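"""Shared helpers: random model/series generators used across the suite."""

import numpy as np
import pytest

from energylandscape import BinaryPatternSeries, MEMParams


def random_params(n, rng, scale=0.5):
    """MEM parameters with h and upper-triangle J uniform in [-scale, scale]."""
    h = rng.uniform(-scale, scale, size=n)
    J = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    J[iu] = rng.uniform(-scale, scale, size=len(iu[0]))
    J = J + J.T
    return MEMParams(h=h, J=J)


def random_series(n, t, rng):
    """A uniformly random ±1 series (no model structure)."""
    data = rng.choice([-1, 1], size=(n, t))
    return BinaryPatternSeries(data=data, roi_names=[f"r{i}" for i in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
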