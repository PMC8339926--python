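import numpy as np
import pytest
from hypothesis import settings

from grudyn import GRUParams

settings.register_profile("repro", derandomize=True, deadline=None,
                          max_examples=25)
settings.load_profile("repro")


def random_params(rng, d=2, gate_scale=1.0, rec_scale=1.5, bias_scale=0.5):
    """A generic random GRU draw used across the property tests."""
    return GRUParams(
        rng.normal(0, gate_scale, (d, d)), rng.normal(0, gate_scale, (d, d)),
        rng.normal(0, rec_scale, (d, d)), rng.normal(0, bias_scale, d),
        rng.normal(0, bias_scale, d), rng.normal(0, bias_scale, d))


@pytest.fixture
def bistable_pair():
    """Two decoupled bistable units: U_h = diag(3, 3), everything else zero."""
    z = np.zeros((2, 2))
    return GRUParams(z.copy(), z.copy(), np.diag([3.0, 3.0]),
                     np.zeros(2), np.zeros(2), np.zeros(2))


def scalar_gru(u, b):
    """One-dimensional GRU with candidate gain ``u`` and bias ``b``."""
    return GRUParams(np.zeros((1, 1)), np.zeros((1, 1)), np.array([[float(u)]]),
                     np.zeros(1), np.zeros(1), np.array([float(b)]))
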