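import numpy as np
import pytest

from mrlink import HarmonizedInstrument


def make_harmonized(bx, sx, by, sy, ids=None):
    """Build a list of HarmonizedInstrument from parallel arrays."""
    bx, sx, by, sy = map(np.atleast_1d, (bx, sx, by, sy))
    n = len(bx)
    sx = np.broadcast_to(sx, (n,))
    sy = np.broadcast_to(sy, (n,))
    ids = ids or [f"rs{j}" for j in range(n)]
    return [
        HarmonizedInstrument(ids[j], float(bx[j]), float(sx[j]),
                             float(by[j]), float(sy[j]))
        for j in range(n)
    ]


def random_harmonized(rng, n, causal=0.1, se_y=0.05):
    """Valid-instrument set drawn from the linear causal model."""
    gamma = rng.uniform(0.05, 0.3, n)
    bx = rng.normal(gamma, 0.003)
    by = rng.normal(causal * gamma, se_y)
    return make_harmonized(np.abs(bx), 0.003, by, se_y)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
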