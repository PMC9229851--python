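import numpy as np
import pytest

from vesselseg.preprocessing import preprocess
from vesselseg.synthetic import SynthConfig, generate_vessel_mask, render_sample


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig(size=128, target_density=0.10, seed=1)


@pytest.fixture(scope="session")
def synth_sample(synth_cfg):
    return render_sample(generate_vessel_mask(synth_cfg), synth_cfg)


@pytest.fixture(scope="session")
def enhanced(synth_sample):
    return preprocess(synth_sample)


def numeric_grad(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f()
        flat[i] = orig - eps
        lo = f()
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g
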