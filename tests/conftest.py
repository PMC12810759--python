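import numpy as np
import pytest

from ecgrqa import SynthSpec, gen_signal


@pytest.fixture(scope="session")
def sine_signal():
    """Clean sine with a period incommensurate with the sampling grid."""
    t = np.arange(2000)
    return np.sin(2 * np.pi * t / 128.7)


@pytest.fixture(scope="session")
def lorenz_signal():
    return gen_signal(SynthSpec("lorenz", fs=250, duration=8.0, seed=0,
                                params={"dt": 0.03}))


@pytest.fixture(scope="session")
def noise_signal():
    return gen_signal(SynthSpec("white_noise", fs=250, duration=8.0, seed=7))


@pytest.fixture(scope="session")
def random_binary_grids():
    """Seeded random binary matrices spanning sides 4-16, densities 0.05-0.95."""
    rng = np.random.default_rng(2024)
    grids = []
    for _ in range(100):
        side = int(rng.integers(4, 17))
        density = rng.uniform(0.05, 0.95)
        grids.append((rng.random((side, side)) < density).astype(np.uint8))
    return grids
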