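import numpy as np
import pytest

from sirsevo import SimConfig, Simulation, StrainTraits
from sirsevo import _kernels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A 20x20 lattice config cheap enough for per-test simulation."""
    return SimConfig(L=20, seed=42, init_strain=StrainTraits(1.0, 0.5))


@pytest.fixture
def seeded_kernel():
    """Seed the kernel's global RNG so bare step()/margolus calls reproduce."""
    _kernels.seed_rng(99)
    return 99
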