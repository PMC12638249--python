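import numpy as np
import pytest

from inifield.synth import make_nuclei_volume
from inifield.trainer import CompressionConfig, compress


@pytest.fixture(scope="session")
def nuclei_small():
    """Small 3D nucleus volume shared across suites."""
    return make_nuclei_volume((12, 24, 24), n_nuclei=2, seed=7)


@pytest.fixture(scope="session")
def trained_file(nuclei_small):
    """A short real compression run; reused wherever a trained unit is needed."""
    cfg = CompressionConfig(target_cr=4.0, steps=300, seed=0, log_every=100)
    return compress(nuclei_small, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
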