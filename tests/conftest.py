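import numpy as np
import pytest

from rnachase.simulate import KineticParams, SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact mixed dataset reused across read-level tests."""
    cfg = SimConfig(
        seed=7,
        n_genes=8,
        depth=6000,
        multi_isoform_fraction=0.25,
        include_classes=True,
        p_allnone=0.5,
        s_intron=(0.3, 0.7),
    )
    return simulate_dataset(cfg)
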