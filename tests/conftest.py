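import numpy as np
import pytest

from epimr import synthetic as syn


@pytest.fixture(scope="session")
def small_bundle():
    """Planted study bundle, small enough to reuse across tests."""
    design = syn.planted_design(seed=11, n_genes=300, n_deg_per_direction=40, n_denovo=60)
    return syn.plant_master_regulator(design, n_pwms=20)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
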