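import numpy as np
import pytest

from neurocpm.atlas import Atlas
from neurocpm.simulate import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    """Default planted-signal cohort: 80 subjects, 60 nodes, 30+30 edges."""
    return generate_dataset(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """Quick cohort for structural tests: 40 subjects, 20 nodes, strong signal."""
    cfg = GeneratorConfig(n_subjects=40, n_nodes=20, n_pos_edges=6,
                          n_neg_edges=6, rho_signal=0.7, seed=7)
    return generate_dataset(cfg)


@pytest.fixture
def toy_atlas():
    return Atlas.uniform(8, region_labels=("prefrontal", "motor_strip",
                                           "cerebellum"))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
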