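import numpy as np
import pytest

from mcca.detection import DetectionParams
from mcca.synthetic import GeneratorConfig, generate_population


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def params():
    return DetectionParams()


@pytest.fixture(scope="session")
def small_population():
    """A 40-cell recording with all activity classes and ground truth."""
    cfg = GeneratorConfig(
        n_cells=40,
        silent_fraction=0.25,
        astrocyte_fraction=0.05,
        class_weights=(0.25, 0.55, 0.20),
        seed=7,
    )
    return generate_population(cfg)
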