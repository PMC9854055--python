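import numpy as np
import pytest

from mflogp.dataset import curate
from mflogp.synthetic import GeneratorSpec, generate_dataset, make_gold_fixture, make_gold_records


@pytest.fixture(scope="session")
def gold_records():
    return make_gold_records()


@pytest.fixture(scope="session")
def gold_dataset():
    return make_gold_fixture()


@pytest.fixture(scope="session")
def linear_dataset():
    """Noise-free synthetic data with truth supported on the base counts only,
    so the 10-column design is full rank and coefficients are identifiable."""
    spec = GeneratorSpec(
        n=600,
        seed=11,
        noise_sigma=0.0,
        isomer_sigma=0.0,
        coefficients={
            "C": 0.3,
            "H": 0.02,
            "N": -0.5,
            "O": -0.4,
            "S": 0.2,
            "P": -0.3,
            "F": 0.1,
            "Cl": 0.45,
            "Br": 0.55,
            "I": 0.7,
        },
    )
    records, truth = generate_dataset(spec)
    return curate(records), truth


@pytest.fixture(scope="session")
def noisy_dataset():
    records, truth = generate_dataset(GeneratorSpec(n=800, seed=7))
    return curate(records), truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
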