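import numpy as np
import pytest

from phenobma import PhenotypeScheme, simulate_symptoms


@pytest.fixture(scope="session")
def kpd_scheme():
    return PhenotypeScheme.kpd_default()

@pytest.fixture(scope="session")
def three_class_scheme():
    return PhenotypeScheme.three_class()


@pytest.fixture(scope="session")
def crisp_data(three_class_scheme):
    """Separable three-class symptom data with known labels (n=500)."""
    Y, labels = simulate_symptoms(three_class_scheme, 500, seed=2024)
    return Y, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
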