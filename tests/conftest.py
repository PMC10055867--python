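import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tocsynd as t

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return t.load_reference_table()


@pytest.fixture(scope="session")
def ct_d4(table):
    return t.extract_sample(table, "Ct d4")


@pytest.fixture(scope="session")
def train_4000(ct_d4):
    """Default augmented training set (seed 1), shared across tests."""
    return t.augment_shift(ct_d4, t.AugmentationConfig(seed=1))


def dataset_from_peaks(peak_set):
    """Labeled Dataset built directly from a peak set (no augmentation)."""
    return t.Dataset(
        features=peak_set.features(),
        labels=np.array([p.metabolite for p in peak_set.peaks], dtype=object),
    )


@pytest.fixture(scope="session")
def separated_synthetic():
    """Well-separated 4-known + 2-novel synthetic problem."""
    train, test = t.make_synthetic_table(
        4, 2, 5, min_separation=500.0, seed=3
    )
    return train, test
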