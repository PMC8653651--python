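import numpy as np
import pytest

from ftirquant import (
    NoiseModel,
    WavenumberAxis,
    default_design,
    default_profiles,
    planted_profiles,
    simulate_dataset,
    split_train_test,
)
from ftirquant.preprocessing import fit_chain, spec_by_name

REDUCED_POINTS = 747
PLANTED_WINDOW = (1500.0, 1700.0)


@pytest.fixture(scope="session")
def axis() -> WavenumberAxis:
    """Reduced 747-point mid-IR axis used throughout the unit tests."""
    return WavenumberAxis.default(REDUCED_POINTS)


@pytest.fixture(scope="session")
def default_dataset(axis):
    """Default-profile mixture dataset at default noise, fixed seed."""
    target, adulterant = default_profiles()
    return simulate_dataset(
        default_design(), target, adulterant, NoiseModel(seed=11), axis
    )


def make_planted_dataset(axis, seed: int):
    target, adulterant = planted_profiles(axis, PLANTED_WINDOW)
    return simulate_dataset(
        default_design(), target, adulterant, NoiseModel(seed=seed), axis
    )


@pytest.fixture(scope="session")
def planted_dataset(axis):
    return make_planted_dataset(axis, seed=3)


@pytest.fixture(scope="session")
def planted_calibration(axis, planted_dataset):
    """Preprocessed calibration half of the planted dataset: (X, y, inside-mask)."""
    cal, _ = split_train_test(planted_dataset, seed=4)
    chain = fit_chain(spec_by_name("SNV+first derivative"), axis, cal.absorbance)
    X = chain.transform(cal.absorbance)
    inside = np.zeros(axis.n_points, dtype=bool)
    lo = axis.index_of(max(PLANTED_WINDOW))
    hi = axis.index_of(min(PLANTED_WINDOW))
    inside[lo : hi + 1] = True
    return X, cal.labels, inside


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
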