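import numpy as np
import pytest

from wmvpa import (CohortSpec, HyperparameterGrid, PlantedEffect, build_dataset,
                   default_mask, generate_cohort)
from wmvpa.datasets import load_clinical_table, load_decision_table


@pytest.fixture(scope="session")
def male_decisions():
    return load_decision_table("male")


@pytest.fixture(scope="session")
def female_decisions():
    return load_decision_table("female")


@pytest.fixture(scope="session")
def male_clinical():
    return load_clinical_table("male")


@pytest.fixture(scope="session")
def female_clinical():
    return load_clinical_table("female")


@pytest.fixture(scope="session")
def strong_signal_spec():
    """Planted right-hemisphere sphere at delta = 3 * noise_sd."""
    return CohortSpec(
        grid_shape=(16, 16, 16),
        n_positive=10, n_negative=10,
        noise_sd=0.05,
        effects=[PlantedEffect(center=(12, 8, 8), radius=3,
                               hemisphere="right", delta=0.15)],
        seed=7,
    )


@pytest.fixture(scope="session")
def strong_signal_dataset(strong_signal_spec):
    volumes, clinical = generate_cohort(strong_signal_spec)
    return build_dataset(volumes, default_mask(volumes), clinical)


@pytest.fixture(scope="session")
def small_grid():
    return HyperparameterGrid(C_values=(1.0, 32.0), k_values=(5, 20))


def random_cohort_matrix(rng, n_pos=4, n_neg=4, n_voxels=30):
    """Plain noise feature matrix with labels, for unit tests."""
    X = rng.normal(0.5, 0.1, size=(n_pos + n_neg, n_voxels))
    y = np.array([1] * n_pos + [-1] * n_neg)
    return X, y
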