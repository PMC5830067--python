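import numpy as np
import pytest

from plscm import ClassCoding, PhenotypeMatrix, SyntheticCohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_xy(rng):
    """Seeded 8x5 matrix with a binary response, for oracle comparisons."""
    X = rng.uniform(5.0, 60.0, size=(8, 5))
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
    # give y some real structure so multiple components are meaningful
    X[:, 0] += 10.0 * y
    X[:, 3] -= 6.0 * y
    return X, y


@pytest.fixture
def tiny_matrix():
    return PhenotypeMatrix(
        values=np.array([[10.0, 20.0], [30.0, 40.0], [50.0, 60.0]]),
        subject_ids=["a", "b", "c"],
        variable_names=["v1", "v2"],
        class_labels=np.array([0, 0, 1]),
        coding=ClassCoding("ctrl", "case"),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    return generate_cohort(SyntheticCohortConfig(seed=11))
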