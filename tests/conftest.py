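import numpy as np
import pytest

from devconn.synth import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-effect cohort shared across tests (12 subjects, 40 regions)."""
    spec = SyntheticCohortSpec(n_subjects=12, n_regions=40, seed=123)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def two_triangles() -> np.ndarray:
    w = np.zeros((6, 6))
    for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        w[i, j] = w[j, i] = 1.0
    return w


@pytest.fixture()
def two_triangle_graph():
    return two_triangles()
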