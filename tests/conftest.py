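import numpy as np
import pytest

from strokegraph import PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Three-patient cohort of 128x128 slices; cheap enough for unit tests."""
    spec = PhantomSpec(seed=11, n_patients=3, slices_per_patient_range=(2, 4),
                       image_size=(128, 128), lesion_radius_range=(6.0, 20.0))
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_adjacency(rng, n, p=0.5):
    """Random symmetric nonnegative adjacency with zero diagonal."""
    A = rng.random((n, n))
    A = (A + A.T) / 2.0
    A[A < p] = 0.0
    np.fill_diagonal(A, 0.0)
    return A
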