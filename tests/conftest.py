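import numpy as np
import pytest

from ecomorph import StudyParams, generate_study, gpa, weight_matrix
from ecomorph.procrustes import align_sample_to


SMALL_PARAMS = dict(
    n_species=4,
    n_landmarks=10,
    n_localities=30,
    sample_sizes=(20, 20, 20, 20),
)


@pytest.fixture(scope="session")
def small_study():
    """A compact 4-species study with every effect planted."""
    return generate_study(StudyParams(**SMALL_PARAMS), seed=11)


@pytest.fixture(scope="session")
def aligned_small(small_study):
    """GPA result for the small study, rotated into the generator frame."""
    sample = gpa(small_study.specimens)
    return align_sample_to(sample, np.asarray(small_study.truth["base_shape"]))


@pytest.fixture(scope="session")
def wm_small(aligned_small):
    return weight_matrix(aligned_small)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
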