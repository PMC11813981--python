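"""Shared fixtures: phantoms and small simulated subjects."""

import numpy as np
import pytest

from thalcon.core_io import SubjectRecord
from thalcon.synthetic_cohort import make_phantom, simulate_subject


@pytest.fixture(scope="session")
def truth24():
    """Default phantom on the standard 24^3 grid."""
    return make_phantom()


@pytest.fixture(scope="session")
def truth16():
    """Smallest admissible phantom, for fast tests."""
    return make_phantom(grid_shape=(16, 16, 16))


@pytest.fixture(scope="session")
def truth16_noisefree():
    return make_phantom(grid_shape=(16, 16, 16), noise_sd=0.0)


@pytest.fixture(scope="session")
def control_record():
    return SubjectRecord(subject_id="sub-c001", group="control", lesion_side="none")


@pytest.fixture(scope="session")
def patient_record():
    return SubjectRecord(subject_id="sub-p001", group="patient", lesion_side="left",
                         fma_ue_t1=22, fma_ue_t2=52, fma_le_t1=20, fma_le_t2=30,
                         nihss_t1=6, nihss_t2=1, nihss_sensory_t1=1)


@pytest.fixture(scope="session")
def small_subject(truth16, control_record):
    """One simulated control subject on the 16^3 grid, T=80."""
    return simulate_subject(truth16, control_record, n_timepoints=80, seed=7)


@pytest.fixture(scope="session")
def noisefree_subject(truth16_noisefree, control_record):
    return simulate_subject(truth16_noisefree, control_record, n_timepoints=80,
                            seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
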