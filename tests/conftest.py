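import numpy as np
import pytest

from solewalk import FULL_CONFIG, extract_matrix, simulate_cohort
from solewalk.recognition import make_assignments, roster_from_recordings


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects x 9 activities x 60 s — enough windows to train on."""
    recordings, manifest = simulate_cohort(6, durations=60.0, master_seed=11)
    return recordings, manifest


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    """10 s-window full-configuration feature matrix of the small cohort."""
    recordings, _ = small_cohort
    return extract_matrix(recordings, 10, FULL_CONFIG)


@pytest.fixture(scope="session")
def small_plans(small_cohort):
    """Two subject-wise assignments (4 train / 2 test) with 3 seeds each."""
    recordings, _ = small_cohort
    roster = roster_from_recordings(recordings)
    return make_assignments(roster, n_assignments=2, n_train=4, seed=5, n_random_states=3)
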