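import numpy as np
import pytest

from netdyn import CohortSpec, make_ground_truth, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_truth_2state():
    """Well-separated sticky 2-state chain over 6 parcels."""
    return make_ground_truth(n_states=2, n_parcels=6, self_persistence=0.9,
                             separation=3.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group cohort with one state's dynamics perturbed."""
    truth = make_ground_truth(n_states=4, n_parcels=8, self_persistence=0.9,
                              separation=3.0, seed=11)
    spec = CohortSpec(n_subjects_per_group=(4, 4), samples_per_subject=2000,
                      group_effect={2: 0.05}, seed=11)
    return simulate_cohort(truth, spec)
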