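import numpy as np
import pytest

from synvar import CohortConfig, make_ground_truth, synthesize_envelopes


@pytest.fixture(scope="session")
def tiny_config():
    """Small cohort for fast unit tests (3 subjects x 3 reps, 10 muscles)."""
    return CohortConfig(n_subjects=3, n_repetitions=3, n_tasks=5, n_muscles=10,
                        n_true_synergies=3, samples_per_point=50, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    truth = make_ground_truth(tiny_config)
    env = synthesize_envelopes(truth, tiny_config)
    return env


@pytest.fixture(scope="session")
def tiny_matrices(tiny_cohort):
    return tiny_cohort.phasic_matrices()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
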