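import numpy as np
import pytest

import lifetraj as lt

# The planted reference fixture used across the suite: 120 regions (five
# canonical shape clusters plus a 20-region null block), 300 subjects aged
# 6-82, noise at 0.25x the shape amplitude.
FIXTURE_SEED_COHORT = 11
FIXTURE_SEED_ACTIVITY = 12
N_SUBJECTS = 300
N_ROIS = 120
NOISE_SD = 0.125  # amplitude 0.5


@pytest.fixture(scope="session")
def cohort():
    return lt.generate_cohort(N_SUBJECTS, seed=FIXTURE_SEED_COHORT)


@pytest.fixture(scope="session")
def truth():
    return lt.default_ground_truth(N_ROIS, noise_sd=NOISE_SD)


@pytest.fixture(scope="session")
def activity(cohort, truth):
    act, _ = lt.generate_activity(cohort, truth, seed=FIXTURE_SEED_ACTIVITY)
    return act


@pytest.fixture(scope="session")
def planted_labels(truth):
    return {f"roi-{j:03d}": int(l) for j, l in enumerate(truth.roi_assignment)}


@pytest.fixture(scope="session")
def pipeline_result(activity, cohort):
    return lt.run_pipeline(activity, cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
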