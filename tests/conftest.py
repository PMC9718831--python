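import pytest

from wearfit import evaluation as ev
from wearfit.cohort import CohortConfig
from wearfit.pipeline import simulate_bundle

# Fixed study seeds for the session-wide synthetic cohorts.
STUDY_SEED = 101
LONGITUDINAL_SEED = 202


@pytest.fixture(scope="session")
def study_bundle():
    """1000-participant 6-day cohort, half longitudinal, with follow-up
    sensor weeks and the analytic oracle estimates."""
    config = CohortConfig.fenland_like(1000, seed=STUDY_SEED)
    bundle = simulate_bundle(config, longitudinal_fraction=0.5,
                             followup_traces=True)
    return config, bundle


@pytest.fixture(scope="session")
def task1_result(study_bundle):
    _, bundle = study_bundle
    return ev.run_task("task1_current", bundle, seed=0, n_boot=100)


@pytest.fixture(scope="session")
def longitudinal_bundle():
    """Study-scale longitudinal cohort (2675 participants, baseline
    sensor weeks only) for the fitness-change tasks."""
    config = CohortConfig.fenland_like(2675, seed=LONGITUDINAL_SEED)
    return simulate_bundle(config, longitudinal_fraction=1.0,
                           followup_traces=False, compute_oracle=False)


@pytest.fixture(scope="session")
def small_bundle():
    """Cheap 80-participant cohort for orchestration-level checks."""
    config = CohortConfig.fenland_like(80, seed=7)
    bundle = simulate_bundle(config, longitudinal_fraction=0.5,
                             followup_traces=True)
    return config, bundle
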