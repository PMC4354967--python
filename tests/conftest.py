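import pytest
from hypothesis import HealthCheck, settings

import nsensor as ns

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_trial():
    """One default-truth noisy trial (6 levels x 3 reps x 3 stages)."""
    return ns.simulate_trial(ns.TrialDesign(seed=42))


@pytest.fixture(scope="session")
def booting_truth():
    return ns.truth_presets("paper_booting")


@pytest.fixture(scope="session")
def booting_trial(booting_truth):
    """Noiseless trial generated from the published booting coefficients."""
    with pytest.warns(UserWarning):
        df = ns.simulate_trial(ns.TrialDesign(seed=7), booting_truth)
    return df
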