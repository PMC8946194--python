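import pytest
from hypothesis import HealthCheck, settings

from prostime import DesignSpec, compute_bias, generate_design, linear_clock_model
from prostime.synthetic_data import attach_performance

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    return DesignSpec(n_participants=4, rng_seed=7)


@pytest.fixture(scope="session")
def small_design(small_spec):
    return generate_design(small_spec)


@pytest.fixture(scope="session")
def sim_trials(small_design):
    """Small simulated cohort with estimates and math-task performance."""
    trials = linear_clock_model(small_design, seed=11)
    return attach_performance(trials, seed=12)


@pytest.fixture(scope="session")
def full_trials():
    """Study-scale cohort (16 participants, both conditions)."""
    design = generate_design(DesignSpec(rng_seed=3))
    return linear_clock_model(design, seed=4)


@pytest.fixture(scope="session")
def full_bias(full_trials):
    return compute_bias(full_trials)
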