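import pytest
from hypothesis import HealthCheck, settings

from padhere import classify, cleaning, simulate
from padhere.simulate import SimulationConfig

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_participants=40, seed=5)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Latent states plus emitted logs for a 40-participant cohort."""
    states, logs = simulate.simulate_cohort(small_config)
    return states, logs


@pytest.fixture(scope="session")
def small_weekly(small_config, small_cohort):
    """Weekly statuses classified from the small cohort's logs."""
    _, logs = small_cohort
    grid = cleaning.expand_to_full_grid(
        cleaning.clean_logs(logs), simulate.participant_ids(small_config)
    )
    return classify.weekly_status(grid)
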