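import numpy as np
import pytest

from ccigait import SimulationConfig, TrialCondition, config_variant, simulate_trial


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale cohort: 2+2 participants, one limb, short trials."""
    return config_variant(
        SimulationConfig(),
        n_participants_td=2,
        n_participants_cp=2,
        limbs=("left",),
        strides_per_trial=12,
        seed=101,
    )


@pytest.fixture(scope="session")
def dry_normal_condition() -> TrialCondition:
    return TrialCondition("TD01", "left", "TD", "Dry", "Normal")


@pytest.fixture(scope="session")
def small_trial(small_config, dry_normal_condition):
    return simulate_trial(small_config, dry_normal_condition, np.random.default_rng(7))
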