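import dataclasses

import numpy as np
import pytest

from hapticlearn import ProtocolConfig, StudyConfig, run_study, sample_cohort


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    """A reduced protocol (one short training round) for data-driven tests."""
    return dataclasses.replace(
        StudyConfig(),
        n_participants=8,
        protocol=ProtocolConfig(
            n_training_rounds=1, sets_per_round=5,
            catch_sets=(1,), mirrored_sets=(3,),
        ),
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """One reproducible small cohort run shared across tests."""
    rng = np.random.default_rng(11)
    cohort = sample_cohort(small_config.n_participants, rng, small_config.effects)
    data = run_study(cohort, small_config, seed=11)
    return cohort, data
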