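import numpy as np
import pytest

from statesync.core import EpochSet, SpikeTrain
from statesync.synth import (ANTIPHASE, BURSTY_ANTIPHASE, COACTIVE,
                             INDEPENDENT, SyntheticConfig,
                             generate_recording)


def poisson_train(unit_id, rate, duration, rng, t_start=0.0):
    n = rng.poisson(rate * duration)
    t = np.sort(t_start + rng.uniform(0, duration, n))
    return SpikeTrain(unit_id, t, t_start, t_start + duration)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def single_nrem_epoch():
    return EpochSet.from_tuples([(0.0, 1000.0, "NREM")])


@pytest.fixture(scope="session")
def mixed_recording():
    """Small recording with every pair class, shared across tests."""
    config = SyntheticConfig(
        duration_h=2.0, n_units=16, seed=11,
        class_fractions={INDEPENDENT: 0.25, COACTIVE: 0.25,
                         ANTIPHASE: 0.25, BURSTY_ANTIPHASE: 0.25})
    return generate_recording(config, seed=11)


@pytest.fixture(scope="session")
def antiphase_recording():
    """Strongly anti-phased pairs, no delta coupling, for mechanism tests."""
    config = SyntheticConfig(
        duration_h=1.0, n_units=12, seed=21,
        class_fractions={INDEPENDENT: 0.0, COACTIVE: 0.0, ANTIPHASE: 1.0,
                         BURSTY_ANTIPHASE: 0.0},
        antiphase_strength=0.95, delta_coupling=0.0,
        strength_range=(0.95, 0.95), pair_strength_range=(1.0, 1.0),
        wake_trough_fraction=0.0)
    return generate_recording(config, seed=21)
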