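"""Shared fixtures: small seeded synthetic corpora at a 512 Hz study rate."""

import numpy as np
import pytest

from freesacc import simcore

FS = 512.0


@pytest.fixture(scope="session")
def eog_corpus():
    """EOG-only corpus with default RT distributions and 25% artifact trials."""
    cfg = simcore.SimulationConfig(
        n_trials=300, sampling_rate=FS, delays_ms=(1750.0,), seed=11
    )
    schedule = simcore.build_trial_schedule(cfg)
    eog, schedule = simcore.synthesize_eog(schedule, cfg)
    return cfg, eog, schedule


@pytest.fixture(scope="session")
def clean_eog_corpus():
    """EOG corpus without spontaneous delay artifacts (detection oracle)."""
    cfg = simcore.SimulationConfig(
        n_trials=200,
        sampling_rate=FS,
        delays_ms=(1750.0,),
        exclusion_fraction=0.0,
        seed=13,
    )
    schedule = simcore.build_trial_schedule(cfg)
    eog, schedule = simcore.synthesize_eog(schedule, cfg)
    return cfg, eog, schedule


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
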