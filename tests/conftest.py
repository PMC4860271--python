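import numpy as np
import pytest

from regenchron.simulate import SimConfig, simulate_timecourse


@pytest.fixture(scope="session")
def mixed_sim():
    """A moderate synthetic run with several archetypes, reused across modules."""
    config = SimConfig(
        n_probes=1500,
        archetype_mix={
            "flat": 0.55,
            "immediate_early": 0.1,
            "step": 0.1,
            "dip_9_10": 0.05,
            "late_ramp_22_24": 0.05,
            "muscle_decline": 0.1,
            "gradual_drift": 0.05,
        },
        seed=42,
    )
    matrix, samples, truth = simulate_timecourse(config)
    return config, matrix, samples, truth


@pytest.fixture(scope="session")
def flat_sim():
    """An all-null simulation for calibration checks."""
    config = SimConfig(n_probes=2000, archetype_mix={"flat": 1.0}, seed=7)
    matrix, samples, truth = simulate_timecourse(config)
    return config, matrix, samples, truth
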