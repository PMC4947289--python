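import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kneestretch.limb import Anthropometry, reference_model, scale_model
from kneestretch.reflex import ReflexParams
from kneestretch.simulate import run_gain_sweep
from kneestretch.synth import SynthConfig, generate_subject, generate_trial

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

CHILD = Anthropometry(height=1.45, mass=34.0, leg_length=0.70,
                      tibia_length=0.37)


@pytest.fixture(scope="session")
def child_model():
    """Child-scaled rigid-tendon model shared by the mechanics tests."""
    return scale_model(reference_model("rigid"), CHILD)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free study conditions (kinematic/kinetic noise off)."""
    return SynthConfig(seed=11, angle_noise_deg=0.0, force_noise_N=0.0)


@pytest.fixture(scope="session")
def cp_truth(clean_config):
    """One CP-like subject at the cohort-mean passive parameters with a
    moderate reflex (G = 2, T = 0.08 m/s)."""
    rng = np.random.default_rng(11)
    truth = generate_subject(clean_config, "CP", rng, "CPref")
    return dataclasses.replace(
        truth, S_ham=0.57, K_ham=4.65, S_vas=1.40, K_vas=8.73,
        reflex=ReflexParams(G=2.0, T=0.08))


@pytest.fixture(scope="session")
def slow_trial_clean(cp_truth, clean_config):
    rng = np.random.default_rng(21)
    return generate_trial(cp_truth, "slow", clean_config, rng)


@pytest.fixture(scope="session")
def fast_trial_clean(cp_truth, clean_config):
    rng = np.random.default_rng(22)
    return generate_trial(cp_truth, "fast", clean_config, rng)


@pytest.fixture(scope="session")
def fast_sweep(cp_truth, fast_trial_clean):
    """Gain sweep {0,1,2,4} of the clean fast trial at the true S/K."""
    model = cp_truth.build_model()
    return run_gain_sweep(model, fast_trial_clean, None,
                          ReflexParams(G=0.0, T=0.08))
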