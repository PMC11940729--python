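"""Shared fixtures: degenerate profiles and session-scoped synthetic cohorts."""

import numpy as np
import pytest

import oculocog as oc
from oculocog.profiles import default_profiles


@pytest.fixture(scope="session")
def noiseless_profile():
    """Every stochastic ingredient switched off; ideal oculomotor behaviour."""
    return default_profiles()["control"].replace(
        saccade_latency_mean=0.25, saccade_latency_sd=0.0, anti_error_rate=0.0,
        saccade_gain_mean=1.0, saccade_gain_sd=0.0,
        pursuit_gain=1.0, pursuit_delay=0.0, catchup_rate=0.0,
        memory_gain_mean=1.0, memory_gain_sd=0.0, memory_fail_rate=0.0,
        predictive_anticipation=0.0, predictive_latency_sd=0.0,
        fixation_noise_sd=0.0, blink_rate=0.0)


@pytest.fixture(scope="session")
def small_table():
    """Feature table of a small default three-group cohort."""
    sessions = oc.generate_cohort(6, 8, 8, seed=11)
    return oc.build_feature_table(sessions)


@pytest.fixture(scope="session")
def full_table():
    """Feature table of a full-size default cohort (31 / 57 / 40)."""
    sessions = oc.generate_cohort(31, 57, 40, seed=20)
    return oc.build_feature_table(sessions)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
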