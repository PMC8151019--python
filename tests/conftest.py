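import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emgforce.features import feature_table
from emgforce.signal_io import Window
from emgforce.synth import SynthConfig, generate_dataset

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


def make_window(samples, fs=2000.0, gesture=1, force="medium", trial=1, start=0):
    """Wrap a raw (channels x N) array — or a single channel — as a Window."""
    return Window(
        samples=np.atleast_2d(np.asarray(samples, dtype=float)),
        fs=fs,
        subject_id="T",
        gesture=gesture,
        force=force,
        trial_index=trial,
        start_index=start,
    )


@pytest.fixture(scope="session")
def small_cfg():
    """One synthetic subject, shortened trials; the suite's study conditions."""
    return SynthConfig(n_subjects=1, duration_s=4.0, seed=7)


@pytest.fixture(scope="session")
def small_trials(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def proposed_features(small_trials):
    return feature_table(small_trials, "proposed")


@pytest.fixture(scope="session")
def td_features(small_trials):
    return feature_table(small_trials, "TD")
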