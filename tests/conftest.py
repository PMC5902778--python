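import math

import numpy as np
import pytest

from myoadmit import (
    AnklePlant,
    ControllerConfig,
    TrialLog,
    VirtualSubject,
    default_subject,
    run_mvc_trial,
    run_tracking_trial,
)


@pytest.fixture(scope="session")
def subject_params():
    return default_subject()


@pytest.fixture(scope="session")
def hill(subject_params):
    return subject_params.hill


@pytest.fixture(scope="session")
def geom(subject_params):
    return subject_params.geometry


@pytest.fixture(scope="session")
def virtual_subject(subject_params):
    return VirtualSubject(params=subject_params)


@pytest.fixture(scope="session")
def ideal_mvc_trials(virtual_subject):
    """Noise-free MVC trials at both calibration angles (expensive)."""
    return [run_mvc_trial(virtual_subject, math.radians(a), ideal=True)
            for a in (90, 120)]


@pytest.fixture(scope="session")
def short_tracking_log(virtual_subject):
    """One short assisted tracking trial reused across metric tests."""
    cfg = ControllerConfig(mode="naacs", K_fixed=0.3)
    return run_tracking_trial(virtual_subject, cfg, seed=11, n_cycles=2)


def make_log(fs=100.0, n=1000, **channels):
    """Minimal TrialLog with given channels; others default to zeros."""
    t = np.arange(n) / fs
    zeros = np.zeros(n)
    fields = dict(
        target=zeros, q=zeros, qdot=zeros, qi=zeros, torque_human=zeros,
        torque_est=zeros, torque_assist=zeros, torque_interaction=zeros,
        emg=zeros, envelope=zeros, kj=zeros, gain_k=zeros,
    )
    for k, v in channels.items():
        fields[k] = np.asarray(v, dtype=float)
    return TrialLog(fs=fs, t=t, **fields)


@pytest.fixture
def log_factory():
    return make_log
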