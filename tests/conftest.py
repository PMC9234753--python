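"""Shared fixtures: synthetic trials at the sizes the tests need.

Trials are generated once per session; 130 s covers the 120 s nonlinear
analysis window with margin while keeping the suite fast.
"""

import numpy as np
import pytest

from interlimb import generate_bilateral_gait, preset
from interlimb.io import AnalysisConfig


@pytest.fixture(scope="session")
def healthy_config():
    return preset("healthy", seed=1, duration_s=130.0)


@pytest.fixture(scope="session")
def healthy_trial(healthy_config):
    """(trial, ground-truth events) for the healthy preset, seed 1."""
    return generate_bilateral_gait(healthy_config)


@pytest.fixture(scope="session")
def deterministic_trial():
    """Zero-jitter, zero-noise trial: the fully deterministic limit."""
    cfg = preset("healthy", seed=3, duration_s=130.0, phase_jitter_sd=0.0,
                 meas_noise_sd=0.0, amp_jitter_sd=0.0, sway_mm=0.0)
    return generate_bilateral_gait(cfg)


@pytest.fixture(scope="session")
def analysis_config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def decimated_pair(healthy_trial, analysis_config):
    """Decimated 10 Hz AP heel pair from the healthy seed-1 trial."""
    from interlimb.embedding import decimate

    trial, _ = healthy_trial
    cfg = analysis_config
    ap_L = trial.channel("heel_L", "AP")[: cfg.analysis_samples]
    ap_R = trial.channel("heel_R", "AP")[: cfg.analysis_samples]
    return (decimate(ap_L, cfg.decimation_factor),
            decimate(ap_R, cfg.decimation_factor))
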