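"""Shared fixtures: small synthetic recordings and the default mapping."""

import warnings

import numpy as np
import pytest

import topodecode as td

# FastICA on near-Gaussian synthetic background legitimately hits its
# iteration cap; the cleanup result is still well defined (see module docs)
warnings.filterwarnings("ignore", message="ICA hit the iteration cap")


@pytest.fixture(scope="session")
def layout():
    return td.biosemi128_layout()


@pytest.fixture(scope="session")
def mapping(layout):
    return td.default_biosemi128_mapping(layout)


@pytest.fixture(scope="session")
def small_config():
    """Reduced experiment: 24 trials, short but realistic timing."""
    return td.SimulationConfig(n_trials=24, n_active=12, inter_trial_gap=2.0)


@pytest.fixture(scope="session")
def small_recording(small_config):
    return td.simulate_subject(small_config, "S01", seed=7, store_clean=True)


@pytest.fixture(scope="session")
def small_bandpassed(small_recording):
    return td.bandpass(small_recording, (0.1, 40.0))


@pytest.fixture(scope="session")
def noise_free_recording():
    cfg = td.SimulationConfig(
        n_trials=16,
        n_active=8,
        noise_amp=0.0,
        blink_rate=0.0,
        subject_amp_sd=0.0,
        trial_amp_sd=0.0,
        inter_trial_gap=2.0,
    )
    return td.simulate_subject(cfg, "S00", seed=3, store_clean=True)


@pytest.fixture(scope="session")
def tiny_tensorset(mapping):
    """Two separable classes of (13, 9, 125) trials for decoder tests."""
    rng = np.random.default_rng(11)
    n_per, T = 24, 125
    x0 = rng.normal(size=(n_per, 13, 9, T)).astype(np.float32)
    x1 = rng.normal(size=(n_per, 13, 9, T)).astype(np.float32)
    x1[:, 4:7, 2:5, 40:80] += 1.5
    x = np.concatenate([x0, x1])
    y = np.array([0] * n_per + [1] * n_per)
    return td.TopoTensorSet(
        x, y, mapping, 250.0, class_names=("null", "planted"), task="mode"
    )
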