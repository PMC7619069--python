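"""Shared fixtures: small pre-computed simulations reused across tests."""

import numpy as np
import pytest

from crusparks.model import initial_state, simulate
from crusparks.params import ModelConfig, load_calibrated


@pytest.fixture(scope="session")
def ctrl_cfg():
    cfg = load_calibrated("control")
    cfg.iso = True
    return cfg


@pytest.fixture(scope="session")
def cpvt_cfg():
    cfg = load_calibrated("cpvt")
    cfg.iso = True
    return cfg


@pytest.fixture(scope="session")
def short_paced_run(ctrl_cfg):
    """A 6-beat control run at 1 Hz (4 equilibration + 2 measured)."""
    stim = np.arange(6) * 1000.0 + 50.0
    st = initial_state(ctrl_cfg.resolved(), c_nsr=1000.0)
    traj, stf = simulate(ctrl_cfg, duration=6000.0, seed=3, state=st,
                         stim_times=stim)
    return traj, stf, stim


@pytest.fixture(scope="session")
def single_beat_run(ctrl_cfg):
    """One paced beat from rest (for AP morphology checks)."""
    stim = np.array([50.0])
    st = initial_state(ctrl_cfg.resolved(), c_nsr=1000.0)
    traj, stf = simulate(ctrl_cfg, duration=1000.0, seed=5, state=st,
                         stim_times=stim)
    return traj, stf


@pytest.fixture()
def tiny_cfg():
    """Small uncalibrated config for cheap structural tests."""
    cfg = ModelConfig()
    cfg.ca.n_cru = 10
    return cfg
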