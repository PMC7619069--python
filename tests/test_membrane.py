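"""Membrane currents, clamp stepping and AP metrics."""

import numpy as np
import pytest

from crusparks.membrane import (APMetrics, CurrentSet, NoBeatError, ap_metrics,
                                ap_metrics_paced, compute_currents,
                                ncx_current, ncx_reversal_csub, step_voltage)
from crusparks.model import initial_state, simulate
from crusparks.params import MembraneParams, ModelConfig


class TestNCX:
    def test_zero_at_reversal(self):
        p = MembraneParams()
        for vm in (-60.0, -18.0, 20.0):
            c_rev = ncx_reversal_csub(vm, p)
            assert ncx_current(vm, c_rev, p) == pytest.approx(0.0, abs=1e-9)

    def test_inward_magnitude_increases_with_submembrane_ca(self):
        """At Vm = -18 mV, doubling submembrane Ca strengthens extrusion."""
        p = MembraneParams()
        i1 = ncx_current(-18.0, 0.5, p)
        i2 = ncx_current(-18.0, 1.0, p)
        assert i1 < 0 and i2 < 0
        assert abs(i2) > abs(i1)

    def test_forward_mode_at_rest(self):
        p = MembraneParams()
        assert ncx_current(-85.0, 0.2, p) < 0.0  # extruding, inward current


class TestStepVoltage:
    def test_zero_net_current_keeps_vm(self):
        cs = CurrentSet(0, 0, 0, 0, 0, 0, 0, 0, 0)
        vm, icl = step_voltage(-70.0, cs, 0.01)
        assert vm == -70.0 and icl == 0.0

    def test_vclamp_reproduces_command_samplewise(self):
        cs = CurrentSet(0, -1, 0, 1, 0, 0, 0, 0, 0)
        vm, icl = step_voltage(-70.0, cs, 0.01, mode="v_clamp", command=10.0)
        assert vm == 10.0
        assert icl == pytest.approx(cs.total())

    def test_clamp_without_command_raises(self):
        cs = CurrentSet(0, 0, 0, 0, 0, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            step_voltage(-70.0, cs, 0.01, mode="ap_clamp")

    def test_square_step_clamp_in_simulation(self):
        cfg = ModelConfig()
        cfg.ca.n_cru = 10
        cmd = np.concatenate([np.full(5000, -80.0), np.full(5000, 10.0)])
        traj, _ = simulate(cfg, duration=100.0, seed=0, clamp=cmd, rec_dt=1.0)
        assert np.allclose(traj.vm[:45], -80.0, atol=1e-6)
        assert np.allclose(traj.vm[55:], 10.0, atol=1e-6)


class TestAPMetrics:
    def test_square_pulse_has_equal_apds(self):
        t = np.arange(0, 400.0, 0.5)
        vm = np.where((t >= 50) & (t < 150), 20.0, -80.0)
        m = ap_metrics(t, vm)
        w = 100.0
        assert m.apd30 == pytest.approx(w, abs=1.0)
        assert m.apd50 == pytest.approx(w, abs=1.0)
        assert m.apd90 == pytest.approx(w, abs=1.0)

    def test_monotone_repolarization_has_no_eads(self):
        t = np.arange(0, 400.0, 0.5)
        vm = np.full_like(t, -80.0)
        ap = (t >= 50)
        vm[ap] = -80.0 + 110.0 * np.exp(-(t[ap] - 50) / 60.0)
        m = ap_metrics(t, vm)
        assert m.ead_count == 0
        assert m.apd30 <= m.apd50 <= m.apd90

    def test_secondary_bump_counts_one_ead(self):
        t = np.arange(0, 500.0, 0.5)
        vm = np.full_like(t, -80.0)
        ap = t >= 50
        vm[ap] = -80.0 + 115.0 * np.exp(-(t[ap] - 50) / 80.0)
        bump = (t >= 170) & (t < 210)  # +10 mV hump mid-repolarization
        vm[bump] += 10.0 * np.sin(np.pi * (t[bump] - 170) / 40.0)
        m = ap_metrics(t, vm)
        assert m.ead_count == 1

    def test_flat_trace_raises(self):
        t = np.arange(0, 100.0, 0.5)
        with pytest.raises(NoBeatError):
            ap_metrics(t, np.full_like(t, -80.0))

    def test_vm_at_frac_interpolates_trace(self):
        t = np.arange(0, 400.0, 0.5)
        vm = np.full_like(t, -80.0)
        ap = t >= 50
        vm[ap] = -80.0 + 110.0 * np.exp(-(t[ap] - 50) / 60.0)
        m = ap_metrics(t, vm)
        v50 = m.vm_at_frac(0.5)
        expected = float(np.interp(m.t_upstroke + 0.5 * m.apd90, t, vm))
        assert v50 == pytest.approx(expected, abs=1.0)


def test_compute_currents_returns_full_set(short_paced_run, ctrl_cfg):
    _, stf, _ = short_paced_run
    cs = compute_currents(stf.vm, stf, ctrl_cfg)
    d = cs.as_dict()
    assert set(d) == {"I_Na", "I_CaL", "I_NCX", "I_Kr", "I_Ks", "I_to",
                      "I_K1", "I_NaK", "I_stim"}
    assert all(np.isfinite(v) for v in d.values())


def test_ap_clamp_self_consistency(ctrl_cfg):
    """Replaying a free-running AP under clamp needs ~zero clamp current."""
    st = initial_state(ctrl_cfg.resolved(), c_nsr=950.0)
    stim = np.arange(3) * 1000.0 + 50.0
    free, st_end = simulate(ctrl_cfg, duration=3000.0, seed=4, state=st,
                            stim_times=stim, rec_dt=0.5)
    # replay the recorded Vm of beat 3 from the state at its start
    st2 = initial_state(ctrl_cfg.resolved(), c_nsr=950.0)
    _, st2 = simulate(ctrl_cfg, duration=2000.0, seed=4, state=st2,
                      stim_times=stim[:2])
    m = free.t >= 2000.0
    clamped, _ = simulate(ctrl_cfg, duration=1000.0, seed=4, state=st2,
                          clamp=free.vm[m], rec_dt=0.5)
    # mean absolute clamp current stays small next to the peak currents
    mid = (clamped.t - clamped.t[0] > 5.0)
    assert np.mean(np.abs(clamped.i_clamp[mid])) < 1.0  # pA/pF


@pytest.mark.parametrize("species", ["mouse", "human"])
def test_species_variants_have_expected_morphology(species):
    cfg = ModelConfig()
    cfg.species = species
    cfg.calibrated = True
    st = initial_state(cfg.resolved(), c_nsr=950.0)
    stim = np.arange(3) * 1000.0 + 50.0
    traj, _ = simulate(cfg, duration=3000.0, seed=6, state=st,
                       stim_times=stim)
    mets = ap_metrics_paced(traj.t, traj.vm, stim[-1:])
    m = mets[0]
    if species == "human":
        assert m.vm_at_frac(0.5) > 0.0  # plateau morphology
    else:
        assert m.apd50 / m.apd90 < 0.5  # short, triangular AP
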