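"""CRU trigger/release model and whole-cell integration."""

import numpy as np
import pytest

from crusparks.model import (CRUState, initial_state, simulate,
                             spark_trigger_rate, step_cru, total_calcium,
                             total_sr_load)
from crusparks.params import ModelConfig, RyRParams


# ---------------------------------------------------------------------------
# trigger rate
# ---------------------------------------------------------------------------

class TestTriggerRate:
    def test_zero_at_zero_calcium(self):
        assert spark_trigger_rate(0.0, 1.0, RyRParams()) == 0.0

    def test_hill_midpoint_gives_half_maximal_rate(self):
        p = RyRParams(k_sens=1.0)
        rate = spark_trigger_rate(p.K_half, 1.0, p)
        assert rate == pytest.approx(p.lambda0 / 2)
        p2 = RyRParams(k_sens=2.0)
        assert spark_trigger_rate(p2.K_half / 2.0, 1.0, p2) == \
            pytest.approx(p2.lambda0 / 2)

    @pytest.mark.parametrize("c_ss", [0.1, 1.0, 5.0, 50.0])
    def test_sensitisation_raises_rate_everywhere(self, c_ss):
        lo = spark_trigger_rate(c_ss, 1.0, RyRParams(k_sens=1.0))
        hi = spark_trigger_rate(c_ss, 1.0, RyRParams(k_sens=2.0))
        assert hi > lo

    def test_monotone_in_calcium_and_recovery(self):
        p = RyRParams()
        cs = [0.1, 0.5, 2.0, 10.0, 40.0]
        rates = [spark_trigger_rate(c, 1.0, p) for c in cs]
        assert all(a < b for a, b in zip(rates, rates[1:]))
        rr = [spark_trigger_rate(5.0, R, p) for R in (0.2, 0.5, 1.0)]
        assert rr[0] < rr[1] < rr[2]

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            spark_trigger_rate(-1.0, 1.0, RyRParams())
        with pytest.raises(ValueError):
            spark_trigger_rate(1.0, 1.5, RyRParams())


# ---------------------------------------------------------------------------
# single-CRU stepping
# ---------------------------------------------------------------------------

class TestStepCru:
    def test_zero_rate_stays_closed(self):
        p = RyRParams(lambda0=0.0)
        s = CRUState()
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = step_cru(s, p, 0.05, rng)
        assert not s.open

    def test_deterministic_limit_opens_immediately(self):
        p = RyRParams(lambda0=1e6, K_half=0.01)
        rng = np.random.default_rng(1)
        s = step_cru(CRUState(c_ss=10.0), p, 0.05, rng)
        assert s.open

    def test_opening_count_matches_poisson_oracle(self):
        """Clamped c_ss and R: openings ~ Poisson(N*rate*T) within 3 SD."""
        p = RyRParams(lambda0=0.5, K_half=10.0, hill_h=2.0, gamma_rec=1.0)
        c_clamp, T, dt, n_cru = 5.0, 400.0, 0.05, 64
        rate = spark_trigger_rate(c_clamp, 1.0, p)
        expected = n_cru * rate * T
        rng = np.random.default_rng(7)
        count = 0
        for k in range(n_cru):
            s = CRUState(c_ss=c_clamp)
            t = 0.0
            while t < T:
                was_closed = not s.open
                s = step_cru(s, p, dt, rng, c_ss_clamp=c_clamp)
                if was_closed and s.open:
                    count += 1
                    s.open = False  # re-arm: count raw openings
                    s.R = 1.0
                t += dt
        sd = np.sqrt(expected)
        assert abs(count - expected) < 3 * sd

    def test_closure_resets_recovery_and_refills(self):
        p = RyRParams(tau_open=0.01, R_reset=0.0)
        rng = np.random.default_rng(3)
        s = CRUState(open=True, c_jsr=500.0, R=0.7)
        s = step_cru(s, p, 1.0, rng, c_nsr=1000.0)
        assert not s.open
        assert s.R == pytest.approx(0.0)
        assert s.c_jsr > 500.0  # refilling toward c_nsr

    def test_refractoriness_suppresses_short_intervals(self):
        """Single-CRU inter-opening intervals have a suppressed lower tail,
        and their median shrinks when refractoriness is reduced."""
        def intervals(k_refr, seed):
            p = RyRParams(lambda0=0.5, K_half=2.0, hill_h=2.0,
                          gamma_rec=10.0, tau_refr_R=65.0, R_reset=0.0,
                          tau_open=5.0, k_refr=k_refr)
            rng = np.random.default_rng(seed)
            s = CRUState(c_ss=5.0)
            t, out, last = 0.0, [], None
            while t < 60000.0:
                was_closed = not s.open
                s = step_cru(s, p, 0.25, rng, c_ss_clamp=5.0)
                if was_closed and s.open:
                    if last is not None:
                        out.append(t - last)
                    last = t
                t += 0.25
            return np.array(out)

        base = intervals(1.0, 0)
        fast = intervals(0.4, 0)
        assert base.size > 50 and fast.size > 50
        # lower tail suppressed: essentially nothing below half the
        # recovery time constant
        assert np.quantile(base, 0.02) > 0.5 * 65.0
        assert np.median(fast) < np.median(base)


# ---------------------------------------------------------------------------
# whole-cell integration
# ---------------------------------------------------------------------------

def test_total_calcium_conserved_without_sarcolemmal_fluxes(tiny_cfg):
    cfg = tiny_cfg
    cfg.sim.sarcolemmal_on = False
    st = initial_state(cfg.resolved(), c_nsr=900.0)
    tot0 = total_calcium(st)
    _, st1 = simulate(cfg, duration=2000.0, seed=2, state=st,
                      stim_times=np.array([100.0, 1100.0]))
    tot1 = total_calcium(st1)
    assert abs(tot1 - tot0) / tot0 < 1e-6


def test_simulation_is_deterministic_in_seed(tiny_cfg):
    t1, _ = simulate(tiny_cfg, duration=500.0, seed=9,
                     stim_times=np.array([50.0]))
    t2, _ = simulate(tiny_cfg, duration=500.0, seed=9,
                     stim_times=np.array([50.0]))
    t3, _ = simulate(tiny_cfg, duration=500.0, seed=10,
                     stim_times=np.array([50.0]))
    assert np.array_equal(t1.vm, t2.vm)
    assert np.array_equal(t1.c_i, t2.c_i)
    assert not np.array_equal(t1.c_i, t3.c_i) or len(t1.events) == 0


def test_all_fluxes_zero_leaves_state_unchanged():
    cfg = ModelConfig()
    cfg.ca.n_cru = 8
    cfg.sim.sarcolemmal_on = False
    cfg.ryr.lambda0 = 0.0
    cfg.ca.v_up = 1e-12
    cfg.ca.g_leak = 0.0
    cfg.ca.d_ca = 0.0
    st = initial_state(cfg.resolved(), c_nsr=900.0)
    st.c_jsr[:] = 900.0  # equilibrated with NSR: no refill flux
    _, st1 = simulate(cfg, duration=200.0, seed=0, state=st, clamp=-85.0)
    assert np.allclose(st1.a_i, st.a_i, rtol=1e-6)
    assert st1.c_nsr == pytest.approx(900.0, rel=1e-6)


def test_evoked_release_produces_transient(short_paced_run):
    traj, _, stim = short_paced_run
    m = (traj.t >= stim[-1]) & (traj.t < stim[-1] + 1000.0)
    amp = traj.c_mean[m].max() - traj.c_mean[m][:30].mean()
    assert amp > 0.4  # healthy evoked Ca2+ transient
    ev = traj.events
    n_evoked = ((ev.t_open >= stim[-1]) & (ev.t_open < stim[-1] + 25)).sum()
    assert n_evoked > 35  # most of the 50 CRUs fire on the beat


def test_total_sr_load_reports_positive_and_empties(short_paced_run, ctrl_cfg):
    _, stf, _ = short_paced_run
    load = total_sr_load(stf)
    assert 500.0 < load < 1300.0
    empty = initial_state(ctrl_cfg.resolved(), c_nsr=0.0)
    empty.c_jsr[:] = 0.0
    assert total_sr_load(empty) == 0.0


def test_cpvt_knobs_increase_release_at_matched_seed(ctrl_cfg, cpvt_cfg):
    """Hyperactive RyR2: more openings over matched short runs."""
    def openings(cfg, seed):
        st = initial_state(cfg.resolved(), c_nsr=800.0)
        traj, _ = simulate(cfg, duration=4000.0, seed=seed, state=st,
                           stim_times=np.arange(4) * 1000.0 + 50.0)
        return len(traj.events)

    more = sum(openings(cpvt_cfg, s) > openings(ctrl_cfg, s) for s in (1, 2))
    assert more == 2
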