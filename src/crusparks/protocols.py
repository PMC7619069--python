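"""Stimulation protocols and in-silico interventions.

Reusable experiment designs over the CRU-lattice cell model:

* ``steady_pace`` — fixed-rate current-clamp pacing to steady state.
* ``pace_pause`` — steady pacing, a pause, then resumed pacing; the first
  post-pause beat is where early afterdepolarizations appear when SR load
  and RyR2 hyperactivity conspire.
* ``s1s2`` — steady S1 drive followed by a premature S2 extrastimulus at
  progressively shorter coupling intervals.
* ``sr_loading_prepulse`` — standardized SR Ca2+ loading with a train of
  square voltage-clamp pulses to +10 mV, used to put different genotypes
  at a matched starting load before clamp experiments.
* ``ryr_block_midap`` — all CRU trigger rates forced to zero from a set
  fraction of the control AP duration onward within an indexed beat.
* ``ica_replay`` — the computed L-type current is replaced by a stored
  waveform (e.g. the I_CaL of a run without late sparks) to dissect its
  role in AP prolongation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .membrane import ap_metrics_paced
from .model.cell import (CellState, Trajectory, initial_state, simulate,
                         total_sr_load)
from .params import ModelConfig


class CalibrationRequiredError(RuntimeError):
    """The protocol needs a calibrated model configuration.

    Run the calibration driver (``crusparks.calibrate``) or load the
    frozen calibration (``crusparks.params.load_calibrated``).
    """


class StandardizationError(RuntimeError):
    """SR loading failed to converge into the standard band."""


@dataclass
class ProtocolSpec:
    """Declarative protocol description.

    kind: steady_pace | pace_pause | s1s2 | sr_loading_prepulse |
          ryr_block_midap | ica_replay
    """

    kind: str = "steady_pace"
    pace_hz: float = 1.0
    n_beats: int = 10
    n_pre_beats: int = 20          # equilibration beats before measurement
    pause_ms: float = 5000.0
    s1_ms: float = 1000.0
    s2_list: tuple = ()            # explicit S2 couplings (ms); default scan
    s2_step: float = 10.0
    s2_min: float = 100.0
    block_time_frac: float = 0.5   # fraction of control APD90 for RyR2 block
    block_beat: int = -1           # beat index (within measured beats)
    replay_trace: np.ndarray | None = None
    stim_lead: float = 50.0        # ms from beat start to stimulus
    init_c_nsr: float | None = None

    def __post_init__(self) -> None:
        if self.pace_hz <= 0:
            raise ValueError("pace_hz must be positive")
        if not 0.0 < self.block_time_frac < 1.0:
            raise ValueError("block_time_frac must lie in (0,1)")
        if self.s2_list and max(self.s2_list) >= self.s1_ms:
            raise ValueError("S2 couplings must be shorter than S1")


@dataclass
class ProtocolResult:
    trajectory: Trajectory
    state: CellState
    stim_times: np.ndarray
    spec: ProtocolSpec
    seed: int
    extras: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        sp = asdict(self.spec)
        sp.pop("replay_trace", None)
        return {"protocol": sp, "seed": int(self.seed),
                "config_hash": self.trajectory.config_hash}

    def ap_metrics(self):
        return ap_metrics_paced(self.trajectory.t, self.trajectory.vm,
                                self.stim_times)


def _require_calibrated(cfg: ModelConfig) -> None:
    if not cfg.calibrated:
        raise CalibrationRequiredError(
            "model config is not calibrated; load the frozen calibration "
            "with crusparks.params.load_calibrated() or run "
            "crusparks.calibrate.calibrate() first")


def default_initial_load(cfg: ModelConfig) -> float:
    """Starting network-SR [Ca2+] near the expected steady state.

    Hyperactive RyR2 settles at a lower load; starting nearby shortens
    the pacing needed to reach the steady state.
    """
    r = cfg.ryr
    if r.k_sens > 1.5 or r.k_refr < 0.8:
        return 640.0
    return 1000.0


def run_protocol(spec: ProtocolSpec, cfg: ModelConfig, seed: int = 0,
                 rec_dt: float = 1.0) -> ProtocolResult:
    """Execute a protocol and return trajectory, final state and log."""
    _require_calibrated(cfg)
    rcfg = cfg.resolved()
    period = 1000.0 / spec.pace_hz
    c0 = spec.init_c_nsr if spec.init_c_nsr is not None \
        else default_initial_load(cfg)
    st = initial_state(rcfg, c_nsr=c0)

    if spec.kind == "steady_pace":
        n = spec.n_pre_beats + spec.n_beats
        stim = np.arange(n) * period + spec.stim_lead
        traj, stf = simulate(cfg, duration=n * period, seed=seed, state=st,
                             stim_times=stim, rec_dt=rec_dt)
        return ProtocolResult(traj, stf, stim, spec, seed)

    if spec.kind == "pace_pause":
        stim_pre = np.arange(spec.n_pre_beats) * period + spec.stim_lead
        t_pause_end = spec.n_pre_beats * period + spec.pause_ms
        stim_post = t_pause_end + np.arange(spec.n_beats) * period
        stim = np.concatenate([stim_pre, stim_post])
        dur = stim_post[-1] + period
        traj, stf = simulate(cfg, duration=dur, seed=seed, state=st,
                             stim_times=stim, rec_dt=rec_dt)
        return ProtocolResult(traj, stf, stim, spec, seed,
                              extras={"post_pause_stim": stim_post})

    if spec.kind == "s1s2":
        s2s = list(spec.s2_list) if spec.s2_list else \
            list(np.arange(spec.s1_ms - spec.s2_step, spec.s2_min - 1e-9,
                           -spec.s2_step))
        stim_s1 = np.arange(spec.n_pre_beats) * spec.s1_ms + spec.stim_lead
        results = []
        traj_all = None
        t_cursor = 0.0
        for s2 in s2s:
            st_i = initial_state(rcfg, c_nsr=c0)
            stim = np.concatenate([stim_s1, [stim_s1[-1] + s2]])
            dur = stim[-1] + spec.s1_ms
            traj, stf = simulate(cfg, duration=dur, seed=seed, state=st_i,
                                 stim_times=stim, rec_dt=rec_dt)
            # Ca-transient amplitude of the S2 beat vs the last S1 beat
            def amp(t0, t1):
                m = (traj.t >= t0) & (traj.t < t1)
                if not m.any():
                    return np.nan
                base = traj.c_mean[m][:20].min()
                return float(traj.c_mean[m].max() - base)
            a_s1 = amp(stim[-2], stim[-1])
            a_s2 = amp(stim[-1], dur)
            results.append({"s2": float(s2), "amp_s1": a_s1, "amp_s2": a_s2,
                            "captured": a_s2 > 0.1 * a_s1})
            if traj_all is None:
                traj_all, st_last, stim_last = traj, stf, stim
            t_cursor += dur
        return ProtocolResult(traj_all, st_last, stim_last, spec, seed,
                              extras={"s1s2_table": results})

    if spec.kind == "sr_loading_prepulse":
        st2, info = sr_loading_prepulse(cfg, seed=seed, state=st)
        # represent the loading phase with an empty trajectory stub
        traj, stf = simulate(cfg, duration=1.0, seed=seed, state=st2,
                             clamp=st2.vm, rec_dt=rec_dt)
        return ProtocolResult(traj, st2, np.empty(0), spec, seed,
                              extras=info)

    if spec.kind == "ryr_block_midap":
        n = spec.n_pre_beats + spec.n_beats
        stim = np.arange(n) * period + spec.stim_lead
        # control APD90 determines the block time within the indexed beat
        apd_ref = cfg_apd90_reference(cfg, seed=seed)
        beat = spec.block_beat % spec.n_beats
        t_up = stim[spec.n_pre_beats + beat]
        t_block = t_up + spec.block_time_frac * apd_ref
        traj, stf = simulate(cfg, duration=n * period, seed=seed, state=st,
                             stim_times=stim, rec_dt=rec_dt,
                             ryr_block=(t_block, n * period))
        return ProtocolResult(traj, stf, stim, spec, seed,
                              extras={"t_block": t_block, "apd_ref": apd_ref})

    if spec.kind == "ica_replay":
        if spec.replay_trace is None:
            raise ValueError("ica_replay requires replay_trace (I_CaL, pA/pF)")
        n = spec.n_pre_beats + spec.n_beats
        stim = np.arange(n) * period + spec.stim_lead
        # equilibrate freely, then replay the stored waveform over the
        # measured beats (interpolated onto the integration grid)
        traj0, st1 = simulate(cfg, duration=spec.n_pre_beats * period,
                              seed=seed, state=st,
                              stim_times=stim[:spec.n_pre_beats],
                              rec_dt=rec_dt)
        rep = np.asarray(spec.replay_trace, float)
        reps = np.tile(rep, spec.n_beats)[: int(spec.n_beats * period)]
        traj1, stf = simulate(cfg, duration=spec.n_beats * period, seed=seed,
                              state=st1, stim_times=stim[spec.n_pre_beats:],
                              ica_replay=reps, rec_dt=rec_dt)
        return ProtocolResult(traj0.concat(traj1), stf, stim, spec, seed)

    raise ValueError(f"unknown protocol kind {spec.kind!r}")


_APD_CACHE: dict = {}


def cfg_apd90_reference(cfg: ModelConfig, seed: int = 0) -> float:
    """Steady-pace APD90 of the *control* counterpart of a configuration."""
    ctrl = cfg.with_overrides({"ryr.k_sens": 1.0, "ryr.k_refr": 1.0})
    key = (ctrl.hash(), seed)
    if key not in _APD_CACHE:
        period = 1000.0
        stim = np.arange(8) * period + 50.0
        st = initial_state(ctrl.resolved(), c_nsr=1000.0)
        traj, _ = simulate(ctrl, duration=8 * period, seed=seed, state=st,
                           stim_times=stim)
        mets = ap_metrics_paced(traj.t, traj.vm, stim[-3:])
        _APD_CACHE[key] = float(np.mean([m.apd90 for m in mets]))
    return _APD_CACHE[key]


def sr_loading_prepulse(cfg: ModelConfig, n_pulses: int = 30,
                        v_step: float = 10.0, duration: float = 200.0,
                        v_hold: float = -80.0, interpulse: float = 800.0,
                        target_load: float | None = 900.0,
                        tol: float = 0.12, max_extra: int = 40,
                        seed: int = 0,
                        state: CellState | None = None
                        ) -> tuple[CellState, dict]:
    """Standardized SR Ca2+ loading with square pulses to ``v_step`` mV.

    Repeated voltage-clamp pulses load the SR through L-type Ca2+ entry;
    pulsing continues (up to ``n_pulses + max_extra``) until the total SR
    load is within ``tol`` of ``target_load`` (uM per cytosolic litre),
    so different genotypes start clamp experiments from matched loads.

    Returns the loaded state and an info dict with the load trace.

    Raises
    ------
    StandardizationError
        when the load cannot be brought into the band.
    """
    _require_calibrated(cfg)
    rcfg = cfg.resolved()
    if state is None:
        state = initial_state(rcfg, c_nsr=default_initial_load(cfg))
    st = state
    if n_pulses == 0:
        return st, {"loads": [], "n_pulses": 0}
    loads = []
    dt = rcfg.sim.dt
    n_step = int(round(duration / dt))
    n_hold = int(round(interpulse / dt))
    pulse_cmd = np.concatenate([np.full(n_step, v_step),
                                np.full(n_hold, v_hold)])
    done = False
    for k in range(n_pulses + max_extra):
        _, st = simulate(cfg, duration=duration + interpulse, seed=seed + k,
                         state=st, clamp=pulse_cmd, rec_dt=5.0)
        load = total_sr_load(st)
        loads.append(load)
        if target_load is not None and k >= 4:
            if abs(load - target_load) <= tol * target_load:
                done = True
                break
            # overloaded cells shed Ca through sparks during the hold;
            # underloaded cells keep pulsing
            if load > target_load * (1 + tol):
                pulse_cmd[:n_step] = v_hold  # rest pulse: no further loading
            else:
                pulse_cmd[:n_step] = v_step
    else:
        done = target_load is None
    if target_load is not None and not done:
        raise StandardizationError(
            f"SR load {loads[-1]:.0f} uM did not reach "
            f"{target_load:.0f}±{100*tol:.0f}% after {len(loads)} pulses")
    return st, {"loads": loads, "n_pulses": len(loads)}
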