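"""Cell-level state containers and the simulation driver.

The model is a 1-D chain of Ca2+ release units (CRUs) at 2 um pitch
spanning a 100 um cell.  Each CRU owns a dyadic subspace and a junctional
SR compartment; the cytosol is divided into one compartment per CRU with
nearest-neighbour free-Ca2+ diffusion; a single network-SR pool refills
all junctional SRs.  Release is cluster-level stochastic: a closed CRU
opens as a Bernoulli draw from an inhomogeneous Poisson trigger rate that
increases with subspace [Ca2+] (Hill), with the recovery variable R, and
with the CPVT sensitivity knob; refractoriness is carried jointly by JSR
refilling and by R.

Everything here wraps the compiled loop in :mod:`crusparks.model.kernel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..params import ModelConfig, RyRParams, pack_params
from . import kernel as K


class IntegrationError(RuntimeError):
    """Numerical failure (NaN / negative concentration) with a state dump."""

    def __init__(self, msg: str, state: "CellState | None" = None):
        super().__init__(msg)
        self.state = state


@dataclass
class CRUState:
    """Per-release-site state (used by the single-CRU reference stepper)."""

    x: float = 0.0          # um
    c_jsr: float = 1000.0   # uM
    c_ss: float = 0.1       # uM
    open: bool = False
    t_open: float = 0.0     # ms since opening
    R: float = 1.0          # recovery variable, 1 = fully recovered

    def __post_init__(self) -> None:
        if self.c_jsr < 0 or self.c_ss < 0:
            raise ValueError("concentrations must be non-negative")
        if not 0.0 <= self.R <= 1.0:
            raise ValueError("R must lie in [0, 1]")


@dataclass
class CellState:
    """Full model state: global scalars, gates and per-CRU arrays."""

    t: float
    vm: float
    c_nsr: float
    gates: np.ndarray           # m,h,j,d,f,xr,xs,ato,ito
    a_i: np.ndarray             # total cytosolic Ca per compartment (uM)
    c_ss: np.ndarray
    c_jsr: np.ndarray
    open_state: np.ndarray      # int8
    t_open: np.ndarray
    R: np.ndarray
    config: ModelConfig = field(repr=False, default=None)

    @property
    def n_cru(self) -> int:
        return self.a_i.size

    @property
    def x(self) -> np.ndarray:
        """CRU positions (um)."""
        dx = self.config.ca.dx if self.config else 2.0
        return (np.arange(self.n_cru) + 0.5) * dx

    @property
    def c_i(self) -> np.ndarray:
        """Free cytosolic [Ca2+] per compartment (uM)."""
        ca = self.config.ca if self.config else None
        b_tot = ca.b_tot if ca else 120.0
        b_kd = ca.b_kd if ca else 0.7
        b = b_tot + b_kd - self.a_i
        return 0.5 * (-b + np.sqrt(b * b + 4 * b_kd * self.a_i))

    def copy(self) -> "CellState":
        return CellState(t=self.t, vm=self.vm, c_nsr=self.c_nsr,
                         gates=self.gates.copy(), a_i=self.a_i.copy(),
                         c_ss=self.c_ss.copy(), c_jsr=self.c_jsr.copy(),
                         open_state=self.open_state.copy(),
                         t_open=self.t_open.copy(), R=self.R.copy(),
                         config=self.config)


def initial_state(cfg: ModelConfig, c_nsr: float = 950.0,
                  vm: float = -85.0) -> CellState:
    """Resting state: gates at their steady state for ``vm``."""
    rates = np.empty(18)
    K.gate_rates(vm, rates)
    gates = rates[0::2].copy()
    n = cfg.ca.n_cru
    c_rest = cfg.ca.c_rest
    a_rest = c_rest + cfg.ca.b_tot * c_rest / (c_rest + cfg.ca.b_kd)
    return CellState(t=0.0, vm=vm, c_nsr=c_nsr, gates=gates,
                     a_i=np.full(n, a_rest),
                     c_ss=np.full(n, c_rest),
                     c_jsr=np.full(n, c_nsr),
                     open_state=np.zeros(n, dtype=np.int8),
                     t_open=np.zeros(n), R=np.ones(n), config=cfg)


@dataclass
class Trajectory:
    """Recorded time series plus the CRU opening log of one run."""

    t: np.ndarray
    vm: np.ndarray
    c_mean: np.ndarray
    c_nsr: np.ndarray
    c_ss_mean: np.ndarray
    currents: np.ndarray        # (9, n) in kernel.CURRENT_NAMES order
    i_clamp: np.ndarray
    c_i: np.ndarray             # (n_cru, n)
    events: pd.DataFrame        # t_open, x, duration, c_jsr_at_open
    x: np.ndarray               # compartment centres (um)
    seed: int
    config_hash: str = ""

    def current(self, name: str) -> np.ndarray:
        return self.currents[K.CURRENT_NAMES.index(name)]

    def spark_events(self, t_offset: float = 0.0) -> list:
        """CRU opening log as SparkEvent records (ground-truth events).

        Event times are opening times shifted by ``t_offset`` (e.g. to
        align with a rendered scan's clock); amplitudes carry the
        junctional SR content at opening relative to its reference, a
        proxy for spark size.
        """
        from ..events import SparkEvent

        out = []
        for _, r in self.events.iterrows():
            out.append(SparkEvent(
                t_peak=float(r.t_open) - t_offset, x=float(r.x),
                amplitude=max(float(r.c_jsr_at_open) / 1000.0, 1e-6),
                meta={"cru": int(r.cru), "duration": float(r.duration)}))
        return out

    def to_frame(self) -> pd.DataFrame:
        d = {"t": self.t, "Vm": self.vm, "c_i_mean": self.c_mean,
             "c_nsr": self.c_nsr, "c_ss_mean": self.c_ss_mean,
             "I_clamp": self.i_clamp}
        for k, nm in enumerate(K.CURRENT_NAMES):
            d[nm] = self.currents[k]
        return pd.DataFrame(d)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def concat(self, other: "Trajectory") -> "Trajectory":
        return Trajectory(
            t=np.concatenate([self.t, other.t]),
            vm=np.concatenate([self.vm, other.vm]),
            c_mean=np.concatenate([self.c_mean, other.c_mean]),
            c_nsr=np.concatenate([self.c_nsr, other.c_nsr]),
            c_ss_mean=np.concatenate([self.c_ss_mean, other.c_ss_mean]),
            currents=np.concatenate([self.currents, other.currents], axis=1),
            i_clamp=np.concatenate([self.i_clamp, other.i_clamp]),
            c_i=np.concatenate([self.c_i, other.c_i], axis=1),
            events=pd.concat([self.events, other.events], ignore_index=True),
            x=self.x, seed=self.seed, config_hash=self.config_hash)


def simulate(cfg: ModelConfig, duration: float, seed: int = 0,
             state: CellState | None = None,
             stim_times: np.ndarray | None = None,
             clamp: np.ndarray | float | None = None,
             ica_replay: np.ndarray | None = None,
             ryr_block: tuple[float, float] | None = None,
             rec_dt: float | None = None,
             rng_states: np.ndarray | None = None
             ) -> tuple[Trajectory, CellState]:
    """Run the resolved model configuration for ``duration`` ms.

    ``clamp`` switches to voltage clamp: a scalar holds the potential, an
    array (sampled at the integration step, or at ``rec_dt`` — it will be
    interpolated) is an AP-clamp command.  ``stim_times`` (ms, absolute)
    fire the stimulus current in current-clamp mode.  ``ryr_block``
    zeroes all CRU trigger rates inside the given (t0, t1) window.
    Returns the trajectory and the final state (reusable to continue).
    """
    rcfg = cfg.resolved()
    P = pack_params(rcfg)
    dt = rcfg.sim.dt
    n_steps = int(round(duration / dt))
    if rec_dt is None:
        rec_dt = rcfg.sim.rec_dt
    rec_every = max(1, int(round(rec_dt / dt)))

    if state is None:
        state = initial_state(rcfg)
    st = state.copy()
    st.config = rcfg
    t0 = st.t

    gstate = np.zeros(K.N_GSTATE)
    gstate[K.S_T] = st.t
    gstate[K.S_VM] = st.vm
    gstate[K.S_CNSR] = st.c_nsr
    gstate[K.S_M:K.S_M + 9] = st.gates

    if stim_times is None:
        stim_times = np.empty(0)
    stim_times = np.asarray(stim_times, dtype=np.float64)

    if clamp is None:
        clamp_mode = 0
        command = np.zeros(1)
    else:
        clamp_mode = 1
        if np.isscalar(clamp):
            command = np.full(1, float(clamp))
            gstate[K.S_VM] = float(clamp)
        else:
            cmd = np.asarray(clamp, dtype=np.float64)
            if cmd.size == n_steps:
                command = cmd
            else:  # resample onto the integration grid
                tc = np.linspace(0, duration, cmd.size)
                command = np.interp(np.arange(n_steps) * dt, tc, cmd)
            gstate[K.S_VM] = command[0]

    if ica_replay is None:
        replay = np.empty(0)
    else:
        rep = np.asarray(ica_replay, dtype=np.float64)
        if rep.size == n_steps:
            replay = rep
        else:
            tc = np.linspace(0, duration, rep.size)
            replay = np.interp(np.arange(n_steps) * dt, tc, rep)

    if ryr_block is None:
        block_t0, block_t1 = np.inf, np.inf
    else:
        block_t0, block_t1 = float(ryr_block[0]), float(ryr_block[1])

    n_rec = n_steps // rec_every + 1
    n_cru = rcfg.ca.n_cru
    rec_t = np.zeros(n_rec); rec_vm = np.zeros(n_rec)
    rec_cmean = np.zeros(n_rec); rec_cnsr = np.zeros(n_rec)
    rec_css = np.zeros(n_rec); rec_cur = np.zeros((9, n_rec))
    rec_icl = np.zeros(n_rec); rec_ci = np.zeros((n_cru, n_rec))

    max_ev = rcfg.sim.max_events
    ev_t = np.zeros(max_ev); ev_x = np.zeros(max_ev, dtype=np.int64)
    ev_dur = np.zeros(max_ev); ev_cjsr = np.zeros(max_ev)
    ev_open_idx = np.full(n_cru, -1, dtype=np.int64)

    if rng_states is None:
        rng_states = K.seed_streams(seed, n_cru)

    # fixed per-site spread of the trigger-recovery time constant
    # (release-site heterogeneity; one draw per CRU, deterministic in seed)
    het = rcfg.ryr.het_refr
    if het > 0:
        fac_rng = np.random.default_rng((int(seed) * 2654435761 + 97) % (2**31))
        refr_fac = np.exp(fac_rng.normal(0.0, het, n_cru))
    else:
        refr_fac = np.ones(n_cru)

    status, got_rec, got_ev = K.integrate(
        P, gstate, st.a_i, st.c_ss, st.c_jsr, st.open_state, st.t_open, st.R,
        rng_states, refr_fac, n_steps, stim_times, clamp_mode, command, replay,
        block_t0, block_t1, rec_every,
        rec_t, rec_vm, rec_cmean, rec_cnsr, rec_css, rec_cur, rec_icl, rec_ci,
        ev_t, ev_x, ev_dur, ev_cjsr, ev_open_idx, 0)

    st.t = gstate[K.S_T]
    st.vm = gstate[K.S_VM]
    st.c_nsr = gstate[K.S_CNSR]
    st.gates = gstate[K.S_M:K.S_M + 9].copy()

    if status != 0:
        raise IntegrationError(
            f"integration failed at t={st.t:.2f} ms (Vm={st.vm}, "
            f"c_nsr={st.c_nsr})", state=st)

    dx = rcfg.ca.dx
    ev = pd.DataFrame({
        "t_open": ev_t[:got_ev],
        "x": (ev_x[:got_ev] + 0.5) * dx,
        "cru": ev_x[:got_ev],
        "duration": ev_dur[:got_ev],
        "c_jsr_at_open": ev_cjsr[:got_ev],
    })
    traj = Trajectory(t=rec_t[:got_rec], vm=rec_vm[:got_rec],
                      c_mean=rec_cmean[:got_rec], c_nsr=rec_cnsr[:got_rec],
                      c_ss_mean=rec_css[:got_rec],
                      currents=rec_cur[:, :got_rec], i_clamp=rec_icl[:got_rec],
                      c_i=rec_ci[:, :got_rec], events=ev,
                      x=(np.arange(n_cru) + 0.5) * dx, seed=seed,
                      config_hash=cfg.hash())
    _ = t0
    return traj, st


def step_cell(state: CellState, cfg: ModelConfig, dt: float,
              seed: int = 0, **kw) -> CellState:
    """Advance the cell by ``dt`` ms and return the new state."""
    _, st = simulate(cfg, duration=dt, seed=seed, state=state, **kw)
    return st


def total_sr_load(state: CellState) -> float:
    """Total SR Ca2+ content per litre of cytosol (uM).

    Volume-weighted junctional + network SR Ca2+ including the
    calsequestrin-bound fraction (the quantity a caffeine-dump assay
    reports), expressed per cytosolic volume.
    """
    cfg = state.config
    if cfg is None:
        raise ValueError("state has no attached config")
    ca = cfg.ca
    v_jsr_i = ca.v_jsr / ca.n_cru
    load = float(np.sum(v_jsr_i * state.c_jsr) * ca.beta_sr
                 + ca.v_nsr * state.c_nsr * ca.beta_sr)
    return max(load, 0.0)


def total_calcium(state: CellState) -> float:
    """Total cell Ca2+ (uM per cytosolic litre), all compartments + buffers."""
    P = pack_params(state.config)
    return float(K.total_calcium(P, state.a_i, state.c_ss, state.c_jsr,
                                 state.c_nsr))


# ---------------------------------------------------------------------------
# reference-level single-CRU operations (unit-testable semantics)
# ---------------------------------------------------------------------------

def spark_trigger_rate(c_ss: float, R: float, p: RyRParams) -> float:
    """Cluster spark trigger rate (1/ms).

    lambda0 * c_ss^h / (c_ss^h + (K_half/k_sens)^h) * R^gamma_rec —
    monotone increasing in subspace [Ca2+], in the recovery variable and
    in the sensitivity knob.
    """
    if c_ss < 0 or not 0.0 <= R <= 1.0:
        raise ValueError("require c_ss >= 0 and 0 <= R <= 1")
    return float(K.trigger_rate(c_ss, R, p.lambda0, p.K_half / p.k_sens,
                                p.hill_h, p.gamma_rec))


def step_cru(s: CRUState, p: RyRParams, dt: float,
             rng: np.random.Generator, c_nsr: float = 1000.0,
             c_ss_clamp: float | None = None) -> CRUState:
    """Advance a single CRU by ``dt`` ms (reference implementation).

    Closed -> open is a Bernoulli draw with probability 1 - exp(-rate*dt);
    an open CRU closes with probability 1 - exp(-dt/tau_open), whereupon
    R resets to R_reset and then relaxes to 1 with time constant
    k_refr * tau_refr_R, while the JSR refills from ``c_nsr`` with time
    constant k_refr * tau_refill.  With ``c_ss_clamp`` the subspace Ca is
    held fixed (used for Poisson-statistics checks).
    """
    out = CRUState(x=s.x, c_jsr=s.c_jsr, c_ss=s.c_ss, open=s.open,
                   t_open=s.t_open, R=s.R)
    if c_ss_clamp is not None:
        out.c_ss = c_ss_clamp
    if out.open:
        out.t_open += dt
        if rng.random() < 1.0 - np.exp(-dt / p.tau_open):
            out.open = False
            out.R = p.R_reset
    else:
        rate = spark_trigger_rate(out.c_ss, out.R, p)
        if rate > 0 and rng.random() < 1.0 - np.exp(-rate * dt):
            out.open = True
            out.t_open = 0.0
        else:
            out.R = min(1.0, out.R + dt * (1.0 - out.R) / (p.k_refr * p.tau_refr_R))
    out.c_jsr += dt * (c_nsr - out.c_jsr) / (p.k_refr * p.tau_refill)
    return out
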