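"""Membrane electrophysiology: current computation, clamp stepping, AP metrics.

The sarcolemmal current set is a rabbit-like ventricular complement —
fast Na+ (I_Na), L-type Ca2+ with both voltage- and subspace-Ca-dependent
inactivation (I_CaL), electrogenic 3Na:1Ca exchange (I_NCX), rapid and
slow delayed rectifiers (I_Kr, I_Ks), transient outward (I_to), inward
rectifier (I_K1), Na/K pump (I_NaK) and the stimulus.  Parameters are
refit to current-density anchors at mid-repolarization rather than taken
from any single published parameter set; mouse-like and human-like
variants are qualitative morphology overlays.

Sign convention: inward currents are negative (depolarizing in current
clamp: dVm/dt = -sum(I)/Cm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import kernel as K
from .model.cell import CellState
from .params import MembraneParams, ModelConfig


@dataclass
class CurrentSet:
    """Membrane current densities (pA/pF); inward negative."""

    I_Na: float
    I_CaL: float
    I_NCX: float
    I_Kr: float
    I_Ks: float
    I_to: float
    I_K1: float
    I_NaK: float
    I_stim: float = 0.0

    def total(self) -> float:
        return (self.I_Na + self.I_CaL + self.I_NCX + self.I_Kr + self.I_Ks
                + self.I_to + self.I_K1 + self.I_NaK + self.I_stim)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("I_Na", "I_CaL", "I_NCX", "I_Kr", "I_Ks", "I_to", "I_K1",
                 "I_NaK", "I_stim")}


def ncx_current(vm: float, c_sub: float, p: MembraneParams) -> float:
    """I_NCX density (pA/pF) for submembrane [Ca2+] ``c_sub`` (uM).

    Standard electrogenic 3:1 form; zero at the reversal condition
    Na_i^3 * Ca_o * exp(eta v) = Na_o^3 * c_sub * exp((eta-1) v).
    """
    return float(K.ncx_current(vm, c_sub, p.g_ncx, p.na_i, p.na_o, p.ca_o,
                               p.km_na, p.km_ca, p.eta, p.k_sat))


def ncx_reversal_csub(vm: float, p: MembraneParams) -> float:
    """Submembrane [Ca2+] (uM) at which I_NCX reverses for a given Vm."""
    vf = vm / K.RT_F
    return (p.na_i ** 3 * p.ca_o * np.exp(vf)) / p.na_o ** 3


def compute_currents(vm: float, cell: CellState, params=None,
                     i_stim: float = 0.0) -> CurrentSet:
    """All membrane current densities for the given state.

    I_CaL carries Ca-dependent inactivation driven by the mean dyadic
    subspace Ca; I_NCX is the mean over release sites of the per-site
    exchanger driven by each site's submembrane (local cytosolic) Ca.
    """
    cfg = cell.config if params is None else params
    if not isinstance(cfg, ModelConfig):
        raise TypeError("params must be a ModelConfig (or None to use the "
                        "state's config)")
    from .params import pack_params

    P = pack_params(cfg.resolved())
    out = np.empty(9)
    css_mean = float(cell.c_ss.mean())
    K.membrane_currents(vm, cell.gates, css_mean, css_mean, P, out)
    mem = cfg.resolved().mem
    i_ncx = float(np.mean([ncx_current(vm, c, mem) for c in cell.c_i]))
    return CurrentSet(I_Na=out[0], I_CaL=out[1], I_NCX=i_ncx, I_Kr=out[3],
                      I_Ks=out[4], I_to=out[5], I_K1=out[6], I_NaK=out[7],
                      I_stim=i_stim)


def step_voltage(vm: float, currents: CurrentSet, dt: float,
                 mode: str = "current_clamp",
                 command: float | None = None,
                 command_next: float | None = None,
                 cm: float = 1.0) -> tuple[float, float]:
    """Advance Vm by one step; returns (new_vm, clamp_current).

    ``current_clamp`` integrates dVm/dt = -sum(I)/Cm.  ``v_clamp`` and
    ``ap_clamp`` force Vm to ``command`` and report the current the
    amplifier injects, I_clamp = Cm dV_cmd/dt + sum(I_ionic).
    """
    if mode == "current_clamp":
        return vm - dt * currents.total() / cm, 0.0
    if mode in ("v_clamp", "ap_clamp"):
        if command is None:
            raise ValueError(f"{mode} requires a command potential")
        dcmd = 0.0 if command_next is None else (command_next - command) / dt
        return float(command), currents.total() + cm * dcmd
    raise ValueError(f"unknown clamp mode {mode!r}")


@dataclass
class APMetrics:
    """Per-beat action-potential morphology metrics."""

    apd30: float
    apd50: float
    apd90: float
    peak_vm: float
    rest_vm: float
    ead_count: int
    t_upstroke: float
    _trace_t: np.ndarray = None
    _trace_vm: np.ndarray = None

    def __post_init__(self) -> None:
        if not (self.apd30 <= self.apd50 <= self.apd90):
            raise ValueError("APD ordering violated")
        if self.ead_count < 0:
            raise ValueError("ead_count must be non-negative")

    def vm_at_frac(self, f: float) -> float:
        """Membrane potential ``f`` of the way through repolarization.

        Evaluated at t_upstroke + f * APD90, so a plateau morphology shows
        a positive potential at f = 0.5 while a triangular AP does not.
        """
        if self._trace_t is None:
            return self.peak_vm - f * (self.peak_vm - self.rest_vm)
        t_eval = self.t_upstroke + f * self.apd90
        return float(np.interp(t_eval, self._trace_t, self._trace_vm))


class NoBeatError(ValueError):
    pass


def ap_metrics(t: np.ndarray, vm: np.ndarray,
               ead_slope: float = 0.05, ead_min_dur: float = 2.0) -> APMetrics:
    """Morphology metrics of a single-beat (t, Vm) trace.

    APD_x is the time from the upstroke (maximal dVm/dt) to the crossing
    of peak - x% * (peak - rest).  An early afterdepolarization is
    counted when dVm/dt exceeds ``ead_slope`` (mV/ms) for at least
    ``ead_min_dur`` ms inside the window between 10 % and 90 %
    repolarization after the initial peak.
    """
    t = np.asarray(t, float)
    vm = np.asarray(vm, float)
    if t.size < 5 or np.ptp(vm) < 5.0:
        raise NoBeatError("no identifiable beat in trace (flat or too short)")
    dv = np.gradient(vm, t)
    iup = int(np.argmax(dv))
    ipk = iup + int(np.argmax(vm[iup:]))
    peak = float(vm[ipk])
    rest = float(np.quantile(vm, 0.05))
    t_up = float(t[iup])

    apds = {}
    for frac, name in [(0.3, "apd30"), (0.5, "apd50"), (0.9, "apd90")]:
        thr = peak - frac * (peak - rest)
        below = np.nonzero(vm[ipk:] <= thr)[0]
        apds[name] = float(t[ipk + below[0]] - t_up) if below.size \
            else float(t[-1] - t_up)

    # EAD detection in the 10-90 % repolarization window; a depolarizing
    # run only counts when it *starts* below 30 % repolarization, which
    # excludes the physiological notch-and-dome of the early plateau
    thr10 = peak - 0.1 * (peak - rest)
    thr30 = peak - 0.3 * (peak - rest)
    thr90 = peak - 0.9 * (peak - rest)
    in_win = (np.arange(t.size) > ipk) & (vm <= thr10) & (vm >= thr90)
    rising = in_win & (dv > ead_slope)
    ead_count = 0
    dt_med = float(np.median(np.diff(t)))
    run_len = 0
    run_start_v = np.nan
    for k, flag in enumerate(rising):
        if flag:
            if run_len == 0:
                run_start_v = vm[k]
            run_len += 1
        else:
            if run_len * dt_med >= ead_min_dur and run_start_v <= thr30:
                ead_count += 1
            run_len = 0
    if run_len * dt_med >= ead_min_dur and run_start_v <= thr30:
        ead_count += 1

    return APMetrics(apd30=apds["apd30"], apd50=apds["apd50"],
                     apd90=apds["apd90"], peak_vm=peak, rest_vm=rest,
                     ead_count=ead_count, t_upstroke=t_up,
                     _trace_t=t, _trace_vm=vm)


def ap_metrics_paced(t: np.ndarray, vm: np.ndarray,
                     stim_times: np.ndarray, **kw) -> list[APMetrics]:
    """Per-beat metrics for a multi-beat paced trace."""
    stim_times = np.sort(np.asarray(stim_times, float))
    out = []
    for b, ts in enumerate(stim_times):
        te = stim_times[b + 1] if b + 1 < len(stim_times) else t[-1]
        m = (t >= ts) & (t < te)
        if m.sum() < 5:
            continue
        out.append(ap_metrics(t[m], vm[m], **kw))
    return out


def read_command(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column time (ms) / voltage (mV) command waveform file."""
    arr = np.loadtxt(path)
    return arr[:, 0], arr[:, 1]


def write_command(path, t: np.ndarray, vm: np.ndarray) -> None:
    np.savetxt(path, np.column_stack([t, vm]), fmt="%.5f",
               header="t_ms\tVm_mV")
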