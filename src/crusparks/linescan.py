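"""Confocal-style line-scan synthesis and rendering.

A line scan is a space x time matrix of F/F0 fluorescence sampled along a
line through a myocyte.  This module produces such scans from two sources:

* :func:`render_linescan` converts a simulated per-compartment [Ca2+]
  trajectory into fluorescence through a saturable indicator relation,
  blurs it with the confocal point-spread function and adds noise — the
  bridge from the stochastic CRU model to the image domain the spark
  detector operates on.

* :func:`synth_sparks` fabricates a scan from scratch: a cell-average
  evoked transient (instant rise, exponential decay) with Ca2+ sparks of
  specified amplitude / spatial FWHM / temporal FDHM implanted at Poisson
  times and uniform positions, returned together with the exact ground
  truth.  This is the fixture generator used to validate the detection
  pipeline independently of the simulator.

Scans are written as 32-bit TIFF stacks with a YAML sidecar carrying the
pixel pitch and line period; ground truth goes to a CSV event table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq

from .events import SparkEvent

_SIG2FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class LineScan:
    """Space x time F/F0 matrix with acquisition geometry.

    ``F`` has shape (n_pixels, n_lines); ``dx`` is the pixel pitch (um)
    and ``dt_line`` the line period (ms).  ``f0_region`` is the (t0, t1)
    window (ms) whose per-pixel mean defines the F0 baseline.
    """

    F: np.ndarray
    dx: float
    dt_line: float
    f0_region: tuple[float, float] = (0.0, 100.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=np.float32)
        if self.F.ndim != 2:
            raise ValueError("F must be 2-D (space x time)")
        if np.any(~np.isfinite(self.F)):
            raise ValueError("non-finite fluorescence values")

    @property
    def n_pixels(self) -> int:
        return self.F.shape[0]

    @property
    def n_lines(self) -> int:
        return self.F.shape[1]

    @property
    def length(self) -> float:
        """Scanned length (um)."""
        return self.n_pixels * self.dx

    @property
    def duration(self) -> float:
        """Scan duration (ms)."""
        return self.n_lines * self.dt_line

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.n_pixels) + 0.5) * self.dx

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_lines) * self.dt_line

    def mean_trace(self) -> np.ndarray:
        """Spatially averaged F/F0 versus time."""
        return self.F.mean(axis=0)

    def save(self, path: str | Path) -> None:
        """Write a 32-bit TIFF plus a YAML sidecar with the geometry."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.F.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".yaml")
        with open(sidecar, "w") as fh:
            yaml.safe_dump({"dx_um": float(self.dx),
                            "dt_line_ms": float(self.dt_line),
                            "f0_region_ms": [float(self.f0_region[0]),
                                             float(self.f0_region[1])],
                            "meta": _plain(self.meta)}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "LineScan":
        import tifffile

        path = Path(path)
        F = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".yaml")
        with open(sidecar) as fh:
            info = yaml.safe_load(fh)
        return cls(F=F, dx=info["dx_um"], dt_line=info["dt_line_ms"],
                   f0_region=tuple(info["f0_region_ms"]),
                   meta=info.get("meta", {}))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class GroundTruth:
    """True implanted events matched to a synthetic LineScan."""

    events: list[SparkEvent]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame([{"t_peak_ms": e.t_peak, "x_um": e.x,
                       "amplitude": e.amplitude, "fwhm_x_um": e.fwhm_x,
                       "fdhm_t_ms": e.fdhm_t, "cls": e.cls}
                      for e in self.events]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# indicator relation
# ---------------------------------------------------------------------------

def indicator_fluorescence(c: np.ndarray, kd: float = 1.0) -> np.ndarray:
    """Saturable (Hill-1) indicator relation F = c/(c + Kd), c and Kd in uM."""
    c = np.asarray(c, dtype=float)
    return c / (c + kd)


def psf_attenuation(fwhm_source: float, psf_fwhm: float) -> float:
    """Peak attenuation of a Gaussian profile blurred by a Gaussian PSF.

    A Gaussian of width sigma_s convolved with a PSF of width sigma_p keeps
    its area, so its peak scales by sigma_s / sqrt(sigma_s^2 + sigma_p^2).
    """
    s = fwhm_source / _SIG2FWHM
    p = psf_fwhm / _SIG2FWHM
    return s / np.hypot(s, p)


# ---------------------------------------------------------------------------
# renderer: simulated trajectory -> line scan
# ---------------------------------------------------------------------------

def render_linescan(t_ms: np.ndarray, x_um: np.ndarray, c_i: np.ndarray,
                    psf_fwhm: float = 0.8, dx: float = 0.2,
                    dt_line: float = 2.0, noise_sd: float = 0.0,
                    indicator_kd: float = 1.0,
                    f0_region: tuple[float, float] = (0.0, 100.0),
                    seed: int | None = None) -> LineScan:
    """Render a per-compartment [Ca2+] trajectory as a confocal line scan.

    Parameters
    ----------
    t_ms : recording times (ms), shape (n_t,).
    x_um : compartment centres (um), shape (n_x,).
    c_i : cytosolic [Ca2+] (uM), shape (n_x, n_t).
    psf_fwhm : spatial FWHM of the Gaussian point-spread function (um).
    dx, dt_line : pixel pitch (um) and line period (ms) of the output.
    noise_sd : additive Gaussian noise SD on F/F0.
    indicator_kd : indicator dissociation constant (uM).
    f0_region : baseline window (ms) used for F0 normalisation.
    seed : noise RNG seed.
    """
    t_ms = np.asarray(t_ms, float)
    x_um = np.asarray(x_um, float)
    c_i = np.asarray(c_i, float)
    if c_i.shape != (x_um.size, t_ms.size):
        raise ValueError("c_i must have shape (n_x, n_t)")
    traj_dt = float(np.median(np.diff(t_ms)))
    if dt_line < traj_dt - 1e-9:
        raise ValueError(f"dt_line {dt_line} ms below trajectory resolution {traj_dt} ms")

    # sample times on the scan grid, restricted to the trajectory span
    t_scan = np.arange(t_ms[0], t_ms[-1] + 1e-9, dt_line)
    # pixel grid spanning the compartment chain
    x0, x1 = x_um[0] - 0.5 * (x_um[1] - x_um[0]), x_um[-1] + 0.5 * (x_um[1] - x_um[0])
    n_px = int(round((x1 - x0) / dx))
    x_px = x0 + (np.arange(n_px) + 0.5) * dx

    # time interpolation then spatial interpolation onto pixels
    ci_t = np.empty((x_um.size, t_scan.size))
    for k in range(x_um.size):
        ci_t[k] = np.interp(t_scan, t_ms, c_i[k])
    ci_px = np.empty((n_px, t_scan.size))
    for j in range(t_scan.size):
        ci_px[:, j] = np.interp(x_px, x_um, ci_t[:, j])

    F = indicator_fluorescence(ci_px, kd=indicator_kd)
    sigma_px = (psf_fwhm / _SIG2FWHM) / dx
    if sigma_px > 0:
        F = gaussian_filter1d(F, sigma_px, axis=0, mode="nearest")

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, noise_sd, size=F.shape) * F.mean()

    scan = LineScan(F=F, dx=dx, dt_line=dt_line, f0_region=f0_region,
                    meta={"source": "render", "psf_fwhm_um": psf_fwhm,
                          "indicator_kd_uM": indicator_kd, "noise_sd": noise_sd,
                          "t0_ms": float(t_ms[0])})
    return _normalise_f0(scan)


def _normalise_f0(scan: LineScan) -> LineScan:
    t = scan.t
    m = (t >= scan.f0_region[0]) & (t <= scan.f0_region[1])
    if not m.any():
        m = t < max(scan.dt_line * 5, t[0] + 1)
    f0 = scan.F[:, m].mean(axis=1, keepdims=True)
    f0 = np.maximum(f0, 1e-6)
    scan.F = (scan.F / f0).astype(np.float32)
    return scan


# ---------------------------------------------------------------------------
# synthetic generator with ground truth
# ---------------------------------------------------------------------------

def _spark_time_kernel(dt: float, fdhm: float, n: int) -> tuple[np.ndarray, int]:
    """Rise-and-decay temporal spark kernel with unit peak and given FDHM (ms).

    Shape (1 - exp(-t/tau_r)) * exp(-t/tau_d) with tau_r = fdhm/8 and tau_d
    solved numerically so that the full duration at half maximum matches.
    """
    tau_r = fdhm / 8.0

    def fdhm_of(tau_d: float) -> float:
        tt = np.arange(0, 12 * fdhm, dt / 4)
        s = (1 - np.exp(-tt / tau_r)) * np.exp(-tt / tau_d)
        s /= s.max()
        above = tt[s >= 0.5]
        return above[-1] - above[0] if above.size else 0.0

    tau_d = brentq(lambda td: fdhm_of(td) - fdhm, fdhm / 10, fdhm * 10)
    tt = np.arange(n) * dt
    s = (1 - np.exp(-tt / tau_r)) * np.exp(-tt / tau_d)
    peak_idx = int(np.argmax(s))
    return s / s.max(), peak_idx


def synth_sparks(duration: float = 1500.0, length: float = 100.0,
                 dx: float = 0.2, dt_line: float = 2.0,
                 t_stim: float = 200.0, transient_amp: float = 1.5,
                 transient_tau: float = 250.0,
                 n_sparks: int = 20, spark_amp: float = 0.6,
                 fwhm_x: float = 2.0, fdhm_t: float = 25.0,
                 spark_window: tuple[float, float] | None = None,
                 noise_sd: float = 0.0, psf_fwhm: float = 0.8,
                 pair_mode: bool = False, pair_tau_rec: float = 90.0,
                 pair_intervals: np.ndarray | None = None,
                 seed: int | None = None) -> tuple[LineScan, GroundTruth]:
    """Fabricate a line scan with implanted sparks and exact ground truth.

    The scan is a resting baseline (F/F0 = 1) carrying a cell-average
    evoked transient (instant rise at ``t_stim`` to ``1 + transient_amp``,
    exponential decay with ``transient_tau``), on which ``n_sparks`` events
    of peak amplitude ``spark_amp`` dF/F0, spatial FWHM ``fwhm_x`` and
    temporal FDHM ``fdhm_t`` are superimposed at Poisson-disc times and
    uniform positions, the whole field blurred by the PSF, plus Gaussian
    noise of SD ``noise_sd`` (SNR = spark_amp / noise_sd).

    In ``pair_mode`` events are implanted as same-site pairs: the second
    spark of each pair follows the first by an interval drawn log-uniformly
    from 20-400 ms (or taken from ``pair_intervals``) with its amplitude
    scaled by the refractoriness recovery factor 1 - exp(-dt/pair_tau_rec).
    Ground truth then carries the pair structure in ``meta``.
    """
    rng = np.random.default_rng(seed)
    n_px = int(round(length / dx))
    n_t = int(round(duration / dt_line))
    t = np.arange(n_t) * dt_line
    x = (np.arange(n_px) + 0.5) * dx

    F = np.ones((n_px, n_t))
    post = t >= t_stim
    F[:, post] += transient_amp * np.exp(-(t[post] - t_stim) / transient_tau)

    if spark_window is None:
        spark_window = (t_stim + 20.0, duration - 4 * fdhm_t)
    w0, w1 = spark_window

    kern_t, kpeak = _spark_time_kernel(dt_line, fdhm_t, int(6 * fdhm_t / dt_line) + 2)
    sigma_px = (fwhm_x / _SIG2FWHM) / dx

    events: list[SparkEvent] = []

    def implant(t0: float, x0: float, amp: float, pair_id=None, order=0):
        j0 = int(round(t0 / dt_line))
        prof_x = amp * np.exp(-0.5 * ((np.arange(n_px) - x0 / dx + 0.5) / sigma_px) ** 2)
        j1 = min(n_t, j0 + kern_t.size)
        if j1 <= j0:
            return
        F[:, j0:j1] += prof_x[:, None] * kern_t[None, : j1 - j0]
        ev = SparkEvent(t_peak=(j0 + kpeak) * dt_line, x=x0, amplitude=amp,
                        fwhm_x=fwhm_x, fdhm_t=fdhm_t,
                        meta={} if pair_id is None else
                        {"pair_id": pair_id, "order": order})
        events.append(ev)

    if pair_mode:
        n_pairs = n_sparks // 2
        if pair_intervals is None:
            pair_intervals = np.exp(rng.uniform(np.log(20.0), np.log(400.0), n_pairs))
        else:
            pair_intervals = np.asarray(pair_intervals, float)
            n_pairs = pair_intervals.size
        slots = np.arange(5.0, length - 5.0, 4.0)
        if n_pairs > slots.size:
            raise ValueError("too many pairs for distinct release sites")
        xs = rng.choice(slots, n_pairs, replace=False)
        for k in range(n_pairs):
            dt_k = float(pair_intervals[k])
            t1 = rng.uniform(w0, max(w0 + 1.0, w1 - dt_k))
            implant(t1, xs[k], spark_amp, pair_id=k, order=0)
            implant(t1 + dt_k, xs[k], spark_amp * (1 - np.exp(-dt_k / pair_tau_rec)),
                    pair_id=k, order=1)
    else:
        # Poisson-disc style placement: reject events closer than one spark
        # footprint to keep the overlap fraction low.
        placed: list[tuple[float, float]] = []
        tries = 0
        while len(placed) < n_sparks and tries < 100 * n_sparks:
            tries += 1
            t0 = rng.uniform(w0, w1)
            x0 = rng.uniform(2.0, length - 2.0)
            if any(abs(t0 - tp) < 2.5 * fdhm_t and abs(x0 - xp) < 2.5 * fwhm_x
                   for tp, xp in placed):
                continue
            placed.append((t0, x0))
        if len(placed) < n_sparks:
            raise ValueError("event density too high to place non-overlapping sparks")
        for t0, x0 in placed:
            implant(t0, x0, spark_amp)

    if psf_fwhm > 0:
        F = gaussian_filter1d(F, (psf_fwhm / _SIG2FWHM) / dx, axis=0, mode="nearest")
    if noise_sd > 0:
        F = F + rng.normal(0.0, noise_sd, size=F.shape)
    if F.min() <= 0:
        raise ValueError("parameters yield non-positive fluorescence; reduce noise_sd "
                         "or amplitudes")

    scan = LineScan(F=F, dx=dx, dt_line=dt_line,
                    f0_region=(0.0, max(dt_line, t_stim - 20.0)),
                    meta={"source": "synth", "psf_fwhm_um": psf_fwhm,
                          "noise_sd": noise_sd, "t_stim_ms": t_stim,
                          "transient_amp": transient_amp,
                          "transient_tau_ms": transient_tau,
                          "pair_mode": pair_mode,
                          "pair_tau_rec_ms": pair_tau_rec if pair_mode else None,
                          "seed": seed})
    return scan, GroundTruth(events=events)
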