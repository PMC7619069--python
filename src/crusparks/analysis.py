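"""Late Ca2+ spark (LCS) analysis pipeline.

Implements the line-scan analysis chain: high-pass filtering that removes
the cell-average transient, threshold-based automated spark detection,
classification of events as evoked / LCS / diastolic relative to the
transient time course, LCS frequency in events per second per 100 um,
same-site inter-spark interval statistics, exponential amplitude-recovery
fitting, and the distribution of events over membrane potential and
fractional AP repolarization.

An LCS (late Ca2+ spark) is a spark occurring during the decay of the
electrically evoked transient, between its peak and 90 % recovery; sparks
after the cell-average fluorescence has returned to within 10 % of the
resting level are classed as diastolic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.stats import t as student_t

from .events import SparkEvent
from .linescan import LineScan

__all__ = [
    "SparkEvent", "TransientMetrics", "highpass_filter", "detect_sparks",
    "transient_metrics", "classify_events", "classify_events_paced",
    "lcs_frequency", "pair_intervals", "median_bootstrap_ci", "recovery_fit",
    "RecoveryFit", "voltage_distribution",
]


@dataclass
class TransientMetrics:
    """Cell-average Ca2+ transient metrics for one beat.

    amplitude : peak dF/F0 above baseline.
    fdhm : full duration at half maximum (ms).
    synchrony : SD across pixels of local half-rise times (ms).
    t_peak : time of the transient peak (ms, scan clock).
    t90 : time of 90 % recovery toward baseline (ms).
    baseline : resting F/F0 level before the upstroke.
    """

    amplitude: float
    fdhm: float
    synchrony: float
    t_peak: float
    t90: float
    baseline: float

    def __post_init__(self) -> None:
        if self.fdhm <= 0:
            raise ValueError("fdhm must be positive")
        if not self.t_peak < self.t90:
            raise ValueError("t_peak must precede t90")


class ClassificationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def highpass_filter(scan: LineScan, cutoff_t: float = 120.0,
                    cutoff_x: float = 20.0) -> LineScan:
    """Remove the cell-average transient and slow gradients from a scan.

    Two-stage rolling-median baseline subtraction: a large median kernel
    across space (``cutoff_x`` um) removes spatially uniform structure —
    including the evoked transient — at every time line, then a rolling
    median in time (``cutoff_t`` ms) removes static spatial banding.  The
    output is the zero-mean residual in which sparks stand out.

    Median (rather than mean) baselines are exact on monotone segments,
    so an exponential transient decay leaves almost no residual, and they
    are robust to the sparks themselves.

    A warning is raised when a cutoff is small enough to erode events of
    typical spark scale (FDHM ~25 ms, FWHM ~2 um).
    """
    if cutoff_t < 50.0:
        warnings.warn(f"cutoff_t={cutoff_t} ms is close to spark FDHM; "
                      "events may be attenuated", stacklevel=2)
    if cutoff_x < 6.0:
        warnings.warn(f"cutoff_x={cutoff_x} um is close to spark FWHM; "
                      "events may be attenuated", stacklevel=2)
    F = scan.F.astype(np.float64)
    kx = max(3, int(round(cutoff_x / scan.dx)) | 1)
    kt = max(3, int(round(cutoff_t / scan.dt_line)) | 1)
    resid = F - ndimage.median_filter(F, size=(kx, 1), mode="nearest")
    resid -= ndimage.median_filter(resid, size=(1, kt), mode="nearest")
    out = LineScan(F=resid.astype(np.float32), dx=scan.dx, dt_line=scan.dt_line,
                   f0_region=scan.f0_region,
                   meta={**scan.meta, "filtered": True,
                         "cutoff_t_ms": cutoff_t, "cutoff_x_um": cutoff_x})
    return out


def robust_sd(filtered: np.ndarray) -> float:
    """Baseline noise SD from the median absolute deviation (Gaussian-consistent)."""
    a = np.asarray(filtered, float)
    return float(1.4826 * np.median(np.abs(a - np.median(a))))


_SIG2FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _gauss_atten(sigma_source: float, sigma_kernel: float) -> float:
    """Peak attenuation of a Gaussian of width sigma_source by a Gaussian blur."""
    if sigma_kernel <= 0:
        return 1.0
    return sigma_source / float(np.hypot(sigma_source, sigma_kernel))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_sparks(filtered: LineScan, k_sd: float = 3.8, min_area: int = 4,
                  smooth_x: float = 0.3, smooth_t: float = 1.5,
                  k_sd_peak: float | None = None,
                  edge_px: int = 3) -> list[SparkEvent]:
    """Threshold-based automated spark detection on a high-pass filtered scan.

    The residual is first smoothed with a small Gaussian (``smooth_x`` um,
    ``smooth_t`` ms — well below the spark footprint, so the spark peak is
    barely attenuated while pixel noise is strongly suppressed).  Pixels
    exceeding ``k_sd`` times the robust baseline SD of the smoothed
    residual are grouped by 8-connectivity; groups become events when they
    cover at least ``min_area`` pixels *and* their peak exceeds a second,
    higher criterion (``k_sd_peak``, default ``2.5 * k_sd``) — the classic
    two-threshold scheme that separates spark peaks from connected noise
    excursions.  A small border (``edge_px``) is excluded, where the
    rolling-baseline filters are unreliable.

    Event amplitude, spatial FWHM and temporal FDHM are measured on the
    baseline-subtracted fluorescence with only a 3x3 boxcar applied (so
    amplitudes are essentially unattenuated), interpolating the
    half-maximum crossings.
    """
    if k_sd_peak is None:
        k_sd_peak = 2.5 * k_sd
    raw = filtered.F.astype(np.float64)
    sig = (smooth_x / filtered.dx, smooth_t / filtered.dt_line)
    R = ndimage.gaussian_filter(raw, sig, mode="nearest") if max(sig) > 0 else raw
    # baseline noise estimated on the quiet pre-stimulus (F0) window when
    # available — the global MAD is inflated on scans dense with events
    t = filtered.t
    quiet = (t >= filtered.f0_region[0]) & (t <= filtered.f0_region[1])
    sd = robust_sd(R[:, quiet]) if quiet.sum() >= 20 else robust_sd(R)
    if sd <= 0:
        sd = robust_sd(R)
    if sd <= 0:
        sd = R.std() or 1e-12
    mask = R > k_sd * sd
    if edge_px > 0:
        mask[:edge_px, :] = False
        mask[-edge_px:, :] = False
        mask[:, :edge_px] = False
        mask[:, -edge_px:] = False
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_lab == 0:
        return []

    # split merged regions at watershed lines between distinct peaks —
    # dense recordings (many LCS per transient) otherwise fuse events
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    fp_x = max(1, int(round(1.0 / filtered.dx)))       # 1 um
    fp_t = max(1, int(round(8.0 / filtered.dt_line)))  # 8 ms
    peaks = peak_local_max(R, footprint=np.ones((2 * fp_x + 1, 2 * fp_t + 1)),
                           threshold_abs=k_sd_peak * sd, labels=labels,
                           exclude_border=False)
    if peaks.shape[0] == 0:
        return []
    markers = np.zeros_like(labels)
    for k, (pi, pj) in enumerate(peaks, start=1):
        markers[pi, pj] = k
    n_mark = peaks.shape[0]

    # additional markers from sharp fluorescence *rises*: consecutive
    # release events at one site overlap in amplitude but each opening has
    # its own steep upstroke, so the time-derivative separates them where
    # the amplitude image cannot.  A rise qualifies as a marker when it is
    # fast (its derivative peak is far above the derivative noise) and is
    # followed by a genuine local amplitude increment.
    deriv = np.gradient(ndimage.gaussian_filter(raw, (sig[0], 2.0 / filtered.dt_line),
                                                mode="nearest"), axis=1) \
        / filtered.dt_line
    sd_d = robust_sd(deriv)
    if sd_d > 0:
        rise_mask = deriv > k_sd * sd_d
        rise_mask &= mask  # only inside suprathreshold amplitude regions
        rlab, n_r = ndimage.label(rise_mask, structure=np.ones((3, 3), dtype=int))
        w_t = max(1, int(round(20.0 / filtered.dt_line)))
        b_t = max(1, int(round(6.0 / filtered.dt_line)))
        for sl in ndimage.find_objects(rlab):
            if sl is None:
                continue
            reg_d = np.where(rlab[sl] > 0, deriv[sl], -np.inf)
            pi, pj = np.unravel_index(np.argmax(reg_d), reg_d.shape)
            i = sl[0].start + pi
            j = sl[1].start + pj
            if deriv[i, j] < 1.4 * k_sd * sd_d:      # not a sharp rise
                continue
            j2 = min(R.shape[1], j + w_t)
            jpk = j + int(np.argmax(R[i, j:j2])) if j2 > j else j
            d_amp = R[i, jpk] - R[i, max(0, j - b_t)]
            if R[i, jpk] < k_sd_peak * sd or d_amp < 0.45 * k_sd_peak * sd:
                continue
            # skip when an existing marker already covers this event
            i0, i1 = max(0, i - fp_x), min(markers.shape[0], i + fp_x + 1)
            j0, j1 = max(0, jpk - fp_t), min(markers.shape[1], jpk + fp_t + 1)
            if markers[i0:i1, j0:j1].max() == 0 and mask[i, jpk]:
                n_mark += 1
                markers[i, jpk] = n_mark
    wlab = watershed(-R, markers=markers, mask=mask)

    # measurement image: nearly unsmoothed residual
    B = ndimage.uniform_filter(raw, size=3, mode="nearest")
    events: list[SparkEvent] = []
    objects = ndimage.find_objects(wlab)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        region = wlab[sl] == lab
        if region.sum() < min_area:
            continue
        sub = np.where(region, R[sl], -np.inf)
        if sub.max() < k_sd_peak * sd:
            continue
        pi, pj = np.unravel_index(np.argmax(sub), sub.shape)
        i = sl[0].start + pi
        j = sl[1].start + pj
        amp = float(B[i, j])
        if amp <= 0:
            continue
        fwhm = _half_width(B[:, j], i, filtered.dx)
        fdhm = _half_width(B[i, :], j, filtered.dt_line)
        events.append(SparkEvent(
            t_peak=float(j * filtered.dt_line), x=float((i + 0.5) * filtered.dx),
            amplitude=amp, fwhm_x=fwhm, fdhm_t=fdhm,
            meta={"area_px": int(region.sum()), "label": int(lab)}))
    events.sort(key=lambda e: e.t_peak)
    return events


def _half_width(profile: np.ndarray, peak_idx: int, step: float) -> float:
    """Interpolated width of ``profile`` at half its value at ``peak_idx``."""
    half = 0.5 * profile[peak_idx]
    lo = peak_idx
    while lo > 0 and profile[lo - 1] > half:
        lo -= 1
    hi = peak_idx
    n = len(profile)
    while hi < n - 1 and profile[hi + 1] > half:
        hi += 1
    left = float(lo)
    if lo > 0 and profile[lo] != profile[lo - 1]:
        left = lo - (profile[lo] - half) / (profile[lo] - profile[lo - 1])
    right = float(hi)
    if hi < n - 1 and profile[hi] != profile[hi + 1]:
        right = hi + (profile[hi] - half) / (profile[hi] - profile[hi + 1])
    return float((right - left) * step)


# ---------------------------------------------------------------------------
# transient metrics and classification
# ---------------------------------------------------------------------------

def transient_metrics(scan: LineScan, t_stim: float | None = None,
                      t_end: float | None = None,
                      smooth_ms: float = 6.0) -> TransientMetrics:
    """Cell-average transient metrics for the beat starting near ``t_stim``.

    When ``t_stim`` is omitted the largest upstroke of the mean trace is
    used.  ``t_end`` bounds the recovery search (next stimulus for paced
    recordings).
    """
    t = scan.t
    f = scan.mean_trace().astype(float)
    ns = max(1, int(round(smooth_ms / scan.dt_line)))
    if ns > 1:
        f = ndimage.uniform_filter1d(f, ns)
    if t_stim is None:
        dif = np.diff(f)
        t_stim = float(t[max(0, int(np.argmax(dif)) - 1)])
    if t_end is None:
        t_end = float(t[-1])
    pre = (t >= max(0.0, t_stim - 120.0)) & (t < t_stim)
    baseline = float(f[pre].mean()) if pre.any() else float(f[t < t_stim].mean()
                                                            if (t < t_stim).any()
                                                            else f[0])
    seg = (t >= t_stim) & (t <= t_end)
    if not seg.any():
        raise ClassificationError("no samples in the transient window")
    tseg, fseg = t[seg], f[seg]
    # peak of the *electrically evoked* transient: the first local maximum
    # that reaches near the beat maximum, so that late release (LCS) riding
    # on the decay cannot drag the peak outward
    ig = int(np.argmax(fseg))
    amp_g = fseg[ig] - baseline
    ip = ig
    thresh_pk = baseline + 0.85 * amp_g
    for k in range(1, len(fseg) - 1):
        if fseg[k] >= thresh_pk and fseg[k] >= fseg[k - 1] and fseg[k] >= fseg[k + 1]:
            ip = k
            break
    t_peak = float(tseg[ip])
    amplitude = float(fseg[ip] - baseline)
    if amplitude <= 0:
        raise ClassificationError("no transient found (flat trace)")

    # 90 % recovery: first decay sample at baseline + 0.1 * amplitude
    thresh90 = baseline + 0.1 * amplitude
    dec = fseg[ip:]
    below = np.nonzero(dec <= thresh90)[0]
    t90 = float(tseg[ip + below[0]]) if below.size else float(tseg[-1])
    if t90 <= t_peak:
        t90 = t_peak + scan.dt_line

    # FDHM of the transient
    half = baseline + 0.5 * amplitude
    above = np.nonzero(fseg >= half)[0]
    fdhm = float((above[-1] - above[0] + 1) * scan.dt_line) if above.size \
        else scan.dt_line

    # synchrony: SD over pixels of the local half-rise time
    rise_t = []
    i0 = int(np.searchsorted(t, t_stim))
    i1 = int(np.searchsorted(t, t_peak)) + 1
    for px in range(scan.n_pixels):
        tr = scan.F[px, i0:i1].astype(float)
        if tr.size < 2:
            continue
        local_half = tr[0] + 0.5 * (tr.max() - tr[0])
        idx = np.nonzero(tr >= local_half)[0]
        if idx.size:
            rise_t.append(t[i0 + idx[0]] - t_stim)
    synchrony = float(np.std(rise_t)) if len(rise_t) > 1 else 0.0

    return TransientMetrics(amplitude=amplitude, fdhm=fdhm, synchrony=synchrony,
                            t_peak=t_peak, t90=t90, baseline=baseline)


def classify_events(events: list[SparkEvent], tm: TransientMetrics,
                    scan: LineScan | None = None,
                    resting_band: float = 0.10,
                    boundary: str = "resting") -> list[SparkEvent]:
    """Assign evoked / LCS / diastolic classes relative to one transient.

    Events peaking at or before the transient peak are evoked; events in
    the decay up to the LCS/diastolic boundary are LCS; later events are
    diastolic.  Two boundary conventions exist and are both available:
    ``boundary='resting'`` (default) classes events as diastolic only
    once the cell-average fluorescence has returned to within
    ``resting_band`` (10 %) of the resting level — it requires ``scan``;
    ``boundary='t90'`` ends the LCS window earlier, at 90 % recovery of
    the transient.  Events falling between the two boundaries are classed
    LCS under the default and diastolic under 't90'.
    """
    if tm is None:
        raise ClassificationError("transient metrics required for classification")
    if boundary == "t90":
        t_bound = tm.t90
    elif boundary == "resting":
        if scan is None:
            raise ClassificationError("boundary='resting' needs the scan")
        t = scan.t
        f = ndimage.uniform_filter1d(scan.mean_trace().astype(float),
                                     max(1, int(6.0 / scan.dt_line)))
        thr = tm.baseline * (1.0 + resting_band)
        dec = (t > tm.t_peak)
        idx = np.nonzero(dec & (f <= thr))[0]
        t_bound = float(t[idx[0]]) if idx.size else float(t[-1])
    else:
        raise ValueError("boundary must be 't90' or 'resting'")

    out = []
    for e in events:
        if e.t_peak <= tm.t_peak:
            cls = "evoked"
        elif e.t_peak <= t_bound:
            cls = "LCS"
        else:
            cls = "diastolic"
        out.append(SparkEvent(**{**e.__dict__, "cls": cls}))
    return out


def classify_events_paced(events: list[SparkEvent], scan: LineScan,
                          stim_times: np.ndarray,
                          boundary: str = "t90") -> tuple[list[SparkEvent],
                                                          list[TransientMetrics]]:
    """Classify events on a multi-beat paced scan, beat by beat.

    Each event is classified against the transient of the beat it falls
    in (events before the first stimulus are diastolic).
    """
    stim_times = np.sort(np.asarray(stim_times, float))
    tms: list[TransientMetrics] = []
    for b, ts in enumerate(stim_times):
        te = stim_times[b + 1] if b + 1 < len(stim_times) else scan.duration
        tms.append(transient_metrics(scan, t_stim=ts, t_end=te))
    out: list[SparkEvent] = []
    for e in events:
        b = int(np.searchsorted(stim_times, e.t_peak, side="right")) - 1
        if b < 0:
            out.append(SparkEvent(**{**e.__dict__, "cls": "diastolic"}))
            continue
        out.extend(classify_events([e], tms[b], scan=scan, boundary=boundary))
    return out, tms


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def lcs_frequency(events: list[SparkEvent], scan: LineScan,
                  window: float | None = None) -> float:
    """LCS frequency in events per second per 100 um of scanned line.

    ``window`` is the analysed duration (ms); by default the full scan.
    """
    if window is None:
        window = scan.duration
    if window <= 0:
        raise ValueError("window must be positive")
    n = sum(1 for e in events if e.cls == "LCS")
    return n / (window / 1000.0) / (scan.length / 100.0)


def pair_intervals(events: list[SparkEvent], radius: float = 2.0,
                   classes: tuple[str, ...] = ("LCS",)) -> tuple[np.ndarray, float]:
    """Intervals between successive same-site sparks.

    Two events are a pair when the later one is the next event within
    ``radius`` um of the earlier one (the same release site, one CRU
    pitch by default).  Returns the interval array (ms) and its median
    (nan when no pairs exist).
    """
    sel = sorted((e for e in events if e.cls in classes or e.cls is None),
                 key=lambda e: e.t_peak)
    intervals = []
    for i, e in enumerate(sel):
        for j in range(i + 1, len(sel)):
            if abs(sel[j].x - e.x) <= radius:
                if sel[j].t_peak > e.t_peak:
                    intervals.append(sel[j].t_peak - e.t_peak)
                break
    intervals = np.asarray(intervals, float)
    med = float(np.median(intervals)) if intervals.size else float("nan")
    return intervals, med


def median_bootstrap_ci(values: np.ndarray, n_boot: int = 1000,
                        alpha: float = 0.05, seed: int = 0) -> tuple[float, float]:
    """Seeded bootstrap percentile CI for the median."""
    values = np.asarray(values, float)
    if values.size == 0:
        return float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    meds = np.median(rng.choice(values, size=(n_boot, values.size)), axis=1)
    return (float(np.quantile(meds, alpha / 2)),
            float(np.quantile(meds, 1 - alpha / 2)))


@dataclass
class RecoveryFit:
    """Single-exponential amplitude-recovery fit, ratio(dt) = 1 - exp(-dt/tau)."""

    tau_rec: float
    tau_ci: tuple[float, float]
    resid_sd: float
    n_pairs: int
    saturated: bool

    def predict(self, dt: np.ndarray) -> np.ndarray:
        return 1.0 - np.exp(-np.asarray(dt, float) / self.tau_rec)

    def prediction_band(self, dt: np.ndarray,
                        level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Approximate pointwise prediction band from the residual scatter."""
        z = student_t.ppf(0.5 + level / 2, max(1, self.n_pairs - 1))
        mu = self.predict(dt)
        return mu - z * self.resid_sd, mu + z * self.resid_sd


class FitFailureError(RuntimeError):
    pass


def recovery_fit(intervals: np.ndarray, ratios: np.ndarray) -> RecoveryFit:
    """Fit the spark amplitude-recovery time constant from same-site pairs.

    ``intervals`` are pair separations (ms) and ``ratios`` the second/first
    amplitude ratios.  Fits ratio = 1 - exp(-dt/tau) by least squares.
    When all ratios sit near 1 at every interval the recovery is already
    complete at the shortest observed interval; tau is then reported at
    the lower boundary with ``saturated=True``.
    """
    dt = np.asarray(intervals, float)
    r = np.asarray(ratios, float)
    if dt.size != r.size or dt.size < 3:
        raise FitFailureError("need at least 3 pairs")
    if np.ptp(dt) < 1e-9:
        raise FitFailureError("degenerate interval spread")

    lo = max(1e-3, 0.05 * dt.min())
    if np.all(r > 0.9):
        return RecoveryFit(tau_rec=float(dt.min() / 3.0), tau_ci=(0.0, dt.min()),
                           resid_sd=float(np.std(r - 1.0)), n_pairs=dt.size,
                           saturated=True)
    try:
        popt, pcov = curve_fit(lambda d, tau: 1.0 - np.exp(-d / tau), dt, r,
                               p0=[float(np.median(dt))],
                               bounds=(lo, 100.0 * dt.max()), maxfev=10000)
    except Exception as exc:  # pragma: no cover
        raise FitFailureError(f"recovery fit failed: {exc}") from exc
    tau = float(popt[0])
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("inf")
    z = student_t.ppf(0.975, max(1, dt.size - 1))
    resid = r - (1.0 - np.exp(-dt / tau))
    return RecoveryFit(tau_rec=tau, tau_ci=(tau - z * se, tau + z * se),
                       resid_sd=float(resid.std(ddof=1) if dt.size > 2 else 0.0),
                       n_pairs=dt.size, saturated=False)


def pair_amplitude_ratios(events: list[SparkEvent], radius: float = 2.0,
                          classes: tuple[str, ...] = ("LCS",)
                          ) -> tuple[np.ndarray, np.ndarray]:
    """(interval, amp2/amp1) arrays for successive same-site spark pairs."""
    sel = sorted((e for e in events if e.cls in classes or e.cls is None),
                 key=lambda e: e.t_peak)
    dts, ratios = [], []
    for i, e in enumerate(sel):
        for j in range(i + 1, len(sel)):
            if abs(sel[j].x - e.x) <= radius:
                if sel[j].t_peak > e.t_peak:
                    dts.append(sel[j].t_peak - e.t_peak)
                    ratios.append(sel[j].amplitude / e.amplitude)
                break
    return np.asarray(dts, float), np.asarray(ratios, float)


# ---------------------------------------------------------------------------
# voltage / repolarization distribution
# ---------------------------------------------------------------------------

def voltage_distribution(events: list[SparkEvent], t_vm: np.ndarray,
                         vm: np.ndarray, stim_times: np.ndarray | None = None,
                         vm_bins: np.ndarray | None = None,
                         frac_bins: np.ndarray | None = None,
                         classes: tuple[str, ...] = ("LCS", "diastolic"),
                         clock_tol: float | None = None):
    """Distribute events over membrane potential and % AP repolarization.

    Each selected event is assigned the membrane potential at its peak
    time and, within its beat, the fractional repolarization
    (Vpeak - Vm) / (Vpeak - Vrest), clipped to [0, 1].  Returns
    ``(events_annotated, hist_vm, vm_edges, hist_frac, frac_edges)`` with
    both histograms normalised to unit sum.

    Raises when an event falls outside the voltage trace by more than
    ``clock_tol`` (one line period's worth of slack by default).
    """
    t_vm = np.asarray(t_vm, float)
    vm = np.asarray(vm, float)
    if clock_tol is None:
        clock_tol = float(np.median(np.diff(t_vm))) * 2 + 2.0
    sel = [e for e in events if (e.cls in classes) or (e.cls is None)]
    if stim_times is None:
        stim_times = np.array([t_vm[0]])
    stim_times = np.sort(np.asarray(stim_times, float))

    # per-beat peak and rest
    beats = []
    for b, ts in enumerate(stim_times):
        te = stim_times[b + 1] if b + 1 < len(stim_times) else t_vm[-1] + 1e-9
        m = (t_vm >= ts) & (t_vm < te)
        if not m.any():
            continue
        vpk = float(vm[m].max())
        vrest = float(np.quantile(vm[m], 0.02))
        beats.append((ts, te, vpk, vrest))

    annotated = []
    for e in sel:
        if e.t_peak < t_vm[0] - clock_tol or e.t_peak > t_vm[-1] + clock_tol:
            raise ValueError(f"event at {e.t_peak} ms outside the Vm trace "
                             f"(clock mismatch > {clock_tol} ms)")
        v_at = float(np.interp(e.t_peak, t_vm, vm))
        frac = float("nan")
        for ts, te, vpk, vrest in beats:
            if ts <= e.t_peak < te:
                if vpk > vrest:
                    frac = float(np.clip((vpk - v_at) / (vpk - vrest), 0.0, 1.0))
                break
        annotated.append(SparkEvent(**{**e.__dict__, "vm_at_peak": v_at,
                                       "repol_frac": frac}))

    if vm_bins is None:
        vm_bins = np.arange(-90.0, 50.0 + 1e-9, 10.0)
    if frac_bins is None:
        frac_bins = np.linspace(0.0, 1.0, 11)
    vms = np.array([e.vm_at_peak for e in annotated], float)
    fracs = np.array([e.repol_frac for e in annotated], float)
    h_vm, _ = np.histogram(vms, bins=vm_bins)
    h_fr, _ = np.histogram(fracs[np.isfinite(fracs)], bins=frac_bins)
    h_vm = h_vm / h_vm.sum() if h_vm.sum() else h_vm.astype(float)
    h_fr = h_fr / h_fr.sum() if h_fr.sum() else h_fr.astype(float)
    return annotated, h_vm, vm_bins, h_fr, frac_bins
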