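"""Spark detection, classification and LCS statistics."""

import numpy as np
import pytest

from crusparks import analysis as an
from crusparks.events import SparkEvent
from crusparks.linescan import LineScan, synth_sparks


def make_scan(F, dx=0.2, dt=2.0, f0=(0.0, 100.0)):
    return LineScan(F=np.asarray(F, np.float32), dx=dx, dt_line=dt,
                    f0_region=f0)


# ---------------------------------------------------------------------------
# high-pass filter
# ---------------------------------------------------------------------------

def test_constant_scan_filters_to_zero():
    scan = make_scan(np.ones((100, 300)))
    out = an.highpass_filter(scan)
    assert np.allclose(out.F, 0.0, atol=1e-6)


def test_slow_transient_leaves_small_residual():
    t = np.arange(600) * 2.0
    F = 1.0 + 1.5 * np.exp(-t / 400.0)  # decay much slower than cutoff
    scan = make_scan(np.tile(F, (100, 1)))
    out = an.highpass_filter(scan, cutoff_t=120.0)
    assert np.sqrt(np.mean(out.F[:, 30:-30] ** 2)) < 0.05 * 1.5


def test_implanted_spark_peak_survives_filtering():
    scan, gt = synth_sparks(n_sparks=6, spark_amp=0.6, noise_sd=0.0, seed=1)
    filt = an.highpass_filter(scan)
    atten = 0.6 * 0.93  # PSF attenuation of the implanted amplitude
    for e in gt.events:
        i, j = int(e.x / scan.dx), int(e.t_peak / scan.dt_line)
        peak = filt.F[max(0, i - 6):i + 7, max(0, j - 4):j + 5].max()
        assert peak > 0.8 * atten  # preserved to within 20 %


def test_small_cutoff_warns():
    scan = make_scan(np.ones((50, 100)))
    with pytest.warns(UserWarning):
        an.highpass_filter(scan, cutoff_t=30.0)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def test_blank_scan_detects_nothing():
    scan = make_scan(np.ones((100, 300)))
    assert an.detect_sparks(an.highpass_filter(scan)) == []


def test_detection_count_monotone_in_threshold():
    scan, _ = synth_sparks(n_sparks=20, spark_amp=0.6, noise_sd=0.12, seed=0)
    filt = an.highpass_filter(scan)
    counts = [len(an.detect_sparks(filt, k_sd=k))
              for k in (3.0, 3.8, 4.5, 6.0, 9.0)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_detector_finds_implants_with_few_errors():
    """20 implanted sparks at SNR 5: 20 +/- 1 found, clean on most seeds."""
    clean = 0
    for seed in range(5):
        scan, gt = synth_sparks(n_sparks=20, spark_amp=0.6, noise_sd=0.12,
                                seed=seed)
        events = an.detect_sparks(an.highpass_filter(scan))
        matched = _match(gt.events, events)
        if len(events) - matched == 0 and 19 <= len(events) <= 21:
            clean += 1
    assert clean >= 4


def _match(truth, detected, dt=25.0, dx=3.0):
    used, tp = set(), 0
    for g in truth:
        for i, e in enumerate(detected):
            if i in used:
                continue
            if abs(e.t_peak - g.t_peak) < dt and abs(e.x - g.x) < dx:
                used.add(i)
                tp += 1
                break
    return tp


def test_event_morphology_measured_plausibly():
    scan, gt = synth_sparks(n_sparks=10, spark_amp=0.6, fwhm_x=2.0,
                            fdhm_t=25.0, noise_sd=0.0, seed=3)
    events = an.detect_sparks(an.highpass_filter(scan))
    assert np.median([e.fwhm_x for e in events]) == pytest.approx(2.15, rel=0.25)
    assert np.median([e.fdhm_t for e in events]) == pytest.approx(25.0, rel=0.25)


# ---------------------------------------------------------------------------
# transient metrics + classification
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def classified_fixture():
    scan, gt = synth_sparks(n_sparks=15, spark_amp=0.7, noise_sd=0.08,
                            seed=11, duration=2000.0, transient_tau=200.0)
    tm = an.transient_metrics(scan, t_stim=200.0)
    events = an.detect_sparks(an.highpass_filter(scan))
    cls = an.classify_events(events, tm, scan=scan)
    return scan, tm, events, cls


def test_transient_metrics_sane(classified_fixture):
    scan, tm, _, _ = classified_fixture
    assert tm.t_peak == pytest.approx(202, abs=10)
    assert 1.0 < tm.amplitude < 2.0
    assert tm.t_peak < tm.t90 < scan.duration
    assert tm.fdhm > 50.0
    assert tm.synchrony < 10.0  # instant-rise generator: tight synchrony


def test_classification_is_a_partition(classified_fixture):
    _, _, events, cls = classified_fixture
    assert len(cls) == len(events)
    assert all(e.cls in ("evoked", "LCS", "diastolic") for e in cls)


def test_classification_boundary_rules():
    tm = an.TransientMetrics(amplitude=1.0, fdhm=150.0, synchrony=2.0,
                             t_peak=240.0, t90=600.0, baseline=1.0)
    evs = [SparkEvent(t_peak=t, x=50.0, amplitude=0.5)
           for t in (100.0, 241.0, 599.0, 900.0)]
    out = an.classify_events(evs, tm, boundary="t90")
    assert [e.cls for e in out] == ["evoked", "LCS", "LCS", "diastolic"]


def test_resting_rule_extends_lcs_window():
    """Events between 90 % recovery and the 10 %-of-rest point stay LCS."""
    t = np.arange(1000) * 2.0
    f = np.ones((50, 1000))
    decay = 1.0 + 1.5 * np.exp(-(t[t >= 200] - 200.0) / 250.0)
    f[:, t >= 200] = decay[None, :]
    scan = make_scan(f)
    tm = an.transient_metrics(scan, t_stim=200.0)
    mid = SparkEvent(t_peak=tm.t90 + 50.0, x=50.0, amplitude=0.5)
    by_t90 = an.classify_events([mid], tm, scan=scan, boundary="t90")
    by_rest = an.classify_events([mid], tm, scan=scan, boundary="resting")
    assert by_t90[0].cls == "diastolic"
    assert by_rest[0].cls == "LCS"


def test_missing_transient_raises():
    scan = make_scan(np.ones((50, 500)))
    with pytest.raises(an.ClassificationError):
        an.transient_metrics(scan, t_stim=200.0)
    with pytest.raises(an.ClassificationError):
        an.classify_events([], None)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def test_lcs_frequency_unit_arithmetic():
    scan = make_scan(np.ones((500, 500)))  # 100 um x 1 s
    evs = [SparkEvent(t_peak=100.0 * k, x=10.0, amplitude=1.0, cls="LCS")
           for k in range(10)]
    assert an.lcs_frequency(evs, scan, window=1000.0) == pytest.approx(10.0)
    assert an.lcs_frequency([], scan) == 0.0
    with pytest.raises(ValueError):
        an.lcs_frequency(evs, scan, window=0.0)


def test_pair_intervals_worked_example():
    evs = [SparkEvent(t_peak=t, x=20.0, amplitude=1.0, cls="LCS")
           for t in (100.0, 170.0, 300.0)]
    ints, med = an.pair_intervals(evs)
    assert sorted(ints.tolist()) == [70.0, 130.0]
    assert med == pytest.approx(100.0)


def test_pair_intervals_empty_cases():
    one = [SparkEvent(t_peak=50.0, x=10.0, amplitude=1.0, cls="LCS")]
    ints, med = an.pair_intervals(one)
    assert ints.size == 0 and np.isnan(med)
    far = [SparkEvent(t_peak=50.0, x=10.0, amplitude=1.0, cls="LCS"),
           SparkEvent(t_peak=90.0, x=50.0, amplitude=1.0, cls="LCS")]
    ints, _ = an.pair_intervals(far, radius=2.0)
    assert ints.size == 0


def test_recovery_fit_noiseless_tau():
    rng = np.random.default_rng(0)
    dts = np.exp(rng.uniform(np.log(20), np.log(400), 60))
    fit = an.recovery_fit(dts, 1 - np.exp(-dts / 90.0))
    assert fit.tau_rec == pytest.approx(90.0, rel=0.01)
    assert not fit.saturated


def test_recovery_fit_scale_equivariance():
    rng = np.random.default_rng(1)
    dts = np.exp(rng.uniform(np.log(20), np.log(400), 50))
    r = 1 - np.exp(-dts / 90.0) + rng.normal(0, 0.02, 50)
    tau1 = an.recovery_fit(dts, r).tau_rec
    tau3 = an.recovery_fit(3.0 * dts, r).tau_rec
    assert tau3 == pytest.approx(3.0 * tau1, rel=1e-6)


def test_recovery_fit_flags_saturation():
    dts = np.array([50.0, 120.0, 300.0, 400.0])
    fit = an.recovery_fit(dts, np.array([0.99, 1.0, 1.01, 0.98]))
    assert fit.saturated
    assert fit.tau_rec < dts.min()


def test_recovery_fit_rejects_degenerate():
    with pytest.raises(an.FitFailureError):
        an.recovery_fit(np.array([100.0, 100.0, 100.0]),
                        np.array([0.5, 0.6, 0.55]))


def test_pair_amplitude_ratios_feed_recovery_fit():
    scan, gt = synth_sparks(n_sparks=40, pair_mode=True, pair_tau_rec=90.0,
                            noise_sd=0.0, seed=9, duration=5000.0)
    dts, ratios = an.pair_amplitude_ratios(gt.events, radius=1.0)
    fit = an.recovery_fit(dts, ratios)
    assert fit.tau_rec == pytest.approx(90.0, rel=0.10)


def test_median_bootstrap_ci_brackets_median():
    vals = np.random.default_rng(2).exponential(100.0, 200)
    lo, hi = an.median_bootstrap_ci(vals, seed=0)
    med = np.median(vals)
    assert lo <= med <= hi


# ---------------------------------------------------------------------------
# voltage / repolarization distributions
# ---------------------------------------------------------------------------

def _ap_trace():
    t = np.arange(0, 1000.0, 1.0)
    vm = np.full(t.size, -85.0)
    up = (t >= 50) & (t < 250)
    vm[up] = 40.0 - (t[up] - 50) * (125.0 / 200.0)  # linear repolarization
    return t, vm


def test_voltage_distribution_normalised_and_positioned():
    t, vm = _ap_trace()
    evs = [SparkEvent(t_peak=150.0, x=10.0, amplitude=1.0, cls="LCS"),
           SparkEvent(t_peak=700.0, x=30.0, amplitude=1.0, cls="diastolic")]
    out, h_vm, vm_edges, h_fr, fr_edges = an.voltage_distribution(
        evs, t, vm, stim_times=np.array([50.0]))
    assert h_vm.sum() == pytest.approx(1.0)
    assert h_fr.sum() == pytest.approx(1.0)
    mid = out[0]
    assert mid.vm_at_peak == pytest.approx(-22.5, abs=2.0)
    assert 0.4 < mid.repol_frac < 0.6
    dia = out[1]
    assert dia.vm_at_peak == pytest.approx(-85.0, abs=1.0)


def test_all_diastolic_mass_at_resting_bin():
    t, vm = _ap_trace()
    evs = [SparkEvent(t_peak=tt, x=10.0, amplitude=1.0, cls="diastolic")
           for tt in (600.0, 700.0, 800.0)]
    _, h_vm, edges, _, _ = an.voltage_distribution(evs, t, vm,
                                                   stim_times=np.array([50.0]))
    rest_bin = np.searchsorted(edges, -85.0) - 1
    assert h_vm[rest_bin] == pytest.approx(1.0)


def test_clock_mismatch_raises():
    t, vm = _ap_trace()
    evs = [SparkEvent(t_peak=5000.0, x=10.0, amplitude=1.0, cls="LCS")]
    with pytest.raises(ValueError):
        an.voltage_distribution(evs, t, vm)
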