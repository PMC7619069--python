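"""TU-complex decomposition and Bazett correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crusparks import ecg


WINDOW = (0.40, 0.75)  # T-downslope through U end for the default beat


def test_noiseless_fit_recovers_generator_parameters():
    beat = ecg.synth_beat(noise_sd=0.0, seed=1)
    fit = ecg.fit_tu(beat, WINDOW)
    true = beat.meta["true"]
    assert fit.tau_exp == pytest.approx(true["tau_exp"], rel=1e-3)
    assert fit.a_g == pytest.approx(true["a_g"], rel=1e-3)
    assert fit.mu_g == pytest.approx(true["mu_g"], abs=1e-4)
    assert fit.sigma_g == pytest.approx(true["sigma_g"], rel=1e-3)
    assert fit.rmse < 1e-8


def test_u_integral_closed_form():
    # a_g = 0.08 mV, sigma = 0.04 s -> 0.08*0.04*sqrt(2*pi)*1000 ~ 8.02 ms.mV
    beat = ecg.synth_beat(a_g=0.08, sigma_g=0.04, noise_sd=0.0, seed=2)
    fit = ecg.fit_tu(beat, WINDOW)
    expected = 0.08 * 0.04 * np.sqrt(2 * np.pi) * 1000.0
    assert fit.u_integral == pytest.approx(expected, rel=0.01)
    assert ecg.u_wave_integral(0.08, 0.04) == pytest.approx(expected)


def test_pure_exponential_gives_negligible_u_wave():
    beat = ecg.synth_beat(a_g=0.0, noise_sd=0.0, seed=3)
    fit = ecg.fit_tu(beat, WINDOW)
    assert fit.u_integral < 0.15  # ms.mV, ~2 % of a typical U-wave


def test_u_integral_invariant_under_baseline_shift():
    beat = ecg.synth_beat(noise_sd=0.0, seed=4)
    fit0 = ecg.fit_tu(beat, WINDOW)
    beat.v = beat.v + 0.35  # constant offset
    fit1 = ecg.fit_tu(beat, WINDOW)
    assert fit1.u_integral == pytest.approx(fit0.u_integral, rel=0.02)


def test_mu_sweep_maps_one_to_one_onto_qau():
    qaus, mus = [], []
    for mu in (0.50, 0.55, 0.60):
        beat = ecg.synth_beat(mu_g=mu, noise_sd=0.0, seed=5)
        fit = ecg.fit_tu(beat, (0.40, 0.80))
        qaus.append(fit.qau)
        mus.append(mu)
    diffs = np.diff(qaus)
    assert np.allclose(diffs, np.diff(mus), atol=0.005)


def test_parameter_recovery_at_snr_10():
    """a_g/a_exp >= 0.2, sigma <= tau/2: parameters within 10 % at SNR 10."""
    errs = []
    for seed in range(20):
        beat = ecg.synth_beat(a_exp=0.25, tau_exp=0.10, a_g=0.08,
                              sigma_g=0.04, noise_sd=0.008, seed=seed)
        fit = ecg.fit_tu(beat, WINDOW)
        errs.append(abs(fit.u_integral / 8.02 - 1.0))
    assert np.mean(errs) < 0.10


def test_population_contrast_separated_by_u_integral():
    """Generator populations at ~1.8 vs ~8.4 ms.mV are cleanly separated."""
    lo, hi = [], []
    for seed in range(8):
        b1 = ecg.synth_beat(a_g=0.018, sigma_g=0.04, noise_sd=0.004,
                            seed=seed)
        b2 = ecg.synth_beat(a_g=0.084, sigma_g=0.04, noise_sd=0.004,
                            seed=100 + seed)
        lo.append(ecg.fit_tu(b1, WINDOW).u_integral)
        hi.append(ecg.fit_tu(b2, WINDOW).u_integral)
    assert max(lo) < min(hi)
    assert np.mean(lo) == pytest.approx(1.8, rel=0.25)
    assert np.mean(hi) == pytest.approx(8.4, rel=0.25)


class TestQtcBazett:
    def test_printed_values(self):
        assert ecg.qtc_bazett(0.41, 1.00) == pytest.approx(0.41)
        assert ecg.qtc_bazett(0.40, 0.64) == pytest.approx(0.50)

    @given(qt=st.floats(0.1, 0.6), rr=st.floats(0.3, 2.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_closed_form_property(self, qt, rr):
        assert ecg.qtc_bazett(qt, rr) == pytest.approx(qt / np.sqrt(rr))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ecg.qtc_bazett(0.0, 1.0)
        with pytest.raises(ValueError):
            ecg.qtc_bazett(0.4, -1.0)


def test_same_seed_same_beat():
    b1 = ecg.synth_beat(noise_sd=0.01, seed=42)
    b2 = ecg.synth_beat(noise_sd=0.01, seed=42)
    assert np.array_equal(b1.v, b2.v)


def test_beat_io_roundtrip(tmp_path):
    beat = ecg.synth_beat(noise_sd=0.0, seed=6)
    path = tmp_path / "beat.txt"
    ecg.write_beat(path, beat)
    back = ecg.read_beat(path, qrs_onset=beat.qrs_onset)
    assert np.allclose(back.v, beat.v, atol=1e-5)


def test_mean_u_integral_averages_cycles():
    fits = [ecg.fit_tu(ecg.synth_beat(noise_sd=0.004, seed=s), WINDOW)
            for s in range(3)]
    m = ecg.mean_u_integral(fits)
    assert m == pytest.approx(np.mean([f.u_integral for f in fits]))
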