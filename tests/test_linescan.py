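"""Synthetic line-scan generation and rendering."""

import numpy as np
import pytest

from crusparks.linescan import (LineScan, indicator_fluorescence,
                                psf_attenuation, render_linescan,
                                synth_sparks)


def test_zero_rate_zero_noise_equals_pure_transient():
    scan, gt = synth_sparks(n_sparks=0, noise_sd=0.0, psf_fwhm=0.0, seed=1)
    assert len(gt.events) == 0
    t = scan.t
    post = t >= 200.0
    expected = 1.0 + 1.5 * np.exp(-(t[post] - 200.0) / 250.0)
    # every pixel carries exactly the cell-average transient
    assert np.allclose(scan.F[:, post], expected[None, :], rtol=1e-4)


def test_ground_truth_has_exactly_n_events():
    scan, gt = synth_sparks(n_sparks=20, spark_amp=0.6, noise_sd=0.12, seed=2)
    assert len(gt.events) == 20
    for e in gt.events:
        assert 0 <= e.x <= scan.length
        assert 0 <= e.t_peak <= scan.duration


def test_seed_determinism_bit_identical():
    s1, _ = synth_sparks(n_sparks=10, noise_sd=0.1, seed=7)
    s2, _ = synth_sparks(n_sparks=10, noise_sd=0.1, seed=7)
    assert np.array_equal(s1.F, s2.F)


def test_implanted_amplitudes_match_psf_attenuation_oracle():
    """Zero-noise implanted peaks equal spec amplitude x Gaussian attenuation."""
    scan, gt = synth_sparks(n_sparks=12, spark_amp=0.6, fwhm_x=2.0,
                            noise_sd=0.0, psf_fwhm=0.8, seed=3)
    atten = psf_attenuation(2.0, 0.8)
    for e in gt.events:
        i = int(e.x / scan.dx)
        j = int(e.t_peak / scan.dt_line)
        i0, i1 = max(0, i - 6), i + 7
        j0, j1 = max(0, j - 4), j + 5
        peak = scan.F[i0:i1, j0:j1].max()
        # subtract the local transient background (same columns, far rows)
        far = scan.F[(i + 120) % scan.n_pixels, j0:j1].max()
        measured = peak - far
        assert measured == pytest.approx(0.6 * atten, rel=0.12)


def test_pair_mode_generates_recovering_second_sparks():
    scan, gt = synth_sparks(n_sparks=40, pair_mode=True, pair_tau_rec=90.0,
                            noise_sd=0.0, seed=4, duration=3000.0)
    pairs = {}
    for e in gt.events:
        pairs.setdefault(e.meta["pair_id"], []).append(e)
    assert all(len(v) == 2 for v in pairs.values())
    for first, second in ((sorted(v, key=lambda e: e.t_peak)) for v in pairs.values()):
        dt = second.t_peak - first.t_peak
        expected = first.amplitude * (1 - np.exp(-dt / 90.0))
        assert second.amplitude == pytest.approx(expected, rel=0.05)


def test_overcrowded_spec_raises():
    with pytest.raises(ValueError):
        synth_sparks(n_sparks=4000, duration=500.0, seed=5)


def test_negative_fluorescence_raises():
    with pytest.raises(ValueError):
        synth_sparks(n_sparks=0, noise_sd=3.0, seed=6)


# ---------------------------------------------------------------------------
# renderer
# ---------------------------------------------------------------------------

def _flat_traj(n_x=20, n_t=200, c=0.1):
    t = np.arange(n_t) * 2.0
    x = (np.arange(n_x) + 0.5) * 2.0
    ci = np.full((n_x, n_t), c)
    return t, x, ci


def test_quiescent_render_is_unity():
    t, x, ci = _flat_traj()
    scan = render_linescan(t, x, ci, noise_sd=0.0)
    assert np.allclose(scan.F, 1.0, atol=1e-5)


def test_renderer_low_ca_linearity():
    """Sub-saturation: doubling a small delta-Ca doubles dF/F0 within 5 %."""
    t, x, ci = _flat_traj()
    for k, dca in ((1, 0.02), (2, 0.04)):
        cc = ci.copy()
        cc[:, 100:] += dca
        scan = render_linescan(t, x, cc, noise_sd=0.0)
        if k == 1:
            d1 = scan.F[5, 150] - 1.0
        else:
            d2 = scan.F[5, 150] - 1.0
    assert d2 / d1 == pytest.approx(2.0, rel=0.05)


def test_single_site_release_broadened_at_least_to_psf():
    t, x, ci = _flat_traj(n_x=40)
    ci = ci.copy()
    ci[20, 80:120] = 2.0  # one hot compartment
    scan = render_linescan(t, x, ci, psf_fwhm=0.8, noise_sd=0.0)
    prof = scan.F[:, 100].astype(float)
    prof -= prof.min()
    above = np.nonzero(prof >= 0.5 * prof.max())[0]
    fwhm = (above[-1] - above[0]) * scan.dx
    assert fwhm >= 0.8


def test_render_rejects_too_fine_dt_line():
    t, x, ci = _flat_traj()
    with pytest.raises(ValueError):
        render_linescan(t, x, ci, dt_line=0.5)  # trajectory is at 2 ms


def test_linescan_tiff_roundtrip(tmp_path):
    scan, _ = synth_sparks(n_sparks=5, noise_sd=0.05, seed=8)
    p = tmp_path / "scan.tif"
    scan.save(p)
    back = LineScan.load(p)
    assert np.allclose(back.F, scan.F)
    assert back.dx == scan.dx and back.dt_line == scan.dt_line
    assert back.meta["source"] == "synth"


def test_indicator_is_saturable():
    f = indicator_fluorescence(np.array([0.5, 1.0, 100.0]), kd=1.0)
    assert f[0] == pytest.approx(1 / 3)
    assert f[1] == pytest.approx(0.5)
    assert f[2] > 0.99 * 100 / 101
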