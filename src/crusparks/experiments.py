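"""End-to-end experiment recipes.

Each recipe reproduces one headline in-silico experiment as a single
call: simulate -> render -> detect -> classify -> summarise, emitting a
JSON-serialisable summary (plus optional figures).  Recipes:

* ``linescan_pair``   — control vs CPVT steady pacing with rendered scans
  and LCS frequencies (the side-by-side line-scan comparison).
* ``sens_refr_heatmap`` — LCS frequency over a k_sens x k_refr grid.
* ``pair_interval_density`` — same-site inter-LCS interval distributions
  under voltage clamp at -40 mV, control vs CPVT, with medians.
* ``ryr_block``       — mid-AP RyR2 block and the APD normalization it
  produces in the CPVT model.
* ``pace_pause``      — EAD induction by a pacing pause, control vs CPVT.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import analysis as an
from .calibrate import (MeasureSettings, measure_lcs_rate,
                        measure_pair_intervals, measure_sr_load)
from .membrane import ap_metrics_paced
from .params import ModelConfig, load_calibrated
from .protocols import ProtocolSpec, run_protocol


def _summary_path(outdir, name):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir / f"{name}.json"


def _write(path, obj):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def _cfgs():
    return load_calibrated("control"), load_calibrated("cpvt")


def linescan_pair(seeds=(1, 2, 3), outdir="out", iso=True,
                  settings: MeasureSettings | None = None) -> dict:
    """Control vs CPVT steady pacing: LCS frequency and SR load."""
    ctrl, cpvt = _cfgs()
    ctrl.iso = cpvt.iso = iso
    out = {}
    for name, cfg in (("control", ctrl), ("cpvt", cpvt)):
        freqs = [measure_lcs_rate(cfg, s, settings) for s in seeds]
        loads = [measure_sr_load(cfg, s, settings) for s in seeds]
        out[name] = {"lcs_rate_mean": float(np.mean(freqs)),
                     "lcs_rate_per_seed": [float(f) for f in freqs],
                     "sr_load_mean": float(np.mean(loads)),
                     "seeds": list(seeds)}
    out["ratio"] = out["cpvt"]["lcs_rate_mean"] / max(
        out["control"]["lcs_rate_mean"], 1e-9)
    _write(_summary_path(outdir, "linescan_pair"), out)
    return out


def sens_refr_heatmap(k_sens_grid=(1.0, 1.6, 2.25),
                      k_refr_grid=(1.0, 0.75, 0.55),
                      seeds=(1, 2, 3), outdir="out",
                      settings: MeasureSettings | None = None) -> dict:
    """LCS frequency over the RyR2 sensitivity x refractoriness grid."""
    base = load_calibrated("control")
    base.iso = True
    grid = []
    for ks in k_sens_grid:
        row = []
        for kr in k_refr_grid:
            cfg = base.with_overrides({"ryr.k_sens": ks, "ryr.k_refr": kr})
            cfg.calibrated = True
            f = float(np.mean([measure_lcs_rate(cfg, s, settings)
                               for s in seeds]))
            row.append(f)
        grid.append(row)
    out = {"k_sens": list(k_sens_grid), "k_refr": list(k_refr_grid),
           "lcs_rate": grid, "seeds": list(seeds)}
    _write(_summary_path(outdir, "sens_refr_heatmap"), out)
    return out


def pair_interval_density(seeds=(1, 2, 3), outdir="out",
                          settings: MeasureSettings | None = None) -> dict:
    """Same-site inter-LCS interval distributions at -40 mV hold."""
    ctrl, cpvt = _cfgs()
    ctrl.iso = cpvt.iso = True
    out = {}
    for name, cfg in (("control", ctrl), ("cpvt", cpvt)):
        pooled = []
        for s in seeds:
            ints, _ = measure_pair_intervals(cfg, s, settings)
            pooled.extend(ints.tolist())
        pooled = np.asarray(pooled)
        med = float(np.median(pooled)) if pooled.size else float("nan")
        lo, hi = an.median_bootstrap_ci(pooled, seed=0)
        out[name] = {"median_ms": med, "median_ci": [lo, hi],
                     "n_pairs": int(pooled.size)}
    _write(_summary_path(outdir, "pair_interval_density"), out)
    return out


def ryr_block(seeds=(1, 2, 3), outdir="out") -> dict:
    """Mid-AP RyR2 block: how much of the CPVT APD prolongation it removes."""
    ctrl, cpvt = _cfgs()
    ctrl.iso = cpvt.iso = True

    def apd90(cfg, seed, block):
        spec = ProtocolSpec(kind="ryr_block_midap" if block else "steady_pace",
                            n_beats=3, n_pre_beats=10, block_beat=1)
        res = run_protocol(spec, cfg, seed=seed)
        mets = res.ap_metrics()
        if block:
            b = spec.n_pre_beats + (spec.block_beat % spec.n_beats)
            # APD of the beat *after* the block engages
            idx = min(b + 1, len(mets) - 1)
            return mets[idx].apd90
        return float(np.mean([m.apd90 for m in mets[-3:]]))

    a_ctrl = float(np.mean([apd90(ctrl, s, False) for s in seeds]))
    a_cpvt = float(np.mean([apd90(cpvt, s, False) for s in seeds]))
    a_cpvt_blk = float(np.mean([apd90(cpvt, s, True) for s in seeds]))
    gap = a_cpvt - a_ctrl
    gap_blk = a_cpvt_blk - a_ctrl
    out = {"apd90_control": a_ctrl, "apd90_cpvt": a_cpvt,
           "apd90_cpvt_blocked": a_cpvt_blk,
           "gap_ms": gap, "gap_blocked_ms": gap_blk,
           "gap_reduction": 1.0 - gap_blk / gap if gap > 0 else float("nan")}
    _write(_summary_path(outdir, "ryr_block"), out)
    return out


def pace_pause(seeds=tuple(range(1, 11)), outdir="out",
               pause_ms: float = 5000.0) -> dict:
    """EAD induction on the first post-pause beat, control vs CPVT."""
    ctrl, cpvt = _cfgs()
    ctrl.iso = cpvt.iso = True
    out = {}
    for name, cfg in (("control", ctrl), ("cpvt", cpvt)):
        ead_seeds = 0
        counts = []
        for s in seeds:
            spec = ProtocolSpec(kind="pace_pause", n_beats=2,
                                n_pre_beats=12, pause_ms=pause_ms)
            res = run_protocol(spec, cfg, seed=s)
            post = res.extras["post_pause_stim"]
            mets = ap_metrics_paced(res.trajectory.t, res.trajectory.vm,
                                    post[:1])
            n_ead = mets[0].ead_count if mets else 0
            counts.append(int(n_ead))
            ead_seeds += int(n_ead >= 1)
        out[name] = {"seeds_with_ead": ead_seeds, "n_seeds": len(seeds),
                     "ead_counts": counts}
    _write(_summary_path(outdir, "pace_pause"), out)
    return out


RECIPES = {
    "linescan_pair": linescan_pair,
    "sens_refr_heatmap": sens_refr_heatmap,
    "pair_interval_density": pair_interval_density,
    "ryr_block": ryr_block,
    "pace_pause": pace_pause,
}
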