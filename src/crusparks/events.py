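"""Ca2+ release event records shared by the synthesiser, detector and simulator."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SparkEvent:
    """A detected or ground-truth Ca2+ release event on a line scan.

    Attributes
    ----------
    t_peak : time of the event peak (ms, scan clock).
    x : longitudinal position of the peak (um).
    amplitude : peak dF/F0 above the local baseline.
    fwhm_x : spatial full width at half maximum (um).
    fdhm_t : temporal full duration at half maximum (ms).
    cls : 'evoked' | 'LCS' | 'diastolic' | None (unclassified).
    vm_at_peak : membrane potential at the event peak (mV), when a
        synchronised voltage trace is available.
    repol_frac : fractional AP repolarization at the event peak (0 at the
        AP peak, 1 at full repolarization), when available.
    """

    t_peak: float
    x: float
    amplitude: float
    fwhm_x: float = float("nan")
    fdhm_t: float = float("nan")
    cls: str | None = None
    vm_at_peak: float = float("nan")
    repol_frac: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("event amplitude must be positive")
        if self.cls not in (None, "evoked", "LCS", "diastolic"):
            raise ValueError(f"unknown event class {self.cls!r}")
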