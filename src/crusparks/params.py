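"""Model parameters: RyR2 gating, Ca2+ handling geometry, membrane currents.

All concentrations are umol/L (uM); time is ms; membrane potential is mV;
current densities are pA/pF; compartment volumes are fractions of the
cytosolic volume, so every flux is expressed in umol per litre of cytosol
per ms and total-Ca bookkeeping is exact.

The two CPVT knobs live on :class:`RyRParams`:

* ``k_sens`` scales RyR2 Ca2+ sensitivity — the half-activation [Ca2+] of
  the trigger-rate Hill function is divided by it (1 = normal, ~2 = CPVT).
* ``k_refr`` scales refractoriness — both the junctional-SR refilling time
  constant and the trigger-recovery time constant are multiplied by it
  (1 = normal, < 1 = CPVT, faster recovery).

Parameter sets load from and dump to flat YAML files; the shipped
``configs/calibration.yaml`` holds the frozen calibration used by the
experiment recipes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml


@dataclass
class RyRParams:
    """Cluster-level RyR2 trigger/release parameters.

    The spark trigger rate of a closed CRU is
    ``lambda0 * c_ss^h / (c_ss^h + (K_half/k_sens)^h) * R^gamma_rec``
    (1/ms), with ``R`` the recovery variable.  While open, the release
    flux is ``J_rel_max * c_jsr / c_jsr_ref`` (uM of cytosol per ms); the
    open duration is exponential with mean ``tau_open``.  On closure R
    resets to ``R_reset`` and relaxes to 1 with time constant
    ``k_refr * tau_refr_R`` while the junctional SR refills from the
    network SR with time constant ``k_refr * tau_refill``.
    """

    k_sens: float = 1.0
    k_refr: float = 1.0
    lambda0: float = 0.35         # 1/ms, maximal trigger rate
    K_half: float = 10.0          # uM subspace Ca at half-maximal trigger
    hill_h: float = 2.0
    tau_refill: float = 90.0      # ms, JSR refilling from NSR
    gamma_rec: float = 10.0       # exponent of R in the trigger rate
    J_rel_max: float = 0.18       # uM/ms (cytosolic volume) per open CRU
    tau_refr_R: float = 65.0      # ms, recovery-variable relaxation
    R_reset: float = 0.0
    tau_open: float = 9.0         # ms, mean open duration
    c_jsr_ref: float = 1000.0     # uM, JSR reference (release-flux scale)
    het_refr: float = 0.2         # SD of per-CRU log tau_refr_R heterogeneity

    def __post_init__(self) -> None:
        if self.k_sens <= 0 or self.k_refr <= 0:
            raise ValueError("k_sens and k_refr must be positive")
        if self.lambda0 < 0:
            raise ValueError("lambda0 must be non-negative")
        if self.hill_h < 1:
            raise ValueError("hill_h must be >= 1")
        if self.tau_refill <= 0 or self.tau_refr_R <= 0 or self.tau_open <= 0:
            raise ValueError("time constants must be positive")
        if not (0.0 <= self.R_reset <= 1.0):
            raise ValueError("R_reset must lie in [0, 1]")


@dataclass
class CaParams:
    """Ca2+ handling: geometry, buffers, SERCA, diffusion, background flux."""

    n_cru: int = 50
    dx: float = 2.0               # um CRU pitch (100 um cell)
    v_ss: float = 0.001           # subspace volume fraction (total)
    v_jsr: float = 0.010          # junctional SR volume fraction (total)
    v_nsr: float = 0.050          # network SR volume fraction
    beta_sr: float = 15.0         # 1 + linearised calsequestrin capacity
    b_tot: float = 120.0          # uM cytosolic rapid buffer
    b_kd: float = 0.7             # uM
    d_ca: float = 0.30            # um^2/ms effective free-Ca diffusion
    tau_ss: float = 0.15          # ms subspace <-> cytosol equilibration
    v_up: float = 0.30            # uM/ms maximal SERCA rate
    k_up: float = 0.30            # uM SERCA half-activation (Hill 2)
    g_leak: float = 2.0e-5        # 1/ms NSR->cytosol leak
    j_bg: float = 0.0036          # uM/ms background sarcolemmal Ca influx
    cal_ss_frac: float = 1.0      # fraction of I_CaL flux entering the dyads
    c_rest: float = 0.10          # uM target diastolic [Ca2+]

    def __post_init__(self) -> None:
        if self.n_cru < 2:
            raise ValueError("need at least 2 CRUs")
        for name in ("v_ss", "v_jsr", "v_nsr", "beta_sr", "tau_ss", "v_up"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MembraneParams:
    """Rabbit-like ventricular membrane model (Hodgkin-Huxley style).

    Conductances are in mS/uF ~ pA/pF/mV; NCX and NaK are maximal
    densities in pA/pF.  ``current_to_flux`` converts 1 pA/pF of a
    divalent current into uM/ms of cytosolic Ca2+.
    """

    g_na: float = 12.0
    g_cal: float = 0.13
    e_cal: float = 60.0           # mV effective reversal of I_CaL
    k_fca: float = 50.0           # uM Ca-dependent inactivation of I_CaL (dyadic)
    g_kr: float = 0.012
    g_ks: float = 0.006
    g_to: float = 0.025
    g_k1: float = 0.35
    g_nak: float = 0.4            # pA/pF maximal NaK
    g_ncx: float = 2400.0         # NCX scale (dimensionless prefactor)
    ncx_sub_frac: float = 0.002   # dyadic-Ca weight in the NCX submembrane mix
    e_na: float = 70.0
    e_k: float = -88.0
    na_i: float = 10.0            # mM
    na_o: float = 140.0           # mM
    ca_o: float = 1800.0          # uM
    km_na: float = 87.5           # mM
    km_ca: float = 1380.0         # uM
    eta: float = 0.35
    k_sat: float = 0.27
    cm: float = 1.0               # uF/cm^2 (currents already per-pF)
    current_to_flux: float = 0.0333  # uM/ms per pA/pF, z = 2
    stim_amp: float = -40.0       # pA/pF
    stim_dur: float = 1.0         # ms

    def __post_init__(self) -> None:
        if self.g_na < 0 or self.g_cal < 0:
            raise ValueError("conductances must be non-negative")


@dataclass
class SimParams:
    """Integration and recording settings."""

    dt: float = 0.01              # ms membrane step
    cru_substep: int = 5          # CRU gating every cru_substep membrane steps
    rec_dt: float = 1.0           # ms trajectory recording interval
    sarcolemmal_on: bool = True
    max_events: int = 400000


ISO_OVERLAY: dict[str, float] = {
    # beta-adrenergic (isoproterenol) effects as parameter multipliers
    "ca.v_up": 1.75,
    "mem.g_cal": 1.5,
    "ryr.lambda0": 1.5,
    "mem.g_ks": 2.0,
}

SPECIES_VARIANTS: dict[str, dict[str, float]] = {
    # qualitative morphology variants; rabbit-like is the baseline
    "rabbit": {},
    "mouse": {"mem.g_to": 0.9, "mem.g_kr": 0.006, "mem.g_ks": 0.004,
              "mem.g_k1": 0.5, "mem.g_cal": 0.07},
    "human": {"mem.g_to": 0.005, "mem.g_kr": 0.007, "mem.g_ks": 0.007,
              "mem.g_cal": 0.24},
}


@dataclass
class ModelConfig:
    """Complete model configuration: the four parameter blocks plus flags."""

    ryr: RyRParams = field(default_factory=RyRParams)
    ca: CaParams = field(default_factory=CaParams)
    mem: MembraneParams = field(default_factory=MembraneParams)
    sim: SimParams = field(default_factory=SimParams)
    iso: bool = False
    species: str = "rabbit"
    calibrated: bool = False

    def copy(self) -> "ModelConfig":
        return ModelConfig(ryr=dataclasses.replace(self.ryr),
                           ca=dataclasses.replace(self.ca),
                           mem=dataclasses.replace(self.mem),
                           sim=dataclasses.replace(self.sim),
                           iso=self.iso, species=self.species,
                           calibrated=self.calibrated)

    def with_overrides(self, overrides: dict[str, float]) -> "ModelConfig":
        """Return a copy with dotted-path overrides applied ('ryr.k_sens': 2)."""
        cfg = self.copy()
        for key, val in overrides.items():
            block, name = key.split(".")
            tgt = getattr(cfg, block)
            if not hasattr(tgt, name):
                raise KeyError(f"unknown parameter {key}")
            setattr(tgt, name, val)
        return cfg

    def with_multipliers(self, mult: dict[str, float]) -> "ModelConfig":
        cfg = self.copy()
        for key, fac in mult.items():
            block, name = key.split(".")
            tgt = getattr(cfg, block)
            setattr(tgt, name, getattr(tgt, name) * fac)
        return cfg

    def resolved(self) -> "ModelConfig":
        """Apply species variant and ISO overlay, returning the effective config."""
        cfg = self.copy()
        if self.species != "rabbit":
            cfg = cfg.with_overrides(SPECIES_VARIANTS[self.species])
        if self.iso:
            cfg = cfg.with_multipliers(ISO_OVERLAY)
            cfg.iso = True
        return cfg

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {"ryr": dataclasses.asdict(self.ryr),
                "ca": dataclasses.asdict(self.ca),
                "mem": dataclasses.asdict(self.mem),
                "sim": dataclasses.asdict(self.sim),
                "iso": self.iso, "species": self.species,
                "calibrated": self.calibrated}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(ryr=RyRParams(**d.get("ryr", {})),
                   ca=CaParams(**d.get("ca", {})),
                   mem=MembraneParams(**d.get("mem", {})),
                   sim=SimParams(**d.get("sim", {})),
                   iso=d.get("iso", False), species=d.get("species", "rabbit"),
                   calibrated=d.get("calibrated", False))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        import hashlib
        import json

        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_calibrated(genotype: str = "control") -> ModelConfig:
    """Load the frozen calibrated configuration shipped with the package.

    ``genotype`` is 'control' (normal RyR2) or 'cpvt' (k_sens ~2, reduced
    k_refr on top of the same base calibration).
    """
    ref = resources.files("crusparks").joinpath("configs/calibration.yaml")
    with ref.open() as fh:
        data = yaml.safe_load(fh)
    cfg = ModelConfig.from_dict(data["base"])
    cfg.calibrated = True
    if genotype == "control":
        return cfg
    if genotype == "cpvt":
        return cfg.with_overrides({"ryr.k_sens": data["cpvt"]["k_sens"],
                                   "ryr.k_refr": data["cpvt"]["k_refr"]})
    raise ValueError("genotype must be 'control' or 'cpvt'")


# ---------------------------------------------------------------------------
# packing for the compiled integrator
# ---------------------------------------------------------------------------
# Index layout of the flat parameter vector handed to the numba kernel.
_PNAMES = [
    # RyR
    "k_sens", "k_refr", "lambda0", "K_half", "hill_h", "tau_refill",
    "gamma_rec", "J_rel_max", "tau_refr_R", "R_reset", "tau_open", "c_jsr_ref",
    # Ca handling
    "n_cru", "dx", "v_ss", "v_jsr", "v_nsr", "beta_sr", "b_tot", "b_kd",
    "d_ca", "tau_ss", "v_up", "k_up", "g_leak", "j_bg", "cal_ss_frac", "c_rest",
    # membrane
    "g_na", "g_cal", "e_cal", "k_fca", "g_kr", "g_ks", "g_to", "g_k1",
    "g_nak", "g_ncx", "ncx_sub_frac", "e_na", "e_k", "na_i", "na_o", "ca_o",
    "km_na", "km_ca", "eta", "k_sat", "cm", "current_to_flux", "stim_amp",
    "stim_dur",
    # integration
    "dt", "cru_substep", "sarco_on",
]
P_IDX = {name: i for i, name in enumerate(_PNAMES)}


def pack_params(cfg: ModelConfig) -> np.ndarray:
    """Flatten the resolved config into the kernel parameter vector."""
    r, c, m, s = cfg.ryr, cfg.ca, cfg.mem, cfg.sim
    vals = {
        "k_sens": r.k_sens, "k_refr": r.k_refr, "lambda0": r.lambda0,
        "K_half": r.K_half, "hill_h": r.hill_h, "tau_refill": r.tau_refill,
        "gamma_rec": r.gamma_rec, "J_rel_max": r.J_rel_max,
        "tau_refr_R": r.tau_refr_R, "R_reset": r.R_reset,
        "tau_open": r.tau_open, "c_jsr_ref": r.c_jsr_ref,
        "n_cru": c.n_cru, "dx": c.dx, "v_ss": c.v_ss, "v_jsr": c.v_jsr,
        "v_nsr": c.v_nsr, "beta_sr": c.beta_sr, "b_tot": c.b_tot,
        "b_kd": c.b_kd, "d_ca": c.d_ca, "tau_ss": c.tau_ss, "v_up": c.v_up,
        "k_up": c.k_up, "g_leak": c.g_leak, "j_bg": c.j_bg,
        "cal_ss_frac": c.cal_ss_frac, "c_rest": c.c_rest,
        "g_na": m.g_na, "g_cal": m.g_cal, "e_cal": m.e_cal, "k_fca": m.k_fca,
        "g_kr": m.g_kr, "g_ks": m.g_ks, "g_to": m.g_to, "g_k1": m.g_k1,
        "g_nak": m.g_nak, "g_ncx": m.g_ncx, "ncx_sub_frac": m.ncx_sub_frac,
        "e_na": m.e_na, "e_k": m.e_k,
        "na_i": m.na_i, "na_o": m.na_o, "ca_o": m.ca_o, "km_na": m.km_na,
        "km_ca": m.km_ca, "eta": m.eta, "k_sat": m.k_sat, "cm": m.cm,
        "current_to_flux": m.current_to_flux, "stim_amp": m.stim_amp,
        "stim_dur": m.stim_dur,
        "dt": s.dt, "cru_substep": s.cru_substep,
        "sarco_on": 1.0 if s.sarcolemmal_on else 0.0,
    }
    return np.array([vals[n] for n in _PNAMES], dtype=np.float64)
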