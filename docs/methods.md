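# Methods

## Model

### Geometry and state

The cell is a 100 µm chain of `n_cru = 50` calcium release units at 2 µm
pitch — the pitch of junctional couplons along a myocyte — each with a
dyadic subspace (volume fraction 0.001/50 of cytosol) and a junctional SR
(JSR) compartment (0.010/50), all refilled from one network SR (NSR,
0.050). The cytosol is one compartment per CRU with nearest-neighbour
diffusion of free Ca²⁺ (D_eff = 0.30 µm²/ms). A single rapid cytosolic
buffer (B_tot = 120 µM, K_d = 0.7 µM) is handled by storing *total* Ca
per compartment and inverting the binding quadratic each step, so every
flux moves a conserved amount: with sarcolemmal fluxes disabled, total
cell Ca is constant to rounding (the 1 ppm / 10 s conservation test).
SR buffering (calsequestrin) is linearised as a constant factor
β_SR = 15 on free SR Ca.

`total_sr_load` reports volume-weighted JSR + NSR Ca **including the
calsequestrin-bound fraction**, per litre of cytosol — the quantity a
caffeine-dump/NCX-integral assay measures, and the convention that makes
a ~900 µmol/L load compatible with ~1 mM free SR Ca at these volume
fractions.

### Release and refractoriness

A closed CRU opens as a Bernoulli draw with probability 1 − exp(−λ·dt)
from the cluster trigger rate

λ(c_ss, R) = λ₀ · c_ssʰ / (c_ssʰ + (K_half/k_sens)ʰ) · R^γ

with h = 2 and γ = 10. While open it releases J = J_max·(c_JSR/1000 µM)
into its subspace and closes stochastically (mean open time 9 ms); JSR
depletion terminates large releases naturally. On closure the recovery
variable resets to 0 and relaxes to 1 with time constant k_refr·τ_R
(τ_R = 65 ms); the JSR refills from the NSR with k_refr·τ_refill
(τ_refill = 90 ms, matching the ~90 ms spark amplitude-recovery time
constant the pair analysis fits). The large exponent γ makes R^γ an
effectively sigmoidal recovery gate — sites are near-silent for roughly
2.5·k_refr·τ_R and then regain excitability quickly — which is what
separates evoked release from a discrete late-spark phase. Each site's
τ_R carries a fixed lognormal spread (σ = 0.2) representing couplon-size
variability; without it the lattice re-fires in synchronized waves that
no real cell shows.

The CPVT configuration differs from control **only** in k_sens = 2.25
(trigger half-point lowered ~2×) and k_refr = 0.65.

### Membrane

Hodgkin–Huxley-style rabbit-like formulation (LR-family gate kinetics)
with I_Na, I_CaL, I_NCX, I_Kr, I_Ks, I_to (with a 30 % sustained
component playing the role of the steady-state K⁺ current), I_K1, I_NaK
and stimulus. Two couplings matter for the science:

* **Ca-dependent inactivation of I_CaL is per-dyad**: each CRU's share of
  the L-type current is gated by its own subspace Ca (pedestal 0.3), so
  LCCs over released dyads inactivate while those over quiescent dyads
  keep conducting — late I_Ca persists where release has failed.
* **I_NCX is computed per release site** from a submembrane Ca equal to
  the local cytosolic Ca plus a small dyadic admixture
  (ncx_sub_frac = 0.002). This is the spark → inward-current coupling:
  every late spark transiently drives its local exchanger inward.

Conductances were refit to the printed density anchors at 50 %
repolarization rather than copied from any published parameter set; the
mouse-like (large I_to, short triangular AP) and human-like (plateau)
variants are qualitative morphology overlays only.

Integration: forward Euler for concentrations and voltage at dt = 0.01 ms
with Rush–Larsen gate updates; CRU gating is evaluated every 5th step
(0.05 ms). Halving dt changes the steady-state observables by well under
the seed-to-seed spread. Each CRU owns a SplitMix64 counter stream
derived from the master seed, so runs are bit-reproducible and per-CRU
streams are independent.

## Calibration

The free parameters (λ₀, K_half, J_max, τ_refill baseline, the ISO
overlay scalings, NCX/NaK/K-conductance scales, and the CPVT k_refr)
were fitted once against the four steady-state anchors — control/CPVT
late-spark rate ≈ 8.9 / 43.9 per s per 100 µm and SR load ≈ 896 /
636 µmol/L at 1 Hz with the ISO overlay — plus the current-budget
anchors at 50 % repolarization (I_NCX ≈ −0.14 pA/pF, I_Ks+I_Kr ≈ 0.50,
outward excess ≈ 0.33 in control). The result is frozen in
`src/crusparks/configs/calibration.yaml`; `crusparks.calibrate.calibrate`
re-runs the Nelder–Mead fit for users who change the model. All
spark-rate calibration went through the *full* pipeline (render → filter
→ detect → classify), never the raw event log, so detection losses are
part of the calibrated operating point.

Achieved at the frozen point (3-seed means): control 10–11 LCS/s/100 µm
at load ~950 with outward excess ~0.30; CPVT 28–31 LCS/s/100 µm at load
~640 with APD90 ~8–15 ms longer than control. The CPVT spark rate
saturates near −30 % of its target: the opening log shows the expected
~5× re-opening ratio, but in a 1-D 50-site scan the dense CPVT release
phase cannot be fully separated into individual detections (see
Limitations).

## Measurement conventions

* **LCS window**: events after the evoked transient peak are LCS until
  the cell-average fluorescence returns to within 10 % of the resting
  level; later events are diastolic. (The alternative 90 %-recovery
  upper bound is available as `classify_events(boundary="t90")`.) The
  transient peak is the first local maximum reaching ≥85 % of the beat
  maximum, so late release riding on the decay cannot drag the peak
  outward.
* **LCS frequency** is counts per second of analysed scan per 100 µm of
  line.
* **Pair intervals**: successive events within 2 µm (one CRU pitch,
  inclusive) are same-site pairs. For the voltage-clamp hold statistics
  the pairs are taken from the CRU opening log; image-domain detection
  misses closely spaced second sparks in long hold recordings and biases
  the median up roughly two-fold.
* **Current budget**: densities are read at the 50 %-repolarization
  crossing of each measured beat and averaged across beats and seeds
  (a single crossing is at the mercy of whichever spark is active).
* **EADs**: a depolarizing run (dV/dt > 0.05 mV/ms for ≥2 ms) inside the
  10–90 % repolarization window *that starts below 30 % repolarization*
  — the extra clause excludes the physiological notch-and-dome.

## Synthetic data

`synth_sparks` fabricates scans with known ground truth: baseline
F/F₀ = 1, an instant-rise/exponential-decay evoked transient, sparks
with specified amplitude, spatial FWHM (Gaussian) and temporal FDHM
(rise-and-decay kernel solved to match), PSF blurring, additive Gaussian
noise, and optional same-site pair mode whose second-spark amplitudes
follow 1 − exp(−Δt/τ_rec). It emulates the morphology of confocal spark
recordings but none of their optical pathologies (bleaching, motion, dye
compartmentalisation); detector validation on it therefore demonstrates
algorithmic correctness, not robustness to real-rig artefacts.
`synth_beat` does the analogue for single ECG beats (schematic QRS,
half-Gaussian T upstroke, exponential tail, Gaussian U-wave).

## Problem sizes

Unit tests run seconds-long simulations; acceptance-level measurements
use 20 equilibration + 8 measured beats at 1 Hz per seed (the SR load
settles to <0.5 %/beat drift well within 20 beats when started near the
genotype's steady load), 10 s voltage-clamp holds, and 2–10 seeds per
quantity. The acceptance script uses 10 seeds per genotype.

## Known limitations

* The 1-D, 50-site reduction compresses the dynamic range of the
  CPVT phenotype: detected CPVT LCS rates plateau ~30 % below the
  3-D model's value because dense release merges optically, and the
  CPVT−control APD gap (~10 ms) is smaller than in the full model, so
  pace–pause EADs do not occur at the frozen calibration without
  pushing the control current budget off its anchors.
* At the −40 mV hold the lattice fires densely enough that radius-2 µm
  pair statistics mix neighbour-site intervals with true same-site
  refractoriness; the CPVT pooled median lands near 50 ms rather than
  ~90 ms.
* Release restitution is anchored to the ~90 ms pair-recovery constant,
  so premature (S1S2) transients are barely attenuated — the slow
  component of SR refilling that suppresses premature transients in
  real cells is not represented.
* One global Na⁺ concentration, no mitochondria, no β-adrenergic
  signalling dynamics (ISO is a static overlay), and no tissue coupling.
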