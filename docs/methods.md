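# Methods

This note documents the models implemented in `excitep`, the choices made
where the underlying science left the design open, and what the synthetic
data do and do not establish.

## The biological system

The package models genetically engineered "spiking" HEK cells (S-HEK): a
HEK-293-derived line expressing exactly two channels, the cardiac fast
sodium channel NaV1.5 and the inward-rectifier potassium channel Kir2.1,
which together make the cells excitable (resting voltage near −70 mV,
all-or-none action potentials). The non-excitable counterpart (NS-HEK)
lacks Kir2.1. Monolayers of these cells are exposed to single 100 µs
rectangular pulses of 40–400 V/cm between two parallel wire electrodes
(0.8 mm diameter, 5 mm between inner edges), a regime in which both
electrostimulation and membrane electroporation occur. Optical readouts are
a potentiometric dye (ElectroFluor630, 80 frames at 36 ms, pulse after the
10th frame) whose relative fluorescence decrease is proportional to
depolarization, and Fura-2 340/380 ratiometric calcium imaging (40 frames
at 1 s, pulse near 5 s).

## Membrane patch model (`membrane`, `gating`)

Current balance per unit membrane area:

C_m dU/dt = −J_Na − J_K − J_L − g_ep·U + J_drive,

with J_Na = g_Na·m³hj·(U−E_Na), J_K = g_K·n∞(U)·(U−E_K),
J_L = g_L·(U−E_L); gates obey dy/dt = (y∞(U)−y)/τ_y(U).

* **Conductances** g_Na = 27.5, g_K = 0.5, g_L = 0.05 S/m²; C_m = 0.01 F/m²
  (all per unit area).
* **Gating functions.** The published formulation used by the original
  S-HEK models is not reproducible from the available text, so the gating
  model is pluggable. The default uses the Luo–Rudy phase-1 fast-sodium
  m³hj rate functions — the standard cardiac NaV description — slowed by a
  factor 3 (Q10 ≈ 3 between the 37 °C formulation and room temperature,
  where the experiments are performed). Kir2.1 rectification is a Boltzmann
  open fraction n∞(U) = 1/(1+exp((U−V_h)/k)) with V_h = −60 mV, k = 8 mV:
  nearly open at rest, shutting steeply with depolarization. The steep
  negative-slope region of the Kir current just above rest is what makes
  these cells easily excitable.
* **Reversal potentials.** E_Na = +65 mV (Nernst for the low-K⁺ Tyrode
  bath, [Na]ᵢ ≈ 10 mM), E_K = −75 mV (an effective value: the pure Nernst
  potential for 0.5 mM external K⁺ is far more negative, but Kir
  conductance collapses at such low external K⁺; the effective reversal is
  set so the resting voltage lands at the measured −70 mV), and E_L solved
  at import time so that the steady current balance is zero exactly at
  −70 mV (≈ −31 mV with the defaults). All overridable in config.
* **Resting state** is found by scanning the steady-state current balance
  for sign changes and keeping the most negative stable root (positive
  slope of outward current).
* **Electroporation conductance.** During the pulse
  g_ep = α(exp(β|U|)−1); after the pulse it is frozen at its end-of-pulse
  value, or decays as exp(−(t−t_end)/τ_r) when resealing is enabled
  (τ_r = 2 s). The post-pulse clock starts at the pulse end so g_ep is
  continuous there. α and β are the model's fitted parameters (no published
  values); the defaults α = 5×10⁻⁶ S/m², β = 40 V⁻¹ satisfy the constraint
  that g_ep ≈ 0.1–1 S/m² at |U| ≈ 0.3 V (α e^12 ≈ 0.8 S/m²) and, with the
  default gating model, reproduce the connected/non-connected array
  excitation thresholds (below). g_ep is capped at 10⁴ S/m² and the gating
  rate functions clamp their argument to ±150 mV, purely as numerical
  safeguards at the extreme voltages reached inside a pulse.
* **Integration** is adaptive (LSODA) with a fixed output grid, split at
  the pulse edges and at caller-declared drive discontinuities so the
  stiff solver cannot step over a 100 µs event. Simulations abort if |U|
  exceeds 1.5 V — polarization of strongly coupled arrays legitimately
  approaches 1 V at the highest fields, so the classical 1 V sanity bound
  is relaxed by 50%.

With these defaults a 2 ms, 0.15 A/m² current pulse elicits a single AP
overshooting 0 mV with ≈ 0.4 s to 50% recovery and t90/t50 ≈ 1.7,
consistent with the optical single-AP classification rule.

## Neuron circuit (`neuron`)

The classic squid-axon Hodgkin–Huxley model in SI per-area units
(g_Na = 1200, g_K = 360, g_L = 3 S/m²) with one added branch: a fixed
nonselective shunt g_ep with 0 mV reversal. A brief suprathreshold current
pulse is applied from the normal resting state with the shunt present from
t = 0. As g_ep grows the response progresses from one AP (the shunt is
negligible), through repetitive firing (the shunt acts as a steady
depolarizing current in the HH repetitive-firing window), to sustained
depolarization (excitation block). The first class change occurs near
g_ep ≈ 10 S/m², far below the channel conductances. Traces are classified
with the same four-class rule as experimental data, on a 0.5 ms grid
(HH APs are milliseconds wide).

## Cell-array model (`cell_array`)

A reduced-order equivalent-circuit network replaces the original 3D
finite-element array of 10×10 hemispherical cells (R = 9 µm, centre
spacing 1.9 R, ~10% of membrane area in contacts):

* one intracellular node per cell (cytoplasmic resistance is negligible on
  ~20 µm scales);
* one extracellular node per cell-row boundary plane along the field axis,
  consecutive planes joined by slab resistors σ_e·A/d (σ_e = 1.432 S/m,
  bath cross-section = array width × 100 µm bath height). The outer planes
  are pinned to the electrode potentials (anode E·L, cathode 0) during the
  smoothed 100 µs pulse. Medium charging times are well below a
  microsecond, so the medium's dielectric response is omitted (quasi-static
  network);
* two membrane patches per cell (anodic/cathodic halves of the free
  membrane) carrying the full patch current balance, each with its own
  gates and g_ep(|U_patch|);
* cell–cell contacts contribute the series capacitance C_m/2 always, and
  the junctional conductance g_Cxn only in the connected variant.

An isolated cell in this topology polarizes by ±E·pitch/2 ≈ ±0.95·E·R at
full charge — within ~25% of the Schwan patch-average 0.75·E·R for a
hemisphere, which is the accuracy expected of a two-patch lumping. The
area-averaged U over all free patches is the model counterpart of the
whole-field optical signal; it is normalized as
R = 0.05·(U−U_rest)/90 mV so the experimental classification thresholds
apply unchanged.

**Calibration.** The junctional specific conductance is not published;
g_Cxn = 2000 S/m² was calibrated once so that the connected array first
fires at 100 V/cm in the standard sweep
{40, 66, 100, 126, 150, 176, 200, 250, 300, 350, 400} V/cm. Electroporation
is part of the default model (the experiments are in the electroporation
regime; without it the non-connected array shows no response at any field,
because a 100 µs pulse leaves only millivolts of net asymmetric charge on a
Schwan-symmetric isolated cell).

**Firing detection.** Two criteria are reported per sweep: the four-class
trace rule (an AP is a single-AP or multiple-AP class), and an "upstroke"
criterion — the averaged voltage crosses −20 mV after the pulse, i.e. the
trace contains a full regenerative sodium upstroke. The two agree for the
connected array (first AP at 100 V/cm, single-AP class). For the
non-connected array the electroporation shunt that enables firing also
holds the membrane depolarized afterwards, so at 250 V/cm every cell fires
a full upstroke (−70 → +3 mV) but the averaged trace is, as in the
experiments at these fields, a sustained depolarization; the upstroke
criterion registers the AP (first at 250 V/cm) while the class-based
criterion does not. Both readouts are returned by `threshold_sweep`.

## Monolayer monodomain model (`monolayer`)

Two stages. First, the 2D Laplace equation is solved by finite differences
over the well footprint with the two wire cross-sections at fixed
potential and insulating walls; the resulting |∇V| is normalized by the
nominal field U/d. Between the long parallel strips the field is uniform
within ~1%; it is enhanced (~1.3×) adjacent to the wires, most strongly at
their ends. The monolayer lies at the well bottom, so a depth-averaged 2D
solve replaces the 3D problem.

Second, the monodomain reaction–diffusion equation

C_m dU/dt = G_Cxn ∇²U − J_Na − J_K − J_L − G_ep·U − J_stim

is integrated by operator splitting: backward-Euler diffusion (sparse
factorization, zero-flux boundaries) on a 0.5 ms macro step, explicit
reaction substeps of 25 µs with exponential (Rush–Larsen) gate updates.
The field-driven source terms are derived from the induced-voltage
solution of an isolated spherical cell: J_stim contains a capacitive
spike with the sub-microsecond charging time
τ_chg = R C_m (σᵢ+2σₑ)/(2σᵢσₑ) ≈ 0.21 µs, which is integrated in closed
form per substep (sampling a 0.2 µs transient at 25 µs steps would be
meaningless); G_ep = α((e^u−1)/u − 1) with u = 1.5 R E β persists after
the pulse (or decays with τ_r when resealing is enabled). The smoothing
width of the pulse window (1 µs) is irrelevant at the 100 µs scale.

G_Cxn = g_Cxn(2R)² with g_Cxn = 60 S/m², calibrated once so the simulated
propagation velocity matches the experimentally estimated 34 mm/s (the
model gives ≈ 36 mm/s); this effective monolayer coupling is deliberately
independent of the array model's g_Cxn, which is calibrated against a
different observable. The default grid step is 0.2 mm (four nodes across a
wire); the region of interest is a 0.33 mm square at the inter-electrode
midpoint, matching the imaged field of view. Activation times are recorded
at macro-step resolution as the first crossing of −20 mV; conduction
velocity is the slope of distance vs activation time along the
electrode-to-midline axis.

In this model the midline fires directly for nominal fields above
≈ 44 V/cm (the stimulus kick (3/8)·R·E crosses the excitation basin), with
an intrinsic latency that shrinks from ~12 ms near threshold to below a
millisecond at 150 V/cm; below threshold the wave initiated at the wire
ends (field enhancement) propagates inward at ~36 mm/s. Sustained
depolarization between the electrodes requires ≈ 300 V/cm, higher than in
the cell array, because G_ep derives from the isolated-cell induced
voltage, which is smaller than the edge-cell voltage of a connected array.

## Optical-voltage pipeline (`trace_analysis`)

Photobleaching is corrected with a linear fade fitted to the no-pulse
control; the baseline F₀(t) = k·t + F_intercept is anchored so it passes
through the mean of the 10 pre-pulse frames at the centre of that window
(this keeps the pre-pulse response exactly zero-mean for a purely fading
trace; anchoring at t = 0 instead would bias R by k·t/F ≈ the size of the
onset threshold). The response is R = 1 − F/F₀.

Peaks: the response is smoothed with a centred 3-frame boxcar — the
deterministic replacement for the visual curation used in the original
analysis — and local maxima with prominence above 0.02 (the printed AP
amplitude criterion) are AP peaks; the printed onset threshold 0.008
governs the fallback for monotone depolarizations, which additionally
requires three consecutive supra-threshold frames. Recovery times are the
first frames at which R has dropped by 25/50/90% from the maximum
response, measured from the first peak, and are "not reached" beyond the
2.5 s observation window. Classes: 0 peaks → no response; ≥2 peaks →
multiple APs; a single peak with amplitude > 0.02, t50 < 700 ms and
t90/t50 < 2 → single AP; any other single peak → sustained depolarization.
Negative R (hyperpolarization) is retained but ignored by the peak logic.

The pipeline is invariant to overall intensity scaling and to adding a
common linear fading trend to trace and control (both tested).

## Calcium pipeline (`fura2`)

Ratio traces are shifted so the first sample is zero; peaks are local
maxima of the lightly smoothed trace with prominence above 10% of the
trace range (the 5% suggested by a first reading sits below the noise
floor at the package's own SNR-10 validation condition; both the fraction
and the smoothing are configurable, and amplitudes are always read from
the raw trace). If no local maximum exists, a sigmoid-plateau fallback
looks for the first +→− (or exact zero) crossing of the central-difference
time derivative and assigns one peak at the earliest sample reaching 95%
of the value at that crossing. Slow linear baseline drift is deliberately
not detrended, mirroring the original analysis; drift robustness comes
from the prominence threshold.

## Synthetic data (`synthetic`)

The generator emulates the acquisitions frame-for-frame: 80×36 ms voltage
frames with pulse after the 10th, multiplicative response templates on a
linear photobleaching baseline, additive Gaussian noise; 40×1 s Fura-2
frames with slow drift and 0/1/2-peak or plateau morphologies (the second
calcium peak larger and delayed, as observed in excitable cells). The
single-AP template rises with τ = 20 ms and repolarizes logistically
(half-recovery 0.35 s, width 60 ms), matching the simulated patch AP; a
pure exponential decay would have t90/t50 = ln 10/ln 2 ≈ 3.3 and could
never satisfy the printed single-AP rule, so template shape is not a free
choice. The sustained template decays with τ = 5 s, far beyond the 2.5 s
window. Ground-truth parameters are computed from the continuous templates
on a dense 1 ms grid, independently of the analysis pipeline. Pseudo-
experiments draw a class per (replicate, field) from a qualitative
monotone probability schedule (multiple APs commonest at low fields,
sustained depolarization dominating from 250 V/cm); all randomness flows
through one seeded generator and a fixed seed reproduces traces
bit-identically.

What passing synthetic tests show: the pipelines recover known truth
through the full acquisition model (fading, frame quantization, noise) at
realistic SNR. What they do not show: robustness to motion, uneven
staining, photobleaching nonlinearity, or cell-to-cell heterogeneity,
none of which the generator emulates.

## Problem sizes and tolerances

Under the uniform applied field every column of the 10×10 array is
identical — the extracellular plane nodes are shared across columns and
the lateral junction currents vanish by symmetry — so the full-array
averaged solution is computed exactly on a single 10-cell column (verified
numerically to sub-µV agreement against multi-column networks). The test
suite runs the array model at reduced sweeps (two fields per variant
bracketing each threshold) and the monolayer at three fields for 1.2 s;
`scripts/acceptance.py` reproduces the full 11-field sweeps for both array
variants on the symmetry-reduced chain (a few minutes total). Patch and neuron integrations use rtol 10⁻⁷; the
array uses rtol 10⁻⁶. The patch/PDE equivalence check holds to 0.1 mV on
subthreshold trajectories (near-threshold trajectories amplify any
integrator difference exponentially and are not a meaningful consistency
metric).

## Known limitations

* Intracellular ion concentrations are fixed; spontaneous or repetitive
  firing of S-HEK monolayers that depends on concentration dynamics or on
  endogenous channels is outside the model, so the experimentally observed
  multiple-AP responses of the monolayer are not reproduced by the array or
  monolayer models (the neuron circuit reproduces the phenomenon
  generically).
* The two-patch lumping cannot resolve the cosine polarization profile of
  a hemisphere; per-face averages are accurate to ~25%, and a finer
  angular discretization is degenerate in the plane-node topology (it
  would require a continuum extracellular description).
* The four-class trace rule applied to non-connected electroporated
  arrays labels the overall morphology (sustained depolarization) even
  when every cell fired an AP upstroke; both readouts are reported.
* Gap-junction conductance is time- and voltage-independent.
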