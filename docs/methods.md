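# Methods

`nram` implements an ionic model of the cultured neonatal rat atrial
cardiomyocyte (NRAM) carrying a constitutively active acetylcholine-mediated
K⁺ current, and a 2D monodomain monolayer built from it. This note records
the model equations' provenance, the meaning and defaults of the tunable
parameters, the numerical choices, what the synthetic-data generators
emulate, and the known limitations.

## The single-cell model

The membrane obeys

    dV/dt = (−I_ion + I_stim) / C_m,
    I_ion = I_Na + I_CaL + I̅_K1 + I_to + I_CaT + I_Cab + I_NCX + I_NaK
            + I_f + I_Nab + I_Ksus + I_KACh,

with all current densities in pA/pF (C_m = 1 µF/cm² makes pA/pF and µA/cm²
numerically identical). Outward current is positive; a positive stimulus
depolarizes. Intracellular Na⁺ and K⁺ are constant in time (8 mM and
140 mM, the pipette-solution values); extracellular Na⁺/K⁺/Ca²⁺ are
140/5.4/1.8 mM and the temperature is 295 K (room temperature), giving
E_K ≈ −82.8 mV and E_Na ≈ +72.8 mV.

Current formulations:

- **I_Na** — Beeler–Reuter-type m³hj scheme. The activation and
  inactivation steady states are logistic fits to neonatal rat atrial
  data (midpoints −44 mV and −64 mV); h∞ and j∞ share one curve. Time
  constants use the Luo–Rudy rate functions with a named scale
  `k_temp_na`; the slow-inactivation (j) recovery runs at twice the
  Luo–Rudy rate (see "Conduction velocity vs upstroke velocity" below).
- **I_CaL** — Goldman–Hodgkin–Katz driving force (Ca²⁺ permeability only,
  the 0.341 activity factor on [Ca]_o), gates d, f and a Ca-dependent
  gate f_Ca with half-inhibition at 0.75 µM. The activation time constant
  carries the documented +10 ms correction (`tau_d_shift`). The removable
  GHK singularity at V = 0 is evaluated analytically for |V| < 10⁻⁶ mV.
- **I_CaT** — Dokos-type b·g kinetics with the printed +106.5 mV shifted
  driving force G_CaT·b·g·(V − E_Ca + 106.5).
- **I_to** — Pandit rat-ventricle kinetics with the printed fast/slow
  inactivation weights: G_to·r·(0.706 s + 0.294 s_slow)(V − E_K).
- **I_Ksus = 0.16·(I_Kur + I_Kr + I_Ks)** — ultra-rapid component with
  Bondarenko kinetics; rapid and slow delayed rectifiers with
  two-exponential activation gates. The 0.16 scale is the model-defining
  constant `k_ksus`.
- **I̅_K1** — the printed composite inward rectifier plus K⁺ leak:
  0.048925·(K_o/(K_o+210))·(V−E_K−10)/(1+e^{0.041(V−E_K−10)}) +
  0.01·(V−E_K). The prefactor already contains the 47.5 %-of-ventricle
  adjustment; the +10 mV reversal shift is applied exactly as printed in
  all three K⁺ laws that carry it (I̅_K1, I_KACh, I_KACh-c).
- **I_KACh** (single-cell mode) — dose-dependent law
  (3.5/(1+9.13652/[ACh]^0.477811))·(0.04+0.23/(1+e^{(V+102)/10}))·(V−E_K−10)
  with [ACh] = 1 µM by default; the carbachol intervention sets a
  saturating dose. **I_KACh-c** (tissue mode) — the agonist-independent
  form 0.37488·(0.075+0.35/(1+e^{(V+102)/10}))·(V−E_K−10). A common scale
  `g_kach` multiplies both. Tertiapin-Q is modelled as block fraction 1.0
  of this current; arbitrary partial blocks are supported per current.
- **I_f** — Korhonen-type y gate with a 0.2/0.8 Na⁺/K⁺ conductance split;
  small (its removal moves the resting potential by < 1 mV).
- **I_NaK** — Luo–Rudy pump (σ-factor voltage dependence, K_m,Nai = 10 mM,
  K_m,Ko = 1.5 mM); **I_NCX** — Pandit-form exchanger (γ = 0.5, saturation
  factor 10⁻⁴); **I_Nab, I_Cab** — linear backgrounds whose conductances
  set the resting potential.

## Ca²⁺ subsystem

Two SR compartments (uptake/NSR and release/JSR, the JSR being 10 % of
total SR volume; V_NSR/V_cyto = 0.03), a reversible Shannon-type SERCA
(K_mf = 0.25 µM, K_mr = 1.7 mM, Hill 1.787), an NSR→JSR transfer flux with
τ_tr = 8 ms, a linear NSR→cytosol leak, and a four-state (R/O/I/RI)
ryanodine-receptor scheme with luminal regulation (EC50 0.45 mM,
Max/Min_SR 15/1). Cytosolic Ca²⁺ is buffered by troponin (35 µM,
K_d 0.5 µM) and calmodulin (50 µM, K_d 2.38 µM), JSR Ca²⁺ by calsequestrin
(24 mM, K_d 0.63 mM). Buffers are integrated as explicit mass-action ODEs
rather than the rapid-buffer approximation: the flux network is then
antisymmetric and forward Euler conserves total cell Ca exactly (to float
rounding), which the test suite checks over 1000 steps with membrane Ca
transport disabled.

Because the model has no spatial cytosol or diffusive subspace, RyR
opening is triggered by a local-Ca proxy

    Ca_trig = Ca_i + k_local · max(0, −(I_CaL + I_CaT)),   k_local = 0.02 mM/(pA/pF)

which represents the Ca²⁺ concentration near the release sites during
sarcolemmal influx (peak trigger ≈ 30–60 µM, diastolic ≈ 0.2 µM). This is
a standard common-pool surrogate for a subspace compartment and is the
main structural simplification of the Ca²⁺ subsystem.

Membrane flux conversion uses `ca_conv` = 5·10⁻⁵ mM/ms per pA/pF of
Ca-carrying current (capacitance-to-volume ratio of a small neonatal
cell).

One point where this reconstruction deviates from a printed idealization:
the Shannon SERCA is reversible, so at zero cytosolic Ca²⁺ the pump flux
is a small *backward* term rather than exactly zero; the test asserts
"no forward uptake without substrate" (J_up ≤ 0) instead of J_up = 0.

## Calibration

The exact source-model constants live in a supplement that is not part of
this package's inputs, so free magnitudes were calibrated the same way the
model itself was built: G_Na and the Na⁺ kinetics to the upstroke and the
planar conduction velocity; G_CaL, the K⁺ conductances and I_KACh scale to
the AP shape (APD50/APD80) in all three operating modes; backgrounds to
the resting potential; SR flux rates to the published Ca²⁺ summary. The
resulting defaults (in `params.py` and the bundled
`data/paper_default.yaml`) reproduce, at 1 Hz: RMP −73.4 mV (target
−72.0), amplitude 133.3 mV (132.74), APD50 25.3 ms (27.0), APD80 58.7 ms
(58.0), mean [Ca]_i 0.40 µM (~0.36), NSR/JSR 880/790 µM (~775/715), planar
CV 22.8 cm/s (22.2), full-block APD80 ratio 2.7 ("near-tripling"), and a
minimum 1:1-capture cycle length of 145 ms after full block (125 ms
reported). All of these are recomputed by `scripts/acceptance.py` and by
the acceptance tests; none is hard-coded anywhere.

### Conduction velocity vs upstroke velocity

With the published numerics (D = 1.2·10⁻⁴ cm²/ms, δx = 0.00625 cm,
δt = 0.02 ms) a planar CV of 22.2 cm/s requires a Na⁺ front of roughly
body-temperature Luo–Rudy speed. Any parameterization that also pinned the
single-cell instantaneous dV/dt_max at 114 mV/ms (slowed kinetics,
fast-truncated inactivation, shallow activation) either capped CV near
15–17 cm/s or created a depolarized second resting state. The package
therefore prioritizes the conduction velocity; the instantaneous upstroke
velocity of the default model is ≈ 360 mV/ms, and the corresponding clause
of the single-cell acceptance test fails by design and documents this.
A dV/dt_max of ~114 mV/ms is recovered if the upstroke is differentiated
at millisecond sampling (as in optical-mapping-style traces), but the
package reports the honest instantaneous value.

The j-gate recovery runs at twice the Luo–Rudy rate so that post-AP
excitability recovers on the ~30 ms scale that the blocked-capture
experiment implies; the I_Kr reconstruction deactivates slowly below
−50 mV, supplying the terminal-repolarization current that the printed
composite rectifier (whose prefactor is only ~0.0012 nS/pF) cannot.

## Numerics

Forward Euler for V, Ca²⁺, buffers and RyR states at δt = 0.02 ms;
Hodgkin–Huxley gates use Rush–Larsen exponential updates by default
(unconditionally within bounds) with a pure-Euler switch
(`rush_larsen=False`, gates clamped to [0, 1]) for fidelity comparison —
the two agree to within 1 ms of APD80 at the operating step. δt-refinement
to 0.005 ms moves APD80 by < 1 % (amplitude by < 2 %, the capture error of
a very steep upstroke). Space: 5-point Laplacian, δx = 0.00625 cm, Neumann
(mirror) boundaries on the domain mask — the masked sum of the diffusion
term is identically zero (discrete divergence theorem), tested to machine
precision. δt = 0.02 ms satisfies the diffusion stability bound
δx²/4D ≈ 0.081 ms with a 4× margin; the solver refuses a δt above the
bound. Halving δx changes the measured CV by ~3 %, the discretization
error of the scheme at these settings.

Uniform tissue with a whole-domain stimulus reproduces the single-cell
trajectory exactly (the diffusion term vanishes identically), which pins
the tissue kernel to the cell kernel bit-for-bit in the tests.

## Monolayer construction

A 15.6 mm disc inscribed in a 256×256 lattice (smaller discs scale the
same geometry in tests and examples). Exactly round(fraction·N) nodes are
fibroblasts, placed uniformly at random; myofibroblasts are MacCannell-type
passive RC elements (g_fb = 0.03 nS/pF, E_fb = −49.6 mV) coupled to their
adjacent myocyte nodes through G_gap = 0.5 nS/pF split equally among them,
normalized per pF on both sides; they do not enter the diffusion operator
(a no-coupling switch turns them into inexcitable obstacles). Intercellular
variability draws, per myocyte, 19 independent uniform multipliers on
[X₁/100, X₂/100] — one per maximal conductance/flux; the enumerated list
(`constants.MULT_FIELDS`) covers the 13 sarcolemmal conductance scales,
the pump/exchanger maxima and the four SR flux rates. All randomness flows
through a single seeded generator; the same seed rebuilds the grid
bit-for-bit.

QC of a paced monolayer follows the culture-acceptance rule: reject if the
interior APD80 spread (after eroding a 2-node boundary margin) exceeds
20 ms, or if a contiguous region (≥ 9 nodes) deviates from the map median
by more than 10 ms ("non-uniform APD distribution" — the threshold is
configurable since the original rule is qualitative).

## Analysis conventions

- AP metrics: RMP is the pre-stimulus potential; amplitude is peak − RMP;
  APD_x runs from the instant of maximal dV/dt to the crossing of
  peak − x %·amplitude on the downstroke, making the duration independent
  of stimulus shape.
- Activation maps: first rising crossing of −20 mV, linearly interpolated
  between frames; CV by regression of transversely averaged activation
  time on distance, excluding stimulus/boundary margins.
- Dynamic restitution: descending cycle-length staircase with state
  carry-over, 20 conditioning beats per level by default (configurable —
  the original count is not stated); capture requires one far-field
  upstroke per stimulus over the final five.
- 1:1 capture in tissue: one propagated activation (far-field probe
  crossing −20 mV) per stimulus for the final five stimuli; the capture
  scan restarts from rest at each cycle length and stops at first failure.
- S1–S2: the S2 fires automatically when the repolarization back of the
  S1 wave (median mid-column V falling through −60 mV after excitation)
  crosses half the domain; the upper 37 % of rows (162/256) receives S2.
- Spiral tips: intersection of the V = −30 mV isoline with the dV/dt = 0
  contour (isoline-intersection method), linked across frames by nearest
  neighbour with a gap tolerance; a phase-free, parameter-light choice
  appropriate for noise-free simulation data. Core size is the maximum
  pairwise extent of the trajectory.
- Dominant period: Hann-windowed power spectrum of the detrended trace
  (≥ 1 s window), reported with the spectral resolution. Wavelength is
  CV × APD80.
- Termination: no node crosses −20 mV for 500 ms after the last stimulus.

## Synthetic data

The fixture generators produce: rigid Archimedean-rotor movies (known
period, known singularity location, optional circular meander of known
radius), plane-wave movies of known speed, piecewise-linear AP traces
whose metrics follow from their construction, and APD maps with designed
gradients/steps. They emulate the *geometry* of recordings, not their
physiology: no optical-mapping blur, photon noise, motion artifact, or
fractionated electrograms. Tests passing on them demonstrate the
estimators' correctness on clean fields, not robustness to experimental
noise.

## Problem sizes used in tests and the acceptance script

Single-cell runs use 12–20 beats at 1 Hz; CV uses a 256×2-node strip (16 mm)
with probes ≥ 30 nodes from stimulus and boundary; the blocked-capture scan
uses a 128×2 strip and a 5 ms cycle-length grid from 170 ms downward; the
heterogeneity/QC check uses a 48×48 disc (3 mm) — chosen as the smallest
domains on which the respective quantities are scale-converged (CV changes
< 1 % on longer strips; the capture cycle length is set by refractoriness,
not domain size). Full 256×256 spiral experiments (S1–S2, burst-pacing
induction/termination) are supported by the same code paths and run in the
tens of minutes each; the `examples/spiral_s1s2.py` demo uses a 128×128
domain on which reentry is only marginally sustainable because the
wavelength (~0.9 cm) is comparable to the domain size.

## Known limitations

- No spatial cytosolic Ca²⁺ model; the local-trigger proxy reproduces
  common-pool CICR, not wave-like subcellular release.
- Temperature enters only through the named Na⁺ time-constant scale and
  the fitted conductances; there is no general Q₁₀ model.
- The printed dV/dt_max and CV could not be reconciled (see above).
- Intracellular Na⁺/K⁺ are fixed, so very long pacing protocols cannot
  show slow ionic drift.
- Myofibroblasts are passive; no active fibroblast variant, no
  anisotropy, no bidomain effects.
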