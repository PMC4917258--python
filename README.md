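# nram — neonatal rat atrial myocyte and monolayer electrophysiology

Primary cultures of neonatal rat atrial cardiomyocytes (NRAMs) are a
standard substrate for studying atrial fibrillation *in vitro*: monolayers
of these cells develop a constitutively active acetylcholine-mediated K⁺
current (I_KACh-c) that shortens the action potential and stabilizes
reentrant spiral waves, and blocking it with tertiapin-Q terminates the
arrhythmia. `nram` is a Python implementation of an ionic model of this
cell and of the 2D monolayer built from it, for researchers who want to
run the corresponding *in silico* experiments: single-cell pacing and
restitution, planar conduction, spiral-wave initiation (S1–S2 cross-field,
burst pacing), channel-block interventions, and the analysis that goes
with them (activation/APD maps, conduction velocity, tip trajectories,
dominant frequency).

## The model

A Hodgkin–Huxley-type membrane,

dV/dt = −(I_ion − I_stim)/C_m,  
I_ion = I_Na + I_CaL + I̅_K1 + I_to + I_CaT + I_Cab + I_NCX + I_NaK + I_f + I_Nab + I_Ksus + I_KACh,

with a two-compartment sarcoplasmic reticulum (SERCA uptake, RyR release,
calsequestrin/troponin/calmodulin buffering). Model-defining features: the
sustained K⁺ current is scaled as I_Ksus = 0.16·(I_Kur + I_Kr + I_Ks); the
inward rectifier is a composite of a weak rectifier and a linear K⁺ leak,
0.048925·(K_o/(K_o+210))·(V−E_K−10)/(1+e^{0.041(V−E_K−10)}) + 0.01·(V−E_K);
and I_KACh comes in two forms — a dose-dependent single-cell law and the
agonist-independent constitutive tissue form
0.37488·(0.075 + 0.35/(1+e^{(V+102)/10}))·(V−E_K−10). Tissue is the
isotropic monodomain equation ∂V/∂t = −I_ion/C_m + D∇²V solved by forward
Euler (δt = 0.02 ms) and centred differences (δx = 0.00625 cm, no-flux
boundaries, D = 1.2·10⁻⁴ cm²/ms), on a 15.6 mm circular virtual monolayer
with 15–20 % randomly placed passive (MacCannell-type) myofibroblasts and
50–150 % per-cell conductance variability. See `docs/methods.md` for the
full account, including where the reconstruction had to make choices.

## A worked example

```python
from nram import CellParams, ap_metrics, pace_to_steady_state

params = CellParams()                       # bundled model defaults
rec = pace_to_steady_state(params, bcl=1000.0, n_beats=12,
                           mode="single_cell")
m = ap_metrics(rec.window(11000, 12000), stim_time=11000)
print(m.rmp, m.amplitude, m.apd50, m.apd80)
```

Running `python examples/single_cell_ap.py` prints

```
resting potential :    -73.4 mV
AP amplitude      :    133.3 mV
max upstroke rate :      363 mV/ms
APD50 / APD80     :  25.3 /  58.7 ms
mean [Ca]_i       :     0.40 uM
mean [Ca]_NSR     :      880 uM
mean [Ca]_JSR     :      790 uM
```

— the triangular, notch-free atrial AP of the cultured cell: it rests near
−73 mV, fires a ~133 mV action potential that is 80 %-repolarized within
~59 ms, and cycles sub-micromolar cytosolic Ca²⁺ against a ~0.8 mM SR
store. `python examples/planar_wave_cv.py` launches a plane wave on a
16 mm strip and prints a conduction velocity of 22.8 cm/s, in the
20–25 cm/s range of confluent monolayers. The other examples build a
heterogeneous monolayer and quality-control its APD₈₀ map
(`monolayer_qc.py`), compare APD restitution with and without the
constitutive current (`restitution.py` — full block roughly triples APD₈₀,
the tertiapin-Q signature), and initiate a spiral by S1–S2 cross-field
stimulation on a scaled domain (`spiral_s1s2.py`).

A thin CLI mirrors these capabilities
(`nram single-cell`, `nram restitution`, `nram build-monolayer`,
`nram tissue pace|s1s2|burst|scan-capture`, `nram analyze`,
`nram fixture`).

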