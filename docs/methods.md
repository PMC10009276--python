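# Methods

## Scope and model structure

`cardiak` simulates extracellular potassium accumulation during the first
~30 minutes of acute myocardial ischemia, at two levels:

* **0D** — an isolated human ventricular cardiomyocyte whose extracellular
  cleft potassium concentration `[K+]o` is a dynamic state variable:

      d[K+]o/dt = alpha * sum(I_Kx) + ([K+]b - [K+]o) / tau_wo

  where `sum(I_Kx) = IKr + IKs + Ito + IK1 + IK(ATP) + IKb + ICaK - 2*INaK`
  is the total transmembrane potassium current (the pump imports two K+ per
  cycle), `alpha = Ac/(F*vo)` converts a current density into a rate of
  change of cleft concentration, and the wash-out term relaxes the cleft
  toward the bulk (blood) concentration `[K+]b = 5.4 mmol/L` with time
  constant `tau_wo` (15 s in normoxia, infinite — no flow — in ischemia).

* **1D** — a 4-cm strand whose first 2 cm stay normoxic while the rest is
  progressively ischemic.  Membrane potential obeys the monodomain
  reaction-diffusion equation `Cm dVm/dt = DV Vxx - Iion + Istm` with
  zero-flux ends; the extracellular potential is recovered from the
  two-step reduction `Vo_xx = -Vm_xx / (1 + lambda)` (lambda = 3.647) with
  zero-flux ends and a zero-spatial-mean gauge (a zero-at-left-end gauge is
  available).  Extracellular K+ obeys a Nernst-Planck transport equation:
  Fickian diffusion (DK), electromigration along the Vo gradient (the F/RT
  drift term), the transmembrane source `alpha * sum(I_Kx)` and wash-out,
  with zero-flux ends.  The intracellular injury current is the
  post-processing diagnostic `Iinj = DV * Vxx`, converted to uA/mm^3 of
  tissue through the intracellular surface-to-volume ratio (363.6 mm^-1).

## Baseline cell model and modifications

The membrane kinetics are the O'Hara-Rudy (2011) endocardial human
ventricular model, re-implemented from the published equations, with two
modifications:

1. the fast sodium current uses the ten Tusscher-Panfilov (2006) m3hj
   formulation.  Its maximum conductance (5.37 mS/uF) is calibrated so the
   normoxic strand conducts at 70 cm/s with the tabulated effective
   conductivity DV = 0.0026 (interpreted as cm^2/ms) at dx = 0.25 mm,
   dt = 0.02 ms.  The printed conduction velocity is treated as the binding
   constraint because the tabulated conductivity units are ambiguous.
2. an ATP-sensitive potassium current is added (see below).

**Stimulus bookkeeping.**  The stimulus charge is booked as a sodium
influx.  Any convention that lets the stimulus charge leave the cell
through potassium channels (the common "stimulus into Ki" bookkeeping, or
an unassigned stimulus, which the diastolic IK1 dominance funnels into the
same K+ pathway) imposes a spurious net cleft K+ efflux of
`2*threshold*0.5 ms/BCL*alpha` — several (umol/L)/s — at the paced limit
cycle.  With the Na+ assignment the extra charge is exported by the NaK
pump (3 Na+ out / 2 K+ in) and the channel K+ efflux balances the pump K+
influx at steady state, as required for a stable normoxic `[K+]o`.  The
residual imbalance of the frozen limit cycle is ~0.5 (umol/L)/s (1.6% of
the unidirectional rates).

**The `alpha` prefactor.**  The tabulated cell surface (0.0152 mm^2) and
cleft volume (13.3 um^3) are mutually inconsistent as dimensional anchors,
so `alpha` is a single calibrated constant: it is fixed by requiring the
normoxic unidirectional efflux rate at steady 1-Hz pacing to equal
34.5 (umol/L)/s, giving 134.87 (umol/L)/s per uA/uF.  Both raw anchors and
the derived constant are stored in `cardiak.params`.

## Ischemia interventions

Five prescribed metabolite drivers evolve over 30 min of ischemia:
[ATP]i (10 -> 2.7 mmol/L), free [ADP]i (15 -> ~100 -> 80 umol/L, biphasic),
pHi (7.2 -> 6.4) with pHo tracking at +0.2, and [LPC]i (linear 2 -> 20
umol/L).  The ATP/ADP/pH tables are digitized control points
(`cardiak/data/*.csv`, monotone piecewise-cubic interpolation) constructed
from the experimental literature shapes; an alternative slower ADP profile
is selectable.  In tissue, ATP/ADP/LPC switch stepwise at the metabolic
border (x = 2 cm) and pH ramps linearly over a transition zone
(default 0.5 cm; 0 and 1 cm variants available).

The membrane-level effects, all multiplicative factors equal to 1 at the
normoxic anchors:

* **IK(ATP)** (Ferrero et al. 1996 functional form):
  `IKatp = g * (Ko/5.4)^0.24 * f_ATP * (Vm - EK)` with
  `f_ATP = 1/(1 + (ATP/Km)^H)`, `Km = km_scale*(35.8 + 17.9*ADP^0.256)` uM
  and `H = h_scale*(1.3 + 0.74*exp(-0.09*ADP))`.  The human adaptation
  scales (km_scale 17, h_scale 4.3) and g = 4.0 mS/uF are calibration
  constants (see below).
* **Pump scaling** (NaK pump, sarcolemmal Ca pump, SERCA): Hill functions
  of [ATP]i whose half-activation grows with ADP along a saturating Hill
  curve `Km = 0.3 + 11.73/(1 + (25/ADP)^6)` mmol/L, exponent 2.61; the Ca
  pumps use 0.35x that Km (less ATP-sensitive).
* **Acidosis**: linear reductions per pH-unit drop (floored at 0.05) for
  ICaL (2.0/pH, on pHo), INa (2.0), INaL (3.0), INaCa (1.2, on pHi) and
  INaK (0.25, on pHi).
* **LPC**: INa reduced by 0.0167 per umol/L above normoxic; INaL enhanced
  by 0.01 per umol/L.

All of these parameter values are **model-fit constants**, versioned in
`cardiak/data/calibration.json`: the source formulations are cited by the
study design but their human-adapted parameters are not printed, so they
were calibrated once against the printed single-cell outcomes (balanced
normoxic fluxes at 34.5 (umol/L)/s; influx 15.0 / efflux 37.2 / net 22.2
(umol/L)/s at 2.5 min; net 0.9 at 10 min and 4.5 at 20 min; [Na+]i
7.3 -> 9.3 mmol/L by 5 min; plateau `[K+]o` near 11.7-12 mmol/L; >50% pump
reduction at 30 min) and then frozen.  The metabolite tables were frozen
*before* this calibration and were not adjusted afterwards.

**Interventions.**  Alternans suppression is a time-windowed multiplicative
gain on ICaL (default preset: gain 2.0 from minute 3.5 to 12 after
occlusion).  Extracellular-volume shrinkage is a prescribed linear
reduction of the cleft volume reaching -9% at 30 min (scales `alpha` as
1/vo(t)); off by default.

## Stimulation

Pulses of 0.5 ms at twice the diastolic threshold, 1 Hz by default (0, 30,
120, 180 bpm presets).  Thresholds are found by bisection to 0.5% (capture:
peak Vm > -20 mV within 50 ms) and stored with the calibration: 49.7 uA/uF
for the isolated cell, 279.7 uA/uF for the leftmost cable node (a single
stimulated node must also charge its neighbours).  In 1D the stimulated
region defaults to one node at dx = 0.25 mm and scales to keep ~0.25 mm of
stimulated tissue on finer grids.

## Numerics

Gates are advanced by Rush-Larsen exponential integration and
concentrations/Vm by forward Euler, with two-level time-step adaptivity:
dt = 0.02 ms whenever a stimulus is near, any node is depolarized
(Vm > -40 mV) or |dVm/dt| exceeds a threshold, and dt = 0.25 ms (0D) or the
diffusive stability bound (1D) in diastole.  Halving both steps changes
APD90 by < 0.5 ms, and a single paced beat agrees with an independent
stiff integration (LSODA, rtol 1e-6) of the same right-hand side within
1 mV RMS.  The 1D operator splitting is: per-node reaction update ->
explicit Vm diffusion (conservative flux-form stencil, zero-flux ends) ->
K+ transport update (flux-form diffusion + electromigration, sub-cycled at
5 electrical steps by default, Vo recomputed from the closed form at each
transport step).  The K+ current time-integrals are accumulated at solver
resolution, so flux rates over any window are exact quadratures of the
trajectory rather than re-integrations of sampled traces.

Traces are recorded at 1 ms; the "macro" `[K+]o` series additionally at
1 s, which removes the systole-diastole micro-fluctuations.

### Problem sizes used by the test suite and the acceptance script

Chosen so the standard runs complete in minutes on one core:

* 0D control: 5 min normoxia + 20-21 min ischemia (the full 35-min protocol
  is available as the `0d-control` preset).
* conduction velocity: 3 paced beats on the full 161-node cable (and a
  321-node, dt = 0.01 ms refinement benchmark).
* 1D sensitivity suite: dx = 1 mm, 1 min normoxia + 4 min ischemia, with
  the coarse-accuracy stepping profile (fine dt only at wavefronts).  At
  this scale the conductivity/K+-diffusion *orderings* are asserted, not
  the absolute 15-min border-zone widths (which require the full-resolution
  long runs); the injury-current magnitude is checked within a factor-3
  band because the coarse grid under-resolves the border-zone curvature.

## Alternans detection and derived metrics

* APD90: from maximum upstroke velocity to 90% repolarization relative to
  the beat's own amplitude (peak minus pre-stimulus diastolic Vm);
  non-captured beats (peak < -20 mV within 50 ms of the stimulus) are
  flagged, not zeroed.
* Alternans: beat pairs with |dAPD90| > 5 ms, runs of >= 8 captured beats;
  a strict sign flip at every step is labelled 2:2, anything else complex.
  The 5-ms threshold is far above solver noise (< 0.5 ms) and far below the
  alternans magnitude (tens of ms).
* Diastolic minimum `[K+]o` (per beat): minimum over the last 100 ms before
  each stimulus.
* Border-zone metrics: primary width = metabolic border to the
  (parabolically interpolated) profile peak; an alternative span width
  (10%-90% of the CIZ-normoxic difference) is reported alongside and is the
  more robust measure on coarse grids or monotone profiles; invasion depth
  = reach of `[K+]o` elevation (> normoxic + 0.1 mmol/L) into the normoxic
  segment.
* Flux-rate reports: 4-beat windows (Basic Cycle Length 1000 ms), positive
  = efflux; additivity (net = sum over currents = efflux + influx) holds to
  round-off by construction.

## What the prescribed-driver design does and does not show

The metabolite drivers are imposed, not mechanistically computed, exactly
as in the study design this package follows: conclusions about *why*
potassium accumulates (pump inhibition vs channel efflux, alternans-driven
plateau, electrotonic border-zone formation) are conditional on those
driver time courses.  The synthetic fixtures used in unit tests (square
APs, constant currents, prescribed Vm profiles) validate the analysis
operators exactly but say nothing about physiology.  Real ischemic tissue
additionally involves mechano-sensitivity of the K(ATP) channel,
catecholamine/fatty-acid effects, cell-to-cell variability, membrane damage
in the late phase and 3D anatomy — all out of scope here.

## Known limitations

* The calibrated fast-Na conductance that reproduces CV = 70 cm/s at the
  tabulated DV yields a moderate upstroke velocity (~150-300 mV/ms
  depending on state) and a correspondingly high diastolic stimulus
  threshold; AP peak and APD are unaffected.
* APD90 immediately before alternans onset is ~223 ms versus the reported
  192 ms (normoxic APD90 266 ms vs 289 ms); the alternans window
  (~4.3-7.5 min) starts within the reported fourth-to-sixth-minute span
  but extends longer.
* The quiescent ischemic cell's transient `[K+]o` dip is deeper
  (~1.5 mmol/L) than the "slight" dip described experimentally, though the
  dip-then-rise shape is reproduced.
* Quasi-steady drifts of the paced limit cycle (Ki ~ -0.25 mmol/L per
  1000 s) are inherent to the stimulus bookkeeping and are small relative
  to the ischemic signals.
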