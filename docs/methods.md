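# Methods

`cardioinflam` simulates how the acute-phase cytokines TNF-α, IL-1β and
IL-6 reshape human ventricular electrophysiology, from single myocytes to
tissue-level arrhythmia markers.  This note records the models, the
numerical choices, and the places where the design was genuinely open.

## Ionic model

The myocyte is the ten Tusscher–Panfilov (2006) human ventricular model
with full dynamic intracellular Na⁺/K⁺/Ca²⁺ handling (19 state variables:
Vm, 12 Hodgkin–Huxley gates, the ryanodine-receptor adaptation variable,
and Ca_i, Ca_SR, Ca_ss, Na_i, K_i).  The three transmural variants differ
only in their repolarizing conductances: the MID cell has the small slow
delayed-rectifier conductance (G_Ks = 0.098 vs 0.392 nS/pF) that gives it
its long action potential, and the ENDO cell has the reduced
transient-outward conductance (G_to = 0.073 vs 0.294 nS/pF) with its own
I_to inactivation kinetics.  For τ_f2 we use the corrected formulation
published in the model authors' reference code rather than the journal
table's typo.

Calcium buffering uses the instantaneous-buffering approximation in its
ODE form (a chain-rule factor on each free-calcium derivative) rather than
the per-step algebraic quadratic update of the reference code; the two are
discretizations of the same approximation and agree under step halving.

### Cytokine perturbation surface

Cytokine effects act on exactly seven handles: the I_to, I_Kr and I_CaL
maximal conductances, the SERCA uptake rate V_max_up, the SR leak rate
constant V_leak, and voltage offsets of the I_to inactivation and I_Kr
activation steady-state curves.  Offsets shift the steady-state curve only
(evaluated at Vm − shift); time constants are untouched, because the
source experiments report shifted activation/inactivation curves, not
kinetics.  Where a source reports a range (TNF-α on I_to: −23.4…−65%;
IL-6 on SERCA expression: −21…−50%) the default is the range midpoint,
overridable per target.

Combined ("inflammation") effects accumulate as **summed fractional
changes** per target, then scale by a severity in [0, 1]:
factor = 1 + severity · Σ fractions, floored at 0 with a warning.
Severity 1.0 is the full reported effect, 0.5 is "mild inflammation"
(every effect halved — with summed fractions the halving rule is exact).
A multiplied-factors composition mode is provided for comparison.  Tissue
coupling falls linearly with severity to −35% at severity 1.

## Integration

Rush–Larsen exponential integration for the 12 HH gates and forward Euler
for voltage, concentrations and the RyR variable, at dt = 0.02 ms
(convergence-tested: halving dt moves steady-state APD₉₀ by ~0.1 ms).
Tissue uses operator splitting — a reaction step followed by an explicit
diffusion step — on a conservative flux stencil with harmonic-mean
interface diffusivities, so flux is continuous across the
normal/inflamed border; boundaries and mask edges are no-flux.  The
solver aborts (with node and time) if Vm leaves ±200 mV.

The production kernels replace the voltage-dependent coefficient
functions (gate steady states, Rush–Larsen factors e^(−dt/τ), the
rectification and exchanger exponentials) by linear interpolation in
0.02 mV lookup tables, the standard optimization for this model family;
the closed-form path remains behind the public `step`/`derivatives` API
and the two agree to well below the time-discretization error.

## Study conditions

* **Single cell** — 1 Hz trains of 80 pA/pF × 0.5 ms pulses.  The paper
  paces 1000 beats; the desk-scale default throughout tests and the
  acceptance script is 200 beats, which changes APD₉₀ by < 2 ms and is
  reported with a |ΔAPD₉₀| < 1 ms steady-state criterion.  APD₉₀ runs
  from the upstroke's maximum dVm/dt to the downward crossing of
  V_rest + 0.1·(V_peak − V_rest), linearly interpolated; V_rest/V_peak
  are per-beat quantities.  The transmural dispersion ΔAPD is reported
  under both conventions (MID − mean(ENDO, EPI), the default, and
  MID − max(ENDO, EPI)).
* **Strand** — 15 mm, 100 nodes at dx = 0.15 mm, ENDO:MID:EPI = 25:35:40
  from the ENDO end, D = 0.154 mm²/ms (CV ≈ 0.74 m/s in this
  implementation: 0.76).  Fully inflamed tissue uses D = 0.1 mm²/ms
  (CV ≈ 0.6); at intermediate severity D interpolates linearly between
  the two, since only the endpoints are constrained by the reported
  coupling data.  Tissue nodes are initialized from cached single-cell
  1 Hz steady states and settled for three strand beats before
  measurements.
* **Sheet** — parameterized stand-in for an undeposited realistic slice:
  transmural layer bands along x, isotropic D, full-edge endocardial
  pacing, optional central circular obstacle (the "ventricular cavity
  ring"), and for local inflammation a rectangular free-wall lesion
  (default 1/3 × 1/3 of the sheet) carrying the severity-1 perturbation
  and the 35% coupling reduction.

## Vulnerable window

S1 paces the first three ENDO-end nodes at 1 Hz; after a coupling
interval Δt (anchored at the last S1 delivery) S2 hits a 0.45 mm
(3-node) segment centered on the measurement site.  The response is
classified by whether the premature wave reaches the node 10 nodes away
on each side within 100 ms: both sides → bidirectional conduction, one →
unidirectional block, neither → bidirectional block.  The vulnerable
window is the maximal contiguous unidirectional interval, located by an
adaptive coarse bracket (5 ms), a 1 ms scan, and 0.25 ms bisection of
both edges; each trial restarts from a stored post-S1 state snapshot so
only the classification window is re-integrated.

Two protocol details are unconstrained by the source and were fixed as
follows:

* **S2 strength.**  An 80 pA/pF × 0.5 ms pulse cannot capture a 3-node
  mid-cable segment against the electrotonic load of its neighbours
  (diastolic threshold of a 2 ms pulse ≈ 45–50 pA/pF).  The mean window
  width is strongly stimulus-dependent near threshold (3.3 ms at
  80 pA/pF, 4.8 at 100) but saturates above ≈ 2× the pacing amplitude
  (7.9 ms at 160, 8.1 at 200): in that regime the window measures tissue
  refractoriness rather than capture margin.  The default S2 is therefore
  160 pA/pF × 2 ms.  Under this choice control and mild means land within
  ~7% of the reported values while the full-severity mean overshoots
  (13.2 vs 10.0 ms); no single amplitude reproduces all three, and we
  prefer the stimulus-robust regime over per-condition retuning.
* **Site set.**  Windows are averaged over every 5th node, nodes 10–85,
  keeping both classification probes 10 nodes inside the strand.  The VW
  spatial profile is sharply structured (jumps at layer boundaries, a
  narrow spike near the MID/EPI transition), so subsampling biases the
  mean by 1–3 ms relative to an every-node scan; the per-site map is
  returned for density studies.

## Critical pacing cycle length

Following the source protocol of gradually increasing rate, the PCL ramp
starts at the 1 Hz steady state and descends in 10 ms steps with 8 beats
per step, **carrying the tissue state** so APD restitution accommodates;
1:1 conduction is scored over the last 4 beats at a sensor 10 nodes from
the far end (4 propagated wavefronts → 1:1, ≈ 2 → 2:1, else failure).
When 1:1 is first lost the ramp restarts from the last passing state and
descends in 1 ms steps; the critical PCL is its lowest passing value.
Accommodation matters enormously: restarting every PCL from the 1 Hz
state instead yields 393/401 ms (control/global) versus 302/328 ms for
the ramp, bracketing the slice-model values (319/380 ms).  A 1-row sheet
reproduces the strand value exactly.

## Reentry induction (2-D)

S2 is applied at the lesion border (local scenario) or an epicardial
patch (control), with the coupling interval located by bisection between
full block and full recovery using the same stored-snapshot restarts.
After a unidirectional escape the episode is followed for a configurable
window; reentry is scored when any node activates ≥ 3 times after S2,
and is classified *anatomical* when the late activation circulates the
obstacle — a winding test requiring the ring of border nodes, ordered by
angle, to activate as a single monotone ramp with one wrap-around.

A quantitative caveat: the human excitation wavelength (APD ≈ 0.3 s ×
CV 0.74 m/s ≈ 0.2 m) exceeds any desk-scale sheet by more than an order
of magnitude, so sustained spiral/anatomical reentry cannot exist in the
default geometries; the induction machinery, the negative controls and
the winding classifier (exercised on synthetic rotating activation) are
what the test suite can honestly cover.

## Pseudo-ECG

φ = (a²σ_i/4σ_e) Σ (−∇Vm)·∇(1/r) dΩ with central-difference gradients
(one-sided at boundaries), an electrode 20 mm beyond the EPI end of the
strand on its axis, and a, σ_i, σ_e = 1 (only timing is quantitative; the
prose of the source equation swaps the σ labels and we use the
conventional reading with the ratio configurable).  The 25:35:40 layout
yields a biphasic QRS and an upright T wave.  QRS onset is the first
|dφ/dt| crossing of 5% of its maximum after the stimulus; T-wave end is
the last |φ| ≥ 5% of the T-peak amplitude (tangent-free threshold
method); QT = T_end − QRS onset, robust to the 5%→2% threshold choice
within 10 ms.

## What the synthetic geometries do and do not show

All inputs are printed effect sizes and solver parameters; there is no
external data.  The strand and sheet are idealized: no fiber anisotropy,
no realistic slice outline, no rat model, no cytokine synergy or
dose–response (composition is additive by construction).  Agreement on
CV, ΔAPD, VW ordering, QT prolongation and critical-PCL ordering shows
the cytokine parameterization and solvers behave like the source study's
pipeline at desk scale — not that the geometry-dependent 2-D morphology
(spiral lifetimes, reentry paths) generalizes to real slices.

## Degenerate inputs and tie-breaks

Gates are clamped to [0, 1] only by the Rush–Larsen form itself; any
out-of-range or non-finite state raises rather than being silently
clipped.  A vulnerable-window scan that finds no unidirectional interval
returns width 0 with NaN edges.  A PCL range whose top already fails, or
whose bottom still conducts 1:1, raises with the observed classes.  APD
measurement on a beat that never recrosses threshold returns a
repolarization-failure flag with NaN duration.  Scenario runs are
bit-reproducible at fixed dt; the only randomness anywhere is the
optional lesion-placement jitter behind an explicit seed.
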