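# Methods

## The model

`glycsim` simulates the glucose–insulin feedback axis of a critically ill
patient with stress hyperglycemia as a two-delay differential system
derived from mass conservation of glucose `G(t)` and insulin `I(t)`:

    dG/dt = G_in(t) + Ғ·f5(I(t−τ2))·f6(G(t))
            − f2(G(t)) − β·f3(G(t))·f4(I(t)) − f7(G(t)−330)
    dI/dt = I_in(t) + α·f1(G(t−τ1)) − d_i·I(t)

The seven response functions carry the physiology: `f1` pancreatic insulin
release (sigmoid in delayed glucose), `f2` insulin-independent glucose
uptake (saturating), `f3·f4` insulin-dependent uptake (linear in glucose
times a log-sigmoid utilization factor in insulin), `f5` hepatic glucose
production (suppressed by delayed insulin), and `f6`/`f7` inhibitors of
hyperglycemia (a multiplicative damper on hepatic output and an extra
utilization term engaging above ~300 mg/dL).  The two delays — pancreatic
secretion (`τ1`) and hepatic secretion (`τ2`) — make the closed loop a
delayed negative feedback that sustains the ultradian glucose–insulin
oscillation (period tens of minutes to ~2 h) observed under continuous
feeding.

Six patient parameters set the pathophysiology: `α ≤ 1` scales insulin
secretion (pancreatic insulin deficiency, IDp), `β ≤ 1` scales
insulin-dependent utilization (insulin resistance, IR), `Ғ ≥ 1` scales
hepatic glucose production (gluconeogenesis; 2 throughout the study),
`d_i` is the first-order insulin clearance rate (raised clearance, IC),
and `τ1`, `τ2` are the delays.

## Units

State variables are amounts: glucose in mg over the distribution volume
`Vg = 10 L`, insulin in mU.  Concentrations are derived at the I/O
boundary only: glucose in mg/dL is `G/(10·Vg)`; the insulin trace is
reported in model units (mU).  Exogenous rates are mg/min (nutrition) and
mU/min (insulin).  The `f7` argument is the literally shifted amount
`G − 330`, with the shift and center `c7` fixed model constants.

## The constants table

The shape constants of `f1..f7` are not free parameters of the study; they
are inherited from the standard ultradian-oscillator tabulation of the
Sturis/Tolić/Li–Kuang–Mason model lineage and shipped as a flat text file
(`src/glycsim/data/ultradian_constants.txt`) parsed strictly, so a
corrected table changes no code.  Three groups deserve comment.

* Lineage values adopted unchanged: `Rc=210`, `c1=2000`, `e1=300`,
  `Vg=10`, `Ub=72`, `c2=144`, `c3=1000`, `Uo=40`, `Uc=940`, `κ=1.77`,
  `c4=80`, `Vc=11`, `Etc=20` (the exchange-rate × time-constant product),
  `Rg=180`, `Vp=3`.  The `f4` log-sigmoid is evaluated in power form,
  `Uo + (Uc−Uo)·z^κ/(1+z^κ)` with `z=(I/c4)(1/Vc+1/Etc)`, which extends it
  continuously to `f4(0)=Uo` (the raw logarithm is singular at zero
  insulin).
* The hepatic-arm insulin scale: the lineage states `f5` against
  interstitial insulin over 11 L; a literal plasma-volume (3 L) reading in
  a single-insulin-compartment model leaves `f5` switched off at
  stress-level insulin, and the severe-IR patients then have no limit
  cycle anywhere in a physiologic delay box.  We use `c5 = 30 mU/L`,
  `a5 = 0.25 L/mU` — between the two volume readings — so hepatic
  production stays responsive over the cohort's insulin range.
* The hyperglycemia inhibitors have no lineage analog; their constants are
  design choices: `f6 = exp(−γ(G/(c3·Vg) − c6))` with `γ=0.2`, `c6=1`
  (unity at 100 mg/dL, a mild damper), and `f7` a sigmoid from
  `Sc=4 mg/min` to `Sb=180 mg/min` centered near 300 mg/dL (`δ=5`,
  `c7=3`): inert in the study's glycemic band, a guard against runaway
  hyperglycemia.  These choices were fixed by requiring that all eight
  cohort parameter combinations sustain ultradian oscillations whose
  baseline peaks are delay-tunable into the 150–170 mg/dL band, with
  periods (65–115 min) on the order of the rapid analog's absorption
  timescale.

All sigmoid exponents are clamped at ±700 so extreme states degrade to
asymptotes instead of overflowing.

## Exogenous inputs

Continuous enteral nutrition is a constant carbohydrate appearance rate:
135 mg/min at goal (equivalent to 82.2 mL/h of a 1.2 kcal/mL formula —
2367 kcal and 194 g net carbohydrate per 24 h), 67.5 mg/min at half goal,
0 with feeds held.

Subcutaneous insulin enters as piecewise-linear unit absorption shapes
riding on a 0.25 residual baseline: Lispro (onset 5 min, peak 1.25 at
30 min, support 240 min, unit area 117.5) and regular insulin (onset
30 min, peak 1.25 at 120 min, two decay legs, support 480 min, unit area
315).  A dose scales the whole shape by `dose·conversion/area`, so the
delivered integral is exactly `dose·conversion` and dose 0 is the exact
baseline.  Whether the residual 0.25 offset should scale with dose is
ambiguous in the source description; whole-profile scaling was chosen
because it makes total delivery proportional to dose.

The units-to-model conversion is an identified parameter, not the physical
1000 mU/U, because the single insulin compartment conflates plasma and
interstitial kinetics.  It is fixed at **300 mU/U**, the value at which
the fasting-Lispro hypoglycemia threshold of the borderline-clearance
patients lands at ~4 U (the study's reported safety landmark) while a 6-U
bolus still produces an insulin excursion comparable to the endogenous
swing.  It is exposed as a single configuration constant.

## Numerical integration

The two-delay system is advanced by the method of steps: fixed-step
classical Runge–Kutta (4th order), default step 0.1 min, with
delayed-state lookups served by 4-point cubic Lagrange interpolation of
the dense solution history on the step grid.  The step must satisfy
`h ≤ min(τ1, τ2)/4` so every stage lookup falls in completed history;
zero delays reduce the scheme to a plain RK4 ODE integrator (verified
against an independent adaptive solver to < 0.1 mg/dL).  Absorption-shape
corner points (5, 30, 120, 240, 480 min after injection) coincide with
step boundaries, so no order is lost at kinks.  Step halving changes the
750-min glucose trace by < 0.05 mg/dL sup-norm.  States are clamped at
zero after each step (inactive on healthy trajectories).  The scheme is
fully deterministic — there is no randomness anywhere in the package.

Dense output resamples the step grid to the 1-s metric grid with the same
cubic interpolant.

## Burn-in and injection phase

Each run starts from a constant history placed 2 % above the delay-free
equilibrium (the equilibrium itself is a DDE fixed point; an exact
equilibrium history would sit on the unstable focus indefinitely) and
integrates 6000 min.  The trailing 1000 min must show ≥ 3 glucose peaks
with successive heights within 0.5 mg/dL *and* a peak-to-trough swing of
at least 1 mg/dL — the amplitude floor rejects trajectories that damp to a
fixed point, which would otherwise pass the height test trivially.  Time
is then re-based so t = 0 is the last detected peak: every injection is
given at a baseline glucose peak, and treated and baseline runs continue
from the identical history buffer.  The peak is located at step-grid
(0.1-min) resolution, so the phase reference is exact to one step.

## Cohort calibration

The eight patients are the full factorial {mild, severe IR} × {mild,
severe IDp} × {borderline, IC50}, `Ғ = 2` throughout (`β/α ∈ {0.8, 0.6}`,
`d_i ∈ {0.17, 0.25}`).  Delays are calibrated per patient by a
deterministic coarse-to-fine grid search over `τ1 ∈ [1, 10]`,
`τ2 ∈ [12, 40]` min: a pair is admissible when the insulin-free baseline
at goal nutrition sustains an oscillation whose maximum over the 750-min
window lies in 150–170 mg/dL.  Among admissible pairs the one closest to
the normal-physiology delays (5, 25) in relative distance wins, ties
broken lexicographically — the delays stay as normal as the band permits,
which also keeps the cohort's periods in the physiologic 65–115 min range.
(Steering instead toward the band midpoint pushes every patient to the
large-delay corner and periods of 130–150 min.)  An infeasible search box
raises an explicit calibration failure listing the achieved peak range.

## Metrics and event definitions

* **MGC** — arithmetic mean of the per-second glucose samples over the
  750-min window.
* **GV** — mean absolute glucose change: the average absolute difference
  between consecutive local extrema of the trace.  Extrema are sign
  changes of the discrete first difference; runs of exactly equal samples
  (possible on a dense noise-free grid) collapse to one extremum at the
  plateau midpoint; endpoints are never extrema; fewer than two extrema is
  an explicit undefined-GV condition, distinct from zero.  GV is not
  normalized by time because every measurement uses the identical window.
* **ΔMGC / ΔGV** — treated minus baseline at the same patient × nutrition;
  the dose-0 cell *is* the baseline, so its deltas are exactly zero.
* **Hypoglycemia** — trace minimum at or below 60 mg/dL (an
  operationalization of "near 60"; configurable).
* **Rebound hyperglycemia** — first post-injection peak strictly above the
  ordinally matched baseline peak.  Ordinal pairing is the phase-matching
  rule: the injection occurs at a shared baseline peak, so first treated
  peak corresponds to first baseline peak.  Above its onset dose the
  rapid analog suppresses and eventually annihilates the covered first
  peak; the detected "first peak" is then the hepatic recovery overshoot.

## Study orchestration

The full factorial is 8 × 2 × 3 × 25 = 1200 cells.  The baseline
simulation of each patient × nutrition is computed once and shared by all
50 treated cells.  Cell failures are recorded with coordinates and the
factorial continues.  Dose–response linearity is reported as the R² of a
straight-line fit, with "linear" operationalized as R² ≥ 0.98.

Problem sizes used throughout (6000-min burn-in, 750-min measurement,
0.1-min step, 1-s metric grid) make the full factorial run in ~10 s and
the complete calibration in ~25 s on one CPU.

## What the generator does and does not emulate

The virtual patients reproduce: sustained ultradian glucose–insulin
oscillations under continuous feeding, stress-hyperglycemic baselines
(peaks 150–170 mg/dL), graded severity of IR/IDp/IC, and the qualitative
response structure to short-acting subcutaneous insulin — linear lowering
of MGC and GV by regular insulin, variability increase and rebound
hyperglycemia under the rapid analog in severe IR, hypoglycemia only when
nutrition is withheld.  They do not emulate: measurement noise or sensor
artifacts, meal boluses or interrupted feeds, multi-dose regimens and
insulin stacking, circadian modulation, time-varying severity, or
validated human ICU kinetics.  Passing tests therefore demonstrate the
internal consistency of the model and pipeline, not clinical accuracy.

## Known limitations

* The rebound-onset dose is highly sensitive to the constants table — it
  is set by the margin between the baseline insulin trough and the hepatic
  activation knee, and by the phase of the first peak relative to the
  absorption window.  With the adopted table the severe-IR /
  mild-IDp / borderline-IC patient's onset is 1.25 U; the structural
  features (suppression below onset, single crossing, monotone worsening
  above, later onset for IC50 counterparts) are robust, the numeric
  location is not.
* Because calibration assigns each patient individual delays, matched
  borderline-vs-IC50 comparisons confound the clearance effect with a
  period difference; clearance blunting holds in aggregate (and strongly
  for GV under the rapid analog) but not cell-by-cell everywhere.
* A single insulin compartment makes insulin action essentially memoryless
  beyond the absorption window (plasma half-life ~4–6 min), so the
  units-to-model conversion is an effective, identified parameter.
* Baseline oscillations require a nutrition source; the fasting baseline
  of some parameter combinations sits closer to the Hopf boundary and has
  reduced amplitude.
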