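# Methods

This note documents the models, parameter choices and numerical
conventions behind `fdgclamp`, and what the synthetic data do and do not
establish about real studies.

## Tracer kinetic model

Tissue FDG kinetics follow the irreversible two-tissue-compartment
model: free tracer C₁ exchanges with plasma (K₁ in mL·mL⁻¹·min⁻¹ inward,
k₂ min⁻¹ outward) and is phosphorylated into a trapped pool C₂ at k₃
min⁻¹, with no dephosphorylation on the scan's time scale:

    dC₁/dt = K₁·C_p − (k₂+k₃)·C₁,   dC₂/dt = k₃·C₁,
    C_T = (1−V_b)(C₁+C₂) + V_b·C_p.

The net influx constant is K_i = K₁k₃/(k₂+k₃).  The ODEs are integrated
with LSODA at rtol 1e-8 / atol 1e-10; frame means are exact (the running
integral of C_T is carried as an extra state and differenced at frame
edges), so frame binning introduces no quadrature error.

Two properties of the estimators matter for interpretation and are
exploited by the simulator's back-solve:

* The Patlak slope of C_T estimates **(1−V_b)·K_i**, not K_i, because
  the blood term contributes V_b·C_p to both sides of the linearization.
* The FUR at time T estimates, once the free compartment has
  equilibrated, (1−V_b)K_i + [(1−V_b)V_t + V_b]·C_p(T)/AUC(T) with
  V_t = K_i·k₂/(k₃(k₂+k₃)) — FUR exceeds K_i for irreversible tracers,
  and the excess shrinks as T grows (≈9% at T = 90 min for the
  reference parameters K₁=0.1, k₂=0.15, k₃=0.05).

## Input function

A Feng-type tri-exponential bolus C_p(t) = (A₁(t−τ)−A₂−A₃)e^{λ₁(t−τ)} +
A₂e^{λ₂(t−τ)} + A₃e^{λ₃(t−τ)} (zero before the delay τ) stands in for
measured arterial data.  Defaults: A₁ = 800 kBq·mL⁻¹·min⁻¹, A₂ = 20,
A₃ = 21 kBq/mL, λ₁ = −4, λ₂ = −0.5, λ₃ = −0.012 min⁻¹, τ = 0.5 min;
λ₃ varies per subject (SD 10%), and the overall amplitude is rescaled so
the curve's AUC(0,∞) is consistent with the subject's tracer balance
(dose minus urinary loss over whole-body clearance).

The analysis-side input function uses linear interpolation between knots
(with a zero anchor at injection time, which keeps the trapezoidal AUC
exactly additive), no rescaling of the image-derived segment by default
(an optional multiplicative calibration to the first plasma sample
exists), the plasma value winning a tie exactly at the 4.5-min switch,
and a mono-exponential tail fitted log-linearly to the last three knots
for extrapolation beyond the data.  All times are minutes from
injection; all activities are decay-corrected (no isotope decay is
simulated, matching an analysis chain that assumes decay-corrected
inputs).

## Acquisition model

Frame schedules mirror the study protocol: thorax 0–40 min
(4×15, 6×20, 2×60, 2×150, 6×300 s), abdomen 40–55 and thighs 55–70 min
(3×300 s each), 10-min statics for neck and brain.  The two statics are
placed at 70–80 and 80–90 min (the protocol lists their durations but
not their start times).  Patlak regression (t* = 10 min, unweighted OLS,
frame mid-times) serves the dynamically imaged tissues — myocardium,
liver, femoral muscle; FUR at the block mid-time serves VAT, abdominal
and femoral SAT (mean of the three block frames), BAT and brain.  The
t* default is the standard FDG equilibration choice and is configurable.

Frame noise is Gaussian on frame means with SD = scale·√(value/duration)
— the count-statistics approximation in which relative noise falls with
duration and activity.  The default scale 0.1 kBq·mL⁻¹ per
√(kBq·mL⁻¹·min⁻¹) represents ROI-averaged TACs (region means over many
voxels), giving a few-percent noise on typical late frames; voxel-level
noise would be several-fold higher.  Values may go negative, as
decay-corrected PET means can; the left-ventricle curve is clipped at
zero because it feeds the input function, whose evaluation is
nonnegative by contract.  Plasma samples carry 2% multiplicative noise.

## Lumped constants and densities

LC 1.2 (skeletal muscle), 1.0 (liver), 1.14 (adipose) are protocol
values.  The brain LC default 0.65 is a conventional literature value
only — the study delegated brain analysis to an external tool and names
no LC — and is flagged as such in the config.  Densities (muscle 1.06,
liver/myocardium 1.05, adipose 0.925, brain 1.04 kg/L) are
literature-standard reconstructions; all are configurable.

## Clamp indices

M value = steady-state mean GIR (trapezoidal time-average over the
window) − space correction − urinary correction.  The space correction
charges the glucose accumulating in its distribution space,
ΔG[µmol/L]·v_d/window with v_d = 0.19 L/kg; the urinary term defaults to
zero.  Both are reconstructions of a clamp protocol whose detailed
formulas are not in the available text, and both are configurable.
Whole-body Rd uses plasma clearance CL = (dose − urinary activity) /
AUC(0,∞), with Rd = CL·G/(LC_wb·weight) and LC_wb = 1.0 so Rd stays in
glucose equivalents (the liver/whole-body LC convention).  EGP = Rd −
GIR and may be negative (full suppression plus estimation noise).
Matsuda-ISI uses the conventional units (glucose ×18.016 → mg/dL,
insulin ÷6.0 → µU/mL) and, because only fasting and 2-h OGTT values are
available, the OGTT means are taken as the average of the fasting and
2-h samples — with the published group means this reproduces the
published group indices (≈11.0 vs ≈4.9–5.4).  HbA1c conversion uses the
IFCC→NGSP master equation NGSP% = 0.09148·IFCC + 2.152, which
reproduces both published group rows (29→4.8, 32→5.1).

## Synthetic cohort

Group specifications hold per-variable (mean, SD, lower truncation)
drawn from the published group characteristics; sampling is truncated
normal (lower bounds prevent negative masses and rates).  Variables are
independent within subject — the tables publish marginals only — so
between-variable correlation arises solely through group membership.
Consequences: pipeline correlations *within* a group (e.g. M vs muscle
GU in HR subjects) are null by construction and cannot reproduce
published within-group associations; only between-group structure is
encoded.  Per-mass GU targets for tissues with published depot values
are depot GU divided by depot mass; liver, BAT and myocardium per-mass
GU, the depot masses for those tissues, and all kinetic constants k₂,
k₃, V_b are fabricated simulation defaults (flagged in the source) —
K₁ is back-solved per subject from the GU target, inverting the exact
estimator used for that tissue (the (1−V_b) factor for Patlak, the
equilibrium FUR expression for FUR tissues), so the pipeline recovers
targets within ~3% on noise-free data.  Rd targets follow from the M
and EGP targets (Rd = M + EGP, floored at 2 µmol·kg⁻¹·min⁻¹); one
low-risk subject per default cohort has a missing urine collection,
making Rd/EGP missing and exercising the pairwise-deletion path.
Clamp records ramp GIR to the target over the sampled equilibration
time (80 ± 13 min) and hold glycemia at the steady-state target; with
noise off the M estimator recovers the target exactly.  Each subject
also carries an 8×8×4 voxel map of brain uptake (SD 20 µmol·kg⁻¹·min⁻¹
around the subject's brain GU) in which the high-risk group has a
30-µmol·kg⁻¹·min⁻¹ elevation planted in a fixed 3×3×2 block,
emulating a regional group difference detectable by the voxelwise map.

What passing tests show: the estimators are correct on data generated by
the stated models at realistic noise.  What they do not show: robustness
to model violations present in real data — partial-volume effects,
motion, input-function calibration error, non-Gaussian count noise at
low rates, dual liver input, or correlated physiology.

## Statistics

Student's pooled-variance t is the default two-group test (Welch
exposed); rank-sum uses the exact distribution for groups of ≤8 without
ties, otherwise the tie-corrected normal approximation; χ² on category
counts without continuity correction.  Constant identical groups return
t = 0, p = 1 by convention.  Pearson correlation (t-based p) is the
default, Spearman exposed.  Age adjustment removes the least-squares
age slope around the sample-mean age, preserving the mean and acting
idempotently; only brain uptake is adjusted (whether other variables
should also be is ambiguous in the source analysis).  FDR control is
Benjamini–Hochberg across the comparison family or across voxels — a
deliberate simplification of random-field cluster-level FDR, which
needs real registered volumes; zero-variance voxels are excluded from
the family.  Clusters use 26-connectivity.

## Problem sizes and determinism

The default cohort (22+19 subjects, 8 tissue TACs each) simulates in
~10 s and analyzes in <1 s.  Calibration checks use 1,000 power
replicates, 10,000 null replicates and 1,000 FDR vectors.  All
randomness flows through `numpy.random.default_rng` seeds; a fixed seed
yields bit-identical cohorts and byte-identical result files (all CSV
writes use a fixed `%.10g` float format).
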