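# Methods

## The problem

Animal-borne accelerometers let ecologists infer behaviour continuously
without observation, but two design choices shape data quality for a
marine animal: where the tag sits (which changes both signal quality and
hydrodynamic drag) and how fast it samples (which trades accuracy against
battery and memory). This package implements the full
accelerometer-to-ethogram pipeline plus the comparison statistics for
those two choices, with a synthetic-data generator that stands in for
captive-animal recordings so every stage can be tested quantitatively.

## Signal model (synthgen)

Axis convention, fixed package-wide: x = surge (anterior), y = sway
(left), z = heave (dorsal); a motionless level animal reads (0, 0, 1) g.

A recording is a semi-Markov chain over behaviours: the next behaviour is
drawn with probability proportional to the current row of a non-negative
transition-weight matrix (zero diagonal); bout durations are exponential
with behaviour-specific mean, floored at a minimum (≥ 3 s, so a bout
survives the 1 s edge trimming and still yields a window). Exponential
is the simplest renewal choice; nothing downstream depends on the tail
shape. The final bout is truncated so bouts tile the recording exactly.

Within a bout of behaviour b with posture (pitch θ, roll φ), the ideal
signal per sample is

    a(t) = R(θ, φ) · (0,0,1)ᵀ  +  A_b sin(2π f_b t + ψ) · e_x  +  ε(t)

i.e. the gravity unit vector rotated to the posture —
(sin θ, cos θ sin φ, cos θ cos φ), chosen so the downstream
pitch = atan2(aₓ, √(a_y² + a_z²)) and roll = atan2(a_y, a_z) recover θ, φ
exactly — plus a limb-beat sinusoid on the surge axis with a fresh uniform
phase ψ per bout, plus i.i.d. Gaussian noise per axis. Default behaviours
are a five-item captive sea-turtle ethogram (resting, swimming,
surface-breathing, scratching, biting) with oscillation frequencies
0–0.9 Hz: sea-turtle flipper beats are slow, and keeping every f_b at or
below 1 Hz is what makes the frequency-insensitivity result reachable at a
2 Hz sampling rate.

Tag-position effect: the anterior (scute1) tag applies a multiplicative
gain to the *dynamic* part of the signal (oscillation and behavioural
noise) and adds independent Gaussian noise. Gain is not applied to
gravity — an attachment that attenuates movement signal still measures
orientation — which is this package's minimal mechanism for the observed
anterior-placement accuracy penalty; the real mechanism is unknown.
The behaviour sequence, bout phases and base noise stream are drawn from
streams that do not depend on position, so the two tags of one individual
are *paired*: with a null position effect they are bit-identical, which
gives an exact identity test.

Between-individual variation multiplies oscillation amplitudes by a
lognormal factor (SD 0.1 on the log scale by default).

Quantisation follows a signed-integer mid-tread ADC: levels n·R/2^(b−1)
for n ∈ [−2^(b−1), 2^(b−1)−1], then clipping to ±R. This grid contains 0
exactly (as two's-complement hardware does), so axis-aligned postures
survive quantisation unchanged; the error bound is half a step, R/2^b.
At the loggers' 8-bit / ±2 g setting one step is 15.6 mg and posture
angles carry ~0.4° of quantisation error; correctness of the angle
arithmetic itself is verified at 20-bit depth where the error is below
10⁻³ degrees. Both ±2 g and ±4 g ranges are exposed because pilot maxima
and configured ranges differ between species and sources.

What the generator does *not* emulate: depth/temperature channels,
gliding and other wild-only behaviours, observer mislabelling, clock
drift beyond the trimming margin, non-Gaussian sensor noise, and any
overlap structure between behaviours beyond posture/oscillation/noise.
Passing tests therefore show the pipeline recovers structure *of this
kind*; they do not bound accuracy on real animals, where behaviours
overlap far more.

## Labelling, windows, features

Annotation bouts are synchronised to the trace on UTC; each sample in
[start + 1 s, end − 1 s) gets the bout's behaviour (half-open so adjacent
bouts never share a sample); everything else stays unlabelled but is
retained so coverage can be reported. A bout of L seconds at rate f thus
yields round((L−2)·f) labelled samples (round half-up — the exact count
the half-open interval produces on the sample grid).

Labelled runs are tiled from their start into non-overlapping windows of
1 s or 2 s; remainders are discarded, so a run of d seconds gives
⌊d/window⌋ windows, and behaviours whose bouts never reach 2 s simply
contribute only 1 s windows. Decimation to 50/25/12/10/8/4/2 Hz picks the
native sample nearest each target-grid time (count fixed to
round(window · f_target)); no anti-alias filter is applied, preserving the
logger's quantised values — defensible here because the behaviours of
interest oscillate below the lowest Nyquist frequency used, and exposed as
a deliberate, documented choice rather than hidden smoothing.

Eighteen per-window metrics: per-axis mean/SD/min/max (SD with the n−1
denominator), ODBA and VeDBA, and pitch/roll mean and SD in degrees.
The static component is the window mean per axis (windows are ≤ 2 s, the
usual smoothing horizon); dynamic = sample − static; ODBA is the mean L1
norm and VeDBA the mean L2 norm of the dynamic vector, so
VeDBA ≤ ODBA ≤ √3·VeDBA holds per window by the norm inequalities — a
property every generated window is tested against. An alternative metric
list can be registered by name if a different published set is preferred.

## Classification protocol (classify)

1. Behaviours observed in ≤ 3 distinct individuals are excluded: with
   individuals as CV folds, a class present in 3 animals cannot be
   learned and scored blockwise with any reliability.
2. Stratified 70/30 split by behaviour (per-class rounding), rows of one
   individual allowed on both sides — the study default; the stricter
   individual-disjoint evaluation is exactly what the blocked CV measures.
3. Tuning: for each candidate `mtry` (features per split) and each fold
   (one individual held out), minority classes of the *remaining* rows
   are up-sampled with replacement to the majority count, a forest is
   fitted, and macro one-vs-rest AUC is scored on the held-out animal.
   Up-sampling strictly inside the fold matters: up-sampling before the
   hold-out duplicates windows across the fold boundary and inflates CV
   scores. Every row carries its individual id (up-sampled copies
   included) and a provenance assertion (`check_fold_provenance`) raises
   if a fold's training table contains the held-out id — the injected-
   fault test shows the guard fires in 100 % of trials. Classes absent
   from a holdout are skipped in its AUC and reported.
4. The best mean-AUC `mtry` wins, ties to the smallest; the forest is
   refitted on the fully up-sampled training set with 1000 trees by
   default (smaller counts are a parameter for fast runs) and impurity
   importances are recorded.
5. Evaluation: confusion matrix (rows = truth), overall accuracy =
   trace/n, per-class balanced accuracy = (sensitivity + specificity)/2
   one-vs-rest, macro AUC.

## Comparison statistics (inferstats)

Accuracies are proportions, so position/frequency effects are modelled by
beta regression: y ~ Beta(μφ, (1−μ)φ) with logit(μ) = xᵀβ and constant
precision φ on a log link, fitted by maximum likelihood (statsmodels'
beta-model likelihood; quasi-Newton with a simplex polish when the
likelihood is flat, non-convergence flagged on the fit, never silent).
Responses touching 0 or 1 are squeezed by y′ = (y(n−1) + 0.5)/n first —
the beta likelihood is undefined at the boundaries. Wald tests use the
normal reference (df = ∞); OLS (for drag) uses Student t on residual df.

Pairwise contrasts follow the estimated-marginal-means recipe: a reference
grid crosses all categorical levels (numeric covariates at their means),
model-matrix rows are averaged within each level of the focal factor,
differences are taken on the link scale with delta-method SEs, and the
p-value for |z| uses the studentized-range (Tukey) distribution with
k = number of levels — the standard default for a single factor family;
the adjustment label is always reported, and estimates are link-scale with
a response-scale back-transform left to the caller. A numerically zero
difference (|estimate| < 10⁻¹²; e.g. identical responses, where OLS
residual variance is also ~0) is treated as exactly zero rather than
dividing two rounding errors.

The pipeline's default accuracy design uses position with frequency (and
species/window when they vary) and backs off from the interaction model to
additive, then position-only, when the grid is too small to identify the
larger design — small grids are the common case in settings sweeps.

## Drag (drag)

Cd = D/(0.5 ρ U² A) and its inverse round-trip to machine precision;
sea-water density defaults to 1028 kg m⁻³ and the frontal area must be
supplied (it is geometry-specific). CFD is consumed, never run: inputs
are a solver-output CSV (forces or coefficients) or the synthetic
stand-in `synthetic_drag_table`, which draws Cd = offset(position) +
slope·U + noise on the standard 0.2–1.2 m s⁻¹ velocity grid with default
offsets ordered none < scute3 < scute1. The comparison fits
Cd ~ Position × Velocity by OLS and reports Tukey-adjusted pairwise
position contrasts plus per-position velocity slopes.

## Problem sizes and numerical choices

Tests and the acceptance script run cohorts of 6–8 individuals with
120–240 s recordings, 300–500 trees and small `mtry` grids — sizes chosen
so multi-seed studies (5 seeds × 2 positions × 2 frequencies) complete in
minutes on one CPU while leaving hundreds of test windows per model;
accuracy conclusions were not sensitive to doubling any of them. All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning, so identical seeds give bit-identical
cohorts and forests. Timestamps are written at millisecond precision
(exact for the ≥ 10 ms sample steps used); trace-grid uniformity is
validated to the float64 representability limit at the timestamp
magnitude, since absolute epoch seconds cannot hold a 10 ms grid to 1 ns.

## Known limitations

- The synthetic ethogram is far more separable than real turtle data;
  real overall accuracies in this design space are ~0.83–0.86, not 1.0.
- Nearest-sample decimation aliases any energy above the target Nyquist;
  for faster-moving species a low-pass decimator should be registered.
- Beta regression treats grid-cell accuracies as independent; cells from
  one cohort share animals (the original design has the same property).
- The roll statistics average raw per-sample angles; behaviours living
  near ±180° of roll would need circular statistics.
- Only the carapace-mounted, two-position, 1–2 s window design is
  implemented; sliding windows and other placements are out of scope.
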