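# Methods

This note documents the models, algorithms and numerical choices behind
`postop-decomp`, and what the synthetic-cohort experiments do and do not
demonstrate.

## Problem setting

Postoperative ICU patients are monitored continuously (ECG, arterial blood
pressure, pulse plethysmography) and accumulate EHR data (demographics,
comorbidities, labs, medications).  The package predicts, from a 15-minute
waveform span ending 0.5–4 hours before a candidate event time, whether a
hemodynamic-deterioration event occurs.  Labels are taken as given; event
definitions are out of scope.

## Signal processing

**Filtering.** Channel-specific Butterworth band-passes (ECG: order 2,
0.5–40 Hz; ABP: order 3, 1.25–25 Hz; PPG: order 3, 1.75–10 Hz), applied
zero-phase (forward–backward) so waveform morphology is not skewed before
shape-sensitive features are computed.  Zero-phase filtering squares the
magnitude response; the analytic response is used as the test oracle.

**Windows.** Five non-overlapping 3-minute tumbling windows, anchored to
end at the start of the prediction gap.  A record shorter than 15 minutes
is an error; a subject with any incomplete window in any channel is
excluded from the cohort rather than imputed.

**R-peaks and HRV.** The detector squares the differenced, band-passed ECG,
smooths it over 120 ms, thresholds at half the rolling 2-second 95th
percentile, enforces a 200 ms refractory period, and refines each peak to
the local ECG maximum.  All constants are keyword arguments.  HRV is the
series of successive peak-to-peak durations in seconds.  On synthetic ECG
at 10 dB SNR the detector's per-window recall and precision against the
generator's true beat times exceed 0.95 (verified in the test suite).

## Taut-string approximation

For a discrete signal `f` and tube half-width `eps`, the taut string is the
function `g` with `||f − g||_inf ≤ eps` minimising the Euclidean norm of its
first differences — the shape a string pulled tight between `f − eps` and
`f + eps` takes.  It simultaneously minimises every convex symmetric
functional of the increments, including the l1 norm of the second
differences.  The implementation is a corridor walk: from the last wall
contact the feasible straight-line slope wedge shrinks as points are read;
when it empties, the string bends at the wall point that pinched the wedge.
Both endpoints are free inside their tube intervals, so the string enters
and leaves horizontally unless a wall forces otherwise; when an entirely
straight horizontal string fits, its height is the midrange of `f` clamped
to the feasible interval, which also minimises `||f − g||_inf` among
minimisers.  The walk is `O(n)` in practice and is JIT-compiled (numba,
with a pure-Python fallback).  Correctness is cross-checked against an
independent box-constrained quadratic-program oracle (L-BFGS-B plus an
exact active-set polish) on hundreds of random instances to 1e-6.

Epsilon grids (5 values per family) are fixed: ECG and the wavelet family
0.0100–0.6000, HRV 0.0010–0.1000 (seconds), ABP 0.1–2.5 (mmHg), PPG 1–32
(arbitrary units).

## Dual-tree complex wavelet packets

A fully decomposed two-level packet transform is run on two parallel trees
whose filters form an approximate Hilbert pair, so corresponding
tree-1/tree-2 coefficients act as real and imaginary parts of complex,
near-analytic subband coefficients whose magnitudes are nearly
shift-invariant.

**Filter design.** The length-10 q-shift low-pass is built as
`h0 = conv(F, D)`: `F` is linear-phase symmetric with a zero at z = −1, and
`D` is a degree-2 fractional-delay factor fitted so that the allpass ratio
of its reverse to itself approximates a half-sample delay over the
passband.  The orthonormality (CQF half-band) conditions are four quadratic
equations in the free parameters of `F`, solved by least squares and then
polished by a least-norm Newton iteration directly on the filter to
~1e-15.  Tree 2 uses the time reverse of tree 1's filters, giving a
group-delay difference of 0.5 ± 0.02 samples over |ω| ≤ 0.45π.  Level 1
uses the same filter in both trees with a one-sample inter-tree delay
(standard dual-tree practice).  High-passes are quadrature mirrors with
delay parameter d = 9 (odd).

**Boundaries.** Periodization: each tree is then an exactly orthogonal
transform — perfect reconstruction at machine precision and exact energy
conservation, both of which the test suite asserts.  Signals whose length
is not a multiple of 4 are reflection-padded and the pad is recorded for
the inverse.  Subbands are ordered by frequency (Gray-code reordering of
the natural packet order).

## Feature families (5,150 scalars per subject)

Per epsilon and window: 6 morphological summaries of the taut-string
estimate of ECG and of HRV (segment count, mean/SD of segment slopes,
mean/SD of segment lengths, total variation); 21 distributional summaries
for ABP and PPG (mean, SD, median, min, max, skewness, excess kurtosis of
the estimate, its first and its second differences); and 152 statistics of
the level-2 packet coefficients of the taut-string ECG estimate (19
statistics of each of the 8 real sequences given by the real and imaginary
parts of the 4 complex subbands).  The Shannon entropy of an all-zero
subband is defined as 0; near-constant series get zero skewness/kurtosis
rather than catastrophically cancelled moments.  Totals: 5 epsilons x 5
windows x (6+6+152+21+21) = 5,150.

## EHR encoding

A configurable schema orders the columns: one-hot categorical statics
(unseen categories produce a zero group plus a warning, or an error in
strict mode), comorbidity flags, medication-category counts, and temporal
labs/vitals carried forward to each tumbling-window end with a per-window
missing indicator.  Carry-forward only ever looks backwards; a property
test perturbs future entries and asserts window values are unchanged.
Missing values default to NaN and are imputed with training-cohort medians
frozen in the model bundle.  The default schema shipped with the synthetic
generator has 542 columns (87 static, 5 medication counts, 45 temporal
fields x 5 windows x 2).

## Tensor formation and reduction

Per feature type, per-subject (5 x features x 5) arrays are standardized
entry-wise with training means/SDs (zero-variance entries get SD 1) and
stacked along a subject mode.  The wide types are compressed along the
feature mode by truncated HOSVD (mode-2 SVD of the unfolding), with core
feature dimensions DTCWPT 60, ABP 12, PPG 12 — chosen so the stacked
feature mode is 6+6+60+12+12 = 96 and the flattened subject vector is
96 x 4 = 384; the sizes are configurable.  ECG and HRV (6 features each)
enter unreduced.  The epsilon and window modes are never reduced.

The stacked (5 x 96 x 5 x N) tensor is factorized at rank r = 4 by CP-ALS
with random-normal, seed-controlled initialization, stopping when the fit
changes by < 1e-8 relative or after 500 sweeps; the objective is monotone
non-increasing by construction of the per-mode least-squares updates
(pseudoinverse of the Hadamard product of Gram matrices).  The epsilon
factor A (5 x r) and window factor C (5 x r) are reserved.  Any subject's
standardized, HOSVD-reduced (5 x 96 x 5) array S is projected to its
feature matrix by the closed-form least squares

    B = S_(2) (C ⊙ A)(AᵀA * CᵀC)⁺,

with ⊙ the Khatri–Rao product, * the Hadamard product and ⁺ the
Moore–Penrose pseudoinverse (numpy default tolerance).  Training subjects'
ML features are computed with this same projection rather than read off the
CP subject factor, so train and test vectors live in the same space; for a
training subject the projection residual can only improve on the CP
model's own slice reconstruction (asserted in the tests).

## Classifiers and evaluation protocol

Gaussian naive Bayes (no tuning); random forest (trees {50, 75, 100},
minimum leaf {1, 5, 10, 15, 20}, max-splits fraction {25, 50, 75, 100}% of
the training size mapped to a leaf-count cap, split criterion {Gini,
entropy}, predictors-to-sample 10..100 in tens); linear-kernel SVM with box
constraint C ∈ [1e-7, 1e12] and a kernel-scale γ ∈ [1e-12, 1e12] dividing
the inputs (20 log-spaced values each by default); and LUCCK with
similarity

    Q(x) = Π_i (1 + λ x_i²)^(−θ),   λ ∈ {0.01..0.10}, θ ∈ {0.1..1.0}.

LUCCK scores a point by the class-size-normalised positive similarity mass
m₊/(m₊+m₋), computed in log space (long feature vectors would otherwise
underflow); a shared scalar λ, θ is used for all features, matching the
scalar tuning grids.  The λ-factorised grid search reuses the pairwise
log-sums across all θ values.

Protocol: the training cohort is rebalanced to 0.35/0.65
positive/negative by discarding excess negatives (all positives kept;
negatives subsampled without replacement to ceil(n₊ · 0.65/0.35));
hyperparameters maximise mean validation AUROC over stratified 3-fold CV
(ties broken first-in-grid); the winner is refitted on all folds and scored
on untouched test cohorts; the whole loop repeats (101 times by default)
with reshuffled folds and re-drawn negative subsamples, reporting mean and
SD AUROC per model and cohort.  AUROC is the Mann–Whitney rank statistic
with midranks (exact under ties), tested against brute-force pair counting.
A `fast` flag shrinks the grids (random forest to 12 seeded points, SVM to
5 x 5, LUCCK to 5 x 5) for protocol-level experiments where the grid
content is not the question.

No artifact leaks from test data: standardization statistics, U matrices,
A/C factors, imputation medians, EHR scaling and hyperparameters are
functions of the training cohort only, and the suite asserts they are
bit-identical before and after transforming test cohorts.

## Shapley explainability

Model-agnostic permutation sampling: for each explained sample, random
feature orderings are walked from a background row to the sample, and
marginal score changes are credited to the switched feature.  Background
rows are cycled deterministically (up to 100 rows), which makes the
background average exact and the attribution of a linear model equal to
coefficient x (value − background mean) up to permutation noise only.
Local additivity (attributions sum to score minus base value) holds to
Monte-Carlo tolerance on every sample.  The report lists the 10 most
positive and 10 most negative mean attributions (ties broken
lexicographically by feature name) and can be rendered as a horizontal bar
chart.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes, not bedside
physiology in full.  ECG is a Gaussian-bump P-QRS-T template train with
beat-to-beat jitter; ABP/PPG are systolic-upstroke/dicrotic templates
phase-locked to the beats; white noise is added at 18 dB SNR by default.
Positives drift linearly over the span to +10·effect bpm heart rate,
(1 − 0.5·effect) R-R jitter SD, and (1 − 0.3·effect) pulse amplitude;
six EHR columns (HR, lactate, MAP, SBP, Hgb, cardiac index) shift with the
label; negatives are stationary.  A heterogeneity level widens subject
baselines and EHR distributions to emulate increasingly dissimilar test
cohorts; default cohort sizes and incidences (423/0.174, 66/0.212,
21/0.905) mirror a cardiac-surgery training cohort and two smaller,
more heterogeneous test cohorts.  Cohorts regenerate subjects on demand
from spawned per-subject seeds, so hundreds of waveform sets never sit in
memory at once, and everything is bit-reproducible from the spec seed.

What passing tests show: the planted pre-event drift is recoverable through
the entire taut-string → DTCWPT → tensor → classifier path (random-forest
mean test AUROC ≥ 0.85 at unit effect with 400/100 train/test subjects over
25 repetitions), and the pipeline does not hallucinate signal (null effect
stays within 0.45–0.55).  What they do not show: performance on real
monitor data, with its artifacts, arrhythmic morphology, lead changes and
label noise — none of which the generator simulates.

## Problem sizes used in the checks

Full-scale study conditions (15-minute spans at 240/120/120 Hz, five
3-minute windows) are used for the per-subject feature-count check and the
end-to-end planted-effect/null experiment (train 400 / test 100, 25
repetitions, reduced grids).  Property tests that probe scale-free
behaviour (effect-size monotonicity, bundle round-trips, leakage guards)
run on reduced conditions — 1-minute windows at 120/60/60 Hz and a few
dozen subjects — chosen as the smallest sizes at which the checked
properties are non-trivial.  `scripts/acceptance.py` recomputes the
headline quantities with the end-to-end experiment at train 220 / test 80
and 10 repetitions.

## Known limitations

* The 542-column EHR dictionary is illustrative; real deployments must
  supply their own schema (YAML) and vocabularies.
* The taut-string corridor walk restarts its scan at each new anchor;
  adversarial tubes could make this quadratic, though signal-like inputs
  are effectively linear.
* The q-shift filters are length 10 with a degree-2 delay factor; the
  Hilbert-pair approximation degrades above ~0.6π, which bounds the
  achievable shift-invariance of the highest subband.
* CP-ALS converges to a local minimum; the seed is part of the bundle and
  results are reproducible, but different seeds can give slightly
  different (equally valid) factorizations.
* Classifier scores are margins or similarity masses, not calibrated
  probabilities; only rank-based metrics (AUROC) are reported.
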