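# Methods

This note documents the models, parameter choices and numerical decisions
behind `mitransfer`, and what the synthetic experiments do and do not show.

## Pipeline model

The package classifies two-class motor-imagery EEG across subjects in three
stages: preprocessing (EOG removal, zero-phase 8–30 Hz Butterworth
band-pass of order 4 applied forward–backward, 0.5–3.5 s post-cue window
with half-open sample indexing, so a 3 s window at 250 Hz is exactly 750
samples), joint feature extraction (CSP + Welch band power), and
instance-transfer classification (KMM-seeded TrAdaBoost).  The assumptions
are the standard ones for sensorimotor-rhythm BCIs: the class signal is a
stationary, band-limited variance difference between the two conditions
(ERD), the labeling function is shared across subjects, and inter-subject
variability is a covariate shift of the feature distribution rather than a
label shift.

## CSP

Class covariances are per-class averages of trace-normalized trial
covariances `X Xᵀ / tr(X Xᵀ)`; normalization makes them invariant to
per-trial gain.  Whitening uses the eigendecomposition of `Hc = C1 + C2`
with the spectrum sorted descending and eigenvector signs fixed
(largest-magnitude entry positive), which makes the whitener deterministic
and diagonal for diagonal inputs.  The projection `W = Qᵀ R`
simultaneously diagonalizes both class covariances; eigenvalue pairs
satisfy `λ1 + λ2 = 1` per filter.  `m` defaults to 6 filters for montages
of ≥ 8 channels (4 below that, 2 for 3-channel montages), taken as `m/2`
from each end of the spectrum and ordered by `|λ − 0.5|`.  Features are
the ratio-normalized variances; no log transform is applied to this block
(the ratios are already bounded in (0, 1]).  Optional diagonal-loading
shrinkage (`γ·tr/k·I`, default off) handles rank-deficient montages.

## Welch band power

Periodograms use the convention `P(f) = |DFT(x·w)|² / (N·U·fs)` with
`U = mean(w²)` and one-sided folding, i.e. power spectral *density* in
power/Hz: the white-noise level is taper-independent and the one-sided
spectrum integrates to the signal variance (verified to Parseval within
2%).  Defaults: 250-sample (1 s) segments, zero overlap, Hamming taper —
three segments per 750-sample epoch and 1 Hz bin resolution, enough to
resolve the μ band.  Band features are the mean PSD over bins in
8–12 Hz and 13–30 Hz per channel, ordered channel-major.

## Joint feature assembly

The spectral block is log-transformed before standardization (EEG band
powers are strongly right-skewed; log power is the field's standard
variance-stabilizer).  Both blocks are z-scored per column with
training-set statistics, then rescaled so each block carries equal
aggregate variance while the total equals the plain z-score total
(block `k` scaled by `√(total/(n_blocks·width_k))`).  Without this, the
16-column spectral block dominates kernel distances over the 6-column
spatial block simply by width; preserving the total keeps the feature
scale that margin-based classifiers are calibrated to.  All statistics are
fit on source + target-train only; held-out target trials are only ever
transformed.

## KMM

The QP `min ½βᵀKβ − κᵀβ` with `κ_i = (n/p) Σ_j k(x_i^s, x_j^t)` is solved
under `0 ≤ β ≤ B` (B = 10) and `|Σβ − n| ≤ nε` (ε = 0.01); the literal
`β ∈ [0,1]` box is available as a preset (`upper_bound=1,
sum_tolerance=None`).  The kernel width defaults to the median pairwise
distance of the pooled features (seeded subsample of ≤ 1000 rows).

Two numerical points matter:

- **Ridge.**  The Gaussian kernel matrix is effectively low-rank, so the
  MMD minimizer is far from unique: with only a positive-definiteness
  jitter, general-purpose solvers return bang-bang vertex solutions whose
  weights are dominated by null-space noise (effective sample size ~13% of
  the source, Spearman correlation with the true density ratio as low as
  0).  A ridge term `λI` on `K` (default `λ = 1`) selects the smooth
  minimum-norm minimizer.  The default was calibrated against two
  diagnostics with known ground truth: recovery of the analytic density
  ratio for N(0,1) → N(0.5,1) (ρ ≈ 0.87 at λ = 0.01 vs ≈ 0.995 at λ = 1)
  and near-uniform weights when source and target distributions are
  identical (weight variance 6.3 → 1.4).  A post-solve guard returns the
  feasible uniform start in the rare case ridging worsened the raw MMD, so
  the returned objective never exceeds the uniform-weight MMD.
- **Solver.**  A monotone FISTA (accelerated projected gradient) with the
  Lipschitz step `1/λ_max(K)`; projection onto the box-plus-sum-band set
  reduces to a scalar bisection.  Convergence: relative objective change
  below 1e-13 over 50-iteration windows, 20 000 iteration cap.  Agreement
  with an independent SLSQP solve is ~1e-8 in objective at n = 480, at
  roughly 5× less runtime.

## TrAdaBoost

Internal labels are {0, 1} (API labels {1, 2} restored at prediction).
Initial weights: uniform `1/n` source, `1/m` target, or the KMM vector
normalized to unit source mass (uniform KMM weights reproduce the uniform
initialization bit-exactly).  Per round, weights are normalized to a
distribution for the weak-learner fit; the error `ε_t` is measured on the
target-train portion with the *unnormalized* target weights.  `ε_t = 0`
floors `β_t` at 1e-10; `ε_t ≥ 0.5` stops early, keeping completed rounds;
if the *first* round already fails the error contract (plausible with ~9
labeled target trials) the model keeps that single hypothesis with its
error capped at `0.5 − 1e-6` and carries an under-trained warning, so a
cohort sweep cannot be killed by one degenerate fold.  Prediction votes
over iterations `⌈N/2⌉ … N` with weights `ln(1/β_t)`; ties go to the
positive class.

**Weak learner.**  The default is a weight-sensitive linear SVM.  A
depth-2 decision tree — the more common TrAdaBoost choice — interpolates
the small target-train set when fit on the pooled data, driving `ε_t` to 0
every round: `β_t` hits the floor, the weight dynamics freeze, and the
ensemble collapses to a single hypothesis (observed as boosting scoring
~10 points *below* the weight-free SVM baseline).  The linear margin keeps
the target-error signal informative; tree and stump presets remain
available.

## Synthetic cohorts

Each trial is a sum of band-limited μ and β oscillations (3 and 5
sinusoids at random in-band frequencies and phases; summed band variance
`amp²/2`, amplitudes 1.0 and 0.6) on latent channels, mixed through a
subject-specific orthogonal matrix, plus white noise.  Class 1 attenuates
the μ amplitude on one latent-channel subset by `1 − erd_depth`; class 2
attenuates a disjoint subset — so the μ-band variance ratio between
classes on those channels is analytically `(1 − erd_depth)²`, which the
tests verify by unmixing.  Mixing matrices come from sign-fixed QR of
seeded Gaussian matrices; per-subject perturbations of scale
`subject_shift_sd` are re-orthogonalized, so shift changes orientation,
not total power.  Generation is bit-reproducible from the seed,
per-subject independently of cohort order.

Defaults emulate a 9-subject, 72-trials-per-class, 250 Hz study with 3 s
epochs on an 8-channel montage (22 by configuration).  `erd_depth = 0.5`,
`noise_sd = 2.0` and `subject_shift_sd = 0.4` were chosen once so that the
cross-subject baselines land in the 55–75% accuracy range reported for
real motor-imagery cohorts (our LOSO means: CSP+SVM ≈ 66%, PSD+SVM ≈ 60%,
joint+SVM ≈ 68%) rather than at a ceiling that would make all pipelines
indistinguishable.

What the generator does *not* model: 1/f background spectra, artifacts,
within-trial nonstationarity, volume-conduction geometry (mixing is dense
orthogonal, which spreads the ERD power shift nearly uniformly across
sensors, making channel-wise PSD features weaker and more draw-dependent
than on real recordings), or label noise.  Passing tests therefore show
the pipeline's mechanics and relative orderings under controlled covariate
shift — not expected accuracy on real EEG.

## Evaluation design and problem sizes

Transfer experiments pool eight subjects as source, split the target 20%
train / 80% test (stratified, seeded), and report confusion-count accuracy
`(TP+TN)/(TP+TN+FP+FN)` pooled over seeds (class 2 positive).  Comparisons between pipeline
variants average LOSO means over ten independent cohort draws (seeds
0–9 in the test suite, derived from `--seed` in the acceptance script)
with one split seed each: the dominant variance component is the cohort
draw (how the random mixing projects the ERD onto sensors), so averaging
over draws, not over splits of one draw, is the meaningful design.  The
test and acceptance harnesses use 24 trials per class (instead of the
default 72) and 4-subject cohorts for the chance-floor (`erd_depth = 0`;
the acceptance script averages it over four independent cohort draws, as
floor estimates from one draw are strongly correlated across folds and
modes) and ceiling (`erd_depth = 0.7`, `noise_sd = 0.5`, zero shift)
sanity checks; these sizes are the package's chosen evaluation scale and
are stated alongside every reported number.

## Known limitations

- The observed advantage of KMM-seeded over uniformly-initialized
  TrAdaBoost on synthetic cohorts is small (fractions of a percentage
  point on average) — consistent in direction with, but far weaker than,
  differences reported on real competition data, where inter-subject
  structure is richer than an orthogonal rotation.
- KMM assumes covariate shift only; it cannot correct label-conditional
  shift.
- The QP solver is dense (`O(n²)` memory in source trials); cohorts beyond
  a few thousand source trials would need a landmark approximation, which
  is out of scope.
- Multi-class extensions (one-vs-rest CSP, multi-class boosting) are not
  implemented.
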