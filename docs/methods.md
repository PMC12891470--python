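# Methods

This note documents the models, conventions and design choices behind
`gaitstab`, the way the synthetic cohorts are constructed, and what the
test suite does and does not demonstrate about real data.

## Signal model and gait events

The synthetic trunk signal is a sum of cosines at integer multiples of the
stride frequency evaluated on a piecewise-linear per-stride phase, so that
cycle-to-cycle timing jitter (multiplicative SD on stride duration) blurs
the spectrum the way real gait variability does. Anteroposterior (AP) and
vertical (VT) templates concentrate amplitude at even stride harmonics
(step frequency); mediolateral (ML) at odd harmonics. Additive white noise
is configured per group and surface. Stroke-like subjects walk slower
(0.75 ± 0.18 m/s vs 1.20 ± 0.12 m/s), with more jitter (0.05 vs 0.02),
more noise, ~35% larger harmonic amplitudes, and an `odd_weight`
parameter ≈ 2.6 (vs 1.0) that degrades the AP even/odd structure — together
these reproduce, at the signal level, the group differences the tabular
generator injects directly (higher RMS and SampEn, lower HR_AP in the
stroke-like group).

Initial contact (IC) is a prominent positive peak of the shank AP
acceleration; toe-off (TO) the deepest trough between consecutive ICs
(searched in the middle 30–90% of the interval). Peak detection uses a
minimum distance of half the estimated stride period and a prominence of
0.5× the MAD-based robust SD, followed by a height refinement that drops
candidates below half the median detected peak height (noise maxima between
steps). Parameters are recorded in the event metadata. Ground-truth event
times from the generator replace video verification; detection F1 against
them exceeds 0.95 across 50 synthetic subjects at default noise.

The first and last three cycles of each pass are trimmed as
acceleration/deceleration transients (a trimmed recording must retain at
least two cycles); ten consecutive cycles are analyzed. The sampling rate
defaults to 100 Hz (configurable); acceleration is in m/s².

## Stability metrics

All metrics demean their window first, making them offset-invariant.

* **RMS** — √mean(x²) of the demeaned window, divided by gait speed
  squared (speed from a 10 m traverse time). Scales linearly with signal
  amplitude by design; everything else is amplitude-invariant.
* **Harmonic ratio** — amplitudes at the first 20 integer multiples of the
  stride frequency (window duration / cycle count) by direct DFT
  evaluation at each harmonic; harmonics above Nyquist contribute zero. AP
  and VT use Σ even / Σ odd, ML the inverse. A numerically zero
  denominator yields `inf`, flagged as a missing value downstream.
* **Sample entropy** — m = 2, r = 0.2·SD, Chebyshev distance, self-matches
  excluded, −ln(A/B) over the N−m templates; a constant series returns 0
  and B = 0 returns NaN. The implementation is vectorized but matches a
  double-loop oracle exactly.
* **RQA** — time-delay embedding (dimension 5, delay 10 samples),
  Euclidean recurrence with radius 0.4× the RMS amplitude of the centered
  embedded trajectory, Theiler window equal to the delay. %REC is the
  recurrent fraction of admissible pairs; %DET the fraction of recurrent
  points on diagonal lines of length ≥ 2, computed over diagonals long
  enough to host such lines (so a fully recurrent constant series scores
  exactly 100).
* **sLE** — Rosenstein estimator on the time-normalized window
  (100 samples/stride, removing the speed/cadence confound): delay
  embedding (5, 10), nearest neighbor with a temporal exclusion of one
  mean period, mean log-divergence curve, least-squares slope over the
  first half stride, expressed in nats/stride. Log distances are floored
  at 1e−12 so duplicate trajectories give a flat curve (sLE ≈ 0) instead
  of −∞.

Six metrics × three axes gives the 18 canonical features
(`RMS_VT`, `SampEn_AP`, …); the feature table accepts additional
configurable columns. Metrics are computed on the single instrumented
(paretic-side-referenced) window.

## EMG and kinematics

EMG envelopes: bandpass 20–500 Hz (clipped below Nyquist with a warning at
low sampling rates), mean-centering, full-wave rectification, 10 Hz
lowpass, normalization to the subject maximum. A signal whose envelope is
numerically zero (e.g. pure DC) raises a normalization error. The
co-contraction index is the Falconer–Winter-style overlap
CI = 100·2·Σ min(e₁,e₂)/Σ(e₁+e₂), evaluated separately over stance and
swing (split at toe-off); it is symmetric and invariant to common scaling.
Joint angles are lowpass-filtered at 6 Hz with an order-2 Butterworth
applied forward and backward (zero-lag, effective 4th order), cycle curves
are 100-point normalized averages, and named extrema always include the
angle at initial contact (`Ang_IC_ankle` = curve[0]).

## Tabular preprocessing

Per column: IQR outlier replacement (values outside [Q1 − 1.5·IQR,
Q3 + 1.5·IQR], linear-interpolation quartiles, replaced by the
pre-replacement median, computed pooled across groups), then Yeo–Johnson
power transformation (λ by maximum likelihood), then z-scoring. Order
follows the sentence order of the prescription: outliers → power →
z-score. All parameters are fit on the training split and reapplied —
fences, median, λ, mean, SD — to held-out data; `TablePreprocessor`
serializes them to JSON for audit. The experiment runners expose a
`preprocess` switch because a perfectly linear synthetic relationship is
only preserved exactly when the (nonlinear) Yeo–Johnson step is bypassed.

The design-stage power computation inverts the noncentral-t power function
of the two-sided two-sample t-test (equal groups), returning the smallest
integer n per group reaching the target power: d = 0.5, α = 0.05,
power = 0.8 gives n = 64.

## Feature selection

Boruta: per iteration, every feature gains shuffled shadow copies, a
random forest (Gini importance, √p feature sampling) is fit on
[real | shadows], and a feature scores a hit when it beats the maximum
shadow importance. Hits are tested against Binomial(iterations, ½)
two-sidedly with Bonferroni correction over features; iteration stops
early once no feature is tentative. Two stabilizers matter at cohort
scale (n ≈ 110–150): the number of shadow copies sets the null bar (more
copies → fewer chance confirmations of noise features that are
coincidentally correlated with the outcome in a finite sample), and the
number of trees sets the importance stability (more trees → weak true
effects resolve instead of idling tentative). Defaults are 500 trees and
one shadow copy (the canonical algorithm); the repeated-seed experiment
configurations used by the acceptance checks are recorded in their calls.

LASSO: cross-validated L1 logistic (deviance) or linear (MSE) path;
`lambda_min` rule by default, `lambda_1se` available. On orthonormal
designs the path equals the soft-threshold closed form to 1e−6
(verified against that closed form in the tests).

Consensus is the strict intersection of Boruta-confirmed and
LASSO-selected sets; tentative features do not count. An empty consensus
is allowed but flagged.

## Augmentation

All augmenters see the standardized training split only; synthetic rows
carry `is_synthetic=True` and are excluded from every evaluation. Inside
the hyperparameter grid search, folds are drawn over real rows and each
fold's training portion is augmented independently, so synthetic instances
never cross folds.

* **SMOTE** — convex interpolation toward one of k = 5 nearest
  same-class neighbors; every synthetic row lies on a segment between two
  real rows (verified by a brute-force oracle). `balance100` grows the
  minority class to 100; `N200`/`N1000` add that many rows in total,
  equalizing class counts first.
* **GAN / ctGAN** — a deliberately small adversarial pair (one hidden
  layer of 32 units per network, latent dimension 8, Adam 1e−3,
  non-saturating loss, 200 epochs, manual numpy backprop). `gan` trains a
  pair per class; `ctgan` trains one pair with a one-hot class condition
  appended to both networks. Generator outputs receive a per-feature
  affine calibration to the class's training marginal mean/SD (an output
  standardization computed from a large generated sample); a quality gate
  warns when a check sample misses any marginal by more than 0.5 training
  SDs. Per-feature Kolmogorov–Smirnov distances to the training marginals
  stay below 0.3 on the default cohort. Sampling is seeded; training is
  deterministic given the seed in a single-threaded numpy.

## Experiments

Per repeat seed (base 42): stratified 80/20 split, preprocessing fit on
train, augmentation of train, 5-fold grid search scored by ROC AUC
(classification) or MSE (regression), refit on the full augmented train,
evaluation on the untouched test rows. Classification metrics: ROC AUC
(pairwise ranking with 0.5 tie credit — cross-checked against
scikit-learn), sensitivity/specificity/F1 at a 0.5 probability threshold,
Brier score. Regression: R², RMSE, MAE, MSE. Reports keep per-repeat raw
rows; summary means are exactly the arithmetic means of the raws. Model
families: logistic regression, decision tree, SVC, XGBoost, random
forest, KNN (classification); linear, SVR, elastic net, random forest,
gradient boosting, KNN (regression). Grids are package defaults exposed in
`default_*_plan`; a `compact` variant (logistic + SVC + random forest for
classification, linear + random forest for regression, minimal grids)
serves the repeated-seed experiments where runtime matters.

## sPLS-DA

NIPALS PLS2 against the centered one-hot class matrix; each iteration
soft-thresholds the X-weight vector so exactly `keepX` (default 4)
features stay nonzero, then normalizes it. Deflation uses X-loadings (so
score vectors are orthogonal and X is exactly reconstructed from scores,
loadings and residual) and Y-regression coefficients. With keepX = p the
first component equals dense PLS to 1e−6. Class scores for AUC are
centroid-distance differences in the cumulative score space. VIP uses the
explained-Y-variance weights SSₐ = (cᵃ·cᵃ)(tᵃ·tᵃ); since weight vectors
are unit-norm, mean(VIP²) = 1 exactly over all p features, and a
single-feature component yields VIP = √p for that feature. keepX is not
tuned by default.

## Interpretation

Partial dependence sets one feature to each grid value (default: 30 points
over the 5th–95th percentile range) and averages predictions. Shapley
attributions use permutation sampling with a fixed background sample:
along each sampled feature ordering the marginal contributions telescope
from the background expectation to f(x), so Σφ = f(x) − E[f] holds exactly
for any number of permutations; sampling only affects the split of credit.
Curve-shape estimators: a continuous two-segment least-squares changepoint
search (breakpoint), the leading coefficient/vertex of a fitted parabola
(U-shape), and the mean over the rightmost quarter of the grid (plateau
level).

## Synthetic regression cohort

Even-surface predictors (speed uniform on 0.3–1.3 m/s, ankle IC angle
N(5°, 6°), HR uniform on 0.8–2.2, plus nuisance columns) generate
uneven-surface targets embedding: a continuous piecewise-linear speed map
with a kink at 0.8 m/s (extra slope 0.5 below it), an RMS_VT level that is
elevated and flat below the breakpoint, SampEn_AP quadratic in the ankle
angle (coefficient 0.004/deg², minimum at 5°), and
HR_uneven = min(HR_even, 1.5) + noise. Noise SDs (0.06, 0.15, 0.10, 0.08
respectively) were chosen so the linear gait-speed model attains R² ≈ 0.9 —
the high-predictability regime — while the entropy target stays modest,
mirroring the relative difficulty ordering of the four outcomes. All
parameters are returned for recovery testing; a brute-force changepoint
fit recovers the breakpoint within ±0.1 m/s at n = 200.

## Problem sizes used by the checks

Repeated-seed experiments are scaled to keep the suite practical while
leaving the statistical conclusions intact: event-detection F1 uses 50
(tests) / 30 (acceptance script) subjects; classification experiments use
10 repeats of the compact plan; the null uses 10 fresh label permutations
(one repeat each — a single frozen permutation retains chance feature–label
association and is not a proper null); consensus recovery and null
selection use 25 cohort seeds / 20 null runs with 60 Boruta iterations and
100-tree forests; interpretation uses a 300-tree forest on n = 200 with
40-point PDP grids, a 30-row Shapley background and 4 permutations.

## Selection power at the cohort scale

Two statistical facts about the shadow-feature wrapper at this sample size
are worth stating because the recovery tests measure them directly. First,
with ~110 subjects the realized (sample) effect size of an injected d = 0.7
feature varies by roughly ±0.2 between cohorts; a feature drawn at
d̂ ≈ 0.45 beats the maximum shadow importance in well under the sustained
majority of iterations that the binomial confirmation rule requires, so
Boruta leaves it tentative while the L1 path still selects it. The strict
consensus (tentative = not selected) therefore recovers all five injected
features in only a minority of cohorts, even though four of five are
recovered almost always. Second, on finite pure-noise data (n = 150, 10
features) a sizeable fraction of draws contain a feature whose realized
correlation with the random labels reaches |r| ≈ 0.2; that association is
frozen in the dataset — every Boruta iteration re-measures it rather than
providing independent evidence — and any consistent importance measure
confirms it as relevant to that sample. Raising the shadow bar (multiple
shadow copies) or switching to held-out permutation importance cleans the
null but suppresses the weak true effects even harder. These are power
properties of the selection problem, not implementation artifacts, and the
corresponding acceptance checks document the measured rates.

## Known limitations

The generators emulate the statistical structure the analysis assumes —
harmonic spectra, injected mean shifts, smooth nonlinearities — not real
physiology: no asymmetry between paretic/non-paretic sides, no cane or
orthosis effects, no nonstationarity within a pass, feature correlations
are near zero by construction, and uneven ground is represented only as
parameter shifts. Passing tests therefore certify the *computations*
(metrics, selection, augmentation harness, evaluation protocol,
interpretation recovery), not clinical performance on real cohorts.
GAN determinism is best-effort (seeded, single-threaded); SVC probability
calibration uses internal cross-validation and is the least reproducible
model across library versions.
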