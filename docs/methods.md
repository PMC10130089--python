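# Methods

This note documents the modeling choices behind `sibamod`: what each stage
assumes, which parameters matter and why their defaults are what they are,
what the synthetic cohorts do and do not emulate, and the numerical
conventions that make runs reproducible.

## The per-patient pipeline

### Labels: extension and optimistic detrending

MADRS is observed once a month; physiology daily.  Each visit score is copied
to the ±5 days around it (`extension_window`, default 5), resting on the
scale's high short-term test–retest reliability.  Overlapping windows resolve
to the nearest visit; exact ties go to the earlier visit, so the rule is
deterministic.

Raw MADRS trajectories are non-stationary — most treated patients improve —
so the regression target is detrended with an *optimistic* recovery model

    M̂(t) = M_v · (1 − λ/100)^(t − t_v),

a daily multiplicative decay toward 0 anchored at the most recent clinical
evaluation, with λ expressed in percent per day so that typical fitted values
sit near 1–2.  Multiplicative decay (rather than linear) keeps predictions in
range for any horizon and makes λ scale-free; whether the decay should target
0 or a healthy floor (say MADRS 6) is not identifiable from desk-scale
experiments, so the asymptote is exposed as `OptimisticModel.decay_target`
(default 0), and a linear-decay alternative (`form="linear"`, a fixed
fraction of the anchor score shed per day) is available for comparison.

Anchoring conventions, chosen so residuals are informative and test-time
inference is causal:

* During training, days in visit v's window anchor at the latest visit
  strictly *before* v (baseline anchors itself, making residuals near
  enrollment ≈ 0).  The residual then measures the departure from the
  recovery predicted at the previous evaluation.
* At test time every day anchors at the last training (month-3) visit; no
  clinical information after month 3 is consumed.
* Each residual stores its anchor, so detrend→retrend is algebraically exact
  (the round trip is asserted to 1e-12 in the tests); prediction-time
  retrending is a separate function that applies the available-visit rule.

### Preprocessing

Pipeline order is fixed: mean filter → interpolation imputation → min-max
normalization.  The smoothing window (3 days, odd, configurable) is the
smallest that suppresses single-day outliers without erasing weekly
structure.  Imputation is linear in the day index with nearest-value fill at
the series edges; a feature with no observations at all is an error, not a
guess.  Normalization maps each feature to [0, 1] independently.

Normalization is fitted on the training period only (days up to
`train_end_day + extension_window`) and applied with clipping afterwards;
fitting it on the whole series would leak test-period ranges into the model.
Fit-time preprocessing (including the smoothing and imputation passes) runs
on the series truncated at that boundary, so the fitted bundle is bitwise
independent of anything recorded later — an invariant the test suite asserts
by mutating the tail and comparing serialized bundles.  A `normalize_on=
"full"` switch reproduces the leaky whole-series variant for comparison.

### Biosignature selection

Each feature is scored against the extended *absolute* MADRS values on the
labeled training days with the biased empirical HSIC,

    HSIC(x, y) = (n − 1)^-2 · tr(K H L H),

with Gaussian kernels and per-variable median-heuristic bandwidths (median of
pairwise absolute differences; 1.0 fallback for constant input).  HSIC is
zero in expectation iff the variables are independent and, unlike
Pearson/Spearman coefficients, detects non-monotone dependence — the reason
it is the selector here.  The normalizing constant cancels in ranking, which
is all selection uses.  Ties break by ascending feature index, so selection
is deterministic, and the top-ν set for any ν is a prefix of one full
ranking (computed once per patient and reused across a hyperparameter grid).
Two ablation switches exist: a top-ν absolute-Pearson selector, and
`select_on="residual"`, which ranks features against the λ-detrended
residuals instead of the absolute scores.

### Residual regression

The regressor is an MLP with hidden layers (8ν, 4ν, 2ν), rectifier hidden
units and a linear scalar output, trained to minimize MSE with plain
minibatch SGD: batch 16, at most 500 epochs, early stopping after 5 epochs
without validation improvement (min-delta 0), best-validation weights
restored.  The learning rate (0.01) and the 80/20 day-level validation split
are exposed in configuration; the split is drawn once per patient and shared
by all repeats, so repeats differ only in initialization.  Targets are
residual MADRS in raw points (no target scaling), so the loss is in MADRS².

The fit is repeated 11 times (seeds `base+0 … base+10`) and the prediction is
the element-wise member median, which tolerates up to five aberrant members.
A member that diverges under SGD (loss turns non-finite) simply stops
improving, keeps its best finite-loss weights, and is absorbed by the median.

The trainer is written directly in numpy: the networks are tiny, and the
contract here — caller-supplied validation set, restore-best-weights
semantics, bitwise determinism from a seed — is the point.  Member i draws
initialization (He-normal) and per-epoch shuffles from its own
`default_rng(seed_i)` stream, so the stacked-tensor joint training the module
uses is bit-identical to training each member alone (asserted in the tests).

### Hyperparameter search and evaluation

(λ, ν) are selected by grid search with leave-one-patient-out: every pair is
fitted per patient on its training months and scored by binary accuracy on
its extended test labels; the pair assigned to patient p maximizes the mean
accuracy over patients ≠ p (patients weighted equally), with ties going to
smaller ν, then smaller λ.  The default grid, λ ∈ {0, 0.4, …, 2.8} percent/
day × ν ∈ {5, 10, 20, 40, 62, 80, 101}, brackets the clinically plausible
range while staying desk-scale.  Ensemble seeds derive from (run seed,
patient) only, so all grid cells share initialization draws — common random
numbers — and the accuracy surface reflects (λ, ν) effects rather than
per-cell initialization luck.  A `global_selection` helper implements the
no-LOPO variant (one pair maximizing mean accuracy over *all* patients); it
is leaky by construction and labeled as such.

Severity classes follow the clinical stratification — no depression 0–6,
mild 7–19, moderate 20–34, severe ≥ 35 — with the binary merge healthy
(< 20) / ill (≥ 20), positive class ill.  Real-valued predictions are
classified at the half points 6.5/19.5/34.5, which reproduces the integer
thresholds exactly on integer labels.  Accuracies and confusion matrices
pool labeled test days across patients (a per-patient breakdown is emitted
alongside); MAE is averaged per patient first and its 95 % confidence
interval is a Student-t interval treating each patient as one sample.
Unlabeled days appear in the daily curves but never in metrics.  Two
baselines frame every report: the constant predictor (majority training
class / mean training MADRS) and the optimistic model alone (residual ≡ 0).

## The synthetic cohort generator

The generator produces the statistical structure the pipeline assumes, with
known ground truth, under a single hierarchical seed (cohort → patient →
component), so cohorts are byte-reproducible.

**Severity.**  `s(t) = s₀ (1 − λ_true/100)^t + relapse + AR(1) noise`,
clipped to [0, 60].  Defaults: baseline s₀ ~ U(20, 42) (outpatient inclusion
range), λ_true = 1.6 %/day, AR(1) innovation 2.0 MADRS points with
persistence 0.8 — day-to-day mood wobble with week-scale memory.

**Relapse.**  A cohort of uniform recoverers spends months 4–6 entirely in
the healthy class, which matches neither real outpatient cohorts (roughly
half of observed days above the ill threshold) nor the needs of a classifier
test, so relapse is on by default: half the patients relapse (logistic rise
of 35 points over ~4 days).  Three-quarters of relapsers re-respond to
treatment — the episode decays again at λ_true as soon as the rise completes,
so their post-relapse trajectory is once more a clean λ_true decay — and one
quarter are non-responders whose elevation persists.  Onsets are spread
evenly across days 55–105 (with jitter) rather than drawn independently:
8-patient cohorts otherwise wobble between all-early and all-late relapse
compositions, and the quantity of interest (how the accuracy surface ranks
λ) depends on that composition, not just its expectation.  The non-responder
is the relapser just before the latest onset, so its elevation is visible at
the month-3 anchor and persists through the test period.  This composition
is what makes the recovery rate identifiable at all: λ only affects binary
accuracy through trajectories that cross the ill/healthy boundary during the
test months with an elevated month-3 anchor — too-small λ then predicts ill
after the patient has recovered, too-large λ predicts recovery in
non-responders.

**Features.**  Planted features (10 by default) carry the severity signal
through link functions cycling over identity, negation, saturation
(1 − e^(−3u)) and a threshold step — the nonlinear links are deliberate, so
that an HSIC selector is distinguishable from a linear-correlation one.
30 % of planted features encode a half-level, half-7-day-change latent:
physiology reflects the direction of a mood shift as well as its state, and
without such features a relapse in progress is indistinguishable from an
equally severe stable baseline, leaving the regressor with contradictory
training targets.  Decoys are smoothed noise with weekly rhythm.  Each
feature gets a random affine scale (normalization undoes it).  Device-off
gaps of 1–3 days blank whole rows at a configurable rate (default 5 % of
days).  Half the cohort shares a planted core (default), so cohort apparition
histograms show features selected by several but not all patients.

**Visits.**  Monthly (days 0, 30, …, 180, clipped into the study), scored as
round(s) plus integer observation noise in {−2…2} (consistent with the
scale's high interrater reliability), baseline forced to ≥ 20 (inclusion
criterion; the adjustment is flagged in the ground truth).

**What passing tests show — and don't.**  The simulator demonstrates that the
implementation recovers planted structure (signature recall ≈ 0.9; modal
selected λ within one grid step of λ_true; model strictly above the
optimistic baseline with ~0.87 pooled binary accuracy on low-noise cohorts).
It does not emulate circadian physiology, treatment changes, device drift,
informative missingness, or inter-patient feature correlation, so these
numbers say nothing quantitative about clinical data.

## Numerical conventions and degenerate inputs

* HSIC values are floored at 0 (the biased estimator can go ~−1e-16).
* Constant features: bandwidth falls back to 1.0; normalization maps them to
  0 and flags them degenerate.
* Predictions are clipped to [0, 60] and reported as reals; classification
  applies to the unrounded value.
* Binary rates with an empty stratum are reported as missing, not 0.
* All derived seeds come from `stable_seed` (BLAKE2 hash, 31-bit), so results
  are independent of iteration order and safely below RNG seed limits.
* Problem sizes in the shipped experiments (8-patient cohorts, 3–5 cohort
  replicates, reduced grids) are the package's desk-scale defaults; every
  size is a parameter.

## Known limitations

* **λ is only weakly identified near its optimum.**  Residual learning
  partially compensates a mis-set detrending rate (a biased optimistic curve
  yields systematically biased residuals, which the regressor absorbs), so
  the LOPO accuracy surface has a broad plateau across neighboring λ values
  and the argmax within the plateau is sensitive to label noise.  The
  recovery test therefore asserts the modal selection to within one grid
  step, not exact recovery.
* **Per-patient models cannot anticipate unseen phenotypes.**  A relapse
  whose onset lies entirely after month 3 is invisible to that patient's
  training data; the model then inherits the optimistic baseline's miss.
  Likewise the magnitude of a sustained non-response is under-predicted at
  long horizons because the learned residual cannot grow with the forecast
  horizon.  These failure modes cap pooled desk-scale accuracy around 0.9
  and are the price of strictly per-patient training.
* **Label extension is wrong during fast dynamics.**  Copying a visit score
  across ±5 days mislabels days around a relapse onset by several points,
  adding irreducible target noise exactly where prediction matters most.
* The MAE confidence interval assumes approximate normality of patient-level
  MAEs; with few patients it is indicative only.
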