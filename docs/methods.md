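# Methods

## The model

The package treats the mapping from regional brain morphometry to
cognitive performance — the structure–function association (SFA) — as a
cohort-specific linear model. For each diagnostic cohort
*g* ∈ {CN, MCI, Dementia}, each test
*t* ∈ {MMSE, ADAS-13, RAVLT-immediate, TMT-B, DSST} and each feature
family (VBM volumes, SBM thickness/area, or both), a ridge regression

  ŷ = b + wᵀ z(x),  w = argmin ‖y − Zw − b‖² + α‖w‖²,  α = 0.5

is fitted on that cohort's visits, where z(·) z-scores each feature on
the training sample (ridge is not scale-equivariant, so comparable
feature scales are a prerequisite; the penalty never touches the
intercept, so the training-mean feature vector maps to the intercept
exactly). Volumes enter as bilaterally averaged percentages of total
intracranial volume; thickness (mm) and surface area (mm²) enter in
native units.

Screening inverts the regression bank: for a new subject, each cohort's
model predicts each test score, and the absolute residual
|ŷ_g − y| measures how well cohort *g*'s SFA "stamp" fits the subject.
The minimal residual casts that test's vote; the modal vote over the
battery is the label. Predictions are deliberately not clipped to the
scale bounds — clipping would collapse residual differences exactly where
the cohorts separate (e.g. near the MMSE ceiling).

Two tie-breaks are needed and neither is canonical, so both are fixed
and documented: per-test residual ties resolve toward the less severe
label (CN > MCI > Dementia preference — for a screening tool the
conservative error is under-staging, which later assessment catches);
split votes resolve to the vote with the smallest range-normalised
residual, range-normalisation making residuals comparable across scales
whose sizes differ by an order of magnitude.

The default vote battery is {MMSE, ADAS-13, RAVLT}. The two
processing-speed tests are excluded from the default because their
cohort trendlines converge late in life (see below): as the lines
approach, the three models' predictions approach each other and the
minimal-residual vote degrades toward noise, which is visible even in
the noise-free limit, where a dementia subject of the right age can sit
exactly on the CN model's extrapolation. The battery is a parameter;
the five-test variant is reported alongside in the analysis scripts.

## Evaluation protocol

Regression error is summarised by subject-grouped repeated k-fold
cross-validation (default 10×10; the analysis scripts use 5×2 to keep
runtimes in seconds). All visits of one subject share a fold. Reported
are the mean fold MAE, the standard error of fold MAEs, the 95% CI
(mean ± 1.96·SE), and MAE as a percentage of the test's **empirical**
pooled range (max − min over all cohorts). The empirical rather than
nominal range is used because the published MAE / (MAE/range) cell pairs
imply ranges well below nominal (≈18 MMSE points rather than 30); the
nominal `TestScale` range remains available as a fallback. The
classifier is evaluated with subject-grouped 5-fold refits and a strict
train/evaluation subject-disjointness check (`LeakageError`, explicitly
overridable).

Feature relevance is ranked by impurity importance averaged over four
tree ensembles (random forest and extra trees at 500 trees, gradient
boosting at 300 stages, AdaBoost at 100), each importance vector
normalised to sum to one before the mean; the fusion rule (arithmetic
mean) and the hyperparameters are package choices — no canonical
convention exists for either.
Columns are canonicalised by name before fitting so the ranking is
invariant to input column order. Region–score association is Pearson
correlation per Desikan–Killiany cortical volume, uncorrected p < 0.05
by default with an optional Benjamini–Hochberg flag.

Age trends are OLS per cohort (age centred at the pooled mean for
stability; intercepts reported on the age-0 scale so two fits intersect
at (b₂−b₁)/(s₁−s₂)). Slope differences between cohorts come from an
age×group interaction OLS on the two-cohort subset, which by the
interaction coding equals the difference of separate slopes exactly.
Cohort comparisons use Kruskal–Wallis for continuous variables and the
chi-square contingency test for categorical ones — the conventional
pairing, adopted deliberately.

## The synthetic cohorts

The generator (`synthetic_data`) is the testbed: three cross-sectional
cohorts with a planted, fully known SFA structure.

* **Ages** are uniform on 55–90 — the recruitment range, not the
  empirical quartiles.
* **Trendlines.** Score *t* in cohort *g* has population line
  intercept_g,t + slope_g,t·(age − 72.5). Slopes are the published CN
  estimates, with MCI/dementia slopes equal to CN plus the published
  age×group interaction coefficients; MMSE/ADAS trends are therefore
  flat, DSST/TMT decline. Intercepts equal the published cohort means
  for MMSE/ADAS/RAVLT. For the converging tests (DSST, TMT-B) the CN
  line is anchored at the CN mean and the MCI/dementia intercepts are
  *derived* from concurrency of the three lines at `convergence_age`
  (100 years): the published means and slopes are not jointly consistent
  with exact concurrency, and the convergence geometry is the behaviour
  the trend analytics must detect, so it wins for those two tests. The
  main casualty is the synthetic dementia TMT mean (150.6 s rather than
  201 s).
* **Morphometry.** A latent atrophy burden A = base_g +
  γ_g·(age − 72.5) + ε drives all features; γ_g are the published
  GM/TIV-per-year slopes, base offsets (0 / −2 / −4 %TIV) stage the
  cohorts, ε ~ N(0, 1). The cortical gray-matter column tracks A
  additively (so its fitted age slope equals γ_g exactly); every other
  feature responds multiplicatively through a per-structure loading
  (hippocampus and mesial-temporal structures high, ventricles
  negative), plus 5% CV Gaussian measurement noise, clipped at zero.
* **Scores.** score = trendline + δ·wᵀ(x − E[x | g, age]) + noise,
  clipped to the scale bounds. The weight term acts on the morphometric
  *deviation* from the cohort-age expectation; because that expectation
  is affine in age along the atrophy direction, this is the plain
  "weights · features" model reparameterised so the configured
  intercepts and slopes are the exact population values — which is what
  makes slope recovery and convergence checks sharp rather than
  approximate. Weight vectors are sparse Gaussian stamps on
  cohort-and-test-specific supports, drawn from a fixed stream (they are
  part of the configuration, not the data seed). They are scaled so the
  deviation term contributes half the score variance and Gaussian noise
  the other half, making the **total** within-cohort SD match the
  published cohort SDs; `score_noise_sd` therefore equals the target SD
  × √0.5. δ (`separation`) scales the SFA term: δ=0 plus the
  `exchangeable_null_config` equalisation yields three identically
  distributed cohorts, the chance-level control.

What the generator does **not** emulate: longitudinal within-subject
correlation (every record is an independent visit, as the analyses also
assume), non-Gaussian residuals, feature covariance beyond the single
atrophy factor, missing data, and site/scanner effects. Passing tests
therefore demonstrate that the pipeline recovers a linear SFA signal of
realistic magnitude under Gaussian noise — not that real ADNI accuracy
would match.

## Numerical choices and degenerate inputs

* Clipping at scale bounds (not truncated-normal resampling) is the
  simplest bounded-score mechanism; its biases are real and quantified
  in the tests: the CN MMSE sample mean sits ≈0.12 points below the
  configured 29.06 (ceiling censoring; the generator-mean test compares
  against the censored-normal closed form), and the TMT slope
  interaction attenuates by ≈0.05–0.08 s/yr because floor-clipping is
  age-dependent in the CN cohort.
* Zero-variance features are dropped with a warning at fit time;
  constant outcomes yield zero-MAE fits (regression) or a `RankingError`
  (importances); two-point trends return a perfect fit with the SE
  flagged undefined; parallel trendlines have no convergence age (slope
  difference tolerance 1e-9).
* Ridge fits use scikit-learn's solver and are verified against the
  closed-form penalised normal equations to 1e-8 on random designs.
* All randomness flows through `numpy.random.default_rng` seeds;
  rankings break importance ties by feature name.

## Problem sizes

Defaults mirror the reference cohorts (287/646/369). The test-suite
generative checks run at 120–300 subjects per cohort, the interaction
coverage check at 200 replicates of 200 per cohort, and the acceptance
script estimates trend slopes on a 20,000-per-cohort draw — at the
study's own size the TMT interaction standard error (~0.6 s/yr) would
swamp the quantity being reported.

## Known limitations

* The classifier's MCI true-positive rate is the weakest (≈55–70%
  across feature sets on synthetic data): MCI is bracketed by both
  neighbours on every scale, so its stamp is the easiest to imitate.
  The same ordering (MCI hardest of the well-classified classes) is the
  known weak spot of min-residual screening.
* MAE/range for TMT is inflated by its huge empirical range and heavy
  residual spread; comparisons across tests should use the normalised
  numbers only qualitatively.
* FreeSurfer stats parsing covers the aseg/aparc whitespace dialect
  (including the `# Measure` TIV line) but not surface files or
  longitudinal streams.
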