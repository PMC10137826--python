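# Methods

## The problem and the model

Circulating miRNA abundances measured on different platforms
(microarray intensities, RNA-seq counts, qPCR cycle thresholds) live on
incomparable scales, so a diagnostic signature trained on absolute
expression values rarely transfers across cohorts. `mirpair` implements
a rank-based alternative in the top-scoring-pairs tradition: for every
unordered pair of miRNAs (A, B) and every sample, the feature is

    score(A, B) = 0  if expression(A) < expression(B)
                  1  otherwise (ties score 1),

with the comparison inverted on Ct scales (lower Ct = more abundant).
Because the score depends only on the within-sample ordering of two
measurements, it is invariant to any strictly increasing per-platform
transform, which lets cohorts from different platforms be concatenated
into one binary matrix.

Key pairs are selected as the intersection of four selectors run on the
merged matrix, then a classifier (LightGBM by default, six alternatives)
is tuned by grid search with stratified 10-fold cross-validation on a
stratified 70/30 training partition and evaluated once on the held-out
30%. COPD is the positive class throughout; class assignment uses a 0.5
probability threshold.

## Preprocessing

Missing entries denote measurements below a platform's detection limit.
They are replaced with the cohort-wide sentinel for "undetected": the
global minimum of the observed matrix on an expression scale, the global
maximum on a Ct scale (a high cycle count means few copies). The global
(not per-feature) sentinel is deliberate: detection-limit censoring is a
property of the assay, and a per-feature minimum would fabricate
feature-specific floors. After imputation, a feature is dropped when the
fraction of samples pinned at the sentinel is strictly greater than 0.7
within the COPD group *or* within the healthy group — such features
carry almost no ordering information and mostly encode censoring.
Equality with the sentinel is tested exactly, with a 1e-12 relative
tolerance so that serialized matrices survive a round trip. The order
impute → filter is fixed; the filter refuses unimputed input.

No normalization or batch correction is applied anywhere: platform
invariance is the pair transform's job, and that contrast (expression
analyses disagree between renderings, pair features do not) is asserted
by the test suite.

## Pair transform details

Pairs are enumerated over lexicographically sorted feature names in the
orientation A < B. The orientation matters only for ties: the published
scoring rule sends ties to 1, so `score(A,B)` and `score(B,A)` both
score 1 on a tie while summing to 1 otherwise. Fixing the orientation at
enumeration makes the matrix deterministic. A trained model's schema may
carry either orientation and is preserved verbatim. Cohort merging
concatenates samples over the intersection of pair sets and refuses
duplicated sample IDs. A zero-variance pair drop exists but is off by
default: with n features all n(n-1)/2 pairs are kept, constant or not.

## The four selectors

All run on the merged binary matrix; entropies are in bits; ranking ties
break by pair ID so every run is reproducible.

* **ROC filter.** For a binary feature the tie-corrected rank AUC
  reduces to (TPR + TNR)/2 with TPR = P(score=1 | COPD). Selection uses
  the direction-corrected max(AUC, 1-AUC) with a strict threshold of
  0.7, so an informative pair is never lost to its arbitrary canonical
  orientation; the raw AUC is reported alongside.
* **Information gain.** IG(Y;X) = H(Y) − H(Y|X) from empirical
  frequencies; top 20 kept.
* **MRMR**, MID (difference) variant: the first pick maximizes I(X;Y),
  each later pick maximizes I(X;Y) − mean over selected Z of I(X;Z);
  top 20 kept. The difference scheme is well defined at zero redundancy,
  which the quotient variant is not.
* **Boruta.** Each iteration fits a random forest on the surviving real
  features plus sample-permuted shadow copies, scores a "hit" for a real
  feature whose impurity importance beats the *maximum* shadow
  importance, and applies two one-sided binomial tests (null: hit
  probability 1/2) with Bonferroni correction over all features to
  confirm or reject; rejected features leave the forest, tentative
  features at termination are reported but never selected.

Two Boruta internals deserve explanation because they control its
statistical behaviour:

* *Fixed-size padded shadow pool.* Shadows mirror **all** original
  features each iteration — not just the undecided ones — and the pool
  is padded with extra independent permutations up to 200 columns. The
  hit bar is a maximum over the pool, i.e. an extreme quantile of the
  null importance distribution. If the pool shrank with the undecided
  set, the bar would collapse (forest importances are normalized per
  fit) and features with lucky in-sample label correlations would start
  beating it consistently; with a 20-feature pool we measured spurious
  confirmations on most label-shuffled datasets, with the fixed padded
  pool essentially none, at unchanged power for genuinely predictive
  features.
* *Forest size 50 trees.* The binomial hit test aggregates up to 100
  independent forest fits, so per-fit importance noise is largely
  irrelevant to the decisions; small forests keep the iterated refits
  cheap on a single core. Type-I behaviour and power were verified at
  this size (see the acceptance tests). `n_estimators`, `max_iter`,
  `alpha` and the shadow floor are all exposed parameters.

Boruta also stops early when no undecided feature could reach either
binomial decision threshold even with all hits (or all misses) in the
remaining iterations; this shortcut is exact — the confirmed and
rejected sets are identical to running `max_iter` out.

The **consensus** is the set intersection of the four selected lists.
Selector disagreement is the point: the ROC filter is univariate and
threshold-based, information gain is univariate and entropy-based, MRMR
penalizes redundancy, Boruta is multivariate and model-based. Pairs all
four agree on are robust to the choice of selection principle.

## Modeling and metrics

Per-class training counts use floor(0.7 · n_class), which reproduces a
121/52 split with a 19 + 33 test composition for a 63 + 110 cohort.
Hyperparameter grids are small package defaults (documented in
`modeling.DEFAULT_GRIDS`, caller-overridable); the selection metric is
mean CV AUC with ties going to the first-listed grid point. The CV is
used for tuning only; the held-out partition is evaluated once.

Diagnostic metrics are exact ratios from the confusion table
(sensitivity, specificity, PPV, NPV, accuracy), displayed at 3 decimals
with full precision retained. The AUC is the tie-corrected rank
statistic with a 95% CI from DeLong's structural-component variance
estimate, truncated to [0, 1]; constant score vectors yield AUC 0.5 with
a zero-width interval. A seeded stratified bootstrap interval (2000
resamples) is available as an alternative.

Fitted models persist with their ordered pair schema, algorithm,
tuned parameters and CV table, and refuse to score inputs that do not
cover the schema.

## Single-patient prediction

`predict_patient` accepts either explicit 0/1 pair scores or raw values
on a declared scale. Raw values reduce to schema-ordered pair scores via
the same scoring rule the pipeline uses, so prediction from raw values
and from manually derived scores is identical by construction, and
predictions are invariant to strictly increasing transforms of the
input. The single most consequential convention — "expression of A less
than B" means Ct_A *greater* than Ct_B on a Ct scale — is applied by
default and can be disabled (`ct_invert=False`, CLI `--no-ct-invert`)
for data already encoded in expression direction.

## Expression-level baseline

The baseline mirrors the conventional analysis: a per-feature Welch
two-sample t-test (a deliberate plain-statistics stand-in for a
moderated linear-model test; rankings, not exact p-values, are its
contract) with logFC as the case-minus-control mean difference on the
working scale, assumed log2-like; Ct cohorts are negated first.
Stringent flagging requires |logFC| > 1.5 and raw p < 0.05, relaxed mode
p < 0.05 only; BH-adjusted p-values are reported but not used for
flagging. Zero-variance equal-mean features get p = 1. Single-miRNA
ROC uses the direction-corrected AUC with a DeLong interval.

## Synthetic two-platform cohorts

The generator emulates the study design, not real miRNA biology:

* Latent log2-like abundances: per-feature means N(6, 1.5²), per-sample
  deviations N(0, 1).
* Disease signal is planted as **within-sample orderings**: the two
  members of a planted pair share one baseline mean, and the ordering is
  enforced by swapping the two values inside a sample — healthy: A < B,
  COPD: A > B, each with probability 1 − p_flip (p_flip ≤ 0.5). A
  planted pair's population TPR and TNR are therefore both 1 − p_flip,
  giving corrected AUC 0.9 at the standard p_flip = 0.1. A mean-shift
  option plants conventional differential expression for baseline tests.
* Platform rendering applies a strictly increasing map (affine,
  log-affine, or a random monotone piecewise-linear spline), adds
  independent N(0, noise_sd) technical noise, censors the lowest
  `detection_limit_quantile` fraction of rendered abundances to missing,
  and for Ct platforms negates around an offset (default 40) so larger
  values mean fewer copies.
* The standard study (`simulate_two_platform`) draws one latent
  population, assigns half of each class to an array-like platform
  (log-affine, slope 3) and half to a qPCR-like platform (affine,
  negated), both with noise_sd 0.15 and 2% detection-limit censoring —
  so the two cohorts hold *independent samples* but share features and
  planted pairs, as two real study cohorts would. Rendering noise adds
  roughly 4–6 percentage points of effective ordering flips on top of
  p_flip, which the recovery experiments absorb.

What the generator does **not** emulate: realistic miRNA abundance
distributions, probe-level effects, correlated technical error,
class-imbalanced detection limits, or biological covariates. Passing
recovery tests therefore show the pipeline recovers planted ordering
signal under monotone distortion and detection-limit censoring — not
that it would recover real COPD biology.

## Standard experiment sizes

The Monte-Carlo properties asserted by the test suite run at the
generator's standard conditions: 60 + 60 samples, 40 miRNAs (780
pairs), 5 planted pairs, p_flip 0.1; 50 seeds for selector recovery and
null calibration, 25 seeds for classifier power, 50 + 20 seeds for
Boruta type-I/power on 20-pair matrices at n = 100. These sizes make
each claim a stable proportion while keeping a full run of the suite
practical on one core.

## Known limitations

* The five published key pairs ship only as a predictor schema
  (`published.PUBLISHED_KEY_PAIRS`); reproducing their selection or the
  published AUCs requires the original cohorts, which this package does
  not download.
* Probes mapping to the same mature miRNA are an error at harmonization,
  never averaged; merging strategies are the caller's decision.
* The published-workflow pipeline computes selection on the merged cohort
  before the train/test split; the held-out estimate is honest for the
  classifier but not for the selection step itself. `run_study` keeps
  this order deliberately (it mirrors the published workflow); a fully
  nested protocol would wrap selection inside the split.
* Boruta decisions, while seeded and reproducible, depend on random
  forest importances; on matrices with thousands of pairs, borderline
  features routinely end tentative and are excluded by design.
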