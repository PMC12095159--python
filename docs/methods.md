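# Methods

This note records the models, conventions and numerical choices behind
`pwabs`, and what the synthetic-data tests do and do not establish.

## Quantification model

Autoantibody level in arbitrary units is the control-anchored linear
rescaling `AU = (F_ag − F_neg)/(F_pos − F_neg) × 100`. Choices the formula
itself does not fix:

- **Control aggregation** — per-subject *median* over control spots of each
  class. Arrays carry several positive/negative controls and a single
  failed spot should not shift the whole array's scale.
- **Negative AU retained.** The formula permits AU < 0 (spot dimmer than
  the negative control); clipping would bias SAL upward, so AU is never
  clipped except inside the fold-change computation (below).
- **Duplicate antigen spots** are combined by arithmetic mean.
- Degenerate controls (F_pos ≤ F_neg) abort quantification with the
  offending subject named; there is no sensible AU scale for such an array.

SAL is the unweighted row sum over all antigens, negative values included.

## Statistical primitives

Implemented self-contained (scipy supplies only distribution functions),
cross-checked in the test suite against enumeration oracles, scipy,
scikit-learn and statsmodels:

- **Mann-Whitney U**: exact null distribution by dynamic programming over
  rank subsets whenever the smaller group has ≤ 8 observations and the
  pooled sample is tie-free — this covers the cohort's 8-vs-9 contrasts;
  otherwise a normal approximation with tie and continuity correction.
  Two-sided exact P is 2·min(P(U≤u), P(U≥u)) capped at 1. Two-sided is the
  default everywhere; sidedness conventions are ours.
- **Spearman**: Pearson correlation of mid-ranks; P from the t
  approximation on n−2 df; constant inputs yield a flagged undefined
  result, never a silent number.
- **Fisher 2×2**: two-sided P sums hypergeometric probabilities ≤ the
  observed table's (relative tolerance 1e−7, as in R).
- **ROC-AUC** is pair-counting (U/(n₁n₀)); **PR-AUC** is average precision
  (step integral at distinct-score thresholds), *not* the trapezoid — the
  two differ and the choice is deliberate because AP never interpolates
  optimistically.
- **OLS** via QR; rank deficiency raises with the dependent columns named.
- No multiple-testing correction by default (the screen thresholds raw
  P < 0.05); Benjamini-Hochberg is available as an explicit opt-in.

## Differential screen

Fold change is the ratio of *zero-clipped* group arithmetic means, with the
denominator floored at ε = 1 AU: FC = mean_case / max(mean_ctrl, ε) once
mean_ctrl ≤ ε. AU can be negative and a ratio of possibly-negative means is
sign-pathological; clipping plus the ε floor keeps FC ≥ 0 and finite.
Ratio-of-means is the common volcano convention; medians are not used.
"Elevated" is one-directional (case above control) even though P is
two-sided. PCA standardizes features to unit variance (AU scales vary
over orders of magnitude across antigens), drops zero-variance columns
with a warning, and fixes component signs by making each component's
largest-magnitude loading positive.

## Classifier bench

- Fourteen adapters mirror the published comparison table. XGBoost,
  LightGBM and CatBoost are not available in the supported environment;
  three distinct scikit-learn `GradientBoostingClassifier` configurations
  (subsampled, shallow-tree with feature subsampling, slow learning rate)
  stand in for that family. The bench surface, folds, metrics, importances
  and consensus are computed by this package.
- Scaling statistics (min-max or z-score, per adapter) are fit on each
  fold's **training portion only**. Fitting scalers globally leaks
  held-out information; a leak canary test (label signal planted only in
  test folds must score AUC ≈ 0.5) guards the contract.
- Regression-style adapters emit raw predictions; threshold metrics use
  min-max-rescaled predictions at a 0.5 cutoff (rank metrics are
  unaffected by the monotone rescale).
- The reported importance vector comes from a final full-data fit after CV
  (per-fold mean available by flag); the original work does not state
  which it used.
- Consensus: models with mean ROC-AUC strictly above the 0.96 gate
  contribute their top-10 importance-ranked features (ties break by stable
  feature order); features appearing in ≥ `min_models` lists are selected.
  "More than two algorithms" is ambiguous between ≥2 and ≥3; the default
  is `min_models=2` (the source reports 12 consensus features from only 4
  qualifying models, which is hard to reach at ≥3) and the knob is exposed.
- Hyperparameter tuning is a bounded random search over small discrete
  grids whose candidate set always contains the defaults; full Bayesian
  optimization is out of scope.

## Three-class net

Exactly the published recipe: hidden layers 8 → 4 with ReLU, 3 softmax
outputs, cross-entropy loss, Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e−8 —
only the learning rate was specified; the rest are the conventional Adam
constants), 150 epochs of shuffled minibatches of 16, 3-fold CV. Our
choices: per-training-fold standardization of inputs; seeded
Glorot-uniform initialization (±√(6/(fan_in+fan_out))), zero biases; no
early stopping, weight decay or dropout (none were specified). The class
encoding is fixed (class 1 = CNI, 2 = AD, 3 = DLB). Implemented in plain
numpy — single-threaded, hence bit-reproducible per seed. Besides pooled
accuracy the report exposes *balanced* accuracy (mean per-class recall),
whose chance level is 1/3 regardless of the 18/8/9 imbalance; the
permutation-null tests assert on that.

## Clinical association

Pairwise-complete Spearman per (autoantibody, trait) cell with the
complete-pair count reported; cells with < 3 pairs or a constant vector
are marked not-computable. Binary traits (sex, back pain) are rank-coded
0/1 — for a dichotomous variable Spearman reduces to rank-biserial
correlation. Stars: \* P<0.05, \*\* P<0.01, \*\*\* P<0.001, strict
inequalities (P = 0.05 exactly earns no star). Regressions are
complete-case, sex coded M=0/F=1 (logged in the output), univariate
`trait ~ ab` and multivariate `trait ~ age + sex + ab`; fewer complete
cases than coefficients + 1 raises. Box summaries use Tukey hinges with
whiskers at the most extreme points within 1.5 IQR.

## Cross-reactivity

The original analysis used an external alignment service; here the screen
runs Needleman-Wunsch with identity scoring (match 1, mismatch 0, linear
gap −1) and deterministic traceback (diagonal > up > left on ties).
Percent identity is identities / **alignment length** by default; the
"over shorter sequence" convention is available by flag because reported
identity figures depend on this choice. Only pairs with Spearman rho
strictly > 0.5 are aligned; a qualifying pair with a missing sequence is
reported unresolved, not fatal.

## Synthetic cohort

The generator states one world and the tests live in it:

- Group sizes 18 AD / 8 DLB / 9 CNI; female fractions 82.4 / 62.5 / 33.3%;
  ages uniform 70–90 in every group (the cohorts were age-matched).
- Latent truth is defined on the AU scale: background AU is lognormal
  (log-mean 1.0, log-sd 0.8 → median ≈ 2.7 AU, right-skewed as serology
  is); planted antigens are multiplied by `effect_fold` (default 4) in the
  affected group(s). Spot fluorescence is back-computed through the AU
  formula (F_neg 500, F_pos 50 000 fluorescence units) and then jittered
  with unit-mean lognormal noise (CV 0.1), controls included — so
  quantification inverts generation up to noise, which the recovery tests
  exploit through the `TruthLedger`.
- Default desk-scale panel: 300 antigens with 10+10+10 planted elevations
  and 8+8 control spots; the full 13 455-clone scale is reachable by
  config. Control-spot counts are conventions — the source does not
  describe its control layout.
- MMSE and HDSR group baselines are the printed cohort means/sd; CGA7,
  GDS15, Barthel, IADL, back-pain prevalence, comorbidity counts and the
  MMSE subscale splits are plausible geriatric-assessment defaults (not
  printed anywhere). Traits couple linearly to designated driver antigens
  via the driver's standardized latent AU; by default MMSE and its
  memory subscales (Registration, Recall) couple negatively to the first
  shared planted antigen, emulating a memory-tracking autoantibody.
- All randomness flows from named substreams of one seed; identical
  config + seed reproduces byte-identical tables.

**What green tests establish:** the pipeline's operating characteristics
(null false-positive control, fold-4 sensitivity ≥ 0.8, consensus driver
recovery, net separability, leak-freedom, determinism) on data matching
the generator's assumptions — independent lognormal antigens, clean
multiplicative effects, no batch structure. They do **not** reproduce the
patient-data results (raw data unavailable), nor cover inter-array batch
effects, antigen-antigen correlation structure, plate-position artifacts,
or non-lognormal reactivity tails. Headline patient-data numbers
(e.g. best binary AUC 0.978, 188/77 differential counts) are therefore
not targets anywhere in this package.

## Pipeline

Stages run in a fixed order with per-stage seeds derived as
`(master_seed + crc32(stage_name)) mod 2³¹`. The manifest hashes every
artifact (SHA-256) and embeds the normalized config; unknown config keys
are rejected rather than ignored. When no bench model clears the AUC gate,
downstream stages fall back to the best model's top-k features so the run
still completes — the consensus JSON records the empty selection honestly.
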