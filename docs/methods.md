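# Methods

## The model

`clpnet` estimates a **cross-lagged panel network (CLPN)** over p = 15 items
measured at two waves: ten ordinal CES-D depressive-symptom items (codes 0–3,
items 5 and 8 reverse-scored) and five binary Internet-use-purpose indicators.
Edge *i → j* is the penalized regression coefficient β<sub>ij</sub> of item
*i* at wave 1 predicting item *j* at wave 2, controlling for all other wave-1
items; the diagonal holds autoregressive effects. Every wave-2 item is
regressed on the full standardized wave-1 item set with the elastic-net
objective

  (1/2n)‖y − Xβ‖² + λ·[α‖β‖₁ + (1−α)/2·‖β‖²],

with α = 1 (the standard LASSO) by default. λ is selected per outcome by
k-fold cross-validation (default k = 10) minimizing mean squared error over a
100-point log-spaced grid from λ_max (the smallest penalty with an all-zero
solution) down to 10⁻³·λ_max — the "lambda.min" rule. Coefficients are a
full-sample refit at the chosen λ. All variables, binary and ordinal alike,
are standardized (population SD) and fit with the Gaussian loss, so the β on
one matrix are directly comparable; this is the single-linear-family
convention of CLPN work, not a claim that binary items are Gaussian.

Assumptions worth stating: two waves only (no higher-order dynamics), linear
conditional means on the standardized coded scale, edges are regularized
conditional associations — "prediction" here is temporal precedence plus
covariate control, not causal identification.

### Matrix convention

`B[i, j]` is always *row = wave-1 predictor, column = wave-2 outcome*. All
writers (CSV adjacency, GraphML) and readers follow this orientation.

### Reverse-scored items

CES-D items 5 and 8 are positively worded. By default the network is
estimated on reverse-scored values (v → 3 − v) so that every depressive node
points in the "more symptoms" direction; `reverse_score=False` reproduces the
raw-scale analysis (which only flips the signs of the two items' rows and
columns, since standardization absorbs the affine part).

## Centrality

- **Out-EI(i)** = Σ_{j≠i} B[i,j]: signed influence a node exerts.
- **In-EI(j)** = Σ_{i≠j} B[i,j]: signed influence a node receives.
- **Bridge-EI(i)** = Σ_{j in other community, j≠i} B[i,j]: 1-step *outgoing*
  cross-community influence across the depressive/internet bipartition. The
  outgoing variant is the default because bridge influence in temporal
  networks is usually read as a node's effect on the other construct; the
  incoming variant is available via `direction="in"`.

All indices are computed on the signed, unfiltered pooled network. The
|β| ≥ 0.05 display filter (and the exclusion of autoregressive edges) is a
visualization device only and never feeds centrality or stability. Indices
accumulate term-by-term in node order so they agree bit-for-bit with naive
loop oracles; the bootstrap uses an equivalent vectorized path (agreement
asserted in tests).

## Missing data

`missingness_report` gives per-column missing percentages, the phi
correlations between missingness indicators, and an MCAR-like / MAR-like hint
(mean absolute indicator correlation above/below 0.10).

`impute_chained` is a chained-equations imputer written for this package:
each incomplete column is regressed on all other 29 item columns (both waves
predict each other — the dense default, since no sparser imputation model is
obviously right), visited in increasing-missingness order. Ordinal items use
**predictive mean matching** (type-1, k = 5 donors), binary items logistic
draws (falling back to the observed constant when a column is one-class).
Ten iterations per chain and m = 5 chains are the defaults; chains are
independent substreams of one seed. PMM draws observed donor values, so
imputed codes always respect item ranges and observed cells are never
altered. statsmodels' MICE is used as an independent cross-check in the test
suite, not as the implementation: a Generator-seeded imputer was needed for
byte-level reproducibility of full runs, and the compact lstsq-based update
is roughly 20× faster at the package's problem sizes.

Per-imputation networks are pooled by the **point-estimation step of Rubin's
rules** — an elementwise mean. Between-imputation variance is deliberately
not propagated: the analysis targets structure (presence and relative
strength of edges); uncertainty is quantified by the bootstrap instead.

Designated always-MCAR covariates (e.g. education) can be handled by listwise
deletion before imputation (`listwise_delete`), mirroring the usual survey
practice for low, uncorrelated nonresponse.

## Bootstrap stability

All three procedures call the estimator through one `(data, seed) →
CLPNetwork` contract, so stubs can be injected.

- **CS-coefficient** (case-dropping bootstrap): for each drop proportion d in
  {0.05, …, 0.75} (step 0.05), B subsamples without replacement of size
  ⌈n(1−d)⌉ are re-estimated; CS is the largest d such that every proportion
  up to d keeps ≥ 95% of the node-wise Pearson correlations with the
  full-sample centrality at ≥ 0.7. CS ≥ 0.25 is the usual minimum for
  interpretation, ≥ 0.5 preferred. Degenerate correlations (zero-variance
  centrality vectors) count as 1 when the vectors are identical, else 0.
- **Edge CIs**: percentile 95% intervals from B row-resamples with
  replacement. Percentile, not BCa — the simplest convention consistent with
  reporting "bootstrapped 95% CIs". Imputation is *not* re-run inside
  replicates (resampling acts on a completed dataset); re-imputation per
  replicate is possible by composing `impute_chained` into a custom estimator
  but is far slower and changes little at these missing rates.
- **Difference tests**: for every pair of edges (and of node centralities per
  index), the percentile interval of the bootstrap difference; significant
  iff it excludes 0. Masks are symmetrized exactly.

### Resampling estimator settings

Full-sample estimation uses 10-fold CV over 100 λ values. Re-estimating the
network thousands of times inside the bootstrap uses a lighter,
pre-registered configuration (`FAST_RESAMPLING_CONFIG`: 5-fold CV, 25 λ
values). λ selection is insensitive to grid resolution at these sizes, and
the package's own coordinate-descent path solver on the Gram matrix
(`clpnet._cd`, numba-compiled, asserted against scikit-learn's ElasticNet to
~1e-8) keeps one re-estimation under ~0.1 s, which is what makes the
case-dropping bootstrap tractable on one CPU.

## Synthetic data generator

The generator is the package's testbed: it produces two-wave panels with
*known* cross-lagged structure.

- **Latent layer**: wave-1 latent vectors ~ N(0, Σ₁) with
  exchangeable-within-community correlations (0.30 among depressive items,
  0.20 among internet items, 0.05 across — moderate symptom intercorrelation,
  weak construct overlap). Wave-2 latent = Bᵀ·latent₁ + ε, residual SDs
  chosen so latent variances are 1 at both waves; entries of B are then on
  the scale of standardized coefficients and latent cross-wave correlations
  are analytic (checked in tests).
- **Ground truth B**: diagonal (autoregressive) uniform on (0.15, 0.45);
  exactly `n_nonzero_cross` off-diagonal cells, magnitudes uniform on the
  effect range (default 0.05–0.19, capping cross-lagged magnitudes near the
  0.19 typical of two-wave symptom panels) with random signs; spectral radius
  rescaled below 1 if needed.
- **Observation**: each latent value is cut at per-item thresholds into
  {0..3} or {0,1}. Ordinal cutpoints are set from a target symptom-presence
  rate P(code ≥ 1) with higher categories roughly halving in mass
  (P(≥2) = 0.5·p₁, P(≥3) = 0.2·p₁) — a skewed shape typical of community
  CES-D data; only the presence rate is externally constrained, the tail
  shape is a package choice. Reverse-scored items are *emitted* on the raw
  questionnaire scale (3 − code), so generated data exercise the
  reverse-scoring switch end-to-end.
- **Marginals**: the default fixture uses realistic symptom-presence rates
  (21–64%) and binary endorsement of 10% — the upper end of the realistic
  0.5–15% purpose-endorsement band — so that planted effects are identifiable
  at desk-scale n ≈ 5000. The `charls_like()` preset (n = 9290) instead pins
  every item to the survey's exact per-wave rates, including 0.5–4% binary
  endorsements at wave 1. Effects anchored at a 0.5%-endorsement item (~25
  endorsers at n = 5000; biserial attenuation ≈ 0.2) are not recoverable by
  any estimator — the preset is for realism and runtime checks, the default
  fixture for recovery benchmarks.
- **Missingness**: per item-wave rates within [0, 0.30], defaults spanning
  10–27% for depressive items. MCAR masks cells independently. MAR drives
  depressive-item nonresponse through a logistic function of always-observed
  covariates (older age, illiteracy; strength 1.5 on the logit scale), which
  induces positive correlation among depressive missingness indicators;
  intercepts are calibrated on the realized driver so rates land on target.
  Internet items stay MCAR under both mechanisms.
- Covariates (age/gender/illiteracy with plausible older-cohort marginals)
  exist only as MAR drivers and optional adjustment variables — never as
  network nodes.

What the generator does **not** emulate: survey weights and stratified
sampling, panel attrition, the joint wave-1/wave-2 endorsement distribution
of purposes (only per-wave marginals are matched), ceiling/floor response
styles, and item-specific measurement error. Passing tests therefore show
that the pipeline recovers structure from data *of this idealized form*, not
that any particular substantive finding in real survey data is correct.

## Numerical choices and degenerate inputs

- Standardization uses population SD; a zero-variance column raises an error
  naming the node (a degenerate network node, not a recoverable condition).
- λ = 0 is solved exactly by least squares rather than coordinate descent.
- CV ties in the MSE curve resolve toward the stronger penalty.
- Perfectly collinear predictors report VIF = ∞ rather than raising
  (flagged at the conventional VIF ≥ 5).
- Fold assignment is plain random k-fold, independently per outcome, from
  seed-derived substreams; one master seed (numpy `SeedSequence` spawning)
  determines simulation, imputation chains, fold splits and all bootstrap
  draws, giving byte-identical artifacts across runs.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at the package's desk-scale
study conditions: n = 10 000 for null specificity, n = 5000 for recovery and
imputation robustness (m = 5, 10 iterations), n = 4000 with B = 200
case-dropping replicates and n = 5000 with B = 500 resamples for edge CIs,
and a full n = 2000 pipeline (m = 5) run twice for reproducibility. These
sizes were chosen as the smallest at which the asymptotic behavior of the
method is clearly visible.

## Known limitations

- Gaussian loss on standardized binary outcomes is a linear-probability-style
  approximation; with very rare items the resulting β are attenuated
  relative to the latent effect (by design of the measurement model, not a
  bug). Interpret magnitudes on the standardized coded scale.
- CS-coefficients are reported on the 0.05 grid; values are conservative
  (floor of the true breakdown proportion).
- The imputer assumes MAR given the 30 item columns; MNAR sensitivity
  analysis is out of scope.
- No contemporaneous (within-wave) network and no ≥3-wave dynamics.
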