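# Methods

This note documents the statistical procedures implemented in `lipidnet`,
the default parameters and why they were chosen, what the synthetic cohort
generator does and does not emulate, and the numerical choices that affect
results.

## Study design and the synthetic cohort generator

The pipeline targets nested case–control data: incident cases of a binary
endpoint, each matched to 1–3 controls drawn from the risk set at the
case's event time (incidence density sampling), matching on recruitment
center, birth year (±5 years) and sex. The unit of inference is the matched
stratum.

Because individual-level data of this kind are typically enclave-bound,
`lipidnet.cohort` generates cohorts with known ground truth:

- **Design scale.** Defaults are 512 strata with the per-stratum number of
  controls drawn from {1, 2, 3} with probabilities (0.60, 0.36, 0.04), so a
  default cohort has ≈1249 subjects with ≈41% cases — the scale of a large
  nutrition-trial AF substudy. `controls_per_case` may also be fixed.
- **Lipids.** 216 features in 12 blocks ("lipid classes") by default.
  Latent levels are multivariate normal with an exchangeable
  within-block correlation (default 0.5, between-block 0); validity of the
  correlation matrix is enforced constructively by Cholesky. Abundances are
  log-normal (`exp` of an affine map of the latent level). Because the
  downstream Blom transform is rank-based, the marginal shape is
  immaterial; log-normality just makes raw abundances look like LC-MS data.
- **Outcome.** Within each stratum the case is sampled with probability
  proportional to `exp(linear predictor)`, where the predictor applies the
  configured log-odds-per-SD effects to the *latent* (standard-normal)
  lipid levels plus any covariate effects. This is exactly the
  data-generating assumption of conditional logistic regression, so
  parameter recovery is a clean test. True risk-set sampling cannot be
  reproduced without a full longitudinal cohort; conditional-logit
  assignment is its likelihood-equivalent within strata.
- **Missingness.** Default left-censoring: the lowest 2% of each feature
  is set missing (configurable up to 20%, or MCAR), because half-minimum
  imputation downstream presumes a detection limit.
- **Control reuse.** Incidence-density sampling reuses controls across
  strata; the generator supports this behind `allow_control_reuse` with a
  configurable rate, off by default to keep variance-estimation assumptions
  simple. No published rate exists, so it is a parameter, not a default.
- **Composite effect scale.** `scale_effects_to_composite` rescales an
  effect map so that the generating score `Σ βⱼ Zⱼ` has a chosen SD; the
  SD is `√(βᵀΣβ)` with Σ the block-correlation matrix. A composite of
  0.28 log-odds per SD corresponds to an OR per SD of e^0.28 ≈ 1.32.

What the generator does **not** emulate: assay batch/drift structure,
lipid-class-specific missingness, the dietary intervention's effect on
lipid levels, follow-up time, or realistic lipid naming. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those real-data artifacts.

## Preprocessing

- **Half-minimum imputation**: missing entries of feature *j* become
  (minimum observed of *j*)/2. Features with no observed values are an
  error.
- **Blom transform**: per feature, `Φ⁻¹((r − 3/8)/(n + 1/4))` with
  tie-averaged ranks. Ties must be handled because half-minimum imputation
  creates them; averaging keeps the map well-defined and symmetric.
  Output is approximately standard normal, so a conditional-logistic
  coefficient is a log-OR per SD. The transform is computed over the full
  analysis sample (cases + controls).
- **Strata deviations** (forest stage only): subtract the matched-stratum
  mean per feature. This removes between-stratum (matching-driven)
  variation so a pooled classifier respects the matched design. Singleton
  strata are rejected — their deviations are identically zero.
- Fixed order: impute → Blom → (for the forest) deviations, recorded in a
  provenance list.

## Conditional logistic regression core

Newton–Raphson on the exact stratum-conditional likelihood with
step-halving; convergence at |Δloglik| < 1e−10 or 50 iterations. Design
columns are centered within strata (a within-stratum constant shift cancels
in the likelihood), which also makes matching-constant terms exactly zero —
those are dropped and reported rather than raising, since design
conventions often list matching variables (center, sex) among adjustment
covariates. Standard errors come from the inverse observed information;
p-values are two-sided normal Wald. Coefficient norm > 15 at termination is
flagged as (quasi-)separation and the fit marked non-converged — never
silent. The statsmodels `ConditionalLogit` serves as an independent
cross-check in the test suite only.

Adjustment covariates (defaults): center, age, sex, smoking (3 categories
→ 2 indicators), BMI, type 2 diabetes, hypertension, family history of
premature CHD, leisure-time physical activity, education (3 → 2),
statin use, intervention arm (3 → 2). Three-level covariates enter as
indicator sets, not ordinal scores.

## Per-lipid screen and multiple testing

One model per lipid (lipid + covariates). Per-feature failures are
reported with missing p-values and by default still count toward the
multiple-testing family size m (conservative; switchable).
Benjamini–Yekutieli adjustment = Benjamini–Hochberg × c(m), c(m) = Σ_{i≤m}
1/i, capped at 1 and made monotone; implemented in-package to support the
family-size semantics and cross-checked against statsmodels.

## Network and clusters

- **PC skeleton** (PC-stable): start complete; for conditioning-set sizes
  ℓ = 0..3 remove edge (i,j) as soon as some S ⊆ adj(i)\{j} (then
  adj(j)\{i}) with |S| = ℓ satisfies the Fisher-z partial-correlation test
  `√(n−|S|−3)·|atanh r| < z_{α/2}` (α = 0.05 default). Subsets are
  enumerated lexicographically over the input column order and the
  adjacency is frozen per level, so output is deterministic and
  row-permutation invariant. Each removal records its separating set — a
  replayable audit. Partial correlations come from the inverse of the
  relevant correlation submatrix, evaluated for all candidate sets of an
  edge in one batched inversion.
- **Robust edges**: with only one dataset available, edge stability "across
  two studies" is emulated by learning skeletons on two random halves of
  the strata; user-supplied second datasets slot in unchanged. An edge
  survives if present in both skeletons and its pooled partial correlation,
  conditioned on the union of the endpoints' intersection-graph neighbors
  (capped at `max_order` strongest marginal correlates), exceeds 0.1 in
  absolute value. The conditioning convention is recorded in
  `algorithm_params` because other conventions exist.
- **Walktrap** (igraph), step length 4, |partial correlation| edge weights,
  dendrogram cut at maximum modularity; isolated nodes become singletons;
  cluster ids are relabeled densely from 1 in input-node order.

## Cluster importance

Bagged `DecisionTreeClassifier`s (500 trees, √p feature subsampling), each
grown on a 2/3 row subsample **without** replacement — "sampling rate"
read literally; a bootstrap flag exists. Baseline OOB error is the
majority-vote misclassification rate over rows with ≥1 OOB vote (exact vote
ties predict the case class), computed once. For each cluster, every member
column is permuted with **one shared row permutation** of each tree's OOB
rows — preserving within-cluster dependence, which per-column shuffles
would destroy — and the OOB error is recomputed; the increase over
baseline, averaged over R = 10 permutation draws, is the cluster's
importance. Rank 1 = largest increase; ties break by cluster id. The
case share in this design (~41%) makes the error rate an informative
metric. All permutation RNG streams derive from the stage seed, so results
are reproducible bit for bit.

## Predictor selection and the multilipid score

- **Elastic net** (scikit-learn `LogisticRegressionCV`, saga): mixing
  grid {0.1, 0.5, 0.9}, 20-point penalty path, tenfold stratified CV
  minimizing deviance (no 1-SE rule by default). Selection = exact-zero
  pattern at the chosen penalty. Run first within each of the top-7
  clusters by importance rank (7 mirrors the length of the cluster table
  the design was built around; configurable), then across all survivors.
  Selection uses ordinary logistic regression on strata-deviation data —
  the deviation transform already absorbs the matched structure; a
  conditional-model switch is provided.
- **LOOCV score**: for each stratum s, fit the conditional logistic model
  (selected Blom lipids + covariates) on all strata except s; score s's
  subjects as the dot product of their lipid values with the held-out
  coefficients. The leave-out unit is the matched set, not the subject,
  to respect the conditional likelihood. Reported per-feature weights are
  the medians across folds; per-subject scores use fold-specific weights.
  Scores are standardized by the analysis-sample SD, and the final
  conditional-logistic model of outcome on score + covariates gives the OR
  per SD. Intervention interaction: score × arm products, joint 2-df Wald.
  Non-convergent folds are excluded from scoring and counted.

## PCA factors

Correlation-matrix eigendecomposition among **controls only**; components
with eigenvalue > 2 retained; varimax rotation (Kaiser-normalized) of the
retained loading block — communalities are preserved to 1e−8 and asserted.
Factor scores are loading-weighted sums of features standardized by the
controls' means/SDs (the most direct reading of "applying control loadings
to cases"); regression scoring is intentionally not the default. Features
with |loading| > 0.40 label a factor. Quartile cut points come from the
controls' score distribution; associations are conditional-logistic ORs of
quartiles 2–4 vs 1; the trend test replaces indicators with the controls'
quartile-median score as one continuous covariate; intervention interaction
is a joint 2-df Wald on trend × arm products. The extreme-quartile contrast
is reported as Q4 vs Q1.

## Pipeline, determinism and problem sizes

One global seed fans out to per-stage seeds through a fixed CRC-based
derivation, so disabling one stage never shifts another's randomness.
Matrix artifacts are written with `%.17g` and parsed with round-trip float
precision, so re-running downstream stages from saved artifacts is
byte-identical to a single-shot run.

The validation suite exercises the stages at these sizes, chosen so each
check is statistically informative while the whole suite stays desk-scale:
null-screen calibration at 216 lipids × 500 strata × 20 seeds; network
recovery on 3–10-node generated DAGs at n = 5000; importance recovery at
400 strata × 10 clusters × 20 seeds; score recovery at 500 strata ×
20 seeds with a composite effect of 0.28 log-odds per SD; and a full
end-to-end run at ≈1247 subjects × 216 lipids.

## Known limitations

- The PC skeleton assumes joint Gaussianity after the Blom transform;
  marginal normality does not imply joint normality, so edge tests are
  approximate on real data.
- Split-half robustness halves the sample for structure learning; with few
  strata the skeleton intersection can be sparse.
- Elastic-net selection on deviation data followed by conditional-logistic
  weighting mixes two likelihoods; this mirrors the staged design the
  package implements, but the selected set is not guaranteed optimal for
  the conditional model.
- The score's final association reuses the data that selected the
  predictors; only the *weights* are cross-validated. The reported OR can
  therefore be optimistic when selection is aggressive — visible in the
  synthetic demo, where the recovered OR modestly exceeds the generating
  1.32 when many correlated features are selected.
- The final Wald CI treats the LOOCV score as a fixed covariate. Under the
  **global null** the weights are pure estimation noise shared across
  folds, which inflates the true sampling variance of the score coefficient
  (the pre-validation effect): the validation suite measures null CI
  coverage around 75–85% instead of 95%, and it does not improve with more
  strata. Leave-one-stratum-out scoring removes the leakage *bias* (the
  point estimate is centered at null) but not this variance inflation.
  Under genuine effects the weights concentrate on the true direction and
  coverage is close to nominal, as the recovery checks show. Null findings
  from the score stage should therefore be judged by the interaction/trend
  permutation-style checks or by effect size, not by the naive CI alone.
- Interaction Wald tests assume the information matrix is well-conditioned;
  with rare arms the 2-df test can be unstable (flagged, not hidden).
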