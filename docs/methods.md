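# Methods

This note documents the models and procedures implemented in `notchtsp`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Rank-based pair classification

For a gene pair (u, d) and sample s, the order indicator is
I(x_{u,s} > x_{d,s}), with strict inequality: equal values contribute no
vote. The switch score of a pair is

    Δ = P(I = 1 | RD) − P(I = 1 | pCR),

estimated by class-conditional proportions. Δ is computed as a single
integer-valued fraction (hit counts cross-multiplied over class sizes),
which makes Δ(u,d) = −Δ(d,u) exact in floating point for tie-free data.
Ties break on a secondary statistic: the between-class difference of the
mean within-sample rank gap of the two genes. `constrained_search` ranks
each sample's full expression profile (average ranks for ties) and
evaluates both statistics for every mechanism pair in one vectorized
pass; `tsp_score` is the single-pair form and doubles as its oracle.

Prediction sums the votes of the k signature pairs and calls RD when the
count reaches the threshold t (t = 2 for the shipped 5-pair signature).
When a cohort lacks some signature genes, each sample's available pair
count k_a replaces k and the threshold scales proportionally,
ceil(t·k_a/k), so a 4-of-5-measured cohort still predicts with threshold
2. Ties never vote for RD — the conservative choice, since RD is the
action-relevant call. Votes depend only on within-sample orderings, so
predictions are invariant to strictly increasing per-sample transforms;
this is enforced by property tests.

## Mechanism construction

Up- and down-regulated gene sets (GMT format) are unioned per direction
preserving first-occurrence order; symbols appearing in both directions
are removed from both sides; the mechanism is the full cross product,
ordered up-gene-major so feature indices are reproducible. Matching is
exact case-sensitive string equality — alias/ortholog mapping is a
user-side concern. Restriction to measured genes keeps exactly the pairs
with both genes present and is idempotent and order-preserving.

## Preprocessing

Each dataset is Z-scored separately per gene (sample sd, n−1
denominator; zero-variance rows map to zeros rather than NaN), then
datasets are merged on the intersection of gene identifiers. The order
is fixed — normalize, then merge — because pooled Z-scoring would let
the largest dataset dominate each gene's centring.

The train/test split targets covariate balance, not just class
stratification. The named goal is balance; the algorithm is ours: draw
M = 1000 candidate splits stratified on response × dataset-of-origin
(per-stratum train counts by largest-remainder rounding, so class
proportions hold within ±1 sample per stratum and |train| =
round(fraction·n) exactly), score each candidate by the worst imbalance
across the requested covariates — absolute standardized mean difference
for continuous covariates, total variation distance over levels for
categorical ones, with missing values as an explicit "Unknown" level —
and keep the minimizer. The split fraction is a parameter (default
0.7); the balance diagnostic is returned with the partition.

## Regularized random forest selection

Candidate pairs enter the forest as binary order-indicator features. The
RRF grows weighted-Gini trees; at each node ceil(f·p) candidate features
are drawn (f = 0.1 by default), and a feature not yet used anywhere in
the forest has its gain multiplied by the regularization coefficient
λ = 0.5, so a new feature must beat the best already-used feature by a
factor 1/λ to enter. λ = 1 recovers an ordinary weighted random forest
(verified bitwise against an independent reference implementation at
small size). Class prior weights (1.0 pCR, 0.6 RD) multiply sample
contributions in impurity and node totals, up-weighting the minority
pCR class. Defaults: 100 trees, unlimited depth, minimum node size 2.
"Initial feature set of 0.1" is read as the per-split candidate-feature
fraction (mtry-style), the nearest parameter in the RRF formulation;
the alternative reading is expressible through the same config field.

Selection stability: B = 100 class-stratified bootstrap resamples (size
n, with replacement; stratification guarantees both classes), one RRF
fit each; a pair counts as selected when used in ≥1 split of that fit.
Pairs are ranked by selection frequency, then mean cumulative impurity
decrease, then input order; the top k = 5 become the signature with
vote threshold ceil(0.4·k) = 2. Per-bootstrap seeds derive from the
master seed by a counter, so any single bootstrap is reproducible in
isolation. The tree kernel is numba-compiled; split ties go to the
lowest feature index, and the gain expression is written with a fixed
association order so results are bit-reproducible across runs.

## Evaluation statistics

RD is the positive class throughout; a classifier's score is its RD
vote fraction (or RD probability for logistic models). AUC is the
tie-corrected Mann–Whitney probability; the PR area uses step-wise
summation (average precision) rather than trapezoids, avoiding the
optimistic bias of linear interpolation in PR space. Sensitivity,
specificity, balanced accuracy and MCC come from the 2×2 table; MCC is
defined as 0 when a marginal is empty, and a metric with an empty
denominator is reported as NaN rather than silently dropped.

DeLong's variance for one AUC uses the structural components V10/V01
(sample variances, n−1); the test against 0.5 and the paired test for
two score vectors on the same samples are one-sided upper-tail normal
tests, with 95% Wald CIs truncated to [0, 1]. Degenerate inputs
(constant scores, identical vectors) are flagged and reported with
p = 1 rather than raising. Both tests are validated against label-
permutation and paired-bootstrap oracles (±0.02).

The signature-comparison harness refits every supplied gene list as an
L2-penalized logistic regression (fixed penalty, C = 1) on the training
cohort — ridge stabilization is chosen over plain maximum likelihood so
separable small-sample fits remain defined — and compares test AUCs to
a designated reference by the paired DeLong test. Competing published
gene lists are not bundled; the harness accepts arbitrary lists.

## Survival association

Samples are dichotomized into high/low signature groups by the
classifier's own vote rule (high = the RD call), keeping the survival
grouping consistent with classification; a median split is a reasonable
alternative the caller can apply upstream. Kaplan–Meier curves use the
product-limit estimator with events processed before censorings at tied
times; the log-rank test uses hypergeometric variance at each event
time. The multivariate Cox model uses Efron's tie approximation
(lifelines' Newton solver); categorical covariates are expanded to
treatment-coded dummies, constant covariates and models with more terms
than events are rejected, and monotone-likelihood (separation) warnings
are surfaced on the fit object. Time is in months with no delayed
entry. Fits are validated against a brute-force partial-likelihood grid
(1e−3) and a coverage simulation.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not
microarray physics. Defaults are the study conditions: n = 300 samples,
RD fraction 2/3, 5 planted pairs with switch probabilities 0.9 (RD) and
0.1 (pCR), 90 null genes, 3 datasets, covariates drawn to match a
typical clinical table (age ≈ N(50, 11²); grade/T/N level frequencies
with explicit Unknown levels), and exponential survival with hazard
h0·exp(β·votes), h0 = 0.02/month, β = log(2.5)/4 (so the high/low group
contrast is near HR 2.5), with uniform censoring calibrated numerically
to a 40% censoring fraction.

Planted orderings are realized as (z + δ, z − δ) around a shared latent
level z ~ N(0,1), the sign of δ set by a per-sample Bernoulli indicator
with the class's switch probability, δ ~ U(0.3, 1.2). Per-dataset
location/scale jitter (shift sd 0.25, scale U(0.8, 1.25)) gives the
Z-scoring step real work; the two members of a planted pair share
their jitter draw, and δ is bounded away from zero, so the planted
ordering stays identifiable both before and after normalization —
per-dataset centring shifts the two genes of a pair apart by about
2·E[δ]·E[sign], and a δ floor above that keeps realized votes equal to
the latent indicators. Covariates are independent of class by default
(this tests balance, not confounding). Null genes are independent
standard normals; there is no gene–gene correlation beyond the planted
pairs, no probe-level noise model, and no missingness.

Consequently, passing tests show that the estimators and the discovery
procedure are correct and calibrated under the assumed generative
structure — planted pairs are recovered, null configurations stay at
chance, nominal CIs cover — not that the published signature's clinical
performance transfers to any particular real cohort.

## Problem sizes and determinism

Test and acceptance runs use the default cohort size (n = 300, 55
mechanism pairs after adding 50 decoys, B = 100 bootstraps of 100
trees), 20 master seeds for recovery checks, 200 seeds for log-rank
calibration, and 100 replicates for Cox coverage; these sizes give
stable pass/fail behaviour at the stated tolerances while keeping a
full run to a few minutes. All randomness flows from explicit seeds
(numpy `SeedSequence`); reruns are bit-identical.

## Known limitations

- Gene identifiers are matched literally; platform probe collapsing and
  alias resolution must happen upstream.
- The published 5-pair signature is shipped as a constant with NaN
  switch scores (the training statistics belong to the original data).
- The RRF is specialized to binary features — exactly what pair
  indicators produce — and does not implement continuous-feature splits
  or out-of-bag estimates.
- The Cox wrapper reports but does not test proportional-hazards
  violations; competing risks and time-varying covariates are out of
  scope.
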