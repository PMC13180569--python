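# Methods

## The index catalogue

The measured panel is 15 serum bile acids in μmol/L: the primary set TCA,
TCDCA, GCA, GCDCA, CDCA, CA (hepatic products of cholesterol catabolism and
their glycine/taurine amidates) and the secondary set DCA, GDCA, TDCA, LCA,
GLCA, TLCA, UDCA, GUDCA, TUDCA (microbial 7α-dehydroxylation and epimerisation
products and their conjugates).  The derived catalogue is frozen at 71
entries: the 15 raw concentrations, 17 pools, 15 analyte fractions of the
total pool, 16 pool fractions (every pool except the total itself), and 8
ratios (12-OH/non-12-OH, GLCA/TLCA, GDCA/TDCA, primary/secondary,
conjugated/unconjugated, G-conjugated/T-conjugated,
neurotoxic/neuroprotective, CAs/CDCAs).  Including the raw concentrations in
the catalogue is one of two defensible readings of a "71 derived indices"
count; it is the one that makes the arithmetic close (15 + 17 + 31 + 8 = 71)
and is fixed in a versioned JSON export.

Two definitional choices deserve note:

* **"Conjugated" means primary conjugates only** (TCA + TCDCA + GCA + GCDCA).
  Chemically, conjugated bile acids also include GDCA, TDCA, GLCA, TLCA,
  GUDCA and TUDCA, but the panel's pool definitions use the narrower primary-
  conjugate sum, and the catalogue reproduces that arithmetic verbatim.  The
  G-conjugated and T-conjugated pools carry the chemically complete sets.
* **Zero denominators yield missing values**, never infinities.  A subject
  with TLCA = 0 has GLCA/TLCA flagged missing; downstream stages use pairwise
  (column-wise) deletion.  This keeps standardization and penalised fits
  finite without imputation assumptions.

Fractions are stored in [0, 1]; per cent rendering is presentation only.
Every catalogue value reduces to `sum(numerator)/sum(denominator)` over
analyte membership lists, so the whole table evaluates as two matrix
products; an independently typed membership oracle in the test suite guards
the lists against drift.

## Synthetic cohorts

The generator emulates a four-group case–control serum study:
80 AQP4-IgG-seropositive NMOSD, 32 seronegative NMOSD, 50 MS, 66 healthy
controls.  Concentrations are log-normal: per group g and analyte a,
log10 C ~ N(baseline_a + δ_ga, σ_a), with a shared σ = 0.35 log10 units and
baselines ordered physiologically (glyco-conjugates above tauro-conjugates,
trace species such as TLCA near 5 nmol/L).  Group contrasts are therefore
multiplicative, matching the fold-type enrichment/suppression seen in serum
panels.  The planted default directions are:

| contrast | analytes | δ (log10) |
|---|---|---|
| primary conjugates up in NMOSD (both serotypes) | TCA, TCDCA, GCA, GCDCA | +0.25 |
| secondary enrichment in MS | DCA, GDCA, LCA, GLCA | +0.25 |
| secondary suppression in seronegative NMOSD | GDCA, LCA, GLCA | −0.205 |
| calibrated DCA suppression in seronegative NMOSD | DCA | +0.25 − 2.56σ |
| conjugated-UDCA elevation in NMOSD | GUDCA, TUDCA | +0.30 |

Effects are parameterised in standardised units d = δ/σ because the
two-group AUC of a single log-normal analyte then has the binormal closed
form Φ(d/√2).  The headline plant — the MS-vs-seronegative DCA separation —
is fixed at d = 2.56, giving a population AUC of 0.965; this analytic anchor
is what the acceptance checks compare against.

EDSS (ordinal, 0.5 steps on [0, 10], patients only) and spinal T2-lesion
segment counts (Poisson marginals, patients only) are coupled to named
indices through a Gaussian copula: the drivers' rank-based normal scores are
mixed into a unit-variance latent severity variable with weights solved from
R w = r (R the empirical driver correlation, r the Pearson targets
2 sin(πρ_s/6)); an infeasible system raises a configuration error naming the
offending targets.  Default Spearman targets: UDCA-family −0.30 and DCA
+0.30 against EDSS within NMOSD, LCA +0.35 within MS, and lesion-count vs
DCA +0.235 in seropositive NMOSD.  Discretisation (0.5-step rounding,
Poisson ppf) shrinks realised rank correlations slightly; at n = 2000 they
sit within ±0.05 of target.  EDSS marginals are N(4.0, 1.2) for NMOSD and
N(3.0, 0.8) for MS before rounding — calibrated to the reported medians/IQRs
of such cohorts rather than to any exact printed value, since 0.5-step data
cannot reproduce, e.g., a median of 3.55 at odd n.

**What the generator does not emulate:** assay noise floors and LLOQ
censoring, inter-analyte correlation beyond the copula couplings (analytes
are conditionally independent within groups), medication effects,
batch/centre structure, and longitudinal dynamics.  Passing tests therefore
demonstrate that the *pipeline machinery* is correct and well-calibrated
under a realistic effect structure — not that any particular real-world AUC
will replicate.

## Splitting and standardization

The 8:2 train/test split is stratified with largest-remainder seat
allocation; the total number of test seats is the ceiling of
`fraction × n`, per-stratum floors are topped up in decreasing-remainder
order.  For 112 + 50 subjects this yields 23 + 10 = 33 test subjects — the
only allocation convention consistent with a 129/33 split at 8:2 — with
membership random given the seed.  Standardization is z-scoring with
training-set moments only (ddof = 1), reused verbatim on validation and test
rows; zero-variance training columns are dropped with a warning rather than
given unit variance, because a constant feature carries no signal and
destabilises penalised fits.

## Stability selection

The penalty path is glmnet-style: 100 log-spaced values from λ_max
(= max|Xᵀ(y − ȳ)|/n, the smallest all-zero penalty) down to 10⁻³λ_max, an
unpenalised intercept, features pre-standardised upstream.  The CV loss is
binomial deviance — the natural loss for penalised logistic regression.
λ_1se is the largest penalty whose mean CV error is within one standard
error (SD across folds / √k) of the minimum.  The path walk stops 20 grid
points past the running error minimum: the remaining overfitting tail cannot
change λ_min (already passed) or λ_1se (which lies at a heavier penalty), so
the early exit is exact, not approximate.

Stability scores are outer-fold selection frequencies: an outer 5-fold
stratified CV, inner 5-fold CV tuning λ per outer-training portion, the
active set recorded per fold, retention at frequency ≥ 50%.  With K = 5
folds, scores are multiples of 20%.  The single-run reference set ("LASSO +
logistic") comes from one 10-fold CV on the full training data.  Degenerate
single-class inner folds — possible only under extreme imbalance at small
n — trigger a reshuffled fold assignment with a warning.

## Classifier benchmark

Five model kinds share the standardized feature matrix: logistic regression
on the stable set, random forest, linear-kernel SVM, gradient-boosted trees,
and logistic regression on the single-run LASSO set.  Hyperparameter grids
(frozen in `bench.DEFAULT_GRIDS`): random forest — 200/500 trees × depth
3/5/unbounded; SVM — C ∈ {0.01, 0.1, 1, 10}; boosting — learning rate
0.05/0.1 × 100/300 trees × depth 2/3.  Grids are tuned by inner 5-fold
stratified CV on AUC.  SVM probabilities come from a Platt sigmoid fit on
internal CV folds (`CalibratedClassifierCV`, non-ensemble).  Gradient
boosting is the generic algorithm as implemented in scikit-learn; nothing
depends on a branded boosting library.

Validation is three-level: (1) *stability* — 10 × 5 repeated stratified CV
on the training set, refitting the once-tuned hyperparameters per fold (a
full nested re-tune per repetition would multiply cost ~30-fold and, with
these small grids, virtually never changes the winner); (2) *robustness* —
percentile intervals from 1000 stratified bootstrap resamples of the test
predictions, with resample indices shared across models so post-hoc
comparisons are paired; (3) *generalizability* — one untouched test-set
evaluation.  Because a single threshold cannot reproduce every published
metric column on a 33-subject test set, the hold-out panel is reported
twice: at the Youden-optimal threshold and at the conventional 0.5.

Metric identities (balanced accuracy = (sens + spec)/2, J = sens + spec − 1,
F1 = 2TP/(2TP + FP + FN)) are asserted in the `MetricSet` constructor and
verified against a brute-force confusion-matrix oracle in the tests.
The Wald table for the logistic model (B, SE, z = B/SE, OR = exp(B),
CI = exp(B ± 1.96 SE)) flags quasi-separation (non-converged fit or SE > 50)
and suppresses the affected intervals.

## Single-marker inference

The AUC point estimate is the tie-aware Mann–Whitney statistic via the
rank-sum identity; the interval is DeLong's placement-value estimator
(variance = var(V₁₀)/n₁ + var(V₀₁)/n₀, ddof = 1) with normal critical
values, truncated to [0, 1]; perfect separation collapses to a zero-width
interval.  Youden cutoffs are searched over midpoints of adjacent distinct
observed values, ties in J broken toward higher specificity, and reported in
original marker units with the decision direction implied by the declared
orientation.  Orientation is a fixed input — for DCA, *low* values indicate
seronegative NMOSD — and is never auto-flipped, which would bias AUCs
upward.  The permutation test uses the add-one correction
p = (1 + #{AUC_perm ≥ AUC_obs})/(B + 1), so p is never zero and its floor at
B = 5000 is 1/5001 ≈ 0.0002; permuted AUCs are computed vectorised from the
fixed mid-rank vector.  The bootstrap interval is the stratified percentile
95% interval (B = 2000); percentile rather than BCa, stated as such.
Repeated stratified holdout (1000 × 20% draws) and repeated stratified
5-fold CV (200 repetitions, recording each repetition's mean fold AUC)
complete the robustness suite.

## Clinical utility

Decision curves use the rule "positive if probability ≥ p_t" on the grid
0.01–0.99 (step 0.01; p_t = 1 excluded as its weight diverges).  NRI is the
category-free variant — the panel defines no risk categories — with
event/non-event components in [−1, 1]; IDI is the change in discrimination
slope.  Model ranking: Friedman chi-square (average ranks for ties) over the
models × 50 fold-AUC matrix of the repeated CV — the only model × block
matrix the pipeline produces at matched granularity — followed, when
significant at 0.05, by Holm-adjusted paired t-tests on the shared test-set
bootstrap AUC samples.  A constant matrix short-circuits to statistic 0,
p = 1, no post hoc.

## Cohort statistics

Kruskal–Wallis (tie-corrected; all-tied data returns H = 0, p = 1 by
convention), Mann–Whitney, plain Pearson chi-squared (no continuity
correction), Spearman correlation with pairwise deletion (flagged undefined
on zero rank variance), and PCA on standardized indices (correlation-matrix
PCA, since the indices span orders of magnitude in scale).  The per-index
group-comparison table reports raw p-values as primary, with
Benjamini–Hochberg FDR alongside, because a reusable tool should expose the
multiplicity-adjusted view across 71 indices even where raw significance is
the convention.

## Problem sizes and determinism

Default analysis sizes follow the pre-specified framework (outer/inner k = 5,
10 × 5 repeated CV, bootstrap B = 1000/2000, 5000 permutations, 1000
holdouts, 200 k-fold repetitions).  The test suite and the acceptance script
run the Monte-Carlo calibration checks at reduced but statistically adequate
sizes (e.g. 200–2000 replicates for coverage, 20–50 seeds for recovery
studies) chosen so the whole suite completes in minutes on one CPU; each
check states its size next to its tolerance.  Every stochastic routine takes
an explicit seed, reports are written without timestamps, and a pipeline run
is byte-identical under replay with the same (config, seed).

## Known limitations

* Real-data headline values (e.g. a specific AUC on a given serum cohort)
  are not reproducible from synthetic data; the package validates arithmetic
  identities, calibration, and planted-effect recovery instead.
* The stability-selection variant is the fold-frequency definition, not
  randomised-subsample stability selection; frequencies are coarse
  (multiples of 1/K) by construction.
* NRI/IDI are reported without analytic standard errors; only bootstrap
  percentile uncertainty is available.
* The copula couples clinical scores to index *ranks*; joint tail behaviour
  beyond rank correlation is not controlled.
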