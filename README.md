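# bametrics

Serum bile-acid metabolomics toolkit for the differential diagnosis of
neuromyelitis optica spectrum disorder (NMOSD) and multiple sclerosis (MS),
with a focus on the AQP4-IgG–seronegative NMOSD subgroup, where no antibody
marker is available and misdiagnosis carries real treatment risk.

The package is aimed at clinical metabolomics and biomarker-discovery groups
working with targeted bile-acid panels.  It provides, as reusable library
code:

* **A fixed 71-index bile-acid feature engine.**  From 15 quantified serum
  bile acids (TCA, TCDCA, GCA, GCDCA, CDCA, CA; DCA, GDCA, TDCA, LCA, GLCA,
  TLCA, UDCA, GUDCA, TUDCA, μmol/L) it derives 17 physiologic pools (total,
  primary/secondary, conjugation classes, 12-OH vs non-12-OH, the CA/CDCA/
  DCA/LCA/UDCA families, neurotoxic and neuroprotective sets), 31 fractional
  compositions of the total pool, and 8 pathway ratios such as
  12-OH/non-12-OH, GLCA/TLCA and GDCA/TDCA.
* **Stability-selected sparse modelling.**  Nested stratified cross-validation
  with inner L1-penalised logistic regression under the one-standard-error
  rule (λ.1se); a feature's *stability score* is the fraction of outer folds
  in which it enters the active set, and features scoring ≥ 50% form the
  final predictor subset.
* **A five-classifier benchmark** (logistic on stable features, random
  forest, linear SVM with Platt calibration, gradient-boosted trees,
  logistic on a single-run LASSO set) under a three-level validation
  strategy: repeated 10×5 cross-validation, stratified test-set bootstrap
  (B = 1000), and a one-shot held-out evaluation.
* **Single-marker ROC robustness**: Mann–Whitney AUC, DeLong confidence
  intervals, Youden-optimal cutoffs, stratified bootstrap (B = 2000), label
  permutation tests (B = 5000, add-one corrected), repeated stratified
  holdout and repeated stratified 5-fold evaluation.
* **Clinical utility**: decision-curve analysis
  (NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)), category-free NRI and IDI against a
  baseline model, and Friedman + Holm–Bonferroni model ranking.
* **A synthetic cohort generator** reproducing the study's group structure
  (80 seropositive NMOSD, 32 seronegative NMOSD, 50 MS, 66 healthy controls)
  with log-normal concentrations, planted group contrasts, and
  Gaussian-copula coupling of EDSS / spinal-lesion counts to named indices —
  so every stage of the pipeline is testable without patient data.

## Worked example

Score the suppressed-secondary-bile-acid marker (DCA, oriented so that *low*
values indicate seronegative NMOSD) on a synthetic seronegative-vs-MS cohort:

```python
from bametrics.simulate import default_study_config, generate_cohort
from bametrics.catalogue import build_feature_table
from bametrics.roc import marker_inference

cohort = generate_cohort(default_study_config(), seed=7)
table = build_feature_table(cohort.data)
mask = table.labels.isin(["NMOSD_AQP4neg", "MS"])
dca = table.features.loc[mask, "DCA"].to_numpy()
y = (table.labels.loc[mask] == "NMOSD_AQP4neg").astype(int).to_numpy()

mi = marker_inference(dca, y, marker="DCA", orientation="low", seed=7)
```

which prints, via the fields of `mi`:

```
AUC            0.946  (DeLong 95% CI 0.897-0.994)
Youden cutoff  DCA <= 0.222 umol/L  (sens 0.938, spec 0.840)
bootstrap 95%  0.894-0.984  (B=2000)
permutation p  0.0002  (B=5000)
holdout 95%    0.814-1.000  (1000 repeats)
5-fold 95%     0.927-0.965  (200 repetitions)
```

The generator plants a 2.56-standardised-unit suppression of log DCA in the
seronegative group, whose population AUC is Φ(2.56/√2) ≈ 0.965; a single
32-vs-50 cohort scatters around that value, the permutation p sits at its
floor 1/5001 ≈ 0.0002, and the repeated-cross-validation interval is narrow
because fold means average out split noise.

The full pipeline — indices, 8:2 stratified split, stability selection,
benchmark, marker robustness, utility and descriptive statistics — runs from
the shell:

```bash
bametrics run-all --seed 1 --out report/
bametrics simulate --seed 1 --out cohort.csv   # or any subject-level CSV
bametrics indices cohort.csv
```

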