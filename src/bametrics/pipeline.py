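"""End-to-end orchestration: cohort -> indices -> selection -> models -> report.

``run_pipeline`` executes the full analysis on either a subject-level CSV or a
synthetic cohort: catalogue evaluation, leakage-safe 8:2 split, nested
stability selection, the five-model benchmark with three-level validation,
single-marker robustness (default DCA, seronegative-NMOSD-vs-MS, low
orientation), clinical-utility statistics, and cohort descriptives.  Every
artefact lands in a report directory as CSV/JSON with a provenance block
(config hash + seed) so a run is exactly replayable; no timestamps are
written, so replays are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bench, roc, stability, utility
from .catalogue import ANALYTES, build_feature_table, default_catalogue
from .preprocess import apply_standardizer, fit_standardizer, stratified_split
from .simulate import CohortConfig, default_study_config, generate_cohort
from .stats import group_comparison_table, pca_scores, spearman

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("bametrics.pipeline")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and replay seed."""

    def __init__(self, stage: str, seed: int, cause: Exception):
        super().__init__(f"stage {stage!r} failed (replay seed {seed}): {cause}")
        self.stage = stage
        self.seed = seed


@dataclass
class PipelineConfig:
    """Run parameters; defaults mirror the pre-specified validation framework."""

    input_csv: str | None = None          # None -> synthetic default cohort
    output_dir: str = "report"
    seed: int = 0
    test_fraction: float = 0.2
    outer_k: int = 5
    inner_k: int = 5
    stability_threshold: float = 0.5
    n_lambda: int = 100
    cv_repeats: int = 10
    cv_k: int = 5
    bootstrap_B: int = 1000
    marker: str = "DCA"
    marker_orientation: str = "low"       # low DCA marks seronegative NMOSD
    marker_groups: tuple[str, str] = ("NMOSD_AQP4neg", "MS")
    marker_bootstrap_B: int = 2000
    marker_permutation_B: int = 5000
    marker_holdout_repeats: int = 1000
    marker_kfold_repetitions: int = 200
    selection_positive: tuple[str, ...] = ("NMOSD_AQP4pos", "NMOSD_AQP4neg")
    selection_negative: tuple[str, ...] = ("MS",)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["marker_groups"] = list(self.marker_groups)
        d["selection_positive"] = list(self.selection_positive)
        d["selection_negative"] = list(self.selection_negative)
        return d


def _stage(name: str, seed: int):
    """Context wrapper converting stage exceptions into PipelineStageError."""
    class _Ctx:
        def __enter__(self):
            log.info("stage %s (seed %d)", name, seed)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineStageError(name, seed, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a manifest of written artefacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest: dict[str, str] = {}

    # ---- cohort ----------------------------------------------------------
    with _stage("cohort", seed):
        if config.input_csv is not None:
            cohort_df = pd.read_csv(config.input_csv)
            provenance = {"input_csv": str(config.input_csv), "seed": seed}
        else:
            sim_cfg = default_study_config()
            cohort = generate_cohort(sim_cfg, seed=seed)
            cohort_df = cohort.data
            provenance = dict(cohort.provenance)
            cohort_df.to_csv(out / "cohort.csv", index=False)
            manifest["cohort"] = "cohort.csv"

    # ---- indices ---------------------------------------------------------
    with _stage("indices", seed):
        catalogue = default_catalogue()
        table = build_feature_table(cohort_df, catalogue)
        table.to_csv(out / "features.csv")
        (out / "features.schema.json").write_text(json.dumps(table.schema(), indent=2))
        (out / "catalogue.json").write_text(catalogue.to_json())
        manifest["features"] = "features.csv"

    # ---- selection task: NMOSD vs MS ------------------------------------
    with _stage("split", seed):
        pos = set(config.selection_positive)
        neg = set(config.selection_negative)
        mask = table.labels.isin(pos | neg).to_numpy()
        X_all = table.features.loc[mask]
        y_all = table.labels.loc[mask].isin(pos).astype(int).to_numpy()
        # modelling uses complete columns only (ratio indices can go missing
        # on zero denominators; missingness is handled by column deletion)
        complete = [c for c in X_all.columns if X_all[c].notna().all()]
        X_all = X_all[complete]
        plan = stratified_split(y_all, test_fraction=config.test_fraction, seed=seed)
        (out / "split.json").write_text(json.dumps(plan.to_json_dict(), indent=2))
        X_train_raw = X_all.iloc[plan.train_idx]
        X_test_raw = X_all.iloc[plan.test_idx]
        y_train = y_all[plan.train_idx]
        y_test = y_all[plan.test_idx]

    with _stage("standardize", seed):
        params = fit_standardizer(X_train_raw)
        X_train = apply_standardizer(params, X_train_raw)
        X_test = apply_standardizer(params, X_test_raw)

    with _stage("stability_selection", seed):
        stab = stability.nested_stability_selection(
            X_train.to_numpy(), y_train, feature_names=list(X_train.columns),
            outer_k=config.outer_k, inner_k=config.inner_k,
            threshold=config.stability_threshold, seed=seed,
            n_lambda=config.n_lambda,
        )
        pd.DataFrame(stab.to_records()).to_csv(out / "stability.csv", index=False)
        manifest["stability"] = "stability.csv"
        lasso_set = stability.single_lasso_reference(
            X_train.to_numpy(), y_train, feature_names=list(X_train.columns),
            inner_k=10, seed=seed, n_lambda=config.n_lambda,
        )
        stable_set = stab.retained
        if not stable_set:
            log.warning("empty stable set; falling back to single-run LASSO set")
            stable_set = lasso_set
        if not lasso_set:
            lasso_set = stable_set
        if not stable_set:
            # both empty (null data): take the three most frequently selected
            ranked = sorted(stab.frequencies, key=stab.frequencies.get, reverse=True)
            stable_set = lasso_set = ranked[:3]

    with _stage("benchmark", seed):
        specs = {
            "logistic": stable_set,
            "random_forest": stable_set,
            "svm_linear": stable_set,
            "gradient_boosting": stable_set,
            "lasso_logistic": lasso_set,
        }
        result = bench.three_level_validation(
            specs, X_train, y_train, X_test, y_test, positive_label=1,
            reps=config.cv_repeats, k=config.cv_k, boot_B=config.bootstrap_B,
            inner_k=config.inner_k, seed=seed,
        )
        result.panel().to_csv(out / "model_metrics.csv", index=False)
        manifest["model_metrics"] = "model_metrics.csv"
        summary = bench.summarize_logistic(X_train, y_train, stable_set, positive_label=1)
        summary.to_csv(out / "logistic_summary.csv", index=False)

    with _stage("utility", seed):
        baseline_kind = "logistic"
        fitted = {}
        for kind, feats in specs.items():
            m = bench.train_model(kind, X_train, y_train, feats, positive_label=1,
                                  inner_k=config.inner_k, seed=seed)
            fitted[kind] = m.predict_proba(X_test)
        curves = []
        for kind, probs in fitted.items():
            c = utility.decision_curve(probs, y_test).to_frame()
            c.insert(0, "model", kind)
            curves.append(c)
        pd.concat(curves, ignore_index=True).to_csv(out / "decision_curves.csv", index=False)
        reclass = []
        for kind, probs in fitted.items():
            if kind == baseline_kind:
                continue
            r = utility.nri_continuous(fitted[baseline_kind], probs, y_test,
                                       baseline=baseline_kind, comparator=kind)
            reclass.append(asdict(r))
        comparison = utility.friedman_with_holm(result.fold_auc_matrix,
                                                result.bootstrap_matrix)
        payload = {
            "friedman_statistic": comparison.friedman_statistic,
            "friedman_p": comparison.friedman_p,
            "pairwise": None if comparison.pairwise is None
            else comparison.pairwise.to_dict(orient="records"),
            "reclassification": reclass,
        }
        (out / "utility.json").write_text(json.dumps(payload, indent=2))
        manifest["utility"] = "utility.json"

    with _stage("marker", seed):
        g_pos, g_neg = config.marker_groups
        m_mask = table.labels.isin([g_pos, g_neg])
        scores = table.features.loc[m_mask, config.marker].to_numpy()
        m_labels = (table.labels.loc[m_mask] == g_pos).astype(int).to_numpy()
        if m_labels.min() == m_labels.max():
            raise ValueError(f"marker task groups missing: {config.marker_groups}")
        mi = roc.marker_inference(
            scores, m_labels, marker=config.marker,
            orientation=config.marker_orientation,
            bootstrap_B=config.marker_bootstrap_B,
            permutation_B=config.marker_permutation_B,
            holdout_repeats=config.marker_holdout_repeats,
            kfold_repetitions=config.marker_kfold_repetitions,
            seed=seed,
        )
        (out / f"marker_{config.marker}.json").write_text(mi.to_json())
        manifest["marker"] = f"marker_{config.marker}.json"

    with _stage("cohort_stats", seed):
        comp = group_comparison_table(table.features, table.labels)
        comp.to_csv(out / "group_comparisons.csv", index=False)
        std_all = (table.features - table.features.mean()) / table.features.std(ddof=1)
        std_all = std_all.dropna(axis=1, how="any")
        pca = pca_scores(std_all.to_numpy(), n_components=2)
        pd.DataFrame({
            "subject_id": table.features.index,
            "group": table.labels.to_numpy(),
            "PC1": pca.scores[:, 0],
            "PC2": pca.scores[:, 1],
        }).to_csv(out / "pca_scores.csv", index=False)
        corr_rows = []
        if "EDSS" in table.covariates.columns:
            for grp, index_name in (("NMOSD_AQP4pos", "UDCAs"), ("NMOSD_AQP4pos", "DCA"),
                                    ("NMOSD_AQP4neg", "UDCAs"), ("NMOSD_AQP4neg", "DCA"),
                                    ("MS", "LCA")):
                gm = table.labels == grp
                if gm.sum() < 3:
                    continue
                try:
                    r = spearman(table.features.loc[gm, index_name],
                                 table.covariates.loc[gm, "EDSS"],
                                 pair=(index_name, "EDSS"), group=grp)
                except ValueError:
                    continue
                corr_rows.append({"group": grp, "index": index_name,
                                  "rho": r.rho, "p": r.p, "n": r.n})
        pd.DataFrame(corr_rows).to_csv(out / "edss_correlations.csv", index=False)
        manifest["group_comparisons"] = "group_comparisons.csv"

    prov = {"config": config.to_json_dict(), "cohort": provenance, "seed": seed}
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
    manifest["provenance"] = "provenance.json"
    return manifest
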