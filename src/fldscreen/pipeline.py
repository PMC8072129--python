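"""End-to-end screening pipeline with on-disk artifacts.

Stage order mirrors the screening workflow: simulate (or load) the
cohort, filter unlabelled rows and sparse columns, split 70/30, fit the
ChiMerge age bins on the training set, impute by (age-bin x sex)
medians, synthesise symbolic features, train the boosted classifier and
write the evaluation report. Each stage reads the previous stage's
artifacts from the output directory, so the subcommands in
:mod:`fldscreen.cli` can be run one at a time or all at once with
identical results.

A single global seed deterministically derives one sub-seed per
stochastic stage, so re-running any stage alone reproduces its output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chimerge, evaluate, gp, impute, prep, tables
from .cohort import CohortConfig, simulate_cohort
from .exceptions import ConfigurationError
from .tables import AGE, LABEL, labels

log = logging.getLogger("fldscreen")

_STAGE_IDS = {"cohort": 11, "split": 12, "gp": 13, "classifier": 14}


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (always below 2**31)."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] >> 1)


@dataclass
class PipelineConfig:
    """All stage configurations plus the global seed and IO options."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    prep: prep.PrepConfig = field(default_factory=prep.PrepConfig)
    gp: gp.GPConfig = field(default_factory=gp.GPConfig)
    classifier: evaluate.ClassifierConfig = field(
        default_factory=evaluate.ClassifierConfig)
    target_bins: int = 5
    gp_enabled: bool = True
    seed: int = 0
    learning_grid: tuple[int, ...] = (10, 25, 50, 75, 100, 150)
    incremental_max: int = 10
    threshold: float = 0.5
    input_csv: str | None = None

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Propagate a global seed to every stochastic stage."""
        return replace(
            self,
            seed=seed,
            cohort=replace(self.cohort, seed=derive_seed(seed, "cohort")),
            prep=replace(self.prep, split_seed=derive_seed(seed, "split")),
            gp=replace(self.gp, seed=derive_seed(seed, "gp")),
            classifier=replace(self.classifier,
                               seed=derive_seed(seed, "classifier")),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Build a config from a flat YAML file of optional sections."""
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {"cohort", "prep", "gp", "classifier", "pipeline"}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")

        def section(name, factory):
            params = doc.get(name, {}) or {}
            try:
                return factory(**params)
            except TypeError as exc:
                raise ConfigurationError(f"bad {name} section: {exc}") from exc

        cfg = cls(
            cohort=section("cohort", CohortConfig),
            prep=section("prep", prep.PrepConfig),
            gp=section("gp", gp.GPConfig),
            classifier=section("classifier", evaluate.ClassifierConfig),
        )
        top = doc.get("pipeline", {}) or {}
        if "learning_grid" in top:
            top["learning_grid"] = tuple(top["learning_grid"])
        cfg = replace(cfg, **top)
        if "seed" in top:
            cfg = cfg.with_seed(int(top["seed"]))
        return cfg


def _path(out_dir, name) -> Path:
    p = Path(out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p / name


# ------------------------------------------------------------- stages

def stage_simulate(config: PipelineConfig, out_dir) -> Path:
    """Write the input cohort CSV (synthetic, or a copy of input_csv)."""
    dest = _path(out_dir, "cohort.csv")
    if config.input_csv:
        table = tables.read_csv(config.input_csv)
    else:
        table = simulate_cohort(config.cohort)
    tables.write_csv(table, dest)
    log.info("cohort: %d rows, %d feature columns", len(table),
             len(tables.feature_columns(table)))
    return dest


def stage_prep(config: PipelineConfig, out_dir) -> tuple[Path, Path]:
    table = tables.read_csv(_path(out_dir, "cohort.csv"))
    table = prep.filter_unlabeled(table)
    table, dropped = prep.drop_sparse_features(table, config.prep)
    log.info("prep: dropped sparse columns %s", dropped)
    pd.DataFrame({"dropped_column": dropped}).to_csv(
        _path(out_dir, "dropped_columns.csv"), index=False)
    prep.class_summary(table).to_csv(
        _path(out_dir, "class_summary.csv"), index=False)
    train, test = prep.split_train_test(table, config.prep)
    tables.write_csv(train, _path(out_dir, "train.csv"))
    tables.write_csv(test, _path(out_dir, "test.csv"))
    log.info("prep: split %d train / %d test", len(train), len(test))
    return _path(out_dir, "train.csv"), _path(out_dir, "test.csv")


def stage_bin(config: PipelineConfig, out_dir) -> chimerge.BinningScheme:
    train = tables.read_csv(_path(out_dir, "train.csv"))
    scheme = chimerge.fit_chimerge(train[AGE].to_numpy(dtype=float),
                                   labels(train), config.target_bins)
    _path(out_dir, "age_bins.json").write_text(scheme.to_json())
    log.info("bin: age intervals %s", scheme.intervals())
    return scheme


def stage_impute(config: PipelineConfig, out_dir) -> None:
    scheme = chimerge.BinningScheme.from_json(
        _path(out_dir, "age_bins.json").read_text())
    train = tables.read_csv(_path(out_dir, "train.csv"))
    test = tables.read_csv(_path(out_dir, "test.csv"))
    plan = impute.fit_imputer(train, scheme)
    if plan.unusable:
        log.info("impute: dropping unusable columns %s", plan.unusable)
        train = train.drop(columns=plan.unusable)
        test = test.drop(columns=[c for c in plan.unusable if c in test])
    _path(out_dir, "imputation_plan.json").write_text(plan.to_json())
    tables.write_csv(impute.apply_imputer(plan, train),
                     _path(out_dir, "train_imputed.csv"))
    tables.write_csv(impute.apply_imputer(plan, test),
                     _path(out_dir, "test_imputed.csv"))


def stage_gpfeat(config: PipelineConfig, out_dir) -> list[gp.SymbolicFeature]:
    train = tables.read_csv(_path(out_dir, "train_imputed.csv"))
    test = tables.read_csv(_path(out_dir, "test_imputed.csv"))
    if not config.gp_enabled:
        _path(out_dir, "gp_features.json").write_text(json.dumps([]))
        tables.write_csv(train, _path(out_dir, "train_model.csv"))
        tables.write_csv(test, _path(out_dir, "test_model.csv"))
        log.info("gpfeat: disabled, tables passed through")
        return []
    train_norm = gp.normalize_features(train)
    test_norm = gp.normalize_features(train, test)
    result = gp.run_gp(train_norm, labels(train), config.gp)
    for g, best in enumerate(result.best_per_generation):
        log.info("gpfeat: generation %d best fitness %.4f", g, best)
    doc = [{"expression": f.expression, "fitness": f.fitness}
           for f in result.features]
    _path(out_dir, "gp_features.json").write_text(json.dumps(doc, indent=1))
    train_out = train.copy()
    test_out = test.copy()
    for i, f in enumerate(result.features, start=1):
        train_out[f"GA_fea{i}"] = gp.evaluate_tree(f.tree, train_norm)
        test_out[f"GA_fea{i}"] = gp.evaluate_tree(f.tree, test_norm)
    tables.write_csv(train_out, _path(out_dir, "train_model.csv"))
    tables.write_csv(test_out, _path(out_dir, "test_model.csv"))
    return result.features


def stage_train(config: PipelineConfig, out_dir) -> evaluate.ModelHandle:
    train = tables.read_csv(_path(out_dir, "train_model.csv"))
    handle = evaluate.train_classifier(train, config.classifier)
    handle.model.get_booster().save_model(str(_path(out_dir, "model.ubj")))
    log.info("train: %d boosting rounds, hyperparameters %s",
             config.classifier.n_estimators, config.classifier)
    return handle


def stage_evaluate(config: PipelineConfig, out_dir,
                   handle: evaluate.ModelHandle | None = None,
                   full_curves: bool = True) -> evaluate.EvaluationReport:
    train = tables.read_csv(_path(out_dir, "train_model.csv"))
    test = tables.read_csv(_path(out_dir, "test_model.csv"))
    if handle is None:
        # training is seeded and deterministic, so refitting reproduces
        # the persisted booster exactly
        handle = evaluate.train_classifier(train, config.classifier)
    train_auc = evaluate.auc(handle.scores(train), labels(train))
    test_auc = evaluate.auc(handle.scores(test), labels(test))
    importances = evaluate.feature_importance(handle)
    report = evaluate.EvaluationReport(
        train_auc=train_auc, test_auc=test_auc, importances=importances)
    importances.to_csv(_path(out_dir, "feature_importance.csv"), index=False)
    if full_curves:
        report.learning_curve = evaluate.learning_curve(
            train, test, config.classifier, config.learning_grid)
        report.learning_curve.to_csv(
            _path(out_dir, "learning_curve.csv"), index=False)
        max_m = min(config.incremental_max, len(importances))
        report.incremental_curve = evaluate.incremental_feature_curve(
            train, test, config.classifier,
            importances["feature"].tolist(), max_m)
        report.incremental_curve.to_csv(
            _path(out_dir, "incremental_auc.csv"), index=False)
    report.false_negatives = evaluate.false_negative_summary(
        test, handle.scores(test), config.threshold)
    report.false_negatives.to_csv(
        _path(out_dir, "false_negative_summary.csv"), index=False)
    gp_file = _path(out_dir, "gp_features.json")
    gp_doc = json.loads(gp_file.read_text()) if gp_file.exists() else []
    summary = {
        "train_auc": train_auc,
        "test_auc": test_auc,
        "gp_features": gp_doc,
        "gp_enabled": bool(config.gp_enabled and gp_doc),
        "n_train": len(train),
        "n_test": len(test),
        "top_features": importances["feature"].head(10).tolist(),
    }
    if not gp_doc:
        summary["note"] = "no symbolic features (GP disabled or empty)"
    _path(out_dir, "summary.json").write_text(json.dumps(summary, indent=1))
    log.info("evaluate: train AUC %.4f / test AUC %.4f", train_auc, test_auc)
    return report


def run_pipeline(config: PipelineConfig, out_dir,
                 full_curves: bool = True) -> evaluate.EvaluationReport:
    """Run every stage in order; returns the evaluation report."""
    stage_simulate(config, out_dir)
    stage_prep(config, out_dir)
    stage_bin(config, out_dir)
    stage_impute(config, out_dir)
    stage_gpfeat(config, out_dir)
    handle = stage_train(config, out_dir)
    return stage_evaluate(config, out_dir, handle, full_curves=full_curves)


def run_study(config: PipelineConfig,
              compare_without_gp: bool = False) -> dict:
    """In-memory end-to-end run returning the study's key quantities.

    Same stage order as :func:`run_pipeline` but without on-disk
    artifacts, for simulation studies that sweep seeds. The returned
    dict holds the cohort prevalence, the fitted age cut points, the
    synthesised features with their fitness, the best single raw
    feature's Spearman fitness, train/test AUC and the split-count
    importances; with ``compare_without_gp`` also the test AUC of a
    model trained on the raw features alone.
    """
    if config.input_csv:
        table = tables.read_csv(config.input_csv)
    else:
        table = simulate_cohort(config.cohort)
    table = prep.filter_unlabeled(table)
    table, dropped = prep.drop_sparse_features(table, config.prep)
    train, test = prep.split_train_test(table, config.prep)
    y_train, y_test = labels(train), labels(test)

    scheme = chimerge.fit_chimerge(train[AGE].to_numpy(dtype=float),
                                   y_train, config.target_bins)
    plan = impute.fit_imputer(train, scheme)
    if plan.unusable:
        train = train.drop(columns=plan.unusable)
        test = test.drop(columns=[c for c in plan.unusable if c in test])
    train = impute.apply_imputer(plan, train)
    test = impute.apply_imputer(plan, test)

    out = {
        "prevalence": float(table[LABEL].mean()),
        "dropped_columns": dropped,
        "age_cut_points": list(scheme.cut_points),
        "n_train": len(train),
        "n_test": len(test),
    }
    if config.gp_enabled:
        train_norm = gp.normalize_features(train)
        test_norm = gp.normalize_features(train, test)
        result = gp.run_gp(train_norm, y_train, config.gp)
        out["gp_features"] = [{"expression": f.expression,
                               "fitness": f.fitness}
                              for f in result.features]
        out["best_gp_fitness"] = result.features[0].fitness
        out["raw_feature_fitness"] = {
            c: gp.spearman_fitness(train[c].to_numpy(dtype=float), y_train)
            for c in tables.feature_columns(train)}
        for i, f in enumerate(result.features, start=1):
            train[f"GA_fea{i}"] = gp.evaluate_tree(f.tree, train_norm)
            test[f"GA_fea{i}"] = gp.evaluate_tree(f.tree, test_norm)

    handle = evaluate.train_classifier(train, config.classifier)
    out["train_auc"] = evaluate.auc(handle.scores(train), y_train)
    out["test_auc"] = evaluate.auc(handle.scores(test), y_test)
    out["importances"] = evaluate.feature_importance(handle)
    out["_tables"] = (train, test)
    out["_handle"] = handle
    if compare_without_gp and config.gp_enabled:
        raw_cols = [c for c in train.columns if not c.startswith("GA_fea")]
        raw_handle = evaluate.train_classifier(
            train[raw_cols], config.classifier)
        out["test_auc_without_gp"] = evaluate.auc(
            raw_handle.scores(test), y_test)
    return out
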