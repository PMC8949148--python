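"""End-to-end analysis orchestration.

``run_full`` executes the whole study on one dataset: split, rule
baseline, staged feature selection, tree tuning and fitting, holdout
evaluation of both classifiers, and the statistical comparison of feature
sets.  A single master seed fans out to per-stage seeds by fixed offsets,
so one integer reproduces every output bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import amenability_tree as tree_mod
from . import compare_stats, multilabel_metrics, rule_baseline, tabular_io
from . import staged_selection
from .synthetic_descriptors import SyntheticConfig, generate

logger = logging.getLogger(__name__)

# fixed offsets from the master seed, one per randomised stage
SEED_OFFSETS = {
    "synthetic": 11,
    "split": 23,
    "selection": 37,
    "grid": 53,
    "tree": 71,
    "cv": 89,
}


@dataclass
class RunConfig:
    """Everything one analysis run depends on."""

    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    test_fraction: float = 0.2
    selection: staged_selection.SelectionConfig = field(
        default_factory=staged_selection.SelectionConfig)
    grid: tree_mod.GridSpec | None = None
    tree_hyperparameters: dict = field(default_factory=lambda: {"max_depth": 4})
    cv_folds: int = 10
    cv_repetitions: int = 10
    compare_stage_sets: tuple[str, ...] = ("initial", "importance", "final")
    rule_thresholds: rule_baseline.RuleThresholds = field(
        default_factory=rule_baseline.RuleThresholds)
    rule_column_map: dict | None = None
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 101 + SEED_OFFSETS[stage]) % (2**31 - 1)


def _load(config: RunConfig):
    if config.input_csv is not None:
        return tabular_io.read_labeled_table(config.input_csv)
    if config.synthetic is not None:
        cfg = config.synthetic
        if cfg.seed == 0 and config.seed != 0:
            cfg = SyntheticConfig(**{**cfg.to_dict(),
                                     "thresholds": cfg.thresholds,
                                     "seed": config.stage_seed("synthetic")})
        table, labels, _ = generate(cfg)
        return table, labels
    raise ValueError("RunConfig needs either input_csv or a synthetic recipe")


def run_full(config: RunConfig, out_dir) -> dict:
    """Run the complete analysis; write artifacts under ``out_dir``.

    Returns the manifest dict (also written to manifest.json).  Stage
    errors propagate annotated with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed,
                      "stage_seeds": {s: config.stage_seed(s)
                                      for s in SEED_OFFSETS},
                      "stages": []}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(
                {"name": name, "elapsed_s": round(time.perf_counter() - t0, 3)})
            logger.info("stage %s done", name)
            return result
        return deco

    table, labels = stage("load")(lambda: _load(config))
    manifest["n"], manifest["p"] = table.n, table.p

    split = stage("split")(lambda: tabular_io.split_train_test(
        table.n, config.test_fraction, config.stage_seed("split")))
    manifest["n_train"] = int(len(split.train_indices))
    manifest["n_test"] = int(len(split.test_indices))
    tr_table, tr_labels = (table.take_rows(split.train_indices),
                           labels.take_rows(split.train_indices))
    te_table, te_labels = (table.take_rows(split.test_indices),
                           labels.take_rows(split.test_indices))

    # rule baseline on the holdout
    rbc_pred = stage("baseline")(lambda: rule_baseline.predict_table(
        te_table, config.rule_column_map, config.rule_thresholds))
    rbc_report = multilabel_metrics.classification_report(te_labels, rbc_pred)
    (out / "rbc_report.json").write_text(json.dumps(rbc_report.to_dict(), indent=2))

    # feature selection on the training portion only
    sel_cfg = staged_selection.SelectionConfig(
        **{**config.selection.to_dict(), "seed": config.stage_seed("selection")})
    trace = stage("select")(lambda: staged_selection.run_pipeline(
        tr_table, tr_labels, sel_cfg))
    tabular_io.write_trace(trace, out / "selection_trace.json")
    (out / "stage_counts.tsv").write_text(trace.counts_tsv())
    final_features = trace.final
    manifest["final_features"] = final_features

    # hyperparameters: grid search if a grid is given, else the fixed ones
    if config.grid is not None:
        hp, score, results = stage("tune")(lambda: tree_mod.grid_search(
            tr_table.subset(final_features), tr_labels, config.grid,
            folds=config.cv_folds, seed=config.stage_seed("grid")))
        results.to_csv(out / "grid_results.csv", index=False)
        manifest["grid_best"] = {"hyperparameters": hp, "cv_score": score}
    else:
        hp = dict(config.tree_hyperparameters)
    manifest["tree_hyperparameters"] = hp

    model = stage("train")(lambda: tree_mod.fit(
        tr_table.subset(final_features), tr_labels, hp,
        seed=config.stage_seed("tree")))
    tabular_io.write_model(model, out / "model.json")
    (out / "model.dot").write_text(tree_mod.export_dot(model))

    tree_pred = tree_mod.predict(model, te_table)
    tree_report = multilabel_metrics.classification_report(te_labels, tree_pred)
    (out / "tree_report.json").write_text(json.dumps(tree_report.to_dict(), indent=2))

    # paired CV comparison of the recorded feature-set stages
    stage_sets = {s["name"]: s["retained"] for s in trace.stages}
    methods = {}
    for name in config.compare_stage_sets:
        cols = [table.feature_names.index(f) for f in stage_sets[name]]
        methods[name] = (lambda c=cols: tree_mod.TreeMethod(
            hp, seed=config.stage_seed("tree"), columns=c))
    cv = stage("compare_cv")(lambda: compare_stats.repeated_cv(
        methods, tr_table, tr_labels, folds=config.cv_folds,
        repetitions=config.cv_repetitions, seed=config.stage_seed("cv")))
    pair = (config.compare_stage_sets[0], config.compare_stage_sets[-1])
    comparison = compare_stats.compare_feature_sets(cv, wilcoxon_pair=pair)

    # McNemar RBC vs tree per class on the holdout
    mc = {}
    for j, cls in enumerate(("GC", "LC")):
        try:
            chi2, p, oratio, b, c = compare_stats.mcnemar(
                te_labels.labels[:, j], tree_pred.labels[:, j],
                rbc_pred.labels[:, j])
            mc[cls] = {"chi2": chi2, "p": p, "odds_ratio": oratio,
                       "b": b, "c": c}
        except ValueError as exc:  # no discordant pairs on tiny holdouts
            mc[cls] = {"diagnostic": str(exc)}
    comparison.mcnemar = mc
    (out / "comparison.json").write_text(json.dumps(comparison.to_dict(), indent=2))

    manifest["holdout"] = {
        "tree_label_based_accuracy": tree_report.label_based_accuracy,
        "rbc_label_based_accuracy": rbc_report.label_based_accuracy,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
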