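"""Holdout evaluation and the statistical comparison of feature sets.

Scores the fitted tree and the rule baseline on the holdout (reports,
McNemar per class), then compares all six feature-set stages under paired
10x10 cross-validation: Friedman + Kendall's W, Nemenyi post hoc, and the
one-sided Wilcoxon (final > initial) with MPRBC and CLES effect sizes.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402

from amenability import compare_stats as cs  # noqa: E402
from amenability.amenability_tree import TreeMethod, predict  # noqa: E402
from amenability.multilabel_metrics import classification_report  # noqa: E402
from amenability.rule_baseline import predict_table  # noqa: E402
from amenability.tabular_io import read_model, read_trace  # noqa: E402


def main() -> None:
    common.ensure_dirs()
    table, labels, _, split = common.load_study()
    tr_t = table.take_rows(split.train_indices)
    tr_l = labels.take_rows(split.train_indices)
    te_t = table.take_rows(split.test_indices)
    te_l = labels.take_rows(split.test_indices)

    model_path = common.RESULTS / "model.json"
    trace_path = common.RESULTS / "selection_trace.json"
    if not (model_path.exists() and trace_path.exists()):
        sys.exit("run 03_feature_selection.py and 04_fit_tree.py first")
    model = read_model(model_path)
    trace = read_trace(trace_path)

    tree_pred = predict(model, te_t)
    rbc_pred = predict_table(te_t)
    tree_rep = classification_report(te_l, tree_pred)
    (common.RESULTS / "tree_report.json").write_text(
        json.dumps(tree_rep.to_dict(), indent=2))
    print("tree holdout report:")
    print(tree_rep.to_tsv())

    mc = {}
    for j, cls in enumerate(("GC", "LC")):
        try:
            chi2, p, oratio, b, c = cs.mcnemar(te_l.labels[:, j],
                                               tree_pred.labels[:, j],
                                               rbc_pred.labels[:, j])
            mc[cls] = {"chi2": chi2, "p": p, "odds_ratio": oratio,
                       "b": b, "c": c}
            print(f"McNemar {cls}: chi2={chi2:.2f} p={p:.4g} OR={oratio:.2f} "
                  f"(b={b}, c={c})")
        except ValueError as exc:
            mc[cls] = {"diagnostic": str(exc)}
            print(f"McNemar {cls}: {exc}")

    stage_sets = {s["name"]: s["retained"] for s in trace.stages}
    methods = {}
    for name in ("initial", "variance", "correlation", "importance",
                 "rfecv", "final"):
        cols = [tr_t.feature_names.index(f) for f in stage_sets[name]]
        methods[name] = (lambda c=cols: TreeMethod(
            common.TREE_HP, seed=common.TREE_SEED, columns=c))
    cv = cs.repeated_cv(methods, tr_t, tr_l, folds=10, repetitions=10,
                        seed=common.CV_SEED)
    report = cs.compare_feature_sets(cv, wilcoxon_pair=("initial", "final"))
    report.mcnemar = mc
    (common.RESULTS / "comparison.json").write_text(
        json.dumps(report.to_dict(), indent=2))

    means = {m: 100 * cv.scores[m].mean() for m in cv.method_names}
    print("mean CV label-based accuracy per feature set (%):",
          {k: round(v, 2) for k, v in means.items()})
    print(f"Friedman Q={report.friedman_q:.2f} p={report.friedman_p:.4g} "
          f"Kendall W={report.kendall_w:.3f}")
    print("Nemenyi p (final vs earlier stages):",
          np.round(np.array(report.nemenyi_p)[-1, :-1], 3).tolist())
    print(f"Wilcoxon final>initial: W={report.wilcoxon_w:.1f} "
          f"p={report.wilcoxon_p:.4g} MPRBC={report.mprbc:.3f} "
          f"CLES={report.cles:.3f}")


if __name__ == "__main__":
    main()
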