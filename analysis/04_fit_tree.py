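"""Tune the tree depth on the selected features and fit the final model.

Produces the depth validation curve, the recommended depth (smallest depth
within one accuracy point of the best), and the fitted depth-4 tree with
its DOT rendering.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402

from amenability.amenability_tree import (depth_validation_curve,  # noqa: E402
                                          export_dot, fit)
from amenability.tabular_io import read_trace, write_model  # noqa: E402


def main() -> None:
    common.ensure_dirs()
    table, labels, _, split = common.load_study()
    tr_t = table.take_rows(split.train_indices)
    tr_l = labels.take_rows(split.train_indices)

    trace_path = common.RESULTS / "selection_trace.json"
    if not trace_path.exists():
        sys.exit("run 03_feature_selection.py first")
    final = read_trace(trace_path).final
    sub = tr_t.subset(final)

    curve, recommended = depth_validation_curve(sub, tr_l, depths=range(1, 13),
                                                folds=5, seed=common.TREE_SEED)
    curve.to_csv(common.RESULTS / "depth_curve.csv", index=False)
    print(curve.to_string(index=False))
    print(f"recommended depth (within 1 point of best): {recommended}")

    model = fit(sub, tr_l, common.TREE_HP, seed=common.TREE_SEED)
    write_model(model, common.RESULTS / "model.json")
    (common.RESULTS / "model.dot").write_text(export_dot(model))
    print(f"fitted depth-{model.depth} tree with {model.n_nodes} nodes "
          f"on {final}")


if __name__ == "__main__":
    main()
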