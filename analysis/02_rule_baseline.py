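"""Score the expert rule-based classifier on the holdout.

The rules applied here are the same thresholds that generated the labels
(before noise), so this baseline is close to the ceiling that the 5% label
noise allows; a learned model can at best match it on this synthetic
study.  Writes the classification report to results/analysis/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402

from amenability.multilabel_metrics import classification_report  # noqa: E402
from amenability.rule_baseline import predict_table  # noqa: E402


def main() -> None:
    common.ensure_dirs()
    table, labels, _, split = common.load_study()
    te_t = table.take_rows(split.test_indices)
    te_l = labels.take_rows(split.test_indices)
    pred = predict_table(te_t)
    report = classification_report(te_l, pred)
    out = common.RESULTS / "rbc_report.json"
    out.write_text(json.dumps(report.to_dict(), indent=2))
    print(report.to_tsv())
    print(f"rule baseline holdout label-based accuracy: "
          f"{report.label_based_accuracy:.2f}% "
          f"(exact match {report.exact_match_ratio:.2f}%) -> {out}")


if __name__ == "__main__":
    main()
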