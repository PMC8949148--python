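"""Generate the synthetic study dataset and describe its planted structure.

Writes the labeled descriptor CSV (large, so under scratch/) plus the
planted-truth sidecar, and prints the label balance the rule induces.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common  # noqa: E402

from amenability.synthetic_descriptors import write_synthetic  # noqa: E402


def main() -> None:
    common.ensure_dirs()
    table, labels, truth, split = common.load_study()
    csv_path = common.SCRATCH / "study_data.csv"
    write_synthetic(common.STUDY, csv_path, common.RESULTS / "planted_truth.json")
    gc, lc = labels.labels.mean(axis=0)
    both = (labels.labels.sum(axis=1) == 2).mean()
    print(f"wrote {csv_path}: n={table.n}, p={table.p}")
    print(f"planted: {len(truth['informative'])} informative, "
          f"{len(truth['redundant'])} redundant, "
          f"{len(truth['quasi_constant'])} quasi-constant, "
          f"{len(truth['noise'])} noise columns")
    print(f"label balance: GC {gc:.1%}, LC {lc:.1%}, both {both:.1%}")
    print(f"split: {len(split.train_indices)} train / "
          f"{len(split.test_indices)} holdout")


if __name__ == "__main__":
    main()
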