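"""Shared configuration for the numbered analysis drivers.

Every driver derives from the same master seed and study conditions, so
each can be run independently and reproduces the same dataset and split.
"""

from pathlib import Path

from amenability.staged_selection import SelectionConfig
from amenability.synthetic_descriptors import SyntheticConfig
from amenability.tabular_io import split_train_test

MASTER_SEED = 20220223

REPO = Path(__file__).resolve().parent.parent
RESULTS = REPO / "results" / "analysis"
SCRATCH = REPO / "scratch" / "analysis"

STUDY = SyntheticConfig(seed=MASTER_SEED % (2**31 - 1))  # n=2000, 68 columns
TEST_FRACTION = 0.2
SELECTION = SelectionConfig(cv_folds=5, n_trees=50,
                            seed=(MASTER_SEED + 1) % (2**31 - 1))
TREE_HP = {"max_depth": 4}
TREE_SEED = (MASTER_SEED + 2) % (2**31 - 1)
CV_SEED = (MASTER_SEED + 3) % (2**31 - 1)


def load_study():
    """(table, labels, planted_truth, split) for the study conditions."""
    from amenability.synthetic_descriptors import generate

    table, labels, truth = generate(STUDY)
    split = split_train_test(table.n, TEST_FRACTION,
                             seed=(MASTER_SEED + 4) % (2**31 - 1))
    return table, labels, truth, split


def ensure_dirs():
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
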