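"""Staged feature selection for descriptor tables.

The pipeline mirrors the common funnel for wide descriptor matrices:

1. quasi-constant filter (modal-value frequency > 0.99 removed)
2. Spearman rank-correlation filter (|r_s| >= 0.9 redundancy removal)
3. random-forest importance filter (keep importance >= 1.5 x mean)
4. recursive feature elimination with cross-validated label-based accuracy
5. sequential forward selection, repeated with different fold seeds
6. overlap selection across the forward-selection repetitions

Each stage returns a subset of its input feature names (nestedness is an
invariant) and the whole run is recorded in a :class:`SelectionTrace`.
The model-based stages use a random forest purely as a ranking device; the
final classifier is a decision tree, fitted elsewhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold

from .multilabel_metrics import label_based_accuracy
from .tabular_io import DescriptorTable, LabelMatrix

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable knobs of the selection funnel.

    ``quasi_constant_threshold`` is a modal-value frequency (remove above),
    ``correlation_threshold`` an absolute Spearman r_s (redundant at or
    above), ``importance_scale`` multiplies the mean importance to give the
    keep cut-off.  ``sfs_keep`` features are collected per forward-selection
    repetition and ``overlap_min_count`` of the ``sfs_repetitions`` lists
    must contain a feature for it to survive the overlap stage.
    """

    quasi_constant_threshold: float = 0.99
    correlation_threshold: float = 0.9
    importance_scale: float = 1.5
    cv_folds: int = 10
    sfs_keep: int = 10
    sfs_repetitions: int = 5
    overlap_min_count: int = 3
    overlap_cap: int = 10
    n_trees: int = 100
    keep_rule: str = "column_order"
    abs_correlation: bool = True
    sfs_input: str = "importance"  # or "rfecv"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("quasi_constant_threshold", "correlation_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("cv_folds", "sfs_keep", "sfs_repetitions",
                     "overlap_min_count", "n_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.keep_rule not in ("column_order", "label_relevance"):
            raise ValueError(f"unknown keep_rule {self.keep_rule!r}")
        if self.sfs_input not in ("importance", "rfecv"):
            raise ValueError(f"unknown sfs_input {self.sfs_input!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "SelectionConfig":
        return cls(**doc)


@dataclass
class SelectionTrace:
    """Ordered record of the features retained at each stage."""

    stages: list[dict] = field(default_factory=list)   # {name, retained, count}
    sfs_lists: list[list[str]] = field(default_factory=list)
    overlap_counts: dict[str, int] = field(default_factory=dict)
    rfe_curve: list[list[float]] = field(default_factory=list)  # [count, score]

    def add(self, name: str, retained: list[str]) -> None:
        self.stages.append({"name": name, "retained": list(retained),
                            "count": len(retained)})
        logger.info("stage %-12s retained %d features", name, len(retained))

    @property
    def final(self) -> list[str]:
        return list(self.stages[-1]["retained"])

    def counts(self) -> dict[str, int]:
        return {s["name"]: s["count"] for s in self.stages}

    def counts_tsv(self) -> str:
        names = [s["name"] for s in self.stages]
        counts = [str(s["count"]) for s in self.stages]
        return "\t".join(names) + "\n" + "\t".join(counts) + "\n"

    def to_dict(self) -> dict:
        return {"stages": self.stages, "sfs_lists": self.sfs_lists,
                "overlap_counts": self.overlap_counts,
                "rfe_curve": self.rfe_curve}

    @classmethod
    def from_dict(cls, doc: dict) -> "SelectionTrace":
        return cls(stages=doc["stages"], sfs_lists=doc["sfs_lists"],
                   overlap_counts=doc["overlap_counts"],
                   rfe_curve=doc["rfe_curve"])


# ---------------------------------------------------------------------------
# stage 1: quasi-constant filter

def quasi_constant_filter(table: DescriptorTable,
                          threshold: float = 0.99) -> list[str]:
    """Drop features whose modal value covers > threshold of the rows.

    Missing values count as a value of their own (a column that is almost
    entirely NaN is quasi-constant too).
    """
    if table.n < 2:
        raise ValueError("need at least 2 rows")
    retained = []
    for j, name in enumerate(table.feature_names):
        col = table.values[:, j]
        # NaN != NaN, so count them as one shared value explicitly
        n_nan = int(np.isnan(col).sum())
        finite = col[~np.isnan(col)]
        top = max((np.unique(finite, return_counts=True)[1]).max(initial=0), n_nan)
        if top / table.n <= threshold:
            retained.append(name)
    return retained


# ---------------------------------------------------------------------------
# stage 2: Spearman correlation filter

def correlation_filter(table: DescriptorTable, threshold: float = 0.9,
                       keep_rule: str = "column_order",
                       labels: LabelMatrix | None = None,
                       absolute: bool = True) -> list[str]:
    """Remove one member of every descriptor pair with |r_s| >= threshold.

    Pairs are scanned in column order.  Under ``column_order`` the later
    member of a violating pair is dropped; under ``label_relevance`` the
    member with the smaller mean |r_s| against the two label columns is
    dropped (requires ``labels``).  A feature already dropped never triggers
    further removals, so the retained set has all pairwise |r_s| below the
    threshold.  Correlations use pairwise-complete observations.
    """
    if keep_rule == "label_relevance" and labels is None:
        raise ValueError("keep_rule='label_relevance' requires labels")
    p = table.p
    if p < 2:
        return list(table.feature_names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns give NaN r_s
        corr = spearmanr(table.values, nan_policy="omit").statistic
    if p == 2:  # spearmanr returns a scalar for two columns
        corr = np.array([[1.0, corr], [corr, 1.0]])
    corr = np.nan_to_num(np.asarray(corr, dtype=float), nan=0.0)
    cmp_corr = np.abs(corr) if absolute else corr

    relevance = None
    if keep_rule == "label_relevance":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rel = spearmanr(np.column_stack([table.values, labels.labels]),
                            nan_policy="omit").statistic
        rel = np.nan_to_num(np.asarray(rel, dtype=float), nan=0.0)
        relevance = np.abs(rel[:p, p:]).mean(axis=1)

    dropped = np.zeros(p, dtype=bool)
    for i in range(p):
        if dropped[i]:
            continue
        for j in range(i + 1, p):
            if dropped[j]:
                continue
            if cmp_corr[i, j] >= threshold:
                if keep_rule == "column_order":
                    dropped[j] = True
                else:
                    # keep the member more rank-correlated with the labels;
                    # ties keep the earlier column
                    if relevance[j] > relevance[i]:
                        dropped[i] = True
                        break
                    dropped[j] = True
        # note: when i itself is dropped under label_relevance we move on;
        # j survives to be compared from its own row later
    return [f for f, d in zip(table.feature_names, dropped) if not d]


# ---------------------------------------------------------------------------
# stage 3: random-forest importance filter

def apply_importance_rule(importances: np.ndarray, scale: float) -> np.ndarray:
    """Boolean keep-mask: importance >= scale * mean(importance)."""
    imp = np.asarray(importances, dtype=float)
    return imp >= scale * imp.mean()


def _forest(n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=n_trees, random_state=seed % _SEED_MOD)


def _check_model_input(X: np.ndarray) -> None:
    if not np.isfinite(X).all():
        bad = np.flatnonzero(~np.isfinite(X).all(axis=0))
        raise ValueError("model-based selection requires complete numeric "
                         f"columns; offending column indices: {bad.tolist()}")


def importance_filter(table: DescriptorTable, labels: LabelMatrix,
                      scale: float = 1.5, n_trees: int = 100,
                      seed: int = 0) -> list[str]:
    """Keep features whose forest importance is >= scale x the mean.

    The forest is fitted jointly on the two label outputs.  If the rule
    would empty the set, the single most important feature is kept and a
    warning is emitted.
    """
    if table.p < 2:
        raise ValueError("importance filter needs >= 2 features")
    Y = labels.labels
    if len(np.unique(Y[:, 0])) < 2 and len(np.unique(Y[:, 1])) < 2:
        raise ValueError("degenerate labels: both outputs single-class")
    _check_model_input(table.values)
    forest = _forest(n_trees, seed).fit(table.values, Y)
    keep = apply_importance_rule(forest.feature_importances_, scale)
    if not keep.any():
        warnings.warn("importance rule emptied the feature set; "
                      "keeping the top-1 feature", stacklevel=2)
        keep[np.argmax(forest.feature_importances_)] = True
    return [f for f, k in zip(table.feature_names, keep) if k]


# ---------------------------------------------------------------------------
# CV scoring shared by the wrapper stages

def _cv_score(X: np.ndarray, Y: np.ndarray, cols: list[int], folds: int,
              seed: int, n_trees: int) -> float:
    """Mean k-fold cross-validated label-based accuracy of a forest on the
    given column subset."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % _SEED_MOD)
    scores = []
    Xs = X[:, cols]
    for train, val in kf.split(Xs):
        model = _forest(n_trees, seed).fit(Xs[train], Y[train])
        pred = np.asarray(model.predict(Xs[val]))
        scores.append(label_based_accuracy(Y[val], pred))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# stage 4: recursive feature elimination with CV scoring

def recursive_elimination(table: DescriptorTable, labels: LabelMatrix,
                          folds: int = 10, seed: int = 0,
                          n_trees: int = 100,
                          ) -> tuple[list[tuple[int, float]], list[str]]:
    """Eliminate one feature per step, scoring every count by CV accuracy.

    At each step the forest is refitted on the current set and the least
    important feature is removed.  Returns the (count, score) curve from
    the full set down to one feature, plus the best-scoring set (ties go to
    the smaller count).
    """
    if folds > table.n:
        raise ValueError("folds must be <= number of rows")
    _check_model_input(table.values)
    X, Y = table.values, labels.labels
    current = list(range(table.p))
    curve: list[tuple[int, float]] = []
    sets: dict[int, list[int]] = {}
    while current:
        score = _cv_score(X, Y, current, folds, seed, n_trees)
        curve.append((len(current), score))
        sets[len(current)] = list(current)
        if len(current) == 1:
            break
        forest = _forest(n_trees, seed).fit(X[:, current], Y)
        worst = int(np.argmin(forest.feature_importances_))
        current.pop(worst)
    best_count = max(sets, key=lambda c: (round(dict(curve)[c], 12), -c))
    retained = [table.feature_names[j] for j in sets[best_count]]
    return curve[::-1], retained  # curve ordered by increasing count


# ---------------------------------------------------------------------------
# stage 5: sequential forward selection

def sequential_forward(table: DescriptorTable, labels: LabelMatrix,
                       k: int = 10, folds: int = 10, repetitions: int = 5,
                       seed: int = 0, n_trees: int = 100) -> list[list[str]]:
    """Greedy forward selection of k features, repeated with shifted seeds.

    Repetition r shuffles folds and seeds the forest with ``seed + r``.
    Each repetition returns its k features in selection order; ties in the
    greedy step go to the earlier column.
    """
    if k > table.p:
        raise ValueError(f"k={k} exceeds the {table.p} available features")
    if folds > table.n:
        raise ValueError("folds must be <= number of rows")
    _check_model_input(table.values)
    X, Y = table.values, labels.labels
    all_lists: list[list[str]] = []
    for r in range(repetitions):
        rep_seed = seed + r
        selected: list[int] = []
        remaining = list(range(table.p))
        while len(selected) < k:
            best_j, best_score = None, -np.inf
            for j in remaining:
                score = _cv_score(X, Y, selected + [j], folds, rep_seed, n_trees)
                if score > best_score:  # strict: ties keep the earlier column
                    best_j, best_score = j, score
            selected.append(best_j)
            remaining.remove(best_j)
        all_lists.append([table.feature_names[j] for j in selected])
    return all_lists


# ---------------------------------------------------------------------------
# stage 6: overlap selection

def overlap_select(lists: list[list[str]], min_count: int = 3,
                   cap: int = 10) -> tuple[list[str], dict[str, int]]:
    """Keep features appearing in >= min_count of the repetition lists.

    If more than ``cap`` survive, the cap highest are kept ordered by
    (appearance count desc, mean selection position asc, column order as
    encountered).  Deterministic.
    """
    if not lists:
        raise ValueError("need at least one repetition list")
    counts: dict[str, int] = {}
    positions: dict[str, list[int]] = {}
    order: dict[str, int] = {}
    for lst in lists:
        for pos, f in enumerate(lst):
            counts[f] = counts.get(f, 0) + 1
            positions.setdefault(f, []).append(pos)
            order.setdefault(f, len(order))
    survivors = [f for f, c in counts.items() if c >= min_count]
    survivors.sort(key=lambda f: (-counts[f], float(np.mean(positions[f])), order[f]))
    return survivors[:cap], counts


# ---------------------------------------------------------------------------
# the full funnel

def run_pipeline(table: DescriptorTable, labels: LabelMatrix,
                 config: SelectionConfig = SelectionConfig(),
                 ) -> SelectionTrace:
    """Execute all six stages in order and record the trace.

    The forward-selection stage consumes the importance-filter set by
    default (``config.sfs_input``); the RFE stage is still run and recorded
    so its plateau curve is available as a diagnostic.
    """
    if table.p == 0 or table.n == 0:
        raise ValueError("empty descriptor table")
    labels.check_aligned(table)
    trace = SelectionTrace()
    trace.add("initial", list(table.feature_names))

    retained = quasi_constant_filter(table, config.quasi_constant_threshold)
    trace.add("variance", retained)
    sub = table.subset(retained)

    retained = correlation_filter(sub, config.correlation_threshold,
                                  keep_rule=config.keep_rule, labels=labels,
                                  absolute=config.abs_correlation)
    trace.add("correlation", retained)
    sub = table.subset(retained)

    retained = importance_filter(sub, labels, scale=config.importance_scale,
                                 n_trees=config.n_trees, seed=config.seed)
    trace.add("importance", retained)
    importance_set = retained
    sub = table.subset(retained)

    curve, retained = recursive_elimination(sub, labels, folds=config.cv_folds,
                                            seed=config.seed,
                                            n_trees=config.n_trees)
    trace.rfe_curve = [[int(c), float(s)] for c, s in curve]
    trace.add("rfecv", retained)

    sfs_base = importance_set if config.sfs_input == "importance" else retained
    sub = table.subset(sfs_base)
    k = min(config.sfs_keep, sub.p)
    lists = sequential_forward(sub, labels, k=k, folds=config.cv_folds,
                               repetitions=config.sfs_repetitions,
                               seed=config.seed, n_trees=config.n_trees)
    trace.sfs_lists = lists

    final, counts = overlap_select(lists, min_count=config.overlap_min_count,
                                   cap=config.overlap_cap)
    trace.overlap_counts = counts
    # report the final set in stable column order
    final_ordered = [f for f in table.feature_names if f in set(final)]
    trace.add("final", final_ordered)
    return trace
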