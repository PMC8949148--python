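"""Multi-label decision tree: fitting, grid search, depth selection, export.

One tree is fitted jointly on the two binary outputs (GC, LC); split
quality is averaged over the outputs, which is how a multi-output CART
handles multi-label targets.  The fitted tree is exported to plain node
arrays so that a model serialized to JSON predicts identically after a
round-trip without any fitted estimator object.

Prediction convention: the score for a label is the class-1 proportion in
the reached leaf; the predicted label is 1 iff score >= 0.5 (a tie at
exactly 0.5 predicts 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeClassifier

from .multilabel_metrics import label_based_accuracy
from .tabular_io import DescriptorTable, LabelMatrix

_SEED_MOD = 2**31 - 1

#: "auto" historically meant sqrt(p) for classifiers; kept for grid parity
_MAX_FEATURES = {"auto": "sqrt", "sqrt": "sqrt", "none": None, None: None}


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid for the tree search (defaults: the full grid)."""

    criterion: tuple = ("gini", "entropy")
    max_features: tuple = ("auto", "sqrt", "none")
    min_samples_split: tuple = (2, 3, 5, 8, 10, 20, 40)
    max_depth: tuple = tuple(range(3, 30))
    min_samples_leaf: tuple = (1, 2, 3, 4, 5, 10, 20, 40)

    def __post_init__(self) -> None:
        for name in ("criterion", "max_features", "min_samples_split",
                     "max_depth", "min_samples_leaf"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"grid dimension {name} is empty")

    def points(self):
        """Grid points in definition order (the tie-break order)."""
        for combo in itertools.product(self.criterion, self.max_features,
                                       self.min_samples_split, self.max_depth,
                                       self.min_samples_leaf):
            yield {"criterion": combo[0], "max_features": combo[1],
                   "min_samples_split": combo[2], "max_depth": combo[3],
                   "min_samples_leaf": combo[4]}

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FittedTree:
    """A fitted multi-label tree as plain node arrays.

    ``children_left[i] == -1`` marks a leaf.  ``leaf_scores[i][j]`` is the
    class-1 proportion of label j among the training rows in node i.
    """

    feature_names: list[str]
    children_left: list[int]
    children_right: list[int]
    split_feature: list[int]
    threshold: list[float]
    leaf_scores: list[list[float]]
    hyperparameters: dict
    n_train: int
    seed: int
    label_names: tuple[str, str] = ("GC", "LC")

    @property
    def n_nodes(self) -> int:
        return len(self.children_left)

    @property
    def depth(self) -> int:
        def walk(i: int) -> int:
            if self.children_left[i] == -1:
                return 0
            return 1 + max(walk(self.children_left[i]),
                           walk(self.children_right[i]))
        return walk(0)

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["label_names"] = list(self.label_names)
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "FittedTree":
        doc = dict(doc)
        doc["label_names"] = tuple(doc["label_names"])
        return cls(**doc)


def _make_estimator(hp: dict, seed: int) -> DecisionTreeClassifier:
    hp = dict(hp)
    mf = hp.get("max_features")
    if isinstance(mf, str):
        mf = _MAX_FEATURES[mf.lower()]
    return DecisionTreeClassifier(
        criterion=hp.get("criterion", "gini"),
        max_features=mf,
        min_samples_split=hp.get("min_samples_split", 2),
        max_depth=hp.get("max_depth"),
        min_samples_leaf=hp.get("min_samples_leaf", 1),
        random_state=seed % _SEED_MOD,
    )


def _class1_proportions(est: DecisionTreeClassifier) -> np.ndarray:
    """Per-node class-1 proportion for each output, handling the case where
    a training output is single-class (its proportion is constant 0 or 1)."""
    tree = est.tree_
    value = np.asarray(tree.value)  # (n_nodes, n_outputs, n_classes), fractions
    n_nodes = tree.node_count
    classes = est.classes_ if isinstance(est.classes_, list) else [est.classes_]
    n_outputs = len(classes)
    out = np.zeros((n_nodes, n_outputs))
    for j, cls in enumerate(classes):
        cls = np.asarray(cls)
        if 1 in cls:
            idx = int(np.flatnonzero(cls == 1)[0])
            frac = value[:, j, idx]
            out[:, j] = frac / value[:, j].sum(axis=1)
        else:
            out[:, j] = 0.0
    return out


def fit(table: DescriptorTable, labels: LabelMatrix,
        hyperparameters: dict | None = None, seed: int = 0,
        per_label: bool = False) -> "FittedTree | tuple[FittedTree, FittedTree]":
    """Fit the multi-label tree and export it to node arrays.

    ``per_label=True`` fits two independent single-label trees instead (an
    ablation mode) and returns a pair.
    """
    X = table.values
    if not np.isfinite(X).all():
        bad = [table.feature_names[j]
               for j in np.flatnonzero(~np.isfinite(X).all(axis=0))]
        raise ValueError(f"non-finite values in selected features: {bad}")
    hp = dict(hyperparameters or {})
    if per_label:
        trees = []
        for j, lbl in enumerate(labels.label_names):
            single = LabelMatrix(labels.compound_ids,
                                 np.column_stack([labels.labels[:, j]] * 2))
            t = fit(table, single, hp, seed)
            t.label_names = (lbl, lbl)
            trees.append(t)
        return tuple(trees)

    est = _make_estimator(hp, seed).fit(X, labels.labels)
    tree = est.tree_
    scores = _class1_proportions(est)
    return FittedTree(
        feature_names=list(table.feature_names),
        children_left=tree.children_left.tolist(),
        children_right=tree.children_right.tolist(),
        split_feature=tree.feature.tolist(),
        threshold=tree.threshold.tolist(),
        leaf_scores=scores.tolist(),
        hyperparameters=hp,
        n_train=table.n,
        seed=seed,
        label_names=labels.label_names,
    )


def _node_for_rows(model: FittedTree, X: np.ndarray) -> np.ndarray:
    nodes = np.zeros(X.shape[0], dtype=int)
    active = np.arange(X.shape[0])
    while active.size:
        cur = nodes[active]
        leaf = np.asarray(model.children_left)[cur] == -1
        active = active[~leaf]
        if not active.size:
            break
        cur = nodes[active]
        feat = np.asarray(model.split_feature)[cur]
        thr = np.asarray(model.threshold)[cur]
        go_left = X[active, feat] <= thr
        nodes[active] = np.where(go_left,
                                 np.asarray(model.children_left)[cur],
                                 np.asarray(model.children_right)[cur])
    return nodes


def _model_matrix(model: FittedTree, table: DescriptorTable) -> np.ndarray:
    missing = [f for f in model.feature_names if f not in table.feature_names]
    if missing:
        raise ValueError(f"table lacks model features: {missing}")
    return table.subset(model.feature_names).values


def predict_scores(model: FittedTree, table: DescriptorTable) -> np.ndarray:
    """Leaf class-1 proportions, one column per label; values in [0, 1]."""
    X = _model_matrix(model, table)
    nodes = _node_for_rows(model, X)
    return np.asarray(model.leaf_scores)[nodes]


def predict(model: FittedTree, table: DescriptorTable) -> LabelMatrix:
    """Hard labels: 1 iff leaf score >= 0.5 (ties predict 1)."""
    scores = predict_scores(model, table)
    return LabelMatrix(list(table.compound_ids), (scores >= 0.5).astype(int),
                       model.label_names)


class TreeMethod:
    """sklearn-style fit/predict wrapper used by the CV comparison protocol."""

    def __init__(self, hyperparameters: dict | None = None, seed: int = 0,
                 columns: list[int] | None = None) -> None:
        self.hp = dict(hyperparameters or {})
        self.seed = seed
        self.columns = columns
        self._est = None

    def fit(self, X, Y):
        X = np.asarray(X)
        if self.columns is not None:
            X = X[:, self.columns]
        self._est = _make_estimator(self.hp, self.seed).fit(X, Y)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X)
        if self.columns is not None:
            X = X[:, self.columns]
        pred = np.asarray(self._est.predict(X))
        if pred.ndim == 1:
            pred = pred[:, None]
        return pred


def _cv_lba(table: DescriptorTable, labels: LabelMatrix, hp: dict,
            folds: int, seed: int) -> tuple[float, float, float, float]:
    """(val_mean, val_sd, train_mean, train_sd) of k-fold label accuracy."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % _SEED_MOD)
    val_scores, train_scores = [], []
    X, Y = table.values, labels.labels
    for train, val in kf.split(X):
        est = _make_estimator(hp, seed).fit(X[train], Y[train])
        val_scores.append(label_based_accuracy(Y[val], np.asarray(est.predict(X[val]))))
        train_scores.append(label_based_accuracy(Y[train], np.asarray(est.predict(X[train]))))
    return (float(np.mean(val_scores)), float(np.std(val_scores)),
            float(np.mean(train_scores)), float(np.std(train_scores)))


def grid_search(table: DescriptorTable, labels: LabelMatrix,
                grid: GridSpec = GridSpec(), folds: int = 10, seed: int = 0,
                ) -> tuple[dict, float, pd.DataFrame]:
    """Exhaustive CV grid search scored by label-based accuracy.

    Ties are broken by (higher mean score, then smaller max_depth, then grid
    order); the folds are shared across grid points so scores are paired.
    """
    if folds > table.n:
        raise ValueError("folds must be <= number of rows")
    rows = []
    best = None  # (score, -max_depth, -order) to maximise
    best_hp, best_score = None, -np.inf
    for order, hp in enumerate(grid.points()):
        val_mean, val_sd, _, _ = _cv_lba(table, labels, hp, folds, seed)
        rows.append({**hp, "cv_mean": val_mean, "cv_sd": val_sd})
        key = (val_mean, -hp["max_depth"], -order)
        if best is None or key > best:
            best = key
            best_hp, best_score = hp, val_mean
    return best_hp, float(best_score), pd.DataFrame(rows)


def depth_validation_curve(table: DescriptorTable, labels: LabelMatrix,
                           depths=range(1, 30), folds: int = 10, seed: int = 0,
                           tolerance: float = 1.0,
                           base_hp: dict | None = None,
                           ) -> tuple[pd.DataFrame, int]:
    """Train/validation accuracy per depth and the recommended depth.

    The recommendation is the smallest depth whose mean validation score is
    within ``tolerance`` percentage points of the best mean validation
    score (tolerance 0 picks the smallest argmax).
    """
    depths = list(depths)
    if not depths:
        raise ValueError("depths must be nonempty")
    rows = []
    for d in depths:
        hp = dict(base_hp or {}, max_depth=d)
        val_mean, val_sd, train_mean, train_sd = _cv_lba(table, labels, hp,
                                                         folds, seed)
        rows.append({"depth": d, "val_mean": val_mean, "val_sd": val_sd,
                     "train_mean": train_mean, "train_sd": train_sd})
    curve = pd.DataFrame(rows)
    return curve, recommend_depth(curve["depth"].tolist(),
                                  curve["val_mean"].tolist(), tolerance)


def recommend_depth(depths: list[int], val_means: list[float],
                    tolerance: float = 1.0) -> int:
    """Smallest depth within ``tolerance`` percentage points of the best
    mean validation score.  ``val_means`` may be on the [0, 1] or the
    percent scale; the tolerance is interpreted on the same scale per unit
    of 100 (i.e. 1.0 means one percentage point)."""
    means = np.asarray(val_means, dtype=float)
    tol = tolerance / 100 if means.max() <= 1.0 else tolerance
    cutoff = means.max() - tol
    ok = np.flatnonzero(means >= cutoff)
    return int(np.asarray(depths)[ok[0]])


def export_dot(model: FittedTree) -> str:
    """Render the tree as a DOT digraph (edges labelled <= / >)."""
    lines = ["digraph AmenabilityTree {", "  node [shape=box];"]
    for i in range(model.n_nodes):
        if model.children_left[i] == -1:
            gc, lc = model.leaf_scores[i]
            label = (f"leaf\\n{model.label_names[0]}={gc:.2f} "
                     f"{model.label_names[1]}={lc:.2f}")
        else:
            fname = model.feature_names[model.split_feature[i]]
            label = f"{fname} <= {model.threshold[i]:.4g}"
        lines.append(f'  n{i} [label="{label}"];')
    for i in range(model.n_nodes):
        left, right = model.children_left[i], model.children_right[i]
        if left != -1:
            lines.append(f'  n{i} -> n{left} [label="<="];')
            lines.append(f'  n{i} -> n{right} [label=">"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
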