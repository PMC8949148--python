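"""Reading and writing descriptor tables, labels, splits and fitted artifacts.

The central containers are :class:`DescriptorTable` (compounds x numeric
molecular descriptors, missing values carried as NaN) and
:class:`LabelMatrix` (compounds x the two binary amenability labels, GC and
LC, in that fixed column order).  Everything downstream — the rule baseline,
the feature-selection pipeline, the decision tree and the comparison
statistics — consumes these two objects.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABEL_COLUMNS = ("GC", "LC")

#: accepted spellings for binary label cells; anything else is a format error
_LABEL_COERCION = {
    "1": 1, "0": 0,
    "y": 1, "n": 0,
    "yes": 1, "no": 0,
    "true": 1, "false": 0,
    "1.0": 1, "0.0": 0,
}

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular contract."""


@dataclass
class DescriptorTable:
    """Compounds x named numeric descriptors.

    ``values`` is an (n, p) float array; missing entries are NaN.  Column
    order is significant and preserved by every transformation (the
    correlation filter's tie-break scans columns in order).
    """

    compound_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.compound_ids) != n:
            raise ValueError(f"{len(self.compound_ids)} ids for {n} rows")
        if len(self.feature_names) != p:
            raise ValueError(f"{len(self.feature_names)} names for {p} columns")
        dupes = _duplicates(self.feature_names)
        if dupes:
            raise FormatError(f"duplicate feature names: {sorted(dupes)}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"no descriptor column named {name!r}") from None
        return self.values[:, j]

    def subset(self, names: Sequence[str]) -> "DescriptorTable":
        """Column subset, keeping the requested order."""
        idx = [self.feature_names.index(f) for f in names]
        return DescriptorTable(list(self.compound_ids), list(names),
                               self.values[:, idx])

    def take_rows(self, indices: Sequence[int]) -> "DescriptorTable":
        idx = np.asarray(indices, dtype=int)
        return DescriptorTable([self.compound_ids[i] for i in idx],
                               list(self.feature_names), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids,
                            columns=self.feature_names)


@dataclass
class LabelMatrix:
    """Compounds x (GC, LC) binary labels; entries are 0 or 1."""

    compound_ids: list[str]
    labels: np.ndarray
    label_names: tuple[str, str] = LABEL_COLUMNS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2 or self.labels.shape[1] != 2:
            raise ValueError("labels must be an (n, 2) matrix")
        if len(self.compound_ids) != self.labels.shape[0]:
            raise ValueError("id / label row mismatch")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    def take_rows(self, indices: Sequence[int]) -> "LabelMatrix":
        idx = np.asarray(indices, dtype=int)
        return LabelMatrix([self.compound_ids[i] for i in idx],
                           self.labels[idx], self.label_names)

    def check_aligned(self, table: DescriptorTable) -> None:
        if self.compound_ids != table.compound_ids:
            raise ValueError("label rows are not aligned with the table "
                             "(compound ids differ)")


@dataclass
class SplitSpec:
    """A train/test partition of row indices.

    |test| = ceil(fraction * n), which reproduces the 5144/1287 split of a
    6431-compound dataset at fraction 0.2.
    """

    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        both = np.concatenate([self.train_indices, self.test_indices])
        n = len(both)
        if len(np.unique(both)) != n or both.min() != 0 or both.max() != n - 1:
            raise ValueError("train/test must partition 0..n-1")


def _duplicates(names: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for name in names:
        if name in seen:
            dupes.add(name)
        seen.add(name)
    return dupes


def coerce_label(value) -> int:
    """Map a raw label cell onto {0, 1}; unknown spellings are errors."""
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return int(value)
    if isinstance(value, (float, np.floating)) and value in (0.0, 1.0):
        return int(value)
    key = str(value).strip().lower()
    if key in _LABEL_COERCION:
        return _LABEL_COERCION[key]
    raise FormatError(f"cannot interpret label value {value!r} as 0/1")


def read_labeled_table(path, gc_col: str = "GC", lc_col: str = "LC",
                       id_col: str | None = None,
                       ) -> tuple[DescriptorTable, LabelMatrix]:
    """Read a labeled descriptor CSV.

    The file must have a header row.  ``id_col`` names the compound-id
    column (default: first column).  All remaining columns except the two
    label columns are descriptors; non-numeric descriptor cells become NaN.
    """
    # pandas silently mangles duplicate headers, so check the raw header row
    import csv
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), [])
    dupes = _duplicates(header)
    if dupes:
        raise FormatError(f"duplicate feature names: {sorted(dupes)}")
    df = pd.read_csv(path, dtype=object)
    for col in (gc_col, lc_col):
        if col not in df.columns:
            raise FormatError(f"missing label column {col!r}")
    if id_col is None:
        id_col = df.columns[0]
    elif id_col not in df.columns:
        raise FormatError(f"missing id column {id_col!r}")

    ids = df[id_col].astype(str).tolist()
    labels = np.column_stack([
        [coerce_label(v) for v in df[gc_col]],
        [coerce_label(v) for v in df[lc_col]],
    ])
    feature_cols = [c for c in df.columns if c not in (id_col, gc_col, lc_col)]
    values = df[feature_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)

    table = DescriptorTable(ids, feature_cols, values)
    n_missing = int(np.isnan(values).sum())
    logger.info("loaded %s: n=%d, p=%d, missing=%d", path, table.n, table.p,
                n_missing)
    return table, LabelMatrix(ids, labels)


def split_train_test(n: int, fraction: float, seed: int,
                     labels: LabelMatrix | None = None,
                     stratify: bool = False) -> SplitSpec:
    """Uniform random train/test split with |test| = ceil(fraction * n).

    Stratification (on the joint GC/LC label combination) is off by default
    and requires ``labels``.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_test = math.ceil(fraction * n)
    rng = np.random.default_rng(seed)
    if stratify:
        if labels is None:
            raise ValueError("stratified split requires labels")
        combo = labels.labels[:, 0] * 2 + labels.labels[:, 1]
        test_idx: list[int] = []
        for value in np.unique(combo):
            members = np.flatnonzero(combo == value)
            take = int(round(fraction * len(members)))
            test_idx.extend(rng.permutation(members)[:take].tolist())
        # top up / trim to the exact ceil target deterministically
        test = np.array(sorted(test_idx), dtype=int)
        if len(test) > n_test:
            test = rng.permutation(test)[:n_test]
        elif len(test) < n_test:
            rest = np.setdiff1d(np.arange(n), test)
            extra = rng.permutation(rest)[: n_test - len(test)]
            test = np.concatenate([test, extra])
        test = np.sort(test)
    else:
        perm = rng.permutation(n)
        test = np.sort(perm[:n_test])
    train = np.setdiff1d(np.arange(n), test)
    return SplitSpec(train, test, fraction, seed)


# ---------------------------------------------------------------------------
# JSON round-trips for traces and fitted models

class VersionError(ValueError):
    """Artifact file written under an incompatible schema version."""


def _check_version(doc: dict, kind: str) -> None:
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise VersionError(
            f"{kind} file has schema_version={version!r}, expected {SCHEMA_VERSION}")


def write_trace(trace, path) -> None:
    doc = {"schema_version": SCHEMA_VERSION, "kind": "selection_trace",
           "trace": trace.to_dict()}
    Path(path).write_text(json.dumps(doc, indent=2))


def read_trace(path):
    from .staged_selection import SelectionTrace
    doc = json.loads(Path(path).read_text())
    _check_version(doc, "trace")
    return SelectionTrace.from_dict(doc["trace"])


def write_model(model, path) -> None:
    doc = {"schema_version": SCHEMA_VERSION, "kind": "fitted_tree",
           "model": model.to_dict()}
    Path(path).write_text(json.dumps(doc, indent=2))


def read_model(path):
    from .amenability_tree import FittedTree
    doc = json.loads(Path(path).read_text())
    _check_version(doc, "model")
    return FittedTree.from_dict(doc["model"])


def write_predictions(path, ids: Sequence[str], pred: np.ndarray,
                      scores: np.ndarray | None = None) -> None:
    """Prediction CSV: ID, GC_pred, LC_pred and, if given, the leaf scores."""
    df = pd.DataFrame({"ID": list(ids),
                       "GC_pred": pred[:, 0], "LC_pred": pred[:, 1]})
    if scores is not None:
        df["GC_score"] = scores[:, 0]
        df["LC_score"] = scores[:, 1]
    df.to_csv(path, index=False)
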