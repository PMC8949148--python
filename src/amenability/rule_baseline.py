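"""Expert rule-based amenability classifier (the comparison baseline).

A compound is called GC-amenable when it is volatile enough to pass a GC
column but not too heavy or too polar: boiling point within [100, 350] degC,
molecular weight below 700 Da and logP above 2.  LC (reversed-phase)
amenability uses polarity alone: logP below 5.91.  The two labels are
assigned independently, so a compound may be amenable to both platforms or
to neither.

Boundary semantics: "from 100 to 350" is inclusive on both ends; "below
700", "higher than 2" and "less than 5.91" are strict.  All comparisons
live in :func:`classify` so the convention is testable in one place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tabular_io import DescriptorTable, LabelMatrix

logger = logging.getLogger(__name__)

DEFAULT_COLUMN_MAP = {"bp": "BoilingPoint", "mw": "MW", "logp": "logP"}


@dataclass(frozen=True)
class RuleThresholds:
    """Physicochemical cut-offs of the rule-based classifier.

    Units: bp_min/bp_max in degC, mw_max in Da, the logP bounds are
    dimensionless (log10 octanol-water partition coefficient).
    """

    bp_min: float = 100.0
    bp_max: float = 350.0
    mw_max: float = 700.0
    gc_logp_min: float = 2.0
    lc_logp_max: float = 5.91

    def __post_init__(self) -> None:
        if not self.bp_min < self.bp_max:
            raise ValueError("bp_min must be < bp_max")
        if self.mw_max <= 0:
            raise ValueError("mw_max must be positive")


def classify(bp: float, mw: float, logp: float,
             thresholds: RuleThresholds = RuleThresholds(),
             ) -> tuple[int, int]:
    """Apply the amenability rules to one compound.

    Returns the (gc, lc) label pair.  Pure and deterministic; missing-value
    handling belongs to :func:`predict_table`.
    """
    t = thresholds
    gc = int(t.bp_min <= bp <= t.bp_max and mw < t.mw_max and logp > t.gc_logp_min)
    lc = int(logp < t.lc_logp_max)
    return gc, lc


def classify_arrays(bp: np.ndarray, mw: np.ndarray, logp: np.ndarray,
                    thresholds: RuleThresholds = RuleThresholds(),
                    ) -> np.ndarray:
    """Vectorised :func:`classify`; rows with any NaN input get (0, 0)."""
    t = thresholds
    with np.errstate(invalid="ignore"):
        gc = ((bp >= t.bp_min) & (bp <= t.bp_max)
              & (mw < t.mw_max) & (logp > t.gc_logp_min))
        lc = logp < t.lc_logp_max
    missing = np.isnan(bp) | np.isnan(mw) | np.isnan(logp)
    out = np.column_stack([gc, lc]).astype(int)
    out[missing] = 0
    return out


def predict_table(table: DescriptorTable,
                  column_map: dict[str, str] | None = None,
                  thresholds: RuleThresholds = RuleThresholds(),
                  ) -> LabelMatrix:
    """Row-wise rule predictions for a descriptor table.

    ``column_map`` maps the rule inputs {"bp", "mw", "logp"} to descriptor
    column names (default BoilingPoint / MW / logP).  Rows with a missing
    mapped value are labelled (0, 0) and counted in a warning; screening a
    sparse table must not abort.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        unknown = set(column_map) - {"bp", "mw", "logp"}
        if unknown:
            raise ValueError(f"unknown column-map keys: {sorted(unknown)}")
        cmap.update(column_map)
    missing_cols = [c for c in cmap.values() if c not in table.feature_names]
    if missing_cols:
        raise ValueError(f"mapped columns not in table: {missing_cols}")

    bp = table.column(cmap["bp"])
    mw = table.column(cmap["mw"])
    logp = table.column(cmap["logp"])
    out = classify_arrays(bp, mw, logp, thresholds)
    n_missing = int((np.isnan(bp) | np.isnan(mw) | np.isnan(logp)).sum())
    if n_missing:
        logger.warning("rule baseline: %d rows with missing BP/MW/logP "
                       "labelled (0, 0)", n_missing)
    return LabelMatrix(list(table.compound_ids), out)


class RulePredictor:
    """sklearn-style wrapper so the baseline can enter paired CV protocols.

    ``fit`` is a no-op: the rules are fixed, nothing is learned.
    """

    def __init__(self, feature_names: list[str],
                 column_map: dict[str, str] | None = None,
                 thresholds: RuleThresholds = RuleThresholds()) -> None:
        cmap = dict(DEFAULT_COLUMN_MAP)
        if column_map:
            cmap.update(column_map)
        self._cols = [feature_names.index(cmap[k]) for k in ("bp", "mw", "logp")]
        self.thresholds = thresholds

    def fit(self, X, Y):  # noqa: ARG002 - protocol compatibility
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        bp, mw, logp = (X[:, j] for j in self._cols)
        return classify_arrays(bp, mw, logp, self.thresholds)
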