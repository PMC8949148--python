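"""Synthetic descriptor tables with planted statistical structure.

The generator emulates the statistical shape of a real descriptor table
used for amenability modelling: three informative physicochemical columns
(BoilingPoint, MW, logP) whose noisy threshold rules drive the GC/LC
labels, redundant monotone copies of those columns, quasi-constant columns
and label-independent noise columns.  Each downstream stage of the
analysis (filters, importance ranking, wrapper selection, tree fitting,
comparison statistics) is therefore testable without any external data.

Latent distributions (fixed constants, chosen to straddle every rule
threshold so all four label combinations occur):

* BoilingPoint ~ Uniform(0, 600) degC
* MW ~ log-uniform(50, 1500) Da
* logP ~ Uniform(-5, 12)

True labels are the rule-based classifier applied to the latent values;
each label bit is then flipped independently with probability
``label_noise``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .rule_baseline import RuleThresholds, classify_arrays
from .tabular_io import DescriptorTable, LabelMatrix

INFORMATIVE_NAMES = ("BoilingPoint", "MW", "logP")

BP_RANGE = (0.0, 600.0)
MW_RANGE = (50.0, 1500.0)
LOGP_RANGE = (-5.0, 12.0)

#: relative sd of the perturbation added to redundant columns; small enough
#: that the population rank correlation with the parent stays above 0.95
_REDUNDANT_NOISE_SD = 0.02

_QUASI_CONSTANT_MODAL_FRACTION = 0.995


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for one synthetic descriptor table."""

    n_compounds: int = 2000
    label_noise: float = 0.05
    n_redundant: int = 10
    n_quasi_constant: int = 5
    n_noise: int = 50
    thresholds: RuleThresholds = field(default_factory=RuleThresholds)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        for name in ("n_redundant", "n_quasi_constant", "n_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def p(self) -> int:
        return 3 + self.n_redundant + self.n_quasi_constant + self.n_noise

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["thresholds"] = asdict(self.thresholds)
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticConfig":
        doc = dict(doc)
        thr = doc.pop("thresholds", None)
        if thr is not None:
            doc["thresholds"] = RuleThresholds(**thr)
        return cls(**doc)


# the three monotone transforms used for redundant columns; all strictly
# increasing so the rank-correlation filter (not a linear filter) is what
# detects them
def _affine(x, rng):
    a = rng.uniform(0.5, 3.0)
    b = rng.uniform(-10, 10)
    return a * x + b


def _softexp(x, rng):  # noqa: ARG001
    lo, hi = x.min(), x.max()
    z = (x - lo) / (hi - lo + 1e-12)
    return np.exp(3.0 * z)


def _cube(x, rng):  # noqa: ARG001
    return np.sign(x) * np.abs(x) ** 3 / (np.abs(x).max() ** 2 + 1e-12)


_TRANSFORMS = (_affine, _softexp, _cube)


def generate(config: SyntheticConfig,
             ) -> tuple[DescriptorTable, LabelMatrix, dict[str, list[str]]]:
    """Generate (table, labels, planted_truth) deterministically from config.

    ``planted_truth`` maps the roles {"informative", "redundant",
    "quasi_constant", "noise"} to the column names generated for each role.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds

    bp = rng.uniform(*BP_RANGE, size=n)
    mw = np.exp(rng.uniform(np.log(MW_RANGE[0]), np.log(MW_RANGE[1]), size=n))
    logp = rng.uniform(*LOGP_RANGE, size=n)
    informative = {"BoilingPoint": bp, "MW": mw, "logP": logp}

    labels = classify_arrays(bp, mw, logp, config.thresholds)
    if config.label_noise > 0:
        flips = rng.random(labels.shape) < config.label_noise
        labels = np.where(flips, 1 - labels, labels)

    columns: list[tuple[str, np.ndarray]] = list(informative.items())
    truth: dict[str, list[str]] = {
        "informative": list(INFORMATIVE_NAMES),
        "redundant": [], "quasi_constant": [], "noise": [],
    }

    for i in range(config.n_redundant):
        parent = INFORMATIVE_NAMES[rng.integers(3)]
        transform = _TRANSFORMS[rng.integers(len(_TRANSFORMS))]
        base = transform(informative[parent], rng)
        jitter = rng.normal(0.0, _REDUNDANT_NOISE_SD * (np.std(base) + 1e-12), n)
        name = f"red_{parent}_{i}"
        columns.append((name, base + jitter))
        truth["redundant"].append(name)

    for i in range(config.n_quasi_constant):
        modal_value = rng.uniform(-5, 5)
        col = np.full(n, modal_value)
        n_off = int(np.floor(n * (1 - _QUASI_CONSTANT_MODAL_FRACTION)))
        if n_off > 0:
            off_rows = rng.choice(n, size=n_off, replace=False)
            col[off_rows] = modal_value + rng.uniform(1.0, 2.0, n_off)
        name = f"qc_{i}"
        columns.append((name, col))
        truth["quasi_constant"].append(name)

    for i in range(config.n_noise):
        name = f"noise_{i}"
        columns.append((name, rng.normal(0.0, 1.0, n)))
        truth["noise"].append(name)

    ids = [f"CMP{i:06d}" for i in range(n)]
    table = DescriptorTable(ids, [c for c, _ in columns],
                            np.column_stack([v for _, v in columns]))
    return table, LabelMatrix(ids, labels), truth


def write_synthetic(config: SyntheticConfig, csv_path, truth_path=None) -> None:
    """Write the generated table+labels as a labeled CSV (tabular_io dialect)
    with an optional planted-truth JSON sidecar."""
    table, labels, truth = generate(config)
    df = table.to_frame()
    df.insert(0, "ID", table.compound_ids)
    df["GC"] = labels.labels[:, 0]
    df["LC"] = labels.labels[:, 1]
    df.to_csv(csv_path, index=False)
    if truth_path is not None:
        doc = {"config": config.to_dict(), "planted_truth": truth}
        Path(truth_path).write_text(json.dumps(doc, indent=2))
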