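"""Nonparametric machinery for comparing classifiers and feature sets.

The protocol is repeated k-fold cross-validation with fold assignments
shared across methods, so every fold yields a paired block of scores.
On top of that sit:

* Friedman test with tie correction and Kendall's W = Q / (n (k - 1))
* Nemenyi post hoc pairwise comparisons (studentized-range distribution)
* one-sided / two-sided Wilcoxon signed-rank test (exact enumeration for
  up to 20 nonzero pairs, otherwise tie-corrected normal approximation
  with continuity correction), with the matched-pairs rank-biserial
  correlation and the common-language effect size
* McNemar's test on the per-class discordant counts of two classifiers on
  a holdout set, with the odds ratio b/c as its effect size
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import rankdata, studentized_range
from sklearn.model_selection import KFold

from .multilabel_metrics import label_based_accuracy
from .tabular_io import DescriptorTable, LabelMatrix

_SEED_MOD = 2**31 - 1


@dataclass
class CVResults:
    """Paired (repetitions x folds) score matrices, one per method."""

    method_names: list[str]
    scores: dict[str, np.ndarray]
    folds: int
    repetitions: int
    seed: int
    fold_assignments: list[list[np.ndarray]] = field(default_factory=list)

    def matrix(self, flatten: bool = True) -> np.ndarray:
        """(blocks x methods) matrix for the Friedman test; blocks are the
        repetition-fold cells in a fixed order."""
        cols = [self.scores[m].ravel() if flatten else self.scores[m]
                for m in self.method_names]
        return np.column_stack(cols)

    def summary(self) -> dict[str, dict[str, list[float]]]:
        """Per-repetition mean and sd for each method (the usual
        mean +/- sd per 10-fold row of a comparison table)."""
        out = {}
        for m in self.method_names:
            s = self.scores[m]
            out[m] = {"mean": s.mean(axis=1).tolist(),
                      "sd": s.std(axis=1).tolist()}
        return out


def repeated_cv(methods: dict, table: DescriptorTable, labels: LabelMatrix,
                folds: int = 10, repetitions: int = 10,
                seed: int = 0) -> CVResults:
    """Repeated k-fold CV with identical folds reused across methods.

    ``methods`` maps a name to a zero-argument factory returning an object
    with ``fit(X, Y)`` and ``predict(X)``.  Repetition r shuffles with seed
    ``seed + r``.  Scores are label-based accuracies on each validation
    fold, so the score cells are paired across methods.
    """
    if folds > table.n:
        raise ValueError("folds must be <= number of rows")
    X, Y = table.values, labels.labels
    names = list(methods)
    scores = {m: np.zeros((repetitions, folds)) for m in names}
    assignments: list[list[np.ndarray]] = []
    for r in range(repetitions):
        kf = KFold(n_splits=folds, shuffle=True,
                   random_state=(seed + r) % _SEED_MOD)
        splits = list(kf.split(X))
        assignments.append([val for _, val in splits])
        for m in names:
            for f, (train, val) in enumerate(splits):
                model = methods[m]().fit(X[train], Y[train])
                pred = np.asarray(model.predict(X[val]))
                scores[m][r, f] = label_based_accuracy(Y[val], pred)
    return CVResults(names, scores, folds, repetitions, seed, assignments)


# ---------------------------------------------------------------------------
# Friedman / Kendall W

def friedman(scores: np.ndarray) -> tuple[float, float, float]:
    """Tie-corrected Friedman test over an (n_blocks x k) score matrix.

    Returns (Q, p, W) where p comes from the chi-square approximation with
    k - 1 degrees of freedom and W is Kendall's coefficient of concordance
    Q / (n (k - 1)).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a 2-D (blocks x methods) matrix")
    n, k = scores.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 methods")
    ranks = np.apply_along_axis(rankdata, 1, scores)
    col_sums = ranks.sum(axis=0)
    q_uncorrected = 12.0 / (n * k * (k + 1)) * (col_sums ** 2).sum() - 3 * n * (k + 1)
    # tie correction: sum of (t^3 - t) over tie groups within each block
    tie_term = 0.0
    for row in scores:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts ** 3 - counts).sum())
    correction = 1.0 - tie_term / (n * (k ** 3 - k))
    if correction <= 0:
        raise ValueError("every block is entirely tied; Friedman test undefined")
    q = q_uncorrected / correction
    p = float(_chi2.sf(q, k - 1))
    w = q / (n * (k - 1))
    return float(q), p, float(w)


def nemenyi(scores: np.ndarray, cap: float | None = None) -> np.ndarray:
    """Pairwise Nemenyi p-values from mean-rank differences.

    The statistic for methods (i, j) is |Rbar_i - Rbar_j| divided by
    SE = sqrt(k (k + 1) / (12 n)) and referred to the studentized-range
    distribution with k groups and infinite degrees of freedom.  ``cap``
    optionally clips reported p-values from above (display convention
    0.900 in some implementations).
    """
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    if k < 3:
        raise ValueError("Nemenyi post hoc needs at least 3 methods")
    ranks = np.apply_along_axis(rankdata, 1, scores)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            stat = abs(mean_ranks[i] - mean_ranks[j]) / se
            pij = float(np.clip(studentized_range.sf(stat, k, np.inf), 0, 1))
            p[i, j] = p[j, i] = pij
    if cap is not None:
        off = ~np.eye(k, dtype=bool)
        p[off] = np.minimum(p[off], cap)
    return p


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank + effect sizes

def _exact_wplus_sf(ranks: np.ndarray, w: float) -> tuple[float, float]:
    """P(W+ >= w) and P(W+ <= w) by dynamic programming over all 2^n sign
    patterns.  Ranks may be half-integers (average ranks), so they are
    doubled to integers first."""
    doubled = np.round(ranks * 2).astype(int)
    total = int(doubled.sum())
    # dist[s] = number of sign patterns with doubled W+ == s
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(w * 2))
    return float(dist[w2:].sum()), float(dist[:w2 + 1].sum())


def wilcoxon_signed_rank(a, b, alternative: str = "two_sided",
                         exact_limit: int = 20) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped (classic treatment); ties among |d| get
    average ranks.  W is the sum of ranks of positive differences.  The
    p-value is exact (full sign-pattern enumeration) for up to
    ``exact_limit`` nonzero pairs, otherwise a normal approximation with
    continuity correction and tie-adjusted variance.  ``alternative
    ='greater'`` tests whether a tends to exceed b.
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size == 0:
        raise ValueError("a and b must be nonempty and equally long")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_limit:
        p_ge, p_le = _exact_wplus_sf(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        # counts of tied |d| groups; groups of size t remove (t^3 - t)/48
        tie_adj = float((counts ** 3 - counts).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_adj
        sd = np.sqrt(var)
        p_ge = float(_norm.sf((w_plus - 0.5 - mean) / sd))
        p_le = float(_norm.cdf((w_plus + 0.5 - mean) / sd))

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2 * min(p_ge, p_le))
    return w_plus, p


def effect_mprbc(a, b) -> float:
    """Matched-pairs rank-biserial correlation (W+ - W-)/(W+ + W-)."""
    d = np.asarray(a, dtype=float).ravel() - np.asarray(b, dtype=float).ravel()
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    return float((w_plus - w_minus) / (w_plus + w_minus))


def effect_cles(a, b) -> float:
    """Common-language effect size: P(a > b) + 0.5 P(a = b) over all pairs."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("a and b must be nonempty")
    diff = a[:, None] - b[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


# ---------------------------------------------------------------------------
# McNemar + odds ratio

def mcnemar(truth, pred_a, pred_b, continuity: bool = True,
            ) -> tuple[float, float, float, int, int]:
    """McNemar's test on the discordant correctness of two classifiers.

    b counts instances A got right and B got wrong; c the reverse.
    chi2 = (|b - c| - 1)^2 / (b + c) with the continuity correction
    (default), (b - c)^2 / (b + c) without.  The odds ratio is b / c with
    the Haldane +0.5 correction applied to both counts when either is 0.
    Returns (chi2, p, odds_ratio, b, c).
    """
    truth = np.asarray(truth).ravel()
    pa = np.asarray(pred_a).ravel()
    pb = np.asarray(pred_b).ravel()
    if not (truth.shape == pa.shape == pb.shape):
        raise ValueError("truth and predictions must be equally long")
    a_correct = pa == truth
    b_correct = pb == truth
    b_count = int((a_correct & ~b_correct).sum())
    c_count = int((~a_correct & b_correct).sum())
    if b_count + c_count == 0:
        raise ValueError("no discordant pairs; McNemar test undefined")
    if continuity:
        stat = (abs(b_count - c_count) - 1) ** 2 / (b_count + c_count)
    else:
        stat = (b_count - c_count) ** 2 / (b_count + c_count)
    p = float(_chi2.sf(stat, 1))
    bb, cc = float(b_count), float(c_count)
    if bb == 0 or cc == 0:
        bb, cc = bb + 0.5, cc + 0.5
    return float(stat), p, bb / cc, b_count, c_count


# ---------------------------------------------------------------------------
# aggregate report

@dataclass
class ComparisonReport:
    """All comparison statistics of one analysis run, JSON-serialisable."""

    method_names: list[str]
    friedman_q: float
    friedman_p: float
    kendall_w: float
    nemenyi_p: list[list[float]]
    wilcoxon_pair: tuple[str, str] | None = None
    wilcoxon_w: float | None = None
    wilcoxon_p: float | None = None
    mprbc: float | None = None
    cles: float | None = None
    mcnemar: dict | None = None  # per class: chi2, p, odds_ratio, b, c
    mcnemar_continuity: bool = True

    def to_dict(self) -> dict:
        return {
            "method_names": self.method_names,
            "friedman": {"q": self.friedman_q, "p": self.friedman_p,
                         "kendall_w": self.kendall_w},
            "nemenyi_p": self.nemenyi_p,
            "wilcoxon": None if self.wilcoxon_w is None else {
                "pair": list(self.wilcoxon_pair),
                "w": self.wilcoxon_w, "p": self.wilcoxon_p,
                "mprbc": self.mprbc, "cles": self.cles},
            "mcnemar": self.mcnemar,
            "mcnemar_continuity": self.mcnemar_continuity,
        }


def compare_feature_sets(cv: CVResults,
                         wilcoxon_pair: tuple[str, str] | None = None,
                         ) -> ComparisonReport:
    """Friedman + Nemenyi over all methods in ``cv``; optionally a
    one-sided Wilcoxon (second member greater) with effect sizes for one
    named pair (conventionally the initial vs the final feature set)."""
    mat = cv.matrix()
    q, p, w = friedman(mat)
    nem = nemenyi(mat) if len(cv.method_names) >= 3 else np.ones((2, 2))
    report = ComparisonReport(cv.method_names, q, p, w, nem.tolist())
    if wilcoxon_pair is not None:
        first, second = wilcoxon_pair
        a = cv.scores[second].ravel()
        b = cv.scores[first].ravel()
        report.wilcoxon_pair = wilcoxon_pair
        report.wilcoxon_w, report.wilcoxon_p = wilcoxon_signed_rank(
            a, b, alternative="greater")
        report.mprbc = effect_mprbc(a, b)
        report.cles = effect_cles(a, b)
    return report
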