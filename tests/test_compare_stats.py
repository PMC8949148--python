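import itertools

import numpy as np
import pytest
import scipy.stats

from amenability import compare_stats as cs
from amenability.amenability_tree import TreeMethod
from amenability.synthetic_descriptors import SyntheticConfig, generate


class TestFriedman:
    def test_perfect_concordance_closed_form(self):
        """n=3 blocks ranking k=3 methods identically: Q=6, W=1."""
        scores = np.array([[1.0, 2.0, 3.0],
                           [0.1, 0.5, 0.9],
                           [10., 20., 30.]])
        q, p, w = cs.friedman(scores)
        assert q == pytest.approx(6.0)
        assert w == pytest.approx(1.0)

    def test_all_tied_is_diagnostic(self):
        with pytest.raises(ValueError, match="tied"):
            cs.friedman(np.ones((4, 3)))

    def test_k2_reduces_to_sign_test_statistic(self, rng):
        """For k=2 without ties Q = (n_plus - n_minus)^2 / n."""
        for _ in range(20):
            n = int(rng.integers(3, 12))
            a = rng.normal(size=n)
            b = a + rng.choice([-1.0, 1.0], n) * rng.uniform(0.1, 1, n)
            q, _, _ = cs.friedman(np.column_stack([a, b]))
            n_plus = int((b > a).sum())
            n_minus = n - n_plus
            assert q == pytest.approx((n_plus - n_minus) ** 2 / n)

    def test_matches_scipy_for_k_at_least_three(self, rng):
        """Independent oracle: scipy.stats.friedmanchisquare."""
        for _ in range(20):
            scores = rng.normal(size=(int(rng.integers(3, 15)), 4))
            q, p, _ = cs.friedman(scores)
            ref = scipy.stats.friedmanchisquare(*scores.T)
            assert q == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_rank_invariance_under_column_permutation(self, rng):
        scores = rng.normal(size=(10, 4))
        q1, _, _ = cs.friedman(scores)
        q2, _, _ = cs.friedman(scores[:, rng.permutation(4)])
        assert q1 == pytest.approx(q2)

    def test_kendall_w_in_unit_interval(self, rng):
        for _ in range(20):
            _, _, w = cs.friedman(rng.normal(size=(8, 5)))
            assert 0 <= w <= 1


class TestNemenyi:
    def test_identical_columns_maximal_p(self, rng):
        a = rng.normal(size=20)
        scores = np.column_stack([a, a, rng.normal(size=20)])
        p = cs.nemenyi(scores)
        assert p[0, 1] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self, rng):
        p = cs.nemenyi(rng.normal(size=(15, 4)))
        assert np.allclose(p, p.T)
        assert np.allclose(np.diag(p), 1.0)
        assert ((p >= 0) & (p <= 1)).all()

    def test_method_relabeling_permutes_matrix(self, rng):
        scores = rng.normal(size=(20, 4))
        perm = rng.permutation(4)
        p1 = cs.nemenyi(scores)
        p2 = cs.nemenyi(scores[:, perm])
        assert np.allclose(p1[np.ix_(perm, perm)], p2)

    def test_smaller_rank_gap_never_smaller_p(self, rng):
        """p is monotone in the mean-rank difference (same n, k)."""
        scores = rng.normal(size=(20, 4))
        ranks = np.apply_along_axis(scipy.stats.rankdata, 1, scores)
        mean_ranks = ranks.mean(axis=0)
        p = cs.nemenyi(scores)
        pairs = list(itertools.combinations(range(4), 2))
        for (i, j), (a, b) in itertools.product(pairs, pairs):
            gap1 = abs(mean_ranks[i] - mean_ranks[j])
            gap2 = abs(mean_ranks[a] - mean_ranks[b])
            if gap1 < gap2:
                assert p[i, j] >= p[a, b] - 1e-12

    def test_display_cap(self, rng):
        a = rng.normal(size=10)
        scores = np.column_stack([a, a + 0.001 * rng.normal(size=10),
                                  rng.normal(size=10)])
        p = cs.nemenyi(scores, cap=0.9)
        off = ~np.eye(3, dtype=bool)
        assert (p[off] <= 0.9).all()
        assert np.allclose(np.diag(p), 1.0)

    def test_two_methods_rejected(self, rng):
        with pytest.raises(ValueError):
            cs.nemenyi(rng.normal(size=(10, 2)))


class TestWilcoxon:
    def test_all_positive_five_pairs_exact(self):
        a = np.array([5.0, 6, 7, 8, 9])
        b = np.array([1.0, 2, 3, 4, 5])
        w, p = cs.wilcoxon_signed_rank(a, b, alternative="greater")
        assert w == 15.0
        assert p == pytest.approx(1 / 32)

    def test_all_zero_differences_diagnostic(self):
        with pytest.raises(ValueError, match="zero"):
            cs.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_swap_antisymmetry(self, rng):
        a = rng.normal(size=12)
        b = a + rng.normal(size=12)
        w_ab, p_g = cs.wilcoxon_signed_rank(a, b, alternative="greater")
        w_ba, p_l = cs.wilcoxon_signed_rank(b, a, alternative="less")
        n = 12
        assert w_ab + w_ba == pytest.approx(n * (n + 1) / 2)
        assert p_g == pytest.approx(p_l)

    def test_exact_matches_scipy(self, rng):
        """Independent oracle for the exact branch (tie-free data)."""
        for _ in range(20):
            n = int(rng.integers(6, 15))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            for alt in ("greater", "less", "two_sided"):
                _, p = cs.wilcoxon_signed_rank(a, b, alternative=alt)
                ref = scipy.stats.wilcoxon(a, b, alternative=alt.replace("_", "-"),
                                           method="exact")
                assert p == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_exact(self, rng):
        """At n=20 the continuity-corrected normal p is within 0.01 of the
        exact enumeration."""
        for _ in range(20):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            _, p_exact = cs.wilcoxon_signed_rank(a, b, alternative="greater",
                                                 exact_limit=20)
            _, p_norm = cs.wilcoxon_signed_rank(a, b, alternative="greater",
                                                exact_limit=0)
            assert abs(p_exact - p_norm) < 0.01


class TestEffectSizes:
    def test_mprbc_extremes_and_hand_ranking(self):
        assert cs.effect_mprbc([2.0, 3, 4], [1.0, 2, 3]) == 1.0
        # |d| = 1,2,3,4 with signs +,+,+,-: (6 - 4) / 10 = 0.2
        a = np.array([1.0, 2, 3, 0])
        b = np.array([0.0, 0, 0, 4])
        assert cs.effect_mprbc(a, b) == pytest.approx(0.2)

    def test_mprbc_balance_is_zero(self):
        assert cs.effect_mprbc([1.0, -1.0], [0.0, 0.0]) == 0.0

    def test_mprbc_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a, b = rng.normal(size=30), rng.normal(size=30)
        ref = pingouin.wilcoxon(a, b)["RBC"].iloc[0]
        assert cs.effect_mprbc(a, b) == pytest.approx(abs(ref), abs=1e-9) or \
            cs.effect_mprbc(a, b) == pytest.approx(-abs(ref), abs=1e-9)

    def test_cles_enumeration(self):
        assert cs.effect_cles([2.0, 3.0], [0.0, 1.0]) == 1.0
        assert cs.effect_cles([1.0, 2.0], [1.0, 2.0]) == 0.5
        # pairs (1,2),(1,3),(2,2),(2,3): wins 0, ties 1 -> 0.5/4
        assert cs.effect_cles([1.0, 2.0], [2.0, 3.0]) == pytest.approx(0.125)

    def test_cles_complement_without_ties(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(size=17)
        assert cs.effect_cles(a, b) + cs.effect_cles(b, a) == pytest.approx(1.0)

    def test_cles_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a, b = rng.normal(size=25), rng.normal(size=25)
        ref = float(pingouin.compute_effsize(a, b, eftype="CLES"))
        assert cs.effect_cles(a, b) == pytest.approx(ref)


class TestMcNemar:
    def _preds(self, b_count, c_count, n_extra=5):
        """Construct truth/predictions with the requested discordant counts."""
        n = b_count + c_count + n_extra
        truth = np.zeros(n, int)
        pred_a = np.zeros(n, int)
        pred_b = np.zeros(n, int)
        pred_b[:b_count] = 1                       # A correct, B wrong
        pred_a[b_count:b_count + c_count] = 1      # A wrong, B correct
        return truth, pred_a, pred_b

    def test_hand_arithmetic_without_continuity(self):
        truth, pa, pb = self._preds(10, 2)
        chi2, p, oratio, b, c = cs.mcnemar(truth, pa, pb, continuity=False)
        assert (b, c) == (10, 2)
        assert chi2 == pytest.approx(64 / 12)
        assert oratio == pytest.approx(5.0)

    def test_hand_arithmetic_with_continuity(self):
        truth, pa, pb = self._preds(10, 2)
        chi2, _, _, _, _ = cs.mcnemar(truth, pa, pb, continuity=True)
        assert chi2 == pytest.approx(49 / 12)

    def test_balanced_discordance(self):
        truth, pa, pb = self._preds(4, 4)
        chi2, p, oratio, _, _ = cs.mcnemar(truth, pa, pb, continuity=False)
        assert chi2 == 0.0 and oratio == 1.0 and p == pytest.approx(1.0)

    def test_swap_maps_or_to_reciprocal(self):
        truth, pa, pb = self._preds(9, 3)
        chi2_ab, _, or_ab, _, _ = cs.mcnemar(truth, pa, pb)
        chi2_ba, _, or_ba, _, _ = cs.mcnemar(truth, pb, pa)
        assert chi2_ab == pytest.approx(chi2_ba)
        assert or_ab == pytest.approx(1 / or_ba)

    def test_haldane_correction_when_zero_cell(self):
        truth, pa, pb = self._preds(6, 0)
        _, _, oratio, _, _ = cs.mcnemar(truth, pa, pb)
        assert oratio == pytest.approx(6.5 / 0.5)

    def test_no_discordance_diagnostic(self):
        truth = np.array([0, 1, 0])
        with pytest.raises(ValueError, match="discordant"):
            cs.mcnemar(truth, truth, truth)

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        truth, pa, pb = self._preds(10, 2)
        chi2, p, _, b, c = cs.mcnemar(truth, pa, pb, continuity=False)
        table = [[0, b], [c, 0]]  # only discordant cells matter
        ref = sm_mcnemar(table, exact=False, correction=False)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


@pytest.fixture(scope="module")
def data():
    return generate(SyntheticConfig(n_compounds=300, label_noise=0.05,
                                    n_redundant=0, n_quasi_constant=0,
                                    n_noise=3, seed=31))


class TestRepeatedCV:

    def test_deterministic(self, data):
        table, labels, _ = data
        methods = {"tree": lambda: TreeMethod({"max_depth": 3}, seed=1)}
        cv1 = cs.repeated_cv(methods, table, labels, folds=4, repetitions=3,
                             seed=5)
        cv2 = cs.repeated_cv(methods, table, labels, folds=4, repetitions=3,
                             seed=5)
        assert np.array_equal(cv1.scores["tree"], cv2.scores["tree"])

    def test_methods_share_fold_assignments(self, data):
        table, labels, _ = data
        methods = {"a": lambda: TreeMethod({"max_depth": 2}, seed=1),
                   "b": lambda: TreeMethod({"max_depth": 4}, seed=1)}
        cv = cs.repeated_cv(methods, table, labels, folds=4, repetitions=2,
                            seed=5)
        # identical methods on identical folds give identical scores
        methods_same = {"a": lambda: TreeMethod({"max_depth": 3}, seed=1),
                        "b": lambda: TreeMethod({"max_depth": 3}, seed=1)}
        cv_same = cs.repeated_cv(methods_same, table, labels, folds=4,
                                 repetitions=2, seed=5)
        assert np.array_equal(cv_same.scores["a"], cv_same.scores["b"])
        assert len(cv.fold_assignments) == 2
        assert all(len(rep) == 4 for rep in cv.fold_assignments)

    def test_constant_predictor_scores_stable(self, data):
        table, labels, _ = data

        class Majority:
            def fit(self, X, Y):
                self.row = (Y.mean(axis=0) >= 0.5).astype(int)
                return self

            def predict(self, X):
                return np.tile(self.row, (len(X), 1))

        cv = cs.repeated_cv({"maj": Majority}, table, labels, folds=5,
                            repetitions=3, seed=2)
        s = cv.scores["maj"]
        assert s.std() < 0.1  # only fold-composition variation
        rep_var = s.mean(axis=1).var()
        fold_var = s.var(axis=1).mean()
        assert rep_var <= fold_var + 1e-9

    def test_matrix_shape_for_friedman(self, data):
        table, labels, _ = data
        methods = {m: (lambda d=d: TreeMethod({"max_depth": d}, seed=1))
                   for m, d in (("d2", 2), ("d3", 3), ("d4", 4))}
        cv = cs.repeated_cv(methods, table, labels, folds=3, repetitions=2,
                            seed=0)
        assert cv.matrix().shape == (6, 3)
        q, p, w = cs.friedman(cv.matrix())
        assert 0 <= w <= 1
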