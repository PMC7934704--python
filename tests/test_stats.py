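"""ROC, ICC, kappa, paired t and Dice against closed forms and brute force."""

import numpy as np
import pytest
from scipy.stats import norm

from perfrad import imaging, stats


class TestEmpiricalAUC:
    def test_perfect_separation(self):
        assert stats.empirical_auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_tie_counts_half(self):
        assert stats.empirical_auc([0.5], [0.5]) == 0.5

    def test_small_example_by_pair_counting(self):
        # pairs: (3,2) win, (3,0) win, (1,2) loss, (1,0) win -> 3/4
        assert stats.empirical_auc([3, 1], [2, 0]) == 0.75

    def test_matches_brute_force_pairwise_on_random_instances(self, rng):
        for _ in range(300):
            npos = rng.integers(1, 8)
            nneg = rng.integers(1, 8)
            pos = rng.integers(0, 5, size=npos).astype(float)  # heavy ties
            neg = rng.integers(0, 5, size=nneg).astype(float)
            wins = sum(
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            )
            assert stats.empirical_auc(pos, neg) == pytest.approx(
                wins / (npos * nneg), abs=1e-12
            )

    def test_complement_symmetry(self, rng):
        pos = rng.normal(size=9)
        neg = rng.normal(size=7)
        assert stats.empirical_auc(pos, neg) == pytest.approx(
            1.0 - stats.empirical_auc(neg, pos), abs=1e-12
        )

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            stats.empirical_auc([], [1.0])


class TestBinormalROC:
    def test_null_fit_near_half(self, rng):
        pos = rng.normal(size=500)
        neg = rng.normal(size=500)
        roc = stats.fit_binormal_roc(pos, neg)
        assert abs(roc.auc_binormal - 0.5) < 0.03

    def test_recovers_known_auc(self, rng):
        pos = rng.normal(1.0, 1.0, size=2000)
        neg = rng.normal(0.0, 1.0, size=2000)
        roc = stats.fit_binormal_roc(pos, neg)
        assert abs(roc.auc_binormal - norm.cdf(1.0 / np.sqrt(2.0))) < 0.01
        assert roc.ci_low <= roc.auc_binormal <= roc.ci_high
        assert roc.b > 0

    def test_invariant_under_monotone_transform(self, rng):
        pos = rng.normal(0.8, 1.1, size=300)
        neg = rng.normal(0.0, 1.0, size=300)
        r1 = stats.fit_binormal_roc(pos, neg)
        r2 = stats.fit_binormal_roc(np.exp(pos), np.exp(neg))
        assert r2.a == pytest.approx(r1.a, abs=1e-6)
        assert r2.b == pytest.approx(r1.b, abs=1e-6)
        assert r2.auc_binormal == pytest.approx(r1.auc_binormal, abs=1e-6)

    def test_perfect_separation_flagged_degenerate(self):
        roc = stats.fit_binormal_roc([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        assert roc.degenerate
        assert roc.auc_empirical == 1.0

    def test_ci_width_shrinks_with_n(self, rng):
        widths = []
        for n in (50, 500):
            pos = rng.normal(1.0, 1.0, size=n)
            neg = rng.normal(0.0, 1.0, size=n)
            roc = stats.fit_binormal_roc(pos, neg)
            widths.append(roc.ci_high - roc.ci_low)
        assert widths[1] < widths[0]

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            stats.fit_binormal_roc([1.0, 2.0], [0.0, 0.5, 1.0])
        with pytest.raises(ValueError):
            stats.fit_binormal_roc([1.0] * 5, [1.0] * 5)

    def test_run_collapsing_counts(self):
        # scores: neg neg | pos pos | neg | pos  (distinct values ascending)
        neg = np.array([1.0, 2.0, 5.0])
        pos = np.array([3.0, 4.0, 6.0])
        nneg, npos = stats.collapse_to_categories(pos, neg)
        np.testing.assert_array_equal(nneg, [2, 0, 1, 0])
        np.testing.assert_array_equal(npos, [0, 2, 0, 1])

    def test_run_collapsing_mixed_ties_own_category(self):
        neg = np.array([1.0, 2.0, 2.0])
        pos = np.array([2.0, 3.0, 3.0])
        nneg, npos = stats.collapse_to_categories(pos, neg)
        np.testing.assert_array_equal(nneg, [1, 2, 0])
        np.testing.assert_array_equal(npos, [0, 1, 2])

    def test_category_cap_respected(self, rng):
        pos = rng.normal(1, 1, size=400)
        neg = rng.normal(0, 1, size=400)
        nneg, npos = stats.collapse_to_categories(pos, neg, max_categories=20)
        assert len(nneg) <= 20
        assert nneg.sum() == 400 and npos.sum() == 400


class TestICC:
    def test_identical_columns_give_one(self):
        table = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [9.0, 9.0]])
        assert stats.icc(table).icc == pytest.approx(1.0)

    def test_constant_offset_matches_hand_anova(self):
        table = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        res = stats.icc(table)
        # hand ANOVA: n=3, k=2; MSR=2*1=2... computed independently below
        n, k = table.shape
        grand = table.mean()
        msr = k * ((table.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((table.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        sse = ((table - grand) ** 2).sum() - (n - 1) * msr - (k - 1) * msc
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert res.icc == pytest.approx(expected, rel=1e-12)
        assert "absolute agreement" in res.icc_model

    def test_independent_columns_near_zero(self, rng):
        table = rng.normal(size=(2000, 2))
        assert abs(stats.icc(table).icc) < 0.05

    def test_symmetric_under_rater_exchange(self, rng):
        table = rng.normal(size=(30, 2)) + rng.normal(size=(30, 1))
        assert stats.icc(table).icc == pytest.approx(
            stats.icc(table[:, ::-1]).icc, rel=1e-12
        )

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        table = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 1.5
        long = pd.DataFrame(
            {
                "case": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": table.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="case", raters="rater", ratings="score")
        icc_a1 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert stats.icc(table).icc == pytest.approx(icc_a1, rel=1e-6)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="variance"):
            stats.icc(np.full((4, 2), 3.0))


class TestKappa:
    def test_identical_labelings(self):
        a = np.array([0, 1, 0, 1, 1])
        assert stats.cohen_kappa(a, a).kappa == pytest.approx(1.0)

    def test_two_by_two_table_hand_formula(self):
        # confusion a=10 (1,1), b=5 (1,0), c=5 (0,1), d=16 (0,0); n=36
        x = np.array([1] * 10 + [1] * 5 + [0] * 5 + [0] * 16)
        y = np.array([1] * 10 + [0] * 5 + [1] * 5 + [0] * 16)
        p_o = 26 / 36
        p_e = (15 / 36) * (15 / 36) + (21 / 36) * (21 / 36)
        expected = (p_o - p_e) / (1 - p_e)
        assert stats.cohen_kappa(x, y).kappa == pytest.approx(expected, rel=1e-12)

    def test_independent_labelings_near_zero(self, rng):
        a = (rng.random(20000) < 0.3).astype(int)
        b = (rng.random(20000) < 0.6).astype(int)
        assert abs(stats.cohen_kappa(a, b).kappa) < 0.03

    def test_symmetry(self, rng):
        a = (rng.random(50) < 0.4).astype(int)
        b = (rng.random(50) < 0.5).astype(int)
        assert stats.cohen_kappa(a, b).kappa == stats.cohen_kappa(b, a).kappa

    def test_degenerate_when_chance_agreement_is_one(self):
        res = stats.cohen_kappa(np.ones(5, int), np.ones(5, int))
        assert res.degenerate


class TestPairedT:
    def test_constant_shift_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        res = stats.paired_ttest(x + 1.0, x)
        assert res.degenerate

    def test_identical_vectors_degenerate_zero(self):
        x = np.array([1.0, 5.0, 9.0])
        res = stats.paired_ttest(x, x)
        assert res.degenerate and res.t_stat == 0.0

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        res = stats.paired_ttest(x, y)
        d = x - y
        se = d.std(ddof=1) / np.sqrt(10)
        t = d.mean() / se
        from scipy.stats import t as tdist

        assert res.t_stat == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(2 * tdist.sf(abs(t), 9), rel=1e-12)


class TestDice:
    def _mask(self, arr):
        return imaging.BinaryMask(np.asarray(arr, dtype=np.uint8), (1, 1, 1))

    def test_identical(self, rng):
        m = self._mask(rng.random((4, 4, 4)) < 0.5)
        assert stats.dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((2, 2, 2)); a[0] = 1
        b = np.zeros((2, 2, 2)); b[1] = 1
        assert stats.dice(self._mask(a), self._mask(b)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 10, 10)); a.ravel()[:100] = 1
        b = np.zeros((10, 10, 10)); b.ravel()[50:150] = 1
        assert stats.dice(self._mask(a), self._mask(b)) == 0.5

    def test_both_empty_defined_as_one(self):
        z = self._mask(np.zeros((2, 2, 2)))
        assert stats.dice(z, z) == 1.0

    def test_grid_mismatch_rejected(self):
        a = self._mask(np.ones((2, 2, 2)))
        b = imaging.BinaryMask(np.ones((2, 2, 2), dtype=np.uint8), (2, 1, 1))
        with pytest.raises(ValueError):
            stats.dice(a, b)
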