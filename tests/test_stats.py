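import itertools

import numpy as np
import pytest
from scipy import stats as sps

from cbctqa import stats as st


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return st.RepeatedMeasuresMatrix(
        values,
        subjects=[f"s{i}" for i in range(values.shape[0])],
        conditions=[f"c{j}" for j in range(values.shape[1])],
    )


class TestFriedman:
    def test_strictly_increasing_ranks(self):
        # n=5 subjects all ranking the k=3 conditions identically:
        # statistic 12n/(k(k+1)) * sum((Rbar_j - (k+1)/2)^2) = 2n = 10
        m = _matrix(np.tile([1.0, 2.0, 3.0], (5, 1)) + np.arange(5)[:, None] * 10)
        res = st.friedman(m)
        assert res.statistic == pytest.approx(10.0, abs=1e-12)
        assert res.df == 2
        assert res.p == pytest.approx(float(sps.chi2.sf(10.0, 2)), abs=1e-12)
        assert res.p == pytest.approx(0.0067, abs=1e-4)

    def test_identical_columns(self):
        m = _matrix(np.tile([3.0, 3.0, 3.0], (6, 1)) + np.arange(6)[:, None])
        res = st.friedman(m)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_matches_reference_on_random_matrices(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 15))
            k = int(rng.integers(3, 7))
            v = rng.standard_normal((n, k))
            mine = st.friedman(_matrix(v))
            ref = sps.friedmanchisquare(*v.T)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_tied_data_matches_reference(self, rng):
        for _ in range(30):
            v = rng.integers(1, 5, size=(10, 4)).astype(float)
            if np.all(v.min(axis=1) == v.max(axis=1)):
                continue
            mine = st.friedman(_matrix(v))
            ref = sps.friedmanchisquare(*v.T)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-9)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="subjects"):
            st.friedman(_matrix([[1.0, 2.0, 3.0]]))

    def test_two_conditions_delegates_to_wilcoxon(self, rng):
        m = _matrix(rng.standard_normal((8, 2)))
        res = st.friedman(m)
        assert "wilcoxon" in res.method
        assert "delegated" in res.note

    def test_listwise_deletion_counts(self):
        v = np.array([[1.0, 2, 3], [2, np.nan, 1], [3, 1, 2], [1, 3, 2]])
        m = _matrix(v)
        assert m.n_subjects == 3
        assert m.n_excluded == 1


class TestPosthoc:
    def test_all_pairs_family_size(self, rng):
        m = _matrix(rng.standard_normal((10, 6)))
        results = st.posthoc_pairwise(m)
        assert len(results) == 15
        for r in results:
            assert r.p_adj == pytest.approx(min(1.0, 15 * r.p), abs=1e-12)

    def test_baseline_mode(self, rng):
        m = _matrix(rng.standard_normal((10, 6)))
        results = st.posthoc_pairwise(m, baseline="c0")
        assert len(results) == 5
        assert all(r.comparison.startswith("c0 vs ") for r in results)

    def test_identical_pair_degenerates_to_p_one(self, rng):
        col = rng.standard_normal(8)
        v = np.column_stack([col, col, rng.standard_normal(8)])
        with pytest.warns(UserWarning, match="zero"):
            results = st.posthoc_pairwise(_matrix(v))
        first = [r for r in results if r.comparison == "c0 vs c1"][0]
        assert first.p == 1.0


class TestWilcoxon:
    def test_identical_samples(self):
        with pytest.warns(UserWarning, match="zero"):
            res = st.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == 1.0

    def test_all_positive_n5_exact(self):
        # 2^5 equally likely sign patterns; only one reaches W+ = 15
        res = st.wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0], [0.0] * 5)
        assert res.method == "wilcoxon-exact"
        assert res.p == pytest.approx(2 / 32, abs=1e-12)

    def test_exact_p_matches_sign_enumeration(self, rng):
        # independent oracle: enumerate all 2^n sign assignments directly
        for n in range(2, 11):
            d = rng.uniform(0.5, 10, size=n) * rng.choice([-1.0, 1.0], size=n)
            d += rng.uniform(0, 0.01, size=n)  # break accidental magnitude ties
            res = st.wilcoxon_signed_rank(d)
            ranks = sps.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            ws = [
                sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([False, True], repeat=n)
            ]
            ws = np.asarray(ws)
            p_lo = np.mean(ws <= w_obs + 1e-9)
            p_hi = np.mean(ws >= w_obs - 1e-9)
            expected = min(1.0, 2 * min(p_lo, p_hi))
            assert res.method == "wilcoxon-exact"
            assert res.p == pytest.approx(expected, abs=1e-12), f"n={n}"

    def test_normal_approximation_for_large_or_tied(self, rng):
        d = rng.integers(-3, 4, size=40).astype(float)
        d = d[d != 0]
        mine = st.wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="approx", correction=True)
        assert mine.method == "wilcoxon-normal"
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            st.wilcoxon_signed_rank([1.0, 2.0], [1.0])


class TestIcc:
    def test_identical_raters(self):
        grid = np.array([[1, 1], [3, 3], [4, 4], [5, 5]], dtype=float)
        res = st.icc_average_fixed(grid)
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.band == "excellent"

    def test_constant_offset_still_perfect_consistency(self):
        # consistency ICC ignores a fixed rater offset: MS_error = 0
        grid = np.array([[1, 2], [2, 3], [3, 4], [4, 5]], dtype=float)
        res = st.icc_average_fixed(grid)
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_two_way_anova(self):
        # grid ((1,2),(2,4),(3,3),(4,5)): SS_subj=9, SS_rater=2, SS_err=1
        # MS_subj=3, MS_err=1/3 -> ICC(3,k) = (3 - 1/3)/3 = 8/9
        grid = np.array([[1, 2], [2, 4], [3, 3], [4, 5]], dtype=float)
        res = st.icc_average_fixed(grid)
        assert res.icc == pytest.approx(8 / 9, abs=1e-12)
        assert res.band == "good"

    def test_matches_pingouin_on_random_grids(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        for _ in range(10):
            n, k = int(rng.integers(5, 15)), int(rng.integers(2, 4))
            grid = rng.normal(3, 1, size=(n, k))
            df = pd.DataFrame(
                {
                    "s": np.repeat(np.arange(n), k),
                    "r": np.tile(np.arange(k), n),
                    "y": grid.ravel(),
                }
            )
            icc = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
            ref_c = float(icc.loc[icc.Type == "ICC(C,k)", "ICC"].iloc[0])
            ref_a = float(icc.loc[icc.Type == "ICC(A,k)", "ICC"].iloc[0])
            assert st.icc_average_fixed(grid).icc == pytest.approx(ref_c, abs=1e-9)
            assert st.icc_average_fixed(grid, absolute=True).icc == pytest.approx(ref_a, abs=1e-9)

    def test_degenerate_table(self):
        with pytest.raises(ValueError, match="degenerate"):
            st.icc_average_fixed(np.full((4, 2), 3.0))

    @pytest.mark.parametrize(
        "value,band",
        [(0.2, "poor"), (-0.1, "poor"), (0.5, "moderate"), (0.73, "moderate"),
         (0.75, "good"), (0.89, "good"), (0.9, "excellent"), (1.0, "excellent")],
    )
    def test_interpretation_bands(self, value, band):
        assert st.classify_icc(value) == band


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(6.0)
        assert st.spearman(x, x**3).statistic == pytest.approx(1.0)
        assert st.spearman(x, -x - 1).statistic == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            st.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_exact_p_matches_full_permutation(self, rng):
        for n in (4, 5, 6, 7):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            res = st.spearman(x, y)
            rho_obs = abs(sps.spearmanr(x, y).statistic)
            count = 0
            total = 0
            for perm in itertools.permutations(y):
                rho = abs(sps.spearmanr(x, perm).statistic)
                count += rho >= rho_obs - 1e-12
                total += 1
            assert res.method == "spearman-exact"
            assert res.p == pytest.approx(count / total, abs=1e-12), f"n={n}"

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        mine = st.spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert mine.method == "spearman-t"
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestBonferroni:
    def test_direct_arithmetic(self):
        assert st.bonferroni([0.01, 0.04]) == [0.02, 0.08]

    def test_capped_at_one(self):
        assert st.bonferroni([0.5], family_size=15) == [1.0]

    def test_identity_for_single_comparison(self):
        assert st.bonferroni([0.3], family_size=1) == [0.3]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            st.bonferroni([1.2])

    def test_monotone_and_never_below_raw(self, rng):
        p = np.sort(rng.uniform(0, 1, size=20))
        adj = st.bonferroni(p.tolist(), family_size=7)
        assert all(a >= r for a, r in zip(adj, p))
        assert all(adj[i] <= adj[i + 1] for i in range(len(adj) - 1))
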