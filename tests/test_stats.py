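"""Statistical layer: formula oracles, enumeration oracles, and the
contingency pipeline."""

import itertools
import math

import numpy as np
import pytest

import shmcontext as sc
from shmcontext.kmers import KmerRecord
from shmcontext.features import ContextFeatures
from shmcontext.simulate import Repertoire


# ------------------------------------------------------------------ oracles

def permutation_mannwhitney_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of group
    assignments of the pooled sample."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0

    def ustat(gx, gy):
        return sum(a > b for a in gx for b in gy) + 0.5 * sum(a == b for a in gx for b in gy)

    u_obs = ustat(x, y)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        in_x = set(combo)
        gx = [pooled[i] for i in combo]
        gy = [pooled[i] for i in range(len(pooled)) if i not in in_x]
        total += 1
        if abs(ustat(gx, gy) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def hypergeom_fisher_p(table):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    a, b, c, d = table.n_G3G6, table.n_A3G6, table.n_G3H6, table.n_A3H6
    n1, k, N = a + b, a + c, a + b + c + d

    def pmf(x):
        return math.comb(n1, x) * math.comb(N - n1, k - x) / math.comb(N, k)

    p_obs = pmf(a)
    lo, hi = max(0, k - (N - n1)), min(k, n1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


# ------------------------------------------------------------------ tests

class TestPearsonWald:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        assert sc.pearson_with_wald(x, x)[0] == pytest.approx(1.0)
        assert sc.pearson_with_wald(x, -2 * x + 7)[0] == pytest.approx(-1.0)

    def test_hand_formula_oracle(self):
        x = np.array([0.0, 1.0, 3.0, 4.0, 10.0])
        y = np.array([1.0, 0.0, 2.0, 5.0, 9.0])
        r, p = sc.pearson_with_wald(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        assert r == pytest.approx((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
        assert 0 < p <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            sc.pearson_with_wald([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestOls:
    def test_exact_interpolation(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(size=50), rng.normal(size=50)
        y = 1.0 + 2.0 * x1 - 3.0 * x2
        X = np.column_stack([np.ones(50), x1, x2])
        fit = sc.ols_fit(X, y)
        np.testing.assert_allclose(fit.coefficients, [1.0, 2.0, -3.0], atol=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_null_simulation_r_squared_near_zero(self):
        rng = np.random.default_rng(1)
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)  # independent of X
        fit = sc.ols_fit(X, y)
        assert fit.r_squared < 0.01

    def test_nesting_never_lowers_r_squared(self):
        rng = np.random.default_rng(2)
        n = 60
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = x1 + rng.normal(size=n)
        small = sc.ols_fit(np.column_stack([np.ones(n), x1]), y)
        big = sc.ols_fit(np.column_stack([np.ones(n), x1, x2]), y)
        assert big.r_squared >= small.r_squared - 1e-12

    def test_rank_deficient_rejected(self):
        n = 20
        x = np.arange(n, dtype=float)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError):
            sc.ols_fit(X, x)


class TestPypyEboxModel:
    @staticmethod
    def _pairs(pypy, ebox, y):
        out = []
        for pp, eb, mf in zip(pypy, ebox, y):
            kmer = "A" * 5 + ("C" if eb else "T") + "AGCT" + ("G" if eb else "A") + "A" * 4
            rec = KmerRecord(
                allele_id="a", kmer=kmer, central_pos=8, central_base="G",
                subregion="FW1", agct_role="central_G", mut_freq=float(mf), n_total=10,
            )
            out.append((rec, ContextFeatures(int(pp), kmer[5], kmer[10], bool(eb))))
        return out

    def test_sign_recovery_on_constructed_data(self):
        rng = np.random.default_rng(3)
        n = 400
        pypy = rng.integers(0, 6, size=n)
        ebox = rng.integers(0, 2, size=n)
        y = np.clip(0.1 + 0.02 * pypy - 0.06 * ebox + rng.normal(0, 0.01, n), 0, 1)
        fit_pypy, fit_ebox, fit_both = sc.pypy_ebox_model(self._pairs(pypy, ebox, y))
        assert fit_pypy.pearson_r["pypy_count"] > 0
        assert fit_ebox.pearson_r["ebox"] < 0
        assert fit_both.coef("pypy_count") > 0 and fit_both.coef("ebox") < 0
        assert fit_both.r_squared >= max(fit_pypy.r_squared, fit_ebox.r_squared) - 1e-12

    def test_degenerate_feature_rejected(self):
        pairs = self._pairs([2, 2, 2, 2], [0, 1, 0, 1], [0.1, 0.05, 0.11, 0.04])
        with pytest.raises(ValueError):
            sc.pypy_ebox_model(pairs)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            sc.pypy_ebox_model(self._pairs([1, 2], [0, 1], [0.1, 0.2]))


class TestMannWhitney:
    def test_u_identity(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=8), rng.normal(size=11)
        u_xy, _ = sc.mann_whitney(x, y)
        u_yx, _ = sc.mann_whitney(y, x)
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))

    def test_fully_separated(self):
        u, p = sc.mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert u == 0.0
        assert p < 0.2  # most extreme configuration at n=3+3

    def test_exact_p_matches_permutation_enumeration(self):
        x = [1.2, 3.4, 0.5, 7.1, 2.2]
        y = [4.4, 6.0, 5.1, 8.3, 9.9]
        _, p = sc.mann_whitney(x, y)
        assert p == pytest.approx(permutation_mannwhitney_p(x, y), rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sc.mann_whitney([], [1.0])


class TestWelchT:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        t, p = sc.welch_t(x, x)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
        t1, _ = sc.welch_t(x, y)
        t2, _ = sc.welch_t(10 * x, 10 * y)
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_hand_formula_oracle(self):
        x = np.array([2.1, 3.5, 1.8, 4.2, 2.9])
        y = np.array([5.0, 6.1, 4.8, 5.5])
        t, p = sc.welch_t(x, y)
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        t_hand = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
        from scipy.stats import t as tdist

        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(2 * tdist.sf(abs(t_hand), df_hand), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sc.welch_t([1.0, 1.0], [1.0, 2.0])


class TestFisher:
    def test_balanced_table(self):
        odds, p = sc.fisher_exact(sc.ContingencyTable2x2(10, 10, 10, 10))
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_small_tables_match_enumeration(self):
        tables = [(3, 7, 9, 2), (1, 9, 8, 2), (5, 5, 5, 5), (0, 10, 10, 0), (2, 3, 4, 6)]
        for cells in tables:
            table = sc.ContingencyTable2x2(*cells)
            _, p = sc.fisher_exact(table)
            assert p == pytest.approx(hypergeom_fisher_p(table), rel=1e-8)

    def test_transpose_invariance(self):
        t1 = sc.ContingencyTable2x2(3, 7, 9, 2)
        t2 = sc.ContingencyTable2x2(3, 9, 7, 2)  # transpose
        assert sc.fisher_exact(t1)[1] == pytest.approx(sc.fisher_exact(t2)[1], rel=1e-9)

    def test_log_bound_dominates_enumerated_p(self):
        table = sc.ContingencyTable2x2(30, 5, 10, 20)
        p_exact = hypergeom_fisher_p(table)
        bound = sc.fisher_log10_p_bound(table)
        assert math.log10(p_exact) <= bound + 1e-9

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            sc.ContingencyTable2x2(-1, 0, 0, 0)


class TestClassifyFw1Motif:
    @pytest.mark.parametrize(
        "hexamer,expected",
        [
            ("CAGCTG", "G3G6"),
            ("CAACTG", "A3G6"),
            ("CAGCTA", "G3H6"),
            ("CAGCTC", "G3H6"),
            ("CAACTT", "A3H6"),
            ("CAGGTG", "other"),  # site 4 mutated
            ("TAGCTG", "other"),  # site 1 mutated
            ("CACCTG", "other"),  # site 3 neither G nor A
        ],
    )
    def test_categories(self, hexamer, expected):
        v = "AAAAAA" + hexamer + "AAA"
        assert sc.classify_fw1_motif(v) == expected

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            sc.classify_fw1_motif("AAAAAACAGCT")


class TestContingencyPipeline:
    def _make_clones(self, hexamers):
        return ["AAAAAA" + h + "AAA" for h in hexamers]

    def test_unmutated_repertoire(self):
        rep = Repertoire.from_strings("a", self._make_clones(["CAGCTG"] * 40))
        res = sc.contingency_pipeline(rep, fw1_start=1, seed=0)
        assert (res.table.n_G3G6, res.table.n_A3G6, res.table.n_G3H6, res.table.n_A3H6) == (40, 0, 0, 0)
        assert res.freq_g3_given_g6_unmut == 0.0
        assert math.isnan(res.freq_g3_given_g6_mut)

    def test_counts_and_other_exclusion(self):
        hexamers = ["CAGCTG"] * 5 + ["CAACTG"] * 3 + ["CAGCTA"] * 2 + ["CAACTC"] * 1 + ["CCGCTG"] * 4
        rep = Repertoire.from_strings("a", self._make_clones(hexamers))
        res = sc.contingency_pipeline(rep, fw1_start=1, seed=0)
        assert res.table.as_array().tolist() == [[5, 3], [2, 1]]
        assert res.n_other == 4
        assert res.freq_g3_given_g6_unmut == pytest.approx(3 / 8)
        assert res.freq_g3_given_g6_mut == pytest.approx(1 / 3)

    def test_group_selection_is_seeded(self):
        groups = [self._make_clones(["CAGCTG", "CAACTG"]) for _ in range(30)]
        r1 = sc.contingency_pipeline(groups, fw1_start=1, seed=9)
        r2 = sc.contingency_pipeline(groups, fw1_start=1, seed=9)
        assert r1.table == r2.table
        assert r1.table.total == 30  # one representative per clonal group

    def test_empty_usable_set_rejected(self):
        rep = Repertoire.from_strings("a", self._make_clones(["TTTTTT"] * 5))
        with pytest.raises(ValueError):
            sc.contingency_pipeline(rep, fw1_start=1, seed=0)
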