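"""Nonparametric battery: Kruskal-Wallis, Nemenyi, Mann-Whitney, runner."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from pexsplice.stats import (
    StatsError,
    compare_groups,
    five_number_summary,
    kruskal_wallis,
    mann_whitney_u,
    nemenyi_posthoc,
)


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        """Three separated triplets: mean ranks 2, 5, 8 give H = 7.2 by the
        hand computation 12/90 * (3*4 + 3*25 + 3*64) - 30."""
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert df == 2
        assert p == pytest.approx(0.02732, abs=1e-4)

    def test_identical_groups_degenerate(self):
        h, df, p = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert (h, p) == (0.0, 1.0)

    def test_tie_correction_matches_independent_formula(self):
        """Tied toy data against a from-scratch evaluation of the
        tie-corrected formula (separate code path from the implementation)."""
        groups = [[1, 1, 2], [1, 2, 2]]
        h, df, p = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        n = len(pooled)
        r1, r2 = ranks[:3], ranks[3:]
        h_raw = 12 / (n * (n + 1)) * (
            3 * r1.mean() ** 2 + 3 * r2.mean() ** 2
        ) - 3 * (n + 1)
        _, t = np.unique(pooled, return_counts=True)
        c = 1 - ((t**3 - t).sum()) / (n**3 - n)
        assert h == pytest.approx(h_raw / c, abs=1e-12)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            groups = [
                rng.integers(0, 8, size=rng.integers(4, 12)).astype(float)
                for _ in range(3)
            ]
            if all(np.all(g == groups[0][0]) for g in groups):
                continue
            h, _, p = kruskal_wallis(groups)
            h_sp, p_sp = sps.kruskal(*groups)
            assert h == pytest.approx(h_sp, rel=1e-12)
            assert p == pytest.approx(p_sp, rel=1e-9)

    def test_empty_group_errors(self):
        with pytest.raises(StatsError):
            kruskal_wallis([[1, 2], []])

    def test_reduces_to_squared_mwu_z_for_two_groups(self):
        """Without ties, the two-group KW statistic equals the square of the
        (uncorrected) Mann-Whitney normal deviate."""
        rng = np.random.default_rng(7)
        pool = rng.permutation(1000)[:27].astype(float)
        a, b = pool[:12], pool[12:]
        h, _, _ = kruskal_wallis([a, b])
        na, nb = len(a), len(b)
        ranks = sps.rankdata(np.concatenate([a, b]))
        u_a = ranks[:na].sum() - na * (na + 1) / 2
        z = (u_a - na * nb / 2) / math.sqrt(na * nb * (na + nb + 1) / 12)
        assert h == pytest.approx(z**2, rel=1e-10)


class TestNemenyi:
    GROUPS = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]

    def test_extreme_pair_has_smallest_p(self):
        p = nemenyi_posthoc(self.GROUPS)
        assert p[0, 2] < p[0, 1] and p[0, 2] < p[1, 2]

    def test_identical_pair_has_p_near_one(self):
        p = nemenyi_posthoc([[1.0, 2.0], [1.0, 2.0], [50.0, 60.0]])
        assert p[0, 1] > 0.99

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(5)
        p = nemenyi_posthoc([rng.normal(size=6) for _ in range(4)])
        assert np.allclose(p, p.T)
        assert np.allclose(np.diag(p), 1.0)

    def test_two_groups_redirects_to_mwu(self):
        with pytest.raises(StatsError, match="mann_whitney"):
            nemenyi_posthoc([[1, 2], [3, 4]])


class TestMannWhitney:
    def test_exact_enumeration_toy(self):
        """{1,2} vs {3,4}: U = 0 and the two-sided exact p is 2/6 = 1/3,
        from the six equally likely rank assignments."""
        u, p = mann_whitney_u([1, 2], [3, 4], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == 4.5  # n^2 / 2
        assert p == 1.0

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pool = rng.permutation(10_000)[:10].astype(float)
            a, b = pool[:5], pool[5:]
            u, p = mann_whitney_u(a, b, mode="exact")
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(res.pvalue, rel=1e-9)

    @pytest.mark.parametrize("n", [8, 10, 12])
    def test_approx_close_to_exact_without_ties(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            pool = rng.permutation(10_000)[: 2 * n].astype(float)
            a, b = pool[:n], pool[n:]
            _, p_exact = mann_whitney_u(a, b, mode="exact")
            _, p_approx = mann_whitney_u(a, b, mode="approx")
            assert abs(p_exact - p_approx) <= 0.02

    def test_five_vs_five_approx_error(self):
        rng = np.random.default_rng(55)
        pool = rng.permutation(999)[:10].astype(float)
        _, p_exact = mann_whitney_u(pool[:5], pool[5:], mode="exact")
        _, p_approx = mann_whitney_u(pool[:5], pool[5:], mode="approx")
        assert abs(p_exact - p_approx) <= 0.02

    def test_u_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=9)
        b = rng.normal(size=13)
        ranks = sps.rankdata(np.concatenate([a, b]))
        u_a = ranks[:9].sum() - 9 * 10 / 2
        u_b = ranks[9:].sum() - 13 * 14 / 2
        assert u_a + u_b == pytest.approx(9 * 13)
        u_min, _ = mann_whitney_u(a, b)
        assert u_min == pytest.approx(min(u_a, u_b))

    def test_exact_with_ties_rejected(self):
        with pytest.raises(StatsError, match="ties"):
            mann_whitney_u([1, 1], [1, 2], mode="exact")

    def test_rank_sum_conservation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            vals = rng.integers(0, 5, size=14).astype(float)
            ranks = sps.rankdata(vals)
            n = len(vals)
            assert ranks.sum() == pytest.approx(n * (n + 1) / 2)


class TestSummariesAndRunner:
    def test_five_number_summary_is_ordered(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(3, 30)))
            s = five_number_summary(x)
            assert list(s) == sorted(s)
            assert s[0] == x.min() and s[4] == x.max()

    def test_quartiles_use_linear_interpolation(self):
        s = five_number_summary([1, 2, 3, 4])
        assert s[1] == pytest.approx(1.75)
        assert s[2] == pytest.approx(2.5)
        assert s[3] == pytest.approx(3.25)

    def _table(self, rng, effect=0.0):
        rows = []
        for g, mu in (("CE", 0.0), ("splice_site", effect), ("SRE", effect)):
            for _ in range(15):
                rows.append(
                    {"group": g, "feat": rng.normal(mu, 1.0), "const": 1.0}
                )
        return pd.DataFrame(rows)

    def test_constant_feature_has_p_one_and_no_posthoc(self):
        rng = np.random.default_rng(6)
        res = compare_groups(self._table(rng))
        const = next(r for r in res if r.feature == "const")
        assert const.kw_p == 1.0
        assert const.nemenyi_p is None

    def test_planted_group_effect_is_flagged_with_direction(self):
        rng = np.random.default_rng(8)
        res = compare_groups(self._table(rng, effect=2.0))
        feat = next(r for r in res if r.feature == "feat")
        assert feat.kw_p < 0.05
        assert feat.nemenyi_p is not None
        assert feat.nemenyi_p.shape == (3, 3)
        assert feat.mwu_p < 0.05
        # direction: PE groups above CE
        assert (
            feat.group_summary["splice_site"][2] > feat.group_summary["CE"][2]
        )

    def test_missing_values_are_dropped_and_counted(self):
        rng = np.random.default_rng(9)
        t = self._table(rng)
        t.loc[t.index[:4], "feat"] = np.nan
        res = compare_groups(t)
        feat = next(r for r in res if r.feature == "feat")
        assert feat.n_missing == 4
        assert sum(feat.group_n.values()) == len(t) - 4
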