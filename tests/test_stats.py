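import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from fdgclamp.stats import (
    age_adjust,
    bh_fdr,
    compare_groups,
    correlate,
    voxelwise_group_map,
)


def brute_force_bh(p):
    """Independent BH step-up: sort, scale by m/i, enforce monotonicity."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestCompareGroups:
    def test_identical_groups(self):
        c = compare_groups([1, 2, 3, 1, 2, 3], list("AAABBB"), test="t")
        assert c.statistic == 0.0 and c.p_value == 1.0

    def test_pooled_t_matches_formula_oracle(self):
        a = np.array([12.1, 14.3, 11.8, 13.5, 12.9])
        b = np.array([10.2, 11.1, 9.8, 10.9])
        c = compare_groups(np.concatenate([a, b]),
                           ["A"] * 5 + ["B"] * 4, test="t")
        na, nb = len(a), len(b)
        sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
               / (na + nb - 2))
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p = 2 * sps.t.sf(abs(t), na + nb - 2)
        assert c.statistic == pytest.approx(t, abs=1e-10)
        assert c.p_value == pytest.approx(p, abs=1e-10)

    def test_wilcoxon_small_n_matches_permutation_enumeration(self):
        a = [3.1, 5.2, 6.4, 9.9]
        b = [1.2, 2.2, 4.0, 4.4]
        c = compare_groups(a + b, ["A"] * 4 + ["B"] * 4, test="wilcoxon")
        pooled = np.array(a + b)
        ranks = sps.rankdata(pooled)
        obs = ranks[:4].sum()
        n = len(pooled)
        dist = [sum(ranks[list(idx)])
                for idx in itertools.combinations(range(n), 4)]
        dist = np.array(dist)
        mean = dist.mean()
        p_exact = np.mean(np.abs(dist - mean) >= abs(obs - mean) - 1e-12)
        assert c.p_value == pytest.approx(p_exact, abs=1e-12)

    def test_chi2_matches_hand_formula(self):
        values = ["y"] * 8 + ["n"] * 2 + ["y"] * 3 + ["n"] * 7
        groups = ["A"] * 10 + ["B"] * 10
        c = compare_groups(values, groups, test="chi2")
        table = np.array([[2, 8], [7, 3]])  # categories sorted: n, y
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - exp) ** 2 / exp).sum()
        assert c.statistic == pytest.approx(chi2, abs=1e-10)

    def test_missing_values_excluded(self):
        c = compare_groups([1.0, 2.0, np.nan, 5.0, 6.0, 7.0],
                           list("AAABBB"), test="t")
        assert c.n_a == 2 and c.n_b == 3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, np.nan], ["A", "B"], test="t")

    def test_welch_differs_from_pooled_under_heteroscedasticity(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 5, 30)])
        groups = ["A"] * 10 + ["B"] * 30
        p_pooled = compare_groups(vals, groups, test="t").p_value
        p_welch = compare_groups(vals, groups, test="welch").p_value
        assert p_pooled != p_welch


class TestAgeAdjust:
    def test_equal_ages_identity(self):
        v = np.array([3.0, 5.0, 9.0])
        assert np.array_equal(age_adjust(v, [30, 30, 30]), v)

    def test_no_trend_identity(self):
        v = np.array([4.0, 4.0, 4.0, 4.0])
        assert np.allclose(age_adjust(v, [20, 25, 30, 35]), v)

    def test_pure_age_effect_collapses_to_constant(self):
        ages = np.array([20.0, 25.0, 30.0, 40.0])
        adj = age_adjust(2 * ages, ages)
        assert np.allclose(adj, 2 * ages.mean(), atol=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=50)
    def test_mean_preserving_and_idempotent(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 40))
        ages = r.uniform(18, 40, n)
        v = r.normal(50, 15, n) + 0.8 * ages
        adj = age_adjust(v, ages)
        assert adj.mean() == pytest.approx(v.mean(), rel=1e-9, abs=1e-9)
        assert np.allclose(age_adjust(adj, ages), adj, atol=1e-8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            age_adjust([1.0, 2.0], [30.0])


class TestCorrelate:
    def test_perfect_correlations(self):
        x = np.arange(5.0)
        assert correlate(x, x)[0].r == pytest.approx(1.0)
        assert correlate(x, -x)[0].r == pytest.approx(-1.0)

    def test_matches_formula_oracle(self, rng):
        x = rng.normal(0, 1, 10)
        y = 0.5 * x + rng.normal(0, 1, 10)
        res = correlate(x, y)[0]
        r = (np.sum((x - x.mean()) * (y - y.mean()))
             / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        t = r * np.sqrt(8 / (1 - r**2))
        p = 2 * sps.t.sf(abs(t), 8)
        assert res.r == pytest.approx(r, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_per_group_strata(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        groups = ["LR"] * 10 + ["HR"] * 10
        res = correlate(x, y, by_group=groups)
        assert [r.stratum for r in res] == ["overall", "HR", "LR"]
        assert res[1].n == 10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_spearman_option(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = correlate(x, np.exp(x), method="spearman")[0]
        assert res.r == pytest.approx(1.0)


class TestBHFDR:
    def test_textbook_vector(self):
        adj, _ = bh_fdr([0.01, 0.02, 0.03, 0.04])
        # p(i)*m/i = (.04, .04, .04, .04) after step-up monotonicity
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        adj, sig = bh_fdr([0.03])
        assert adj[0] == pytest.approx(0.03) and sig[0]

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=100)
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(0, 1, int(r.integers(1, 40)))
        adj, _ = bh_fdr(p)
        assert np.allclose(adj, brute_force_bh(p), atol=1e-12)
        assert np.all(adj >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestVoxelwise:
    def test_identical_noise_free_groups_empty_mask(self):
        maps = np.ones((3, 4, 4, 2))
        res = voxelwise_group_map(maps, maps.copy())
        assert res.mask.sum() == 0
        assert res.cluster_sizes == {}

    def test_planted_block_detected(self, rng):
        from fdgclamp.synthetic import simulate_voxel_maps

        block = (slice(2, 5), slice(2, 5), slice(1, 3))
        a, b = simulate_voxel_maps((8, 8, 4), 10, 10, rng,
                                   signal_block=block, effect_sd=2.0)
        res = voxelwise_group_map(a, b)
        truth = np.zeros((8, 8, 4), bool)
        truth[block] = True
        inter = (res.mask & truth).sum()
        union = (res.mask | truth).sum()
        assert inter / union > 0.5
        assert sum(res.cluster_sizes.values()) == res.mask.sum()

    def test_label_permutation_kills_signal(self, rng):
        from fdgclamp.synthetic import simulate_voxel_maps

        block = (slice(2, 5), slice(2, 5), slice(1, 3))
        a, b = simulate_voxel_maps((8, 8, 4), 10, 10, rng,
                                   signal_block=block, effect_sd=2.0)
        pooled = np.concatenate([a, b])
        counts = []
        for _ in range(25):
            perm = rng.permutation(20)
            res = voxelwise_group_map(pooled[perm[:10]], pooled[perm[10:]])
            counts.append(res.mask.sum())
        true_count = voxelwise_group_map(a, b).mask.sum()
        assert np.mean(counts) < true_count / 4

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            voxelwise_group_map(np.ones((3, 4, 4, 2)), np.ones((3, 4, 4, 3)))
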