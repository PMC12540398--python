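"""Paired t-maps, cluster permutation, NBS edge tests, and rm-ANOVA."""

import numpy as np
import pytest

from mwdecode.behavior import SizeError
from mwdecode.config import ConfigurationError
from mwdecode.stats import (
    cluster_permutation,
    nbs_edge_test,
    paired_t_map,
    rm_anova_2level,
)


def chain_adjacency(n):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


class TestPairedTMap:
    def test_equal_inputs_give_zero_map(self, rng):
        a = rng.normal(size=(5, 3, 4))
        tm = paired_t_map(a, a.copy())
        assert np.all(tm.t == 0.0)
        assert tm.df == 4

    def test_swap_negates(self, rng):
        a, b = rng.normal(size=(6, 3, 4)), rng.normal(size=(6, 3, 4))
        assert np.allclose(paired_t_map(a, b).t, -paired_t_map(b, a).t)

    def test_constant_difference_flagged_infinite(self):
        a = np.array([[[1.0]], [[2.0]], [[3.0]]])
        b = a - 1.0
        t = paired_t_map(a, b).t
        assert np.isinf(t[0, 0]) and t[0, 0] > 0


class TestClusterPermutation:
    def test_injected_patch_recovered(self, rng):
        adj = chain_adjacency(10)
        hits = 0
        n_runs = 15
        patch = {(c, f) for c in (2, 3) for f in range(1, 6)}
        for r in range(n_runs):
            a = rng.standard_normal((9, 10, 8))
            b = rng.standard_normal((9, 10, 8))
            a[:, 2:4, 1:6] += 3.0
            clusters = cluster_permutation(a, b, adj, n_perm=200, rng_seed=r)
            got = set()
            for c in clusters:
                if c.p < 0.025 and c.sign > 0:
                    got |= set(zip(c.channels.tolist(), c.features.tolist()))
            hits += patch <= got
        assert hits >= int(0.9 * n_runs)

    def test_strong_effect_reaches_minimum_p(self, rng):
        adj = chain_adjacency(6)
        a = rng.standard_normal((10, 6, 5)) + 5.0
        b = rng.standard_normal((10, 6, 5))
        clusters = cluster_permutation(a, b, adj, n_perm=200, rng_seed=0)
        assert clusters[0].p == pytest.approx(1.0 / 201.0)

    def test_members_connected_and_same_sign(self, rng):
        adj = chain_adjacency(8)
        a = rng.standard_normal((8, 8, 6))
        a[:, 1:3, 1:3] += 2.0
        b = rng.standard_normal((8, 8, 6))
        for c in cluster_permutation(a, b, adj, n_perm=50, rng_seed=1):
            assert c.channels.size == c.features.size > 0
            assert c.p >= 1.0 / 51.0

    def test_relabeling_participants_leaves_p_invariant(self, rng):
        adj = chain_adjacency(5)
        a = rng.standard_normal((7, 5, 4))
        b = rng.standard_normal((7, 5, 4))
        a[:, 1:3, :] += 1.5
        c1 = cluster_permutation(a, b, adj, n_perm=100, rng_seed=0)
        perm = rng.permutation(7)
        c2 = cluster_permutation(a[perm], b[perm], adj, n_perm=100, rng_seed=0)
        assert [round(c.p, 6) for c in c1] == [round(c.p, 6) for c in c2]

    def test_invalid_nperm_rejected(self, rng):
        a = rng.normal(size=(4, 3, 3))
        with pytest.raises(ConfigurationError):
            cluster_permutation(a, a, chain_adjacency(3), n_perm=0)


class TestNbsEdgeTest:
    def test_null_networks_mostly_yield_no_components(self, rng):
        zero = 0
        n_runs = 30
        for r in range(n_runs):
            a = rng.standard_normal((9, 10, 10))
            a = (a + a.transpose(0, 2, 1)) / 2
            b = rng.standard_normal((9, 10, 10))
            b = (b + b.transpose(0, 2, 1)) / 2
            comps = nbs_edge_test(a, b, edge_alpha=0.001, n_perm=30,
                                  rng_seed=r)
            zero += len(comps) == 0
        assert zero >= int(0.85 * n_runs)

    def test_injected_clique_recovered_as_single_component(self, rng):
        base = rng.standard_normal((12, 10, 10)) * 0.1
        base = (base + base.transpose(0, 2, 1)) / 2
        a = base.copy()
        for i in (1, 2, 3, 4):
            for j in (1, 2, 3, 4):
                if i < j:
                    a[:, i, j] += 1.0
                    a[:, j, i] += 1.0
        comps = nbs_edge_test(a, base, edge_alpha=0.001, n_perm=100,
                              rng_seed=0)
        sig = [c for c in comps if c.p < 0.05]
        assert len(sig) == 1
        assert sig[0].size == 6   # the 4-node clique has 6 edges
        assert sig[0].sign > 0

    def test_isolated_supra_edge_is_size_one(self, rng):
        base = rng.standard_normal((10, 6, 6)) * 0.05
        base = (base + base.transpose(0, 2, 1)) / 2
        a = base.copy()
        a[:, 0, 3] += 1.0
        a[:, 3, 0] += 1.0
        comps = nbs_edge_test(a, base, edge_alpha=0.001, n_perm=20, rng_seed=0)
        assert any(c.size == 1 and {0, 3} == set(c.edges[0]) for c in comps)


class TestRmAnova:
    def test_equal_levels_give_zero_f(self):
        f, df, p = rm_anova_2level(np.arange(5.0), np.arange(5.0))
        assert f == 0.0 and df == (1, 4) and p == 1.0

    def test_f_equals_squared_paired_t(self, rng):
        from scipy import stats as sps
        a, b = rng.normal(size=12), rng.normal(size=12)
        f, df, p = rm_anova_2level(a, b)
        t = sps.ttest_rel(a, b)
        assert f == pytest.approx(t.statistic ** 2)
        assert p == pytest.approx(t.pvalue)

    def test_textbook_pairs_cross_checked_against_pingouin(self):
        import pandas as pd
        import pingouin as pg
        a = np.array([10.0, 12.0, 14.0])
        b = np.array([11.0, 14.0, 16.0])
        f, df, p = rm_anova_2level(a, b)
        long = pd.DataFrame({
            "subject": list(range(3)) * 2,
            "cond": ["a"] * 3 + ["b"] * 3,
            "value": np.concatenate([a, b]),
        })
        ref = pg.rm_anova(data=long, dv="value", within="cond",
                          subject="subject")
        assert f == pytest.approx(float(ref["F"].iloc[0]))
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]))

    def test_single_pair_rejected(self):
        with pytest.raises(SizeError):
            rm_anova_2level(np.array([1.0]), np.array([2.0]))
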