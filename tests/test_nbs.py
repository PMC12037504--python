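"""Network-based statistic: edgewise tests, components, permutation p."""

import numpy as np
import pytest

from avhnet.connectivity import CorrMatrix
from avhnet.errors import PairingError
from avhnet.nbs import (EdgeStatMatrix, edgewise_stats, fisher_z,
                        nbs_permutation, primary_threshold,
                        supra_threshold_components)


def sample_corr_matrices(rng, n_subj, pop, t_len=100):
    """Sample correlation matrices of Gaussian draws from a population
    (eigenvalue-clipped to PSD first; fixtures here are hand-built)."""
    w, v = np.linalg.eigh(pop)
    pop = (v * np.clip(w, 1e-6, None)) @ v.T
    d = np.sqrt(np.diag(pop))
    pop = pop / np.outer(d, d)
    lchol = np.linalg.cholesky(pop + 1e-9 * np.eye(pop.shape[0]))
    out = []
    for _ in range(n_subj):
        ts = rng.standard_normal((t_len, pop.shape[0])) @ lchol.T
        out.append(CorrMatrix(values=np.corrcoef(ts, rowvar=False)))
    return out


def flat_population(n, r):
    pop = np.full((n, n), r)
    np.fill_diagonal(pop, 1.0)
    return pop


def shifted_population(n, r, edges, dz):
    pop = flat_population(n, r)
    for i, j in edges:
        v = np.tanh(np.arctanh(r) + dz)
        pop[i, j] = pop[j, i] = v
    return pop


class TestEdgewiseStats:
    def test_identical_groups_all_zero(self, rng):
        mats = sample_corr_matrices(rng, 5, flat_population(6, 0.2))
        st = edgewise_stats(mats, [CorrMatrix(values=m.values.copy())
                                   for m in mats], design="unpaired")
        np.testing.assert_allclose(st.t_values, 0.0, atol=1e-10)

    def test_matches_textbook_formula_on_toy(self, rng):
        a = sample_corr_matrices(rng, 4, flat_population(5, 0.1))
        b = sample_corr_matrices(rng, 5, flat_population(5, 0.1))
        st = edgewise_stats(a, b, design="unpaired")
        za = np.stack([fisher_z(m.values) for m in a])
        zb = np.stack([fisher_z(m.values) for m in b])
        i, j = 1, 3
        xa, xb = za[:, i, j], zb[:, i, j]
        sp2 = (3 * xa.var(ddof=1) + 4 * xb.var(ddof=1)) / 7
        t_oracle = (xa.mean() - xb.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 5))
        assert st.t_values[i, j] == pytest.approx(t_oracle, rel=1e-10)
        assert st.df == 7

    def test_planted_edge_carries_max_statistic(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = sample_corr_matrices(rng, 20, flat_population(8, 0.1), 150)
            b = sample_corr_matrices(
                rng, 20, shifted_population(8, 0.1, [(2, 5)], 0.3), 150)
            st = edgewise_stats(a, b, design="unpaired")
            t = np.abs(np.triu(st.t_values, 1))
            hits += np.unravel_index(np.argmax(t), t.shape) == (2, 5)
        assert hits >= 95

    def test_misaligned_pairs_rejected(self, rng):
        a = sample_corr_matrices(rng, 4, flat_population(5, 0.1))
        b = sample_corr_matrices(rng, 5, flat_population(5, 0.1))
        with pytest.raises(PairingError):
            edgewise_stats(a, b, design="paired")


class TestComponents:
    def _stats(self, n, entries):
        t = np.zeros((n, n))
        for (i, j), v in entries.items():
            t[i, j] = t[j, i] = v
        return EdgeStatMatrix(t_values=t, design="unpaired", df=20)

    def test_all_below_threshold_empty(self):
        st = self._stats(5, {(0, 1): 1.5, (2, 3): -1.2})
        assert supra_threshold_components(st, 2.0) == []

    def test_three_edge_path_is_one_component(self):
        st = self._stats(5, {(0, 1): 3.0, (1, 2): 2.5, (2, 3): 4.0})
        comps = supra_threshold_components(st, 2.0)
        assert len(comps) == 1
        assert comps[0].size == 3

    def test_direction_less_selects_negative_edges(self):
        st = self._stats(4, {(0, 1): 3.0, (2, 3): -3.0})
        comps = supra_threshold_components(st, 2.0, direction="less")
        assert len(comps) == 1 and comps[0].edges == [(2, 3)]

    def test_matches_union_find_oracle_on_random_maps(self, rng):
        for _ in range(20):
            t = rng.standard_normal((35, 35)) * 1.5
            t = np.triu(t, 1)
            t = t + t.T
            st = EdgeStatMatrix(t_values=t, design="unpaired", df=30)
            comps = supra_threshold_components(st, 2.0)
            # oracle: union-find over supra-threshold edges
            parent = list(range(35))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            sup = [(i, j) for i in range(35) for j in range(i + 1, 35)
                   if t[i, j] > 2.0]
            for i, j in sup:
                parent[find(i)] = find(j)
            from collections import Counter

            oracle_sizes = sorted(Counter(find(i) for i, _ in sup).values(),
                                  reverse=True)
            assert sorted([c.size for c in comps], reverse=True) == oracle_sizes


class TestPermutation:
    def test_p_floor_is_one_over_n_perm_plus_one(self):
        # overwhelming planted component at an unreachable-by-permutation
        # threshold: the add-one rule floors p at 1/(n_perm + 1)
        from avhnet.nbs import nbs_from_stacks

        rng = np.random.default_rng(0)
        n, n_edges = 10, 45
        web_cols = [0, 1, 2, 3, 4, 5]  # first upper-tri edges share node 0
        za = rng.normal(0, 0.01, (12, n_edges))
        zb = rng.normal(0, 0.01, (12, n_edges))
        za[:, web_cols] += 2.0
        res = nbs_from_stacks(za, zb, n, design="unpaired", t_thr=10.0,
                              n_perm=100, rng_seed=1, direction="greater")
        assert np.sum(res.null_max_sizes >= res.components[0].size) == 0
        assert res.components[0].p_perm == pytest.approx(1 / 101)

    def test_p_never_exactly_zero(self, rng):
        a = sample_corr_matrices(rng, 6, flat_population(8, 0.1))
        b = sample_corr_matrices(rng, 6, flat_population(8, 0.4))
        res = nbs_permutation(a, b, design="unpaired", n_perm=150, rng_seed=2)
        for c in res.components:
            assert c.p_perm > 0

    def test_planted_component_recovered(self):
        web = [(0, 1), (1, 2), (2, 3), (3, 4), (1, 5), (2, 6)]
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            a = sample_corr_matrices(rng, 20, flat_population(12, 0.1), 150)
            b = sample_corr_matrices(
                rng, 20, shifted_population(12, 0.1, web, 0.4), 150)
            res = nbs_permutation(b, a, design="unpaired", n_perm=500,
                                  rng_seed=seed, direction="greater")
            sig = {e for c in res.significant() for e in c.edges}
            hits += set(web) <= sig
        assert hits >= 18

    def test_doubling_permutations_stable_p(self, rng):
        a = sample_corr_matrices(rng, 10, flat_population(10, 0.1), 80)
        b = sample_corr_matrices(rng, 10, flat_population(10, 0.25), 80)
        p1 = nbs_permutation(b, a, n_perm=400, rng_seed=3).components
        p2 = nbs_permutation(b, a, n_perm=800, rng_seed=3).components
        if p1 and p2:
            p = p1[0].p_perm
            se = np.sqrt(p * (1 - p) / 400)
            assert abs(p1[0].p_perm - p2[0].p_perm) < 2 * se + 1e-9

    def test_paired_and_unpaired_agree_on_symmetric_null(self, rng):
        pop = flat_population(8, 0.15)
        a = sample_corr_matrices(rng, 10, pop, 120)
        b = sample_corr_matrices(rng, 10, pop, 120)
        rp = nbs_permutation(a, b, design="paired", n_perm=300, rng_seed=4)
        ru = nbs_permutation(a, b, design="unpaired", n_perm=300, rng_seed=4)
        # same exchangeable null: the max-component-size distributions match
        # in location to within a couple of edges
        assert abs(rp.null_max_sizes.mean() - ru.null_max_sizes.mean()) < 2.0

    def test_primary_threshold_matches_t_quantile(self):
        from scipy import stats as sps

        assert primary_threshold(30, 0.01) == pytest.approx(
            sps.t.ppf(0.995, 30))
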