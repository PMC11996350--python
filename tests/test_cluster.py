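"""Cluster permutation machinery against independent oracles.

Oracles used here: a set-based flood fill written independently of the
implementation's stack-based search, exhaustive sign-flip enumeration
via itertools, and MNE's cluster test for the observed cluster masses.
"""

import itertools

import numpy as np
import pytest
import scipy.stats

from hepkit.channels import standard_positions
from hepkit.cluster import (
    Adjacency,
    build_adjacency,
    find_clusters,
    one_sample_cluster_test,
    paired_cluster_test,
)


def chain_adjacency(n_ch):
    m = np.zeros((n_ch, n_ch), dtype=bool)
    for i in range(n_ch - 1):
        m[i, i + 1] = m[i + 1, i] = True
    return Adjacency([f"ch{i}" for i in range(n_ch)], m)


def oracle_clusters(t_map, threshold, adj_matrix):
    """Independent flood fill: grow sets until fixpoint."""
    n_ch, n_t = t_map.shape
    supra = {(c, t) for c in range(n_ch) for t in range(n_t)
             if abs(t_map[c, t]) > threshold}
    clusters = []
    while supra:
        seed = next(iter(supra))
        grown = {seed}
        while True:
            added = set()
            for (c, t) in grown:
                for (c2, t2) in supra - grown:
                    same_sign = np.sign(t_map[c2, t2]) == np.sign(t_map[c, t])
                    touch = (c2 == c and abs(t2 - t) == 1) or \
                            (t2 == t and adj_matrix[c, c2])
                    if same_sign and touch:
                        added.add((c2, t2))
            if not added:
                break
            grown |= added
        clusters.append(grown)
        supra -= grown
    return clusters


class TestAdjacency:
    def test_collinear_chain_topology(self):
        pos = {f"c{i}": np.array([i * 1.0, 0, 0]) for i in range(3)}
        adj = build_adjacency(pos, max_dist=1.5)
        assert adj.neighbors("c0") == {"c1"}
        assert adj.neighbors("c1") == {"c0", "c2"}

    def test_zero_threshold_warns_isolated(self):
        pos = {f"c{i}": np.array([i * 1.0, 0, 0]) for i in range(3)}
        with pytest.warns(UserWarning, match="no neighbors"):
            adj = build_adjacency(pos, max_dist=0.0)
        assert not adj.matrix.any()

    def test_standard_montage_f3_fz_neighbors(self):
        pos = {c: p for c, p in standard_positions().items() if c != "ECG"}
        adj = build_adjacency(pos)
        assert "Fz" in adj.neighbors("F3")
        mean_neighbors = adj.matrix.sum(axis=1).mean()
        assert 3.0 <= mean_neighbors <= 8.0

    def test_symmetry_enforced(self):
        with pytest.raises(ValueError):
            Adjacency(["a", "b"], np.array([[False, True], [False, False]]))


class TestFindClusters:
    def test_zero_map_has_no_clusters(self):
        adj = chain_adjacency(4)
        assert find_clusters(np.zeros((4, 6)), 2.0, adj) == []

    def test_neighboring_channels_merge(self):
        adj = chain_adjacency(3)
        t_map = np.zeros((3, 4))
        t_map[0, 2] = t_map[1, 2] = 3.0
        clusters = find_clusters(t_map, 2.0, adj)
        assert len(clusters) == 1
        assert clusters[0].size == 2
        assert clusters[0].sum_t == pytest.approx(6.0)

    def test_opposite_signs_do_not_merge(self):
        adj = chain_adjacency(2)
        t_map = np.array([[3.0, -3.0], [0.0, 0.0]])
        clusters = find_clusters(t_map, 2.0, adj)
        assert len(clusters) == 2

    def test_matches_flood_fill_oracle_on_islanded_map(self, rng):
        adj = chain_adjacency(4)
        t_map = np.zeros((4, 6))
        t_map[0:2, 0:2] = 4.0          # island 1
        t_map[3, 4:6] = 4.5            # island 2, separated by subthreshold gap
        t_map += rng.normal(0, 0.1, t_map.shape)
        mine = find_clusters(t_map, 2.5, adj)
        oracle = oracle_clusters(t_map, 2.5, adj.matrix)
        assert len(mine) == len(oracle) == 2
        mine_sets = sorted([frozenset(c.points) for c in mine], key=sorted)
        oracle_sets = sorted([frozenset(o) for o in oracle], key=sorted)
        assert mine_sets == oracle_sets

    def test_random_maps_match_oracle(self, rng):
        adj = chain_adjacency(5)
        for _ in range(10):
            t_map = rng.normal(0, 2, (5, 8))
            mine = {frozenset(c.points) for c in find_clusters(t_map, 2.0, adj)}
            oracle = {frozenset(o) for o in oracle_clusters(t_map, 2.0, adj.matrix)}
            assert mine == oracle


def exhaustive_oracle_p(maps, threshold, adj_matrix, observed_mass):
    """Brute-force two-tailed cluster p over all 2^n sign flips."""
    n = maps.shape[0]
    count = 0
    for signs in itertools.product([1.0, -1.0], repeat=n):
        flipped = maps * np.array(signs)[:, None, None]
        t = (flipped.mean(0)
             / (flipped.std(0, ddof=1) / np.sqrt(n) + 1e-300))
        clusters = oracle_clusters(t, threshold, adj_matrix)
        best = max((abs(t[tuple(zip(*c))].sum()) for c in clusters), default=0.0)
        if best >= abs(observed_mass) - 1e-9:
            count += 1
    return count / 2**n


@pytest.fixture(scope="module")
def planted_maps():
    rng = np.random.default_rng(5)
    maps = rng.normal(0, 1.0, (6, 3, 5))
    maps[:, 0:2, 2] -= 8.0 + rng.normal(0, 0.2, (6, 2))
    return maps


class TestOneSample:
    def test_exhaustive_mode_matches_enumeration_oracle(self, planted_maps):
        adj = chain_adjacency(3)
        res = one_sample_cluster_test(planted_maps, adj, n_perm="all")
        best = res.max_mass_cluster()
        oracle = exhaustive_oracle_p(planted_maps, res.threshold_t,
                                     adj.matrix, best.sum_t)
        assert best.p_value == pytest.approx(oracle, abs=1e-12)
        assert res.mode == "exhaustive"

    def test_montecarlo_converges_to_exhaustive(self, planted_maps):
        adj = chain_adjacency(3)
        res_ex = one_sample_cluster_test(planted_maps, adj, n_perm="all")
        p_ex = res_ex.max_mass_cluster().p_value
        res_mc = one_sample_cluster_test(planted_maps, adj, n_perm=2000, seed=9)
        p_mc = res_mc.max_mass_cluster().p_value
        se = np.sqrt(p_ex * (1 - p_ex) / 2000)
        assert abs(p_mc - p_ex) < 3 * se + 1.0 / 2000

    def test_all_zero_maps_give_empty_result(self):
        res = one_sample_cluster_test(np.zeros((5, 3, 4)), chain_adjacency(3),
                                      n_perm=50, seed=0)
        assert res.clusters == []

    def test_zero_variance_point_warns_not_crashes(self, rng):
        maps = rng.normal(size=(5, 2, 3))
        maps[:, 0, 0] = 4.2  # same value for everyone
        with pytest.warns(UserWarning, match="zero-variance"):
            res = one_sample_cluster_test(maps, chain_adjacency(2),
                                          n_perm=50, seed=0)
        assert np.isfinite(res.t_map).all()
        assert res.t_map[0, 0] == 0.0

    def test_fixed_seed_reproducible(self, planted_maps):
        adj = chain_adjacency(3)
        r1 = one_sample_cluster_test(planted_maps, adj, n_perm=500, seed=4)
        r2 = one_sample_cluster_test(planted_maps, adj, n_perm=500, seed=4)
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]

    def test_scale_invariance_of_p_values(self, planted_maps):
        adj = chain_adjacency(3)
        r1 = one_sample_cluster_test(planted_maps, adj, n_perm=400, seed=8)
        r2 = one_sample_cluster_test(3.7 * planted_maps, adj, n_perm=400, seed=8)
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]

    def test_channel_relabeling_invariance(self, planted_maps, rng):
        adj = chain_adjacency(3)
        perm = np.array([2, 0, 1])
        # relabel channels and permute adjacency consistently
        adj_p = Adjacency([adj.ch_names[i] for i in perm],
                          adj.matrix[np.ix_(perm, perm)])
        r1 = one_sample_cluster_test(planted_maps, adj, n_perm=300, seed=2)
        r2 = one_sample_cluster_test(planted_maps[:, perm], adj_p,
                                     n_perm=300, seed=2)
        assert sorted(round(c.sum_t, 9) for c in r1.clusters) == \
            sorted(round(c.sum_t, 9) for c in r2.clusters)
        assert sorted(c.p_value for c in r1.clusters) == \
            sorted(c.p_value for c in r2.clusters)

    def test_observed_masses_match_mne(self, planted_maps):
        """Cross-check t-map thresholding and clustering against MNE."""
        from mne.stats import permutation_cluster_1samp_test
        from scipy.sparse import csr_matrix

        adj = chain_adjacency(3)
        res = one_sample_cluster_test(planted_maps, adj, n_perm=100, seed=0)
        x = planted_maps.transpose(0, 2, 1)  # mne wants (n, time, space)
        t_obs, clusters, _, _ = permutation_cluster_1samp_test(
            x, threshold=res.threshold_t, n_permutations=50,
            adjacency=csr_matrix(adj.matrix), tail=0, out_type="mask",
            seed=1, verbose="error")
        mne_masses = sorted(round(float(t_obs[m].sum()), 6) for m in clusters)
        my_masses = sorted(round(c.sum_t, 6) for c in res.clusters)
        assert my_masses == mne_masses


class TestPaired:
    def test_constant_offset_yields_covering_positive_cluster(self, rng):
        low = rng.normal(0, 0.5, (6, 3, 5))
        high = low.copy()
        high[:, 0:2, 1:3] += 5.0 + rng.normal(0, 0.2, (6, 2, 2))
        res = paired_cluster_test(high, low, chain_adjacency(3),
                                  n_perm=200, seed=3)
        assert len(res.clusters) >= 1
        best = res.max_mass_cluster()
        assert best.sign == 1
        assert set(best.points) >= {(0, 1), (0, 2), (1, 1), (1, 2)}

    def test_identical_conditions_give_no_clusters(self, rng):
        x = rng.normal(size=(5, 3, 4))
        res = paired_cluster_test(x, x.copy(), chain_adjacency(3),
                                  n_perm=50, seed=0)
        assert res.clusters == []

    def test_equals_one_sample_on_differences(self, rng):
        high = rng.normal(size=(6, 3, 5))
        low = rng.normal(size=(6, 3, 5))
        adj = chain_adjacency(3)
        r_paired = paired_cluster_test(high, low, adj, n_perm=200, seed=6)
        r_one = one_sample_cluster_test(high - low, adj, n_perm=200, seed=6)
        np.testing.assert_array_equal(r_paired.t_map, r_one.t_map)
        assert [c.p_value for c in r_paired.clusters] == \
            [c.p_value for c in r_one.clusters]

    def test_mismatched_participants_rejected(self, rng):
        with pytest.raises(ValueError, match="aligned"):
            paired_cluster_test(rng.normal(size=(5, 3, 4)),
                                rng.normal(size=(6, 3, 4)),
                                chain_adjacency(3))
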