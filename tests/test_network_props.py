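"""Network statistics against hand computations and brute-force oracles."""

import numpy as np
import pytest

from edrnet.network_props import (
    average_binary_path_length,
    clique_counts,
    clustering_coefficient,
    compare_to_ensemble,
    compute_report,
    degree_spectra,
    efficiency_vs_density,
    extract_backbone,
    global_efficiency,
    link_lengths,
    local_efficiency,
    max_clique_summary,
    node_distances,
    reciprocity_counts,
    rmsd,
    triad_census,
)
from conftest import random_digraph, random_weighted_digraph
from oracles import (
    apl_oracle,
    clique_count_oracle,
    clustering_oracle,
    degree_oracle,
    enumerate_paths_oracle,
    global_efficiency_oracle,
    local_efficiency_oracle,
    reciprocity_oracle,
)


def complete_digraph(n):
    A = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(A, 0)
    return A


def cycle_digraph(n):
    A = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        A[i, (i + 1) % n] = 1
    return A


class TestBinaryProperties:
    def test_degree_spectra_complete(self):
        k_in, k_out = degree_spectra(complete_digraph(4))
        assert list(k_in) == [3, 3, 3, 3] and list(k_out) == [3, 3, 3, 3]

    def test_degree_spectra_cycle(self):
        k_in, k_out = degree_spectra(cycle_digraph(3))
        assert list(k_in) == [1, 1, 1] and list(k_out) == [1, 1, 1]

    def test_nonzero_diagonal_rejected(self):
        A = np.eye(3, dtype=int)
        with pytest.raises(ValueError):
            degree_spectra(A)

    def test_reciprocity_complete_and_cycle(self):
        assert reciprocity_counts(complete_digraph(3)) == (0, 3)
        assert reciprocity_counts(cycle_digraph(3)) == (3, 0)

    def test_apl_complete_is_one(self):
        assert average_binary_path_length(complete_digraph(5)).value == 1.0

    def test_apl_directed_cycle(self):
        assert average_binary_path_length(cycle_digraph(3)).value == pytest.approx(1.5)

    def test_clustering_complete_and_star(self):
        assert clustering_coefficient(complete_digraph(4)) == pytest.approx(1.0)
        star = np.zeros((5, 5), dtype=np.int8)
        star[0, 1:] = 1
        assert clustering_coefficient(star) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_graphs_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        A = random_digraph(rng, 7, p=0.45)
        k_in, k_out = degree_spectra(A)
        ok_in, ok_out = degree_oracle(A)
        assert list(k_in) == ok_in and list(k_out) == ok_out
        assert reciprocity_counts(A) == reciprocity_oracle(A)
        res = average_binary_path_length(A)
        o_apl, o_unreach = apl_oracle(A)
        assert res.value == pytest.approx(o_apl)
        assert res.n_unreachable == o_unreach
        assert clustering_coefficient(A) == pytest.approx(clustering_oracle(A))


class TestTriadCensus:
    def test_empty_graph_all_in_empty_class(self):
        c = triad_census(np.zeros((5, 5), dtype=np.int8))
        assert c[0] == 10 and c.sum() == 10

    def test_counts_sum_to_triples(self):
        rng = np.random.default_rng(3)
        A = random_digraph(rng, 10, 0.3)
        from math import comb

        assert triad_census(A).sum() == comb(10, 3)

    def test_fully_reciprocal_class_is_last(self):
        assert triad_census(complete_digraph(3))[-1] == 1

    def test_matches_igraph_cross_check(self):
        import igraph as ig

        rng = np.random.default_rng(7)
        A = random_digraph(rng, 12, 0.35)
        mine = triad_census(A)
        g = ig.Graph.Adjacency(A.tolist(), mode="directed")
        theirs = np.array(list(g.triad_census()))
        # igraph uses the Davis-Leinhardt order; compare order-free and anchors
        assert sorted(mine.tolist()) == sorted(theirs.tolist())
        assert mine.sum() == theirs.sum()
        assert mine[0] == theirs[0] and mine[-1] == theirs[-1]  # empty / 300


class TestCliques:
    def test_complete_digraph_choose(self):
        assert clique_counts(complete_digraph(5), [3])[3] == 10

    def test_no_reciprocal_links_no_cliques(self):
        assert clique_counts(cycle_digraph(5), [2, 3])[2] == 0

    def test_size_larger_than_n_is_zero(self):
        assert clique_counts(complete_digraph(3), [7])[7] == 0

    def test_clique2_equals_bidirectional_pairs(self):
        rng = np.random.default_rng(11)
        A = random_digraph(rng, 9, 0.5)
        assert clique_counts(A, [2])[2] == reciprocity_counts(A)[1]

    @pytest.mark.parametrize("seed", range(3))
    def test_random_graphs_match_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        A = random_digraph(rng, 9, 0.6)
        counts = clique_counts(A, [3, 4, 5])
        for s in (3, 4, 5):
            assert counts[s] == clique_count_oracle(A, s)

    def test_max_clique_summary(self):
        A = complete_digraph(4)
        s = max_clique_summary(A)
        assert s.size == 4 and s.count == 1 and s.members == frozenset(range(4))


class TestWeightedProperties:
    def test_link_length_values(self):
        w = np.array([[0.0, np.exp(-1.0)], [1.0, 0.0]])
        l = link_lengths(w)
        assert l[0, 1] == pytest.approx(1.0)
        assert l[1, 0] == 0.0
        assert np.isnan(l[0, 0])

    def test_link_length_additivity(self):
        w1, w2 = 0.3, 0.2
        assert -np.log(w1 * w2) == pytest.approx(-np.log(w1) - np.log(w2))

    def test_weight_above_one_rejected(self):
        with pytest.raises(ValueError):
            link_lengths(np.array([[0.0, 1.2], [0.1, 0.0]]))

    def test_two_node_distance(self):
        w = np.array([[0.0, 0.1], [0.1, 0.0]])
        r = node_distances(w)
        assert r[0, 1] == pytest.approx(-np.log(0.1))
        assert r[1, 0] == pytest.approx(-np.log(0.1))

    def test_stronger_indirect_path_wins(self):
        # direct w=0.01 vs two-hop 0.2*0.2=0.04: the indirect route is shorter
        w = np.zeros((3, 3))
        w[0, 2] = 0.01
        w[0, 1] = w[1, 2] = 0.2
        r = node_distances(w)
        assert r[0, 2] == pytest.approx(-np.log(0.04))

    @pytest.mark.parametrize("seed", range(4))
    def test_distances_match_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        w = random_weighted_digraph(rng, 6, 0.5)
        r = node_distances(w)
        for s in range(6):
            for t in range(6):
                if s == t:
                    continue
                assert r[s, t] == pytest.approx(enumerate_paths_oracle(w, s, t))

    def test_global_efficiency_two_nodes(self):
        w = np.array([[0.0, 0.1], [0.1, 0.0]])
        assert global_efficiency(w) == pytest.approx(1.0 / -np.log(0.1))

    def test_global_efficiency_empty_graph(self):
        assert global_efficiency(np.zeros((4, 4))) == 0.0

    def test_local_efficiency_reciprocal_triangle(self):
        w = np.full((3, 3), 0.1)
        np.fill_diagonal(w, 0.0)
        assert local_efficiency(w) == pytest.approx(1.0 / -np.log(0.1))

    def test_local_efficiency_star_is_zero(self):
        w = np.zeros((5, 5))
        w[0, 1:] = 0.3
        assert local_efficiency(w) == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_efficiencies_match_oracles(self, seed):
        rng = np.random.default_rng(300 + seed)
        w = random_weighted_digraph(rng, 7, 0.5)
        assert global_efficiency(w) == pytest.approx(global_efficiency_oracle(w))
        assert local_efficiency(w) == pytest.approx(local_efficiency_oracle(w))

    def test_weight_scaling_shifts_distances_by_hop_count(self):
        # fixed topology: scaling weights by c adds -ln(c) per hop
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 2] = w[2, 3] = 0.5
        c = 0.3
        r1, r2 = node_distances(w), node_distances(w * c)
        for t, hops in ((1, 1), (2, 2), (3, 3)):
            assert r2[0, t] - r1[0, t] == pytest.approx(hops * -np.log(c))

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        w = random_weighted_digraph(rng, 8, 0.5)
        perm = rng.permutation(8)
        wp = w[np.ix_(perm, perm)]
        assert global_efficiency(w) == pytest.approx(global_efficiency(wp))
        assert local_efficiency(w) == pytest.approx(local_efficiency(wp))


class TestEfficiencyVsDensity:
    def test_curve_starts_at_intact_values(self):
        rng = np.random.default_rng(5)
        w = random_weighted_digraph(rng, 8, 0.7)
        M0 = int((w > 0).sum())
        curve = efficiency_vs_density(w, "weakest_first", [M0 / (8 * 7)])
        assert curve["E_g"].iloc[0] == pytest.approx(global_efficiency(w))
        assert curve["E_l"].iloc[0] == pytest.approx(local_efficiency(w))

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            efficiency_vs_density(np.zeros((3, 3)), "alphabetical")


class TestBackbone:
    def test_reciprocal_cycle_at_own_density_returns_input(self):
        n = 4
        w = np.zeros((n, n))
        for i in range(n):
            w[i, (i + 1) % n] = w[(i + 1) % n, i] = 0.2
        kept = extract_backbone(w, "strong", (w > 0).sum() / (n * (n - 1)))
        assert np.array_equal(kept, w > 0)

    def test_reciprocal_cycle_reduces_to_directed_cycle(self):
        # pushing the target low leaves a one-directional cycle: the minimal
        # strongly connected remnant
        n = 4
        w = np.zeros((n, n))
        for i in range(n):
            w[i, (i + 1) % n] = w[(i + 1) % n, i] = 0.2 + 0.01 * i
        kept = extract_backbone(w, "strong", 0.01)
        assert n <= kept.sum() < (w > 0).sum()
        from edrnet.network_props import _is_connected

        assert _is_connected(kept, "strong")

    def test_weak_backbone_of_complete_reciprocal_triangle(self):
        w = np.full((3, 3), 0.3)
        np.fill_diagonal(w, 0.0)
        w[0, 1] = 0.9  # make removal order deterministic
        kept = extract_backbone(w, "weak", 2 / 6)
        assert kept.sum() == 2
        # weakly connected: union graph spans all three nodes
        und = kept | kept.T
        from oracles import bfs_hops

        assert len(bfs_hops(und.astype(int), 0)) == 3

    def test_disconnected_input_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        with pytest.raises(ValueError):
            extract_backbone(w, "strong", 0.1)

    @pytest.mark.parametrize("mode", ["strong", "weak"])
    def test_greedy_removal_matches_independent_replay(self, mode):
        # replay the greedy rule with an oracle connectivity check
        rng = np.random.default_rng(21)
        n = 8
        w = random_weighted_digraph(rng, n, 0.8)
        # ensure strong connectivity via a reciprocal ring
        for i in range(n):
            w[i, (i + 1) % n] = max(w[i, (i + 1) % n], 0.05)
            w[(i + 1) % n, i] = max(w[(i + 1) % n, i], 0.05)
        target = 0.25
        kept = extract_backbone(w, mode, target)

        def connected(mask):
            from oracles import bfs_hops

            g = mask.astype(int) if mode == "strong" else (mask | mask.T).astype(int)
            return all(len(bfs_hops(g, s)) == n for s in range(n)) if mode == "strong" else len(bfs_hops(g, 0)) == n

        i, j = np.nonzero(w)
        order = np.lexsort((j, i, w[i, j]))
        mask = w > 0
        cap = n * (n - 1)
        for a, b in zip(i[order], j[order]):
            if mask.sum() <= int(np.ceil(target * cap)):
                break
            mask[a, b] = False
            if not connected(mask):
                mask[a, b] = True
        assert np.array_equal(kept, mask)
        assert connected(kept)


class TestRmsd:
    def test_identical_is_zero(self):
        assert rmsd([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_value(self):
        assert rmsd([0, 0], [3, 4]) == pytest.approx(np.sqrt(25 / 2))

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert rmsd(x, y) == pytest.approx(float(np.sqrt(np.mean((x - y) ** 2))))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd([1, 2], [1, 2, 3])


class TestCompareToEnsemble:
    def test_single_lambda_grid_argmin_is_that_lambda(self):
        rng = np.random.default_rng(4)
        w = random_weighted_digraph(rng, 10, 0.5)
        w2 = random_weighted_digraph(rng, 10, 0.5)
        rep = compute_report(w)
        curve = compare_to_ensemble(rep, {25.0: [compute_report(w2)]},
                                    ("degree_spectra", "log10_weights"))
        assert curve["lambda"].iloc[curve["pooled"].idxmin()] == 25.0

    def test_identical_data_and_model_gives_zero_rmsd(self):
        rng = np.random.default_rng(6)
        w = random_weighted_digraph(rng, 10, 0.5)
        rep = compute_report(w)
        curve = compare_to_ensemble(rep, {33.0: [compute_report(w)]},
                                    ("degree_spectra", "node_distances", "triad_census"))
        for p in ("degree_spectra", "node_distances", "triad_census"):
            assert curve[p].iloc[0] == 0.0
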