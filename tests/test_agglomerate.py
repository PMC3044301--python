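import copy
import itertools
import math

import numpy as np
import pytest

from hacnet import (
    ClusterState,
    PairCounts,
    assign_clusters,
    candidate_pairs,
    collapse_score,
    merge_score_bayes,
    merge_score_ml,
    run_hac,
    tree_model_scores,
)

from conftest import make_network, random_graph, random_merged_state, two_cliques


def star(n_leaves):
    return make_network([("c", f"x{i}") for i in range(n_leaves)])


class TestMergeScoreML:
    def test_identical_neighborhoods_score_zero(self):
        # u, v adjacent to the same two outside vertices
        net = make_network([("u", "w1"), ("v", "w1"), ("u", "w2"), ("v", "w2")])
        state = ClusterState(net)
        ids = {min(m): c for c, m in state.members.items()}
        assert merge_score_ml(state, ids["u"], ids["v"]) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_mismatches_cost_quarter_each(self, m):
        """Each outside vertex adjacent to exactly one of u, v contributes
        ln(1/4) at the singleton stage."""
        edges = [("u", f"w{i}") for i in range(m)]
        edges += [("u", "s"), ("v", "s")]  # one shared neighbor keeps v non-isolated
        net = make_network(edges)
        state = ClusterState(net)
        ids = {min(mem): c for c, mem in state.members.items()}
        got = merge_score_ml(state, ids["u"], ids["v"])
        assert got == pytest.approx(m * math.log(1 / 4), abs=1e-12)

    def test_errors_on_dead_or_equal_clusters(self, triangle):
        state = ClusterState(triangle)
        with pytest.raises(ValueError):
            merge_score_ml(state, 0, 0)
        state.merge(0, 1)
        with pytest.raises(ValueError):
            merge_score_ml(state, 0, 2)


class TestMergeScoreBayes:
    def test_two_vertex_graph_empty_sum(self):
        net = make_network([("u", "v")])
        state = ClusterState(net)
        assert merge_score_bayes(state, 0, 1) == 0.0

    def test_shared_single_neighbor_beta_arithmetic(self):
        # u, v each adjacent only to w: Beta(3,1) / Beta(2,1)^2 = 4/3
        net = make_network([("u", "w"), ("v", "w")])
        state = ClusterState(net)
        ids = {min(m): c for c, m in state.members.items()}
        got = merge_score_bayes(state, ids["u"], ids["v"])
        assert got == pytest.approx(math.log(4 / 3), abs=1e-12)


class TestMergeScoreOracle:
    """Any merge's score equals the full-model score difference computed by
    the independent tree-score path."""

    @pytest.mark.parametrize("seed", range(30))
    def test_full_model_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        net = random_graph(6, float(rng.uniform(0.2, 0.7)), rng)
        state, dend = random_merged_state(net, int(rng.integers(0, 4)), rng)
        before_l, before_p = tree_model_scores(dend, net)
        ids = sorted(state.members)
        for i, j in itertools.combinations(ids, 2):
            sml = merge_score_ml(state, i, j)
            sb = merge_score_bayes(state, i, j)
            st2, d2 = copy.deepcopy(state), copy.deepcopy(dend)
            t = st2.size(i) * st2.size(j)
            counts = (PairCounts.from_totals(st2.cross_count(0, i, j), t),)
            r, _ = st2.merge(i, j)
            d2.add_merge(r, i, j, counts, False, 99, 0.0, 0.0, None)
            after_l, after_p = tree_model_scores(d2, net)
            assert sml == pytest.approx(after_l - before_l, abs=1e-9)
            assert sb == pytest.approx(after_p - before_p, abs=1e-9)
            assert sml <= 1e-12  # removing parameters never helps ML


class TestCollapseScore:
    def test_singletons_always_collapse(self):
        for edge in (True, False):
            net = make_network([("u", "v")]) if edge else make_network([], "uv")
            state = ClusterState(net)
            assert collapse_score(state, 0, 1) == pytest.approx(0.0, abs=1e-15)

    def test_two_3cliques_into_6clique(self):
        net = make_network(
            list(itertools.combinations("abc", 2))
            + list(itertools.combinations("xyz", 2))
            + [(u, v) for u in "abc" for v in "xyz"]
        )
        state = ClusterState(net, partition=[set("abc"), set("xyz")])
        assert collapse_score(state, 0, 1) == pytest.approx(math.log(10), abs=1e-9)

    def test_disconnected_4cliques_stay_structured(self):
        net = two_cliques(4, bridge=False)
        state = ClusterState(
            net, partition=[{f"a{i}" for i in range(4)}, {f"b{i}" for i in range(4)}]
        )
        assert collapse_score(state, 0, 1) < 0

    def test_uncollapsed_child_rejected(self, triangle):
        state = ClusterState(triangle)
        with pytest.raises(ValueError):
            collapse_score(state, 0, 1, collapsed={0: True, 1: False})


class TestCandidatePairs:
    def test_path_graph_candidates(self, path4):
        state = ClusterState(path4)
        ids = {min(m): c for c, m in state.members.items()}
        got = candidate_pairs(state)
        expect = {
            tuple(sorted((ids[u], ids[v])))
            for u, v in [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c"), ("b", "d")]
        }
        assert got == expect  # (a,d) excluded: no edge, no shared neighbor

    def test_disjoint_triangles_no_cross_candidates(self):
        net = make_network(
            [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        )
        state = ClusterState(net)
        left = {c for c, m in state.members.items() if min(m) in "abc"}
        for i, j in candidate_pairs(state):
            assert (i in left) == (j in left)

    def test_star_leaves_all_candidates(self):
        state = ClusterState(star(3))
        assert len(candidate_pairs(state)) == 6  # 3 spokes + 3 leaf pairs


class TestRunHac:
    def test_six_clique_single_collapsed_cluster(self):
        net = make_network(list(itertools.combinations("abcdef", 2)))
        result = run_hac(net)
        assert len(result.top_level_clusters) == 1
        assert result.bottom_level_clusters == [frozenset("abcdef")]

    def test_two_bridged_5cliques(self):
        result = run_hac(two_cliques(5))
        tops = sorted(map(sorted, result.top_level_clusters))
        assert tops == [
            ["a0", "a1", "a2", "a3", "a4"],
            ["b0", "b1", "b2", "b3", "b4"],
        ]
        assert sorted(map(sorted, result.bottom_level_clusters)) == tops

    def test_disconnected_input_yields_forest(self):
        net = make_network(
            [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        )
        result = run_hac(net)
        assert len(result.dendrogram.roots) == 2
        assert len(result.top_level_clusters) == 2

    def test_empty_network_is_an_error(self):
        from hacnet import Network

        with pytest.raises(ValueError):
            run_hac(Network())

    def test_telescoping_sum(self):
        """Sum of accepted log lambda^ML equals the final guide-tree log L
        (collapse off; the initial all-singleton score is zero)."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            net = random_graph(10, 0.35, rng)
            result = run_hac(net, collapse=False)
            total = sum(rec.log_ml for rec in result.merge_sequence)
            final_l, _ = tree_model_scores(result.dendrogram, net, audit=True)
            assert total == pytest.approx(final_l, abs=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(21)
        net = random_graph(9, 0.4, rng)
        mapping = {f"v{i}": f"u{i}" for i in range(9)}  # order-preserving
        relabeled = make_network(
            [(mapping[u], mapping[v]) for u, v in net.edges],
            vertices=[mapping[v] for v in net.vertices],
        )
        a = run_hac(net)
        b = run_hac(relabeled)
        remap = lambda parts: sorted(
            sorted(mapping[v] for v in part) for part in parts
        )
        assert remap(a.top_level_clusters) == sorted(map(sorted, b.top_level_clusters))
        assert remap(a.bottom_level_clusters) == sorted(
            map(sorted, b.bottom_level_clusters)
        )

    def test_bottom_refines_top_and_covers_vertices(self):
        rng = np.random.default_rng(2)
        net = random_graph(14, 0.3, rng)
        result = run_hac(net)
        seen = set()
        for mem in result.bottom_level_clusters:
            assert not (seen & mem)
            seen |= mem
        assert seen == net.vertices
        top_of = {}
        for tid, mem in enumerate(result.top_level_clusters):
            for v in mem:
                top_of[v] = tid
        for mem in result.bottom_level_clusters:
            assert len({top_of[v] for v in mem}) == 1

    def test_terminal_density_bimodal_on_mixed_graph(self):
        """Collapsed terminals include both perfect cliques (density 1) and
        shared-neighbor groups (density 0)."""
        # two 4-cliques plus two non-adjacent vertices hanging off both cliques
        edges = list(itertools.combinations(["a0", "a1", "a2", "a3"], 2))
        edges += list(itertools.combinations(["b0", "b1", "b2", "b3"], 2))
        edges += [(p, q) for p in ("p", "q") for q in ("a0", "a1", "b0", "b1")]
        result = run_hac(make_network(edges))
        densities = set()
        for node in result.dendrogram.terminals():
            if node.size >= 2:
                c = node.counts[0]
                densities.add(c.e / c.t)
        assert 1.0 in densities
        assert 0.0 in densities

    def test_max_merges_cap(self):
        net = two_cliques(4)
        result = run_hac(net, max_merges=2, stop_criterion="none")
        assert len(result.merge_sequence) == 2

    def test_audit_mode_passes(self):
        rng = np.random.default_rng(17)
        net = random_graph(12, 0.3, rng)
        run_hac(net, audit=True)


class TestAssignClusters:
    def test_ids_deterministic_and_refining(self):
        result = run_hac(two_cliques(4, bridge=False))
        assignment = assign_clusters(result)
        assert set(assignment) == {f"{s}{i}" for s in "ab" for i in range(4)}
        # ordered by smallest member: a-clique first
        assert assignment["a0"] == (0, 0)
        assert assignment["b0"] == (1, 1)

    def test_singleton_network(self):
        net = make_network([("a", "b")])
        assignment = assign_clusters(run_hac(net))
        assert assignment == {"a": (0, 0), "b": (0, 0)}
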