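import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hacnet import (
    ClusterState,
    PairCounts,
    flat_model_scores,
    log_bayes_bernoulli,
    log_ml_bernoulli,
    tree_model_scores,
)

from conftest import (
    brute_force_tree_scores,
    make_network,
    random_graph,
    random_merged_state,
    two_cliques,
)


class TestKernels:
    @pytest.mark.parametrize(
        "e,h,expected",
        [
            (2, 1, math.log(4 / 27)),
            (0, 5, 0.0),
            (1, 1, math.log(1 / 4)),
            (0, 0, 0.0),
        ],
    )
    def test_log_ml(self, e, h, expected):
        assert log_ml_bernoulli(PairCounts(e, h)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "e,h,expected",
        [
            (0, 0, 0.0),
            (1, 1, math.log(1 / 6)),
            (3, 0, math.log(1 / 4)),
        ],
    )
    def test_log_bayes(self, e, h, expected):
        assert log_bayes_bernoulli(PairCounts(e, h)) == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            PairCounts(-1, 2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 200), st.integers(0, 200))
    def test_ml_dominates_any_fixed_rate(self, e, h):
        """The MLE plug-in likelihood bounds every fixed-rate likelihood."""
        c = PairCounts(e, h)
        ml = log_ml_bernoulli(c)
        for theta in np.linspace(0.01, 0.99, 25):
            fixed = e * math.log(theta) + h * math.log(1 - theta)
            assert ml >= fixed - 1e-9


class TestClusterState:
    def test_partition_validation(self, triangle):
        with pytest.raises(ValueError):
            ClusterState(triangle, partition=[{"a"}, {"b"}])  # c missing
        with pytest.raises(ValueError):
            ClusterState(triangle, partition=[{"a", "b"}, {"b", "c"}])

    def test_counts_and_merge(self):
        net = two_cliques(3)  # a-clique, b-clique, bridge a0-b0
        state = ClusterState(net, partition=[{"a0", "a1", "a2"}, {"b0", "b1", "b2"}])
        assert state.pair_counts(0, 0, 0) == PairCounts(3, 0)
        assert state.pair_counts(0, 0, 1) == PairCounts(1, 8)
        r, _ = state.merge(0, 1)
        assert state.K == 1
        assert state.pair_counts(0, r, r) == PairCounts(7, 8)
        state.recount_audit()

    def test_incremental_counts_match_recount(self):
        rng = np.random.default_rng(5)
        net = random_graph(12, 0.4, rng)
        state, _ = random_merged_state(net, 7, rng)
        state.recount_audit()  # raises on any drift


class TestFlatModel:
    def test_single_group_path(self):
        net = make_network([("a", "b"), ("b", "c")])
        state = ClusterState(net, partition=[{"a", "b", "c"}])
        log_l, _ = flat_model_scores(state, net)
        assert log_l == pytest.approx(math.log(4 / 27))

    def test_saturated_singletons(self):
        net = make_network([("a", "b"), ("b", "c")])
        log_l, _ = flat_model_scores(ClusterState(net), net)
        assert log_l == pytest.approx(0.0, abs=1e-12)

    def test_against_per_pair_bernoulli_oracle(self):
        """Flat log L equals the product over the 10 vertex pairs of the
        governing block's MLE Bernoulli factor."""
        rng = np.random.default_rng(11)
        net = random_graph(5, 0.5, rng)
        partition = [{"v0", "v3"}, {"v1"}, {"v2", "v4"}]
        state = ClusterState(net, partition=partition)
        log_l, _ = flat_model_scores(state, net)
        block_of = {v: i for i, part in enumerate(partition) for v in part}
        counts: dict = {}
        for u, v in itertools.combinations(sorted(net.vertices), 2):
            key = tuple(sorted((block_of[u], block_of[v])))
            e, t = counts.get(key, (0, 0))
            counts[key] = (e + net.has_edge(u, v), t + 1)
        expected = 0.0
        for u, v in itertools.combinations(sorted(net.vertices), 2):
            e, t = counts[tuple(sorted((block_of[u], block_of[v])))]
            theta = e / t
            expected += math.log(theta if net.has_edge(u, v) else 1 - theta)
        assert log_l == pytest.approx(expected, abs=1e-9)


class TestTreeModel:
    def test_empty_graph_any_tree_is_certain(self):
        rng = np.random.default_rng(0)
        net = random_graph(6, 0.0, rng)
        _, dend = random_merged_state(net, 5, rng)
        log_l, _ = tree_model_scores(dend, net)
        assert log_l == pytest.approx(0.0, abs=1e-12)

    def test_two_perfect_collapsed_cliques(self):
        from hacnet import run_hac

        net = two_cliques(3, bridge=False)
        result = run_hac(net)
        log_l, _ = tree_model_scores(result.dendrogram, net)
        assert log_l == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_lca_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        net = random_graph(8, 0.4, rng)
        _, dend = random_merged_state(net, int(rng.integers(0, 7)), rng)
        got = tree_model_scores(dend, net, audit=True)
        want = brute_force_tree_scores(dend, net)
        assert got[0] == pytest.approx(want[0], abs=1e-9)
        assert got[1] == pytest.approx(want[1], abs=1e-9)

    def test_audit_detects_corrupt_counts(self):
        rng = np.random.default_rng(3)
        net = random_graph(6, 0.5, rng)
        _, dend = random_merged_state(net, 3, rng)
        internal = [n for n in dend.iter_reachable() if not n.is_terminal]
        node = internal[0]
        node.counts = (PairCounts(node.counts[0].e + 1, max(node.counts[0].h - 1, 0)),)
        with pytest.raises(AssertionError):
            tree_model_scores(dend, net, audit=True)


class TestModelInvariants:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_terms_partition_all_pairs(self, seed):
        """Sum of block totals t over all model terms = C(V, 2)."""
        rng = np.random.default_rng(seed)
        net = random_graph(9, 0.3, rng)
        _, dend = random_merged_state(net, int(rng.integers(0, 8)), rng)
        total = 0
        roots = sorted(dend.roots)
        for a, r1 in enumerate(roots):
            for r2 in roots[a + 1:]:
                total += len(dend.nodes[r1].members) * len(dend.nodes[r2].members)
        for node in dend.iter_reachable():
            if node.is_terminal:
                total += node.size * (node.size - 1) // 2
            else:
                total += len(dend.nodes[node.left].members) * len(
                    dend.nodes[node.right].members
                )
        n = net.num_vertices
        assert total == n * (n - 1) // 2

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        net = random_graph(7, 0.4, rng)
        mapping = {f"v{i}": f"w{(i * 3) % 7}" for i in range(7)}
        relabeled = make_network(
            [(mapping[u], mapping[v]) for u, v in net.edges],
            vertices=[mapping[v] for v in net.vertices],
        )
        parts = [{"v0", "v1", "v5"}, {"v2"}, {"v3", "v4", "v6"}]
        a = flat_model_scores(ClusterState(net, partition=parts))
        b = flat_model_scores(
            ClusterState(relabeled, partition=[{mapping[v] for v in p} for p in parts])
        )
        assert a == pytest.approx(b)

    def test_finer_partition_never_hurts_ml(self):
        rng = np.random.default_rng(9)
        net = random_graph(8, 0.4, rng)
        fine = [{f"v{i}"} for i in range(8)]
        mid = [{"v0", "v1"}, {"v2", "v3"}, {"v4", "v5"}, {"v6", "v7"}]
        coarse = [{"v0", "v1", "v2", "v3"}, {"v4", "v5", "v6", "v7"}]
        scores = [
            flat_model_scores(ClusterState(net, partition=p))[0]
            for p in (fine, mid, coarse)
        ]
        assert scores[0] >= scores[1] - 1e-9 >= scores[2] - 2e-9
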