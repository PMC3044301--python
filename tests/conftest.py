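"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from hacnet import ClusterState, Dendrogram, Network, PairCounts


def make_network(edges, vertices=()):
    net = Network(vertices=vertices)
    for u, v in edges:
        net.add_vertex(u)
        net.add_vertex(v)
        net.add_edge(u, v)
    return net


def clique(ids):
    return list(itertools.combinations(ids, 2))


def two_cliques(n, bridge=True):
    """Two n-cliques, optionally joined by a single bridging edge."""
    a = [f"a{i}" for i in range(n)]
    b = [f"b{i}" for i in range(n)]
    edges = clique(a) + clique(b)
    if bridge:
        edges.append((a[0], b[0]))
    return make_network(edges)


@pytest.fixture
def triangle():
    return make_network([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path4():
    return make_network([("a", "b"), ("b", "c"), ("c", "d")])


def random_graph(n, p, rng):
    verts = [f"v{i}" for i in range(n)]
    net = Network(vertices=verts)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(verts[i], verts[j])
    return net


def random_merged_state(net, n_merges, rng):
    """Random partial agglomeration: (ClusterState, Dendrogram), no collapse."""
    state = ClusterState(net)
    dend = Dendrogram(1)
    for cid, mem in state.members.items():
        (v,) = mem
        dend.add_leaf(cid, v)
    for step in range(n_merges):
        ids = sorted(state.members)
        if len(ids) < 2:
            break
        i, j = (int(x) for x in rng.choice(ids, size=2, replace=False))
        t = state.size(i) * state.size(j)
        counts = (PairCounts.from_totals(state.cross_count(0, i, j), t),)
        r, _ = state.merge(i, j)
        dend.add_merge(r, i, j, counts, False, step + 1, 0.0, 0.0, None)
    return state, dend


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def governing_term(dend, leaf_of, u, v):
    """Which model block governs the pair (u, v): found by walking leaf-to-
    root paths, independently of the engine's count bookkeeping."""
    parent = {}
    for node in dend.iter_reachable():
        if node.left is not None:
            parent[node.left] = node.id
            parent[node.right] = node.id
    terminal_of = {}
    root_of = {}
    for node in dend.iter_reachable():
        if node.is_terminal:
            for w in node.members:
                terminal_of[w] = node.id
    for node in dend.iter_reachable():
        nid = node.id
        top = nid
        while top in parent:
            top = parent[top]
        root_of[nid] = top
    tu, tv = terminal_of[u], terminal_of[v]
    if tu == tv:
        return ("terminal", tu)
    ru, rv = root_of[tu], root_of[tv]
    if ru != rv:
        return ("rootpair", tuple(sorted((ru, rv))))
    path = {}
    nid, d = tu, 0
    while True:
        path[nid] = d
        if nid not in parent:
            break
        nid, d = parent[nid], d + 1
    nid = tv
    while nid not in path:
        nid = parent[nid]
    return ("node", nid)


def brute_force_tree_scores(dend, net):
    """(log L, log P) by assigning every vertex pair to its governing block
    via explicit LCA search, then summing per-block Bernoulli/Beta terms."""
    verts = sorted(net.vertices)
    leaf_of = None
    groups: dict = {}
    for u, v in itertools.combinations(verts, 2):
        key = governing_term(dend, leaf_of, u, v)
        e, t = groups.get(key, (0, 0))
        groups[key] = (e + (1 if net.has_edge(u, v) else 0), t + 1)
    log_l = 0.0
    log_p = 0.0
    for e, t in groups.values():
        h = t - e
        if e:
            log_l += e * math.log(e / t)
        if h:
            log_l += h * math.log(h / t)
        log_p += math.lgamma(e + 1) + math.lgamma(h + 1) - math.lgamma(t + 2)
    return log_l, log_p


def ari_of(parts, labels):
    from sklearn.metrics import adjusted_rand_score

    verts = sorted(labels)
    pred = {}
    for cid, mem in enumerate(sorted(parts, key=min)):
        for v in mem:
            pred[v] = cid
    return adjusted_rand_score([labels[v] for v in verts], [pred[v] for v in verts])
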