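"""Bernoulli stochastic block-model likelihoods, flat and hierarchical.

Every group pair (i, j) contributes ``t_ij = n_i * n_j`` Bernoulli trials
(``n_i * (n_i - 1) / 2`` within a group), of which ``e_ij`` succeeded (edges)
and ``h_ij = t_ij - e_ij`` failed (holes).  Two scores are used throughout:

* maximum likelihood, with the edge probability of each block set to its
  MLE ``e/t``:  ``log L = e ln(e/t) + h ln(h/t)`` (with ``0 ln 0 = 0``);
* fully Bayesian, with the block parameter integrated out under a uniform
  prior: ``log P = ln Beta(e + 1, h + 1)``.

All computation is in log space via log-gamma; pair counts can reach ~1e7
for genome-scale networks, so factorials and raw products are never formed.

A hierarchical model is a forest (``Dendrogram``) whose nodes each govern
one block of vertex pairs: branching nodes govern the pairs crossing their
left and right subtrees, collapsed terminals govern the pairs within their
member set, and pairs split across two roots are governed by a flat block
over the root pair.  These blocks partition the set of vertex pairs, so the
model score is a sum of per-block terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log
from typing import Iterator, Sequence

__all__ = [
    "PairCounts",
    "log_ml_bernoulli",
    "log_bayes_bernoulli",
    "ClusterState",
    "TreeNode",
    "Dendrogram",
    "flat_model_scores",
    "tree_model_scores",
]


# ---------------------------------------------------------------------------
# scalar likelihood kernels
# ---------------------------------------------------------------------------


def _log_ml(e: int, t: int) -> float:
    """e ln(e/t) + h ln(h/t) with the 0^0 = 1 convention; 0 when t == 0."""
    if t == 0:
        return 0.0
    h = t - e
    out = 0.0
    if e:
        out += e * log(e / t)
    if h:
        out += h * log(h / t)
    return out


def _log_bayes(e: int, h: int) -> float:
    """ln Beta(e + 1, h + 1) via log-gamma; 0 when e = h = 0."""
    if e == 0 and h == 0:
        return 0.0
    return lgamma(e + 1) + lgamma(h + 1) - lgamma(e + h + 2)


@dataclass(frozen=True)
class PairCounts:
    """Edge/hole counts for one block of vertex pairs (the likelihood unit)."""

    e: int
    h: int

    def __post_init__(self) -> None:
        if self.e < 0 or self.h < 0:
            raise ValueError(f"negative counts: e={self.e}, h={self.h}")

    @property
    def t(self) -> int:
        return self.e + self.h

    @classmethod
    def from_totals(cls, e: int, t: int) -> "PairCounts":
        return cls(e, t - e)


def log_ml_bernoulli(c: PairCounts) -> float:
    """Log maximum-likelihood of a block: each pair a Bernoulli at rate e/t."""
    return _log_ml(c.e, c.t)


def log_bayes_bernoulli(c: PairCounts) -> float:
    """Log marginal probability of a block with its rate integrated out."""
    return _log_bayes(c.e, c.h)


# ---------------------------------------------------------------------------
# cluster state: the current top-level partition with sparse counts
# ---------------------------------------------------------------------------


def _pairkey(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


class ClusterState:
    """Top-level clusters of one or more network layers, with block counts.

    Maintains, per layer, the sparse between-cluster edge counts (absent key
    means zero), the within-cluster edge counts, and per-cluster degree sums
    (for modularity scores).  Merges update counts incrementally; a full
    recount audit is available for tests.
    """

    def __init__(self, networks, partition: Sequence[set[str]] | None = None) -> None:
        layers = getattr(networks, "layers", None)
        if layers is None:
            layers = networks if isinstance(networks, (list, tuple)) else [networks]
        self.networks = list(layers)
        vset = self.networks[0].vertices
        for lay in self.networks[1:]:
            if lay.vertices != vset:
                raise ValueError(
                    "all layers must share one vertex set (run intersect_layers)"
                )
        if not vset:
            raise ValueError("empty network")
        if partition is None:
            partition = [{v} for v in sorted(vset)]
        covered: set[str] = set()
        for part in partition:
            if covered & set(part):
                raise ValueError("partition groups overlap")
            covered |= set(part)
        if covered != vset:
            raise ValueError("partition does not cover the vertex set")

        self.n_layers = len(self.networks)
        self.members: dict[int, set[str]] = {}
        self.min_member: dict[int, str] = {}
        self.version: dict[int, int] = {}
        self.cluster_of: dict[str, int] = {}
        for cid, part in enumerate(partition):
            part = set(part)
            self.members[cid] = part
            self.min_member[cid] = min(part)
            self.version[cid] = 0
            for v in part:
                self.cluster_of[v] = cid
        self._next_id = len(self.members)

        self.cross: list[dict[tuple[int, int], int]] = [dict() for _ in self.networks]
        self.within: list[dict[int, int]] = [
            {cid: 0 for cid in self.members} for _ in self.networks
        ]
        self.nbrs: list[dict[int, set[int]]] = [
            {cid: set() for cid in self.members} for _ in self.networks
        ]
        self.deg_sum: list[dict[int, int]] = [
            {cid: 0 for cid in self.members} for _ in self.networks
        ]
        self.total_edges: list[int] = []
        for li, net in enumerate(self.networks):
            cross, within, nbrs, dsum = (
                self.cross[li], self.within[li], self.nbrs[li], self.deg_sum[li],
            )
            for u, v in net.iter_edges():
                cu, cv = self.cluster_of[u], self.cluster_of[v]
                if cu == cv:
                    within[cu] += 1
                else:
                    key = _pairkey(cu, cv)
                    cross[key] = cross.get(key, 0) + 1
                    nbrs[cu].add(cv)
                    nbrs[cv].add(cu)
            for v in net.vertices:
                dsum[self.cluster_of[v]] += net.degree(v)
            self.total_edges.append(net.num_edges)

    # -- queries ------------------------------------------------------------

    @property
    def K(self) -> int:
        return len(self.members)

    @property
    def n_vertices(self) -> int:
        return len(self.cluster_of)

    def alive(self, cid: int) -> bool:
        return cid in self.members

    def size(self, cid: int) -> int:
        return len(self.members[cid])

    def cross_count(self, layer: int, i: int, j: int) -> int:
        return self.cross[layer].get(_pairkey(i, j), 0)

    def pair_counts(self, layer: int, i: int, j: int) -> PairCounts:
        """Block counts for a cluster pair, or within a cluster when i == j."""
        if i == j:
            n = self.size(i)
            t = n * (n - 1) // 2
            return PairCounts.from_totals(self.within[layer][i], t)
        t = self.size(i) * self.size(j)
        return PairCounts.from_totals(self.cross_count(layer, i, j), t)

    def all_neighbors(self, cid: int) -> set[int]:
        out: set[int] = set()
        for layer_nbrs in self.nbrs:
            out |= layer_nbrs[cid]
        return out

    def snapshot(self) -> list[frozenset[str]]:
        return [frozenset(m) for m in self.members.values()]

    # -- merging ------------------------------------------------------------

    def merge(self, i: int, j: int) -> tuple[int, set[int]]:
        """Merge clusters i and j into a fresh cluster; return (id, touched).

        ``touched`` lists surviving clusters whose count tables changed;
        their version stamps (and those of the merged pair) are bumped so
        priority-queue entries referencing them become stale.
        """
        if i == j or not self.alive(i) or not self.alive(j):
            raise ValueError(f"cannot merge clusters {i}, {j}")
        r = self._next_id
        self._next_id += 1
        mem = self.members.pop(i) | self.members.pop(j)
        self.members[r] = mem
        self.min_member[r] = min(self.min_member.pop(i), self.min_member.pop(j))
        for v in mem:
            self.cluster_of[v] = r
        touched: set[int] = set()
        for li in range(self.n_layers):
            cross, within, nbrs = self.cross[li], self.within[li], self.nbrs[li]
            e_ij = cross.pop(_pairkey(i, j), 0)
            within[r] = within.pop(i) + within.pop(j) + e_ij
            new_nbrs: set[int] = set()
            for old in (i, j):
                for k in nbrs.pop(old):
                    if k in (i, j):
                        continue
                    e = cross.pop(_pairkey(old, k), 0)
                    if e:
                        key = _pairkey(r, k)
                        cross[key] = cross.get(key, 0) + e
                        new_nbrs.add(k)
                        nbrs[k].discard(old)
            for k in new_nbrs:
                nbrs[k].add(r)
            nbrs[r] = new_nbrs
            touched |= new_nbrs
            dsum = self.deg_sum[li]
            dsum[r] = dsum.pop(i) + dsum.pop(j)
        del self.version[i], self.version[j]
        self.version[r] = 0
        for k in touched:
            self.version[k] += 1
        return r, touched

    # -- audit --------------------------------------------------------------

    def recount_audit(self) -> None:
        """Recount all block statistics from the networks; raise on mismatch."""
        fresh = ClusterState(
            self.networks if self.n_layers > 1 else self.networks[0],
            partition=list(self.members.values()),
        )
        remap = {min(m): cid for cid, m in self.members.items()}
        for li in range(self.n_layers):
            for cid, mem in fresh.members.items():
                mine = remap[min(mem)]
                if fresh.within[li][cid] != self.within[li][mine]:
                    raise AssertionError(
                        f"within-count mismatch for cluster {mine} layer {li}"
                    )
            got = {
                tuple(sorted((remap[min(fresh.members[a])], remap[min(fresh.members[b])]))): e
                for (a, b), e in fresh.cross[li].items()
            }
            mine_cross = {k: e for k, e in self.cross[li].items() if e}
            if got != mine_cross:
                raise AssertionError(f"cross-count mismatch in layer {li}")


# ---------------------------------------------------------------------------
# dendrogram
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """One merge node of the forest.

    ``counts`` holds, per layer, the left-right crossing counts for branching
    nodes, or the within-group counts for collapsed terminals.  Singleton
    leaves are collapsed with empty counts.
    """

    id: int
    left: int | None
    right: int | None
    members: frozenset[str]
    counts: tuple[PairCounts, ...]
    collapsed: bool
    step: int | None = None
    log_ml: float | None = None
    log_bayes: float | None = None
    log_collapse: float | None = None

    @property
    def is_terminal(self) -> bool:
        return self.left is None

    @property
    def size(self) -> int:
        return len(self.members)


class Dendrogram:
    """Forest of merge nodes over string vertex ids."""

    def __init__(self, n_layers: int = 1) -> None:
        self.n_layers = n_layers
        self.nodes: dict[int, TreeNode] = {}
        self.roots: set[int] = set()

    def add_leaf(self, nid: int, vertex: str) -> TreeNode:
        node = TreeNode(
            id=nid,
            left=None,
            right=None,
            members=frozenset([vertex]),
            counts=tuple(PairCounts(0, 0) for _ in range(self.n_layers)),
            collapsed=True,
        )
        self.nodes[nid] = node
        self.roots.add(nid)
        return node

    def add_merge(
        self,
        nid: int,
        left: int,
        right: int,
        counts: tuple[PairCounts, ...],
        collapsed: bool,
        step: int,
        log_ml: float,
        log_bayes: float,
        log_collapse: float | None,
    ) -> TreeNode:
        members = self.nodes[left].members | self.nodes[right].members
        node = TreeNode(
            id=nid,
            left=None if collapsed else left,
            right=None if collapsed else right,
            members=members,
            counts=counts,
            collapsed=collapsed,
            step=step,
            log_ml=log_ml,
            log_bayes=log_bayes,
            log_collapse=log_collapse,
        )
        self.nodes[nid] = node
        self.roots.discard(left)
        self.roots.discard(right)
        self.roots.add(nid)
        return node

    def iter_reachable(self) -> Iterator[TreeNode]:
        """Nodes reachable from the roots (collapse discards subtrees)."""
        stack = sorted(self.roots)
        while stack:
            node = self.nodes[stack.pop()]
            yield node
            if node.left is not None:
                stack.append(node.left)
                stack.append(node.right)

    def terminals(self) -> list[TreeNode]:
        """Collapsed terminals and leaves: the bottom-level clusters."""
        return [n for n in self.iter_reachable() if n.is_terminal]

    @property
    def num_nodes(self) -> int:
        return sum(1 for _ in self.iter_reachable())

    def num_parameters(self) -> int:
        """Total model parameters: K(K-1)/2 top-level blocks plus one per node."""
        k = len(self.roots)
        return k * (k - 1) // 2 + self.num_nodes

    def parent_map(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for node in self.iter_reachable():
            if node.left is not None:
                out[node.left] = node.id
                out[node.right] = node.id
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dendrogram):
            return NotImplemented
        mine = {n.id: n for n in self.iter_reachable()}
        theirs = {n.id: n for n in other.iter_reachable()}
        return (
            self.n_layers == other.n_layers
            and self.roots == other.roots
            and mine == theirs
        )


# ---------------------------------------------------------------------------
# model scores
# ---------------------------------------------------------------------------


def flat_model_scores(state: ClusterState, net=None) -> tuple[float, float]:
    """(log L, log P) of the flat block model for the current partition.

    Sums one Bernoulli block per cluster pair plus one per within-cluster
    block.  ``net`` (or a MultiNetwork) may be passed to assert that the
    state is a partition of its vertices.
    """
    if net is not None:
        vset = getattr(net, "vertices", None)
        if vset is not None and set(state.cluster_of) != set(vset):
            raise ValueError("state is not a partition of the network's vertices")
    ids = sorted(state.members)
    log_l = 0.0
    log_p = 0.0
    for li in range(state.n_layers):
        for a, i in enumerate(ids):
            for j in ids[a:]:
                c = state.pair_counts(li, i, j)
                log_l += _log_ml(c.e, c.t)
                log_p += _log_bayes(c.e, c.h)
    return log_l, log_p


def _count_between(net, left: frozenset[str], right: frozenset[str]) -> int:
    if len(left) > len(right):
        left, right = right, left
    return sum(len(net.neighbors(u) & right) for u in left)


def _count_within(net, members: frozenset[str]) -> int:
    return sum(len(net.neighbors(u) & members) for u in members) // 2


def tree_model_scores(dend: Dendrogram, networks, audit: bool = False) -> tuple[float, float]:
    """(log L, log P) of a hierarchical model, recomputed from the network.

    Terms: one block per root pair (edges crossing between top-level groups),
    one block per branching node (edges crossing its children), and one block
    per collapsed terminal (edges within its member set).  With ``audit``,
    recomputed counts are checked against those stored on the nodes.
    """
    layers = getattr(networks, "layers", None)
    nets = list(layers) if layers is not None else [networks]
    if len(nets) != dend.n_layers:
        raise ValueError("layer count mismatch between dendrogram and networks")
    all_members: set[str] = set()
    for rid in dend.roots:
        mem = dend.nodes[rid].members
        if all_members & mem:
            raise ValueError("dendrogram roots overlap")
        all_members |= mem
    if all_members != nets[0].vertices:
        raise ValueError("dendrogram members do not partition the network vertices")

    log_l = 0.0
    log_p = 0.0
    roots = sorted(dend.roots)
    for a, r1 in enumerate(roots):
        m1 = dend.nodes[r1].members
        for r2 in roots[a + 1:]:
            m2 = dend.nodes[r2].members
            t = len(m1) * len(m2)
            for net in nets:
                e = _count_between(net, m1, m2)
                log_l += _log_ml(e, t)
                log_p += _log_bayes(e, t - e)
    for node in dend.iter_reachable():
        if node.is_terminal:
            n = node.size
            t = n * (n - 1) // 2
            counter = _count_within
            args = (node.members,)
        else:
            lm = dend.nodes[node.left].members
            rm = dend.nodes[node.right].members
            t = len(lm) * len(rm)
            counter = _count_between
            args = (lm, rm)
        for li, net in enumerate(nets):
            e = counter(net, *args)
            if audit and node.counts[li] != PairCounts.from_totals(e, t):
                raise AssertionError(
                    f"stored counts for node {node.id} layer {li} "
                    f"({node.counts[li]}) disagree with recount e={e}, t={t}"
                )
            log_l += _log_ml(e, t)
            log_p += _log_bayes(e, t - e)
    return log_l, log_p
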