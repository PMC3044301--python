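"""The greedy agglomerative engine.

Starting from singleton clusters, the engine repeatedly merges the pair of
top-level clusters with the best score under the active method:

* ``ml``     — maximum-likelihood ratio lambda^ML of the hierarchical block
               model before/after the merge (sums over layers);
* ``bayes``  — the fully Bayesian counterpart lambda^B (alias ``bayes-stop``);
* ``e`` / ``es`` / ``q`` — heuristic densities / modularity increments.

Candidate pairs are restricted to clusters joined by an edge or sharing at
least one neighboring cluster; a max-priority queue with per-cluster version
stamps realizes lazy evaluation (stale entries are rescored and reinserted,
never acted on).

Bayesian model selection runs alongside the merge loop: lambda^C decides
whether a merge of two collapsed clusters is itself collapsed into a
homogeneous terminal, and the stopping evidence (lambda^B together with the
flat merged-versus-separate term) gates which merges are structurally
justified.  When no justified merge remains, the gate closes; deferred
merges then complete the guide tree (so link prediction can use densities
at every tree level), and the reported top-level partition is read off the
finished tree by Bayesian top-down descent.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from math import log as _ln

from .blockmodel import (
    ClusterState,
    Dendrogram,
    PairCounts,
    _log_bayes,
    _log_ml,
    _pairkey,
)
from .scores import delta_q, rho_e, rho_s

log = logging.getLogger("hacnet")
_LN2 = _ln(2.0)

__all__ = [
    "MergeRecord",
    "HacResult",
    "merge_score_ml",
    "merge_score_bayes",
    "collapse_score",
    "stop_score",
    "candidate_pairs",
    "bayesian_tree_cut",
    "run_hac",
    "assign_clusters",
]

METHODS = ("ml", "bayes", "bayes-stop", "e", "es", "q")


# ---------------------------------------------------------------------------
# merge scores
# ---------------------------------------------------------------------------


def merge_score_ml(state: ClusterState, i: int, j: int) -> float:
    """log lambda^ML for merging top-level clusters i and j (always <= 0).

    Sum over every other cluster k of the ML block term for the pooled
    counts minus the separate terms; the (i, j) crossing block itself is
    identical before (top-level term) and after (new internal node) the
    merge and cancels.  Blocks with no edges to either cluster contribute
    exactly zero, so only clusters adjacent to i or j are visited.  Layers
    are summed (model scores are additive over edge types).
    """
    if not (state.alive(i) and state.alive(j)) or i == j:
        raise ValueError(f"clusters {i}, {j} are not distinct top-level clusters")
    n_i, n_j = state.size(i), state.size(j)
    total = 0.0
    for li in range(state.n_layers):
        cross = state.cross[li]
        nbrs = (state.nbrs[li][i] | state.nbrs[li][j]) - {i, j}
        for k in nbrs:
            n_k = state.size(k)
            e_ik = cross.get(_pairkey(i, k), 0)
            e_jk = cross.get(_pairkey(j, k), 0)
            t_ik, t_jk = n_i * n_k, n_j * n_k
            total += (
                _log_ml(e_ik + e_jk, t_ik + t_jk)
                - _log_ml(e_ik, t_ik)
                - _log_ml(e_jk, t_jk)
            )
    return total


def merge_score_bayes(state: ClusterState, i: int, j: int) -> float:
    """log lambda^B: the fully Bayesian merge ratio for clusters i and j.

    Same structure as :func:`merge_score_ml` with the marginal (Beta) block
    term in place of the ML term.  Unlike the ML case, all-hole blocks do
    not vanish, so the sum runs over every other top-level cluster.  No
    merge-multiplicity factor is applied.
    """
    if not (state.alive(i) and state.alive(j)) or i == j:
        raise ValueError(f"clusters {i}, {j} are not distinct top-level clusters")
    n_i, n_j = state.size(i), state.size(j)
    total = 0.0
    for li in range(state.n_layers):
        cross = state.cross[li]
        for k in state.members:
            if k == i or k == j:
                continue
            n_k = state.size(k)
            e_ik = cross.get(_pairkey(i, k), 0)
            e_jk = cross.get(_pairkey(j, k), 0)
            h_ik = n_i * n_k - e_ik
            h_jk = n_j * n_k - e_jk
            total += (
                _log_bayes(e_ik + e_jk, h_ik + h_jk)
                - _log_bayes(e_ik, h_ik)
                - _log_bayes(e_jk, h_jk)
            )
    return total


def collapse_score(
    state: ClusterState, i: int, j: int, collapsed: dict[int, bool] | None = None
) -> float:
    """log lambda^C: flat merged group versus the two-group structure.

    Compares one Bernoulli block over all pairs within the merged cluster
    against the three-block model (within i, within j, between).  Both
    children must already be collapsed (singletons count as collapsed);
    a merge of two singletons always gives lambda^C = 1.  No split-
    multiplicity factor is applied.  Layers are summed.
    """
    if collapsed is not None and not (collapsed.get(i, False) and collapsed.get(j, False)):
        raise ValueError(f"collapse score requires both clusters collapsed: {i}, {j}")
    n_i, n_j = state.size(i), state.size(j)
    t_ii = n_i * (n_i - 1) // 2
    t_jj = n_j * (n_j - 1) // 2
    t_ij = n_i * n_j
    total = 0.0
    for li in range(state.n_layers):
        e_ii = state.within[li][i]
        e_jj = state.within[li][j]
        e_ij = state.cross_count(li, i, j)
        e_w = e_ii + e_jj + e_ij
        h_w = (t_ii - e_ii) + (t_jj - e_jj) + (t_ij - e_ij)
        total += (
            _log_bayes(e_w, h_w)
            - _log_bayes(e_ii, t_ii - e_ii)
            - _log_bayes(e_jj, t_jj - e_jj)
            - _log_bayes(e_ij, t_ij - e_ij)
        )
    return total


# ---------------------------------------------------------------------------
# candidates
# ---------------------------------------------------------------------------


def candidate_pairs(state: ClusterState) -> set[tuple[int, int]]:
    """All mergeable cluster pairs: directly connected or sharing a neighbor."""
    out: set[tuple[int, int]] = set()
    for li in range(state.n_layers):
        out.update(state.cross[li].keys())
        for k, nb in state.nbrs[li].items():
            ordered = sorted(nb)
            for a, x in enumerate(ordered):
                for y in ordered[a + 1:]:
                    out.add((x, y))
    return out


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class MergeRecord:
    """Log entry for one accepted merge.

    ``log_stop`` is the Bayesian stopping evidence (:func:`stop_score`)
    evaluated just before the merge; ``log_collapse`` is recorded only when
    both children were collapsed, and ``collapsed`` says whether the merge
    was actually collapsed into a terminal.
    """

    step: int
    pair: tuple[int, int]
    merged_id: int
    score: float
    log_ml: float
    log_bayes: float
    log_stop: float
    log_collapse: float | None
    collapsed: bool


@dataclass
class HacResult:
    """Outcome of one agglomerative run.

    ``top_level_clusters`` is the partition reported by the Bayesian stopping
    rule; ``bottom_level_clusters`` are the collapsed terminals, which refine
    it.  ``root_cross`` stores, per root pair, the per-layer crossing edge
    counts of the final forest (used as top-level block densities in link
    prediction).
    """

    dendrogram: Dendrogram
    merge_sequence: list[MergeRecord]
    top_level_clusters: list[frozenset[str]]
    bottom_level_clusters: list[frozenset[str]]
    networks: list
    method: str
    root_cross: dict[tuple[int, int], list[int]]
    leaf_of: dict[str, int]
    log_l: float | None = None
    log_p: float | None = None

    def partition_at(self, step: int) -> list[frozenset[str]]:
        """Top-level partition after the first ``step`` accepted merges."""
        groups: dict[int, frozenset[str]] = {
            nid: self.dendrogram.nodes[nid].members
            for nid in self.leaf_of.values()
        }
        for rec in self.merge_sequence[:step]:
            i, j = rec.pair
            groups[rec.merged_id] = groups.pop(i) | groups.pop(j)
        return list(groups.values())


def assign_clusters(result: HacResult) -> dict[str, tuple[int, int]]:
    """Map each vertex to deterministic (top, bottom) cluster ids.

    Ids are assigned by sorting clusters on their smallest member vertex;
    bottom-level ids refine top-level ids.
    """
    tops = sorted(result.top_level_clusters, key=min)
    bottoms = sorted(result.bottom_level_clusters, key=min)
    top_of: dict[str, int] = {}
    for tid, mem in enumerate(tops):
        for v in mem:
            top_of[v] = tid
    out: dict[str, tuple[int, int]] = {}
    for bid, mem in enumerate(bottoms):
        for v in mem:
            out[v] = (top_of[v], bid)
    return out


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


def _scorer(method: str):
    if method == "ml":
        return merge_score_ml
    if method in ("bayes", "bayes-stop"):
        return merge_score_bayes
    if method == "e":
        return lambda s, i, j: sum(rho_e(s, i, j, li) for li in range(s.n_layers))
    if method == "es":
        return lambda s, i, j: sum(
            rho_e(s, i, j, li) + rho_s(s, i, j, li) for li in range(s.n_layers)
        )
    if method == "q":
        return lambda s, i, j: sum(delta_q(s, i, j, li) for li in range(s.n_layers))
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def stop_score(state: ClusterState, i: int, j: int) -> float:
    """Bayesian merge evidence used by the top-level stopping criterion.

    The ratio compares "i and j belong to one top-level cluster" against
    "i and j are separate top-level clusters": the pooled-connection terms
    of :func:`merge_score_bayes` times the flat merged-group-versus-
    two-groups term of :func:`collapse_score`.  Without the latter the
    ratio is blind to the density contrast between the two clusters
    themselves (that block cancels between the top-level term and the new
    internal node), and exchangeable groups would always be pooled.
    """
    return merge_score_bayes(state, i, j) + collapse_score(state, i, j)


def bayesian_tree_cut(dend: Dendrogram, networks) -> list[frozenset[str]]:
    """Top-level clusters by Bayesian top-down descent of the guide tree.

    Starting from the forest roots, clusters are split into their two
    children while splitting improves the Bayesian model: the gain of a
    split is minus the merge evidence (:func:`stop_score`) for re-joining
    the children, conditioned on the rest of the current partition.
    Evaluating the evidence against the coarse complementary structure
    (rather than against whatever fine clusters existed when the merge was
    accepted) keeps sampling noise in fine blocks from over-resolving the
    top level.

    Because the guide tree places each split point exactly where the
    agglomeration found the strongest contrast, a naive post-hoc Bayes
    factor double-dips on that selection.  The split model therefore
    carries a uniform prior over the 2^(n-1) - 1 bipartitions of an
    n-vertex cluster, i.e. the evidence for keeping the cluster whole
    gains ln(2^(n-1) - 1).  (The merge-time ratios used during
    agglomeration carry no such multiplicity factors.)

    A single immediately-unfavorable split can hide strongly favored
    structure underneath (e.g. a root that merely attaches one stray vertex
    to the rest of the network), so each candidate split is assessed by a
    one-barrier lookahead: force the split, continue greedily with
    positive-gain splits within the forced node's subtree, and accept the
    prefix of that trajectory with the maximal cumulative gain provided it
    is positive.  Collapsed terminals are never split, so the bottom-level
    clusters always refine the result.  Deterministic; ties break on the
    smallest member id of the split node.
    """
    nets = getattr(networks, "layers", None)
    if nets is None:
        nets = networks if isinstance(networks, (list, tuple)) else [networks]
    nets = list(nets)

    def split_gain(current: list[int], nid: int) -> float:
        node = dend.nodes[nid]
        parts = [set(dend.nodes[c].members) for c in current if c != nid]
        parts.append(set(dend.nodes[node.left].members))
        parts.append(set(dend.nodes[node.right].members))
        state = ClusterState(nets, partition=parts)
        ev = stop_score(state, len(parts) - 2, len(parts) - 1)
        n = len(node.members)  # bipartition-multiplicity prior on the split
        ev += (n - 1) * _LN2 if n > 40 else _ln(2 ** (n - 1) - 1)
        return -ev

    def apply_split(current: list[int], nid: int) -> list[int]:
        node = dend.nodes[nid]
        out = [c for c in current if c != nid]
        out.extend((node.left, node.right))
        out.sort()
        return out

    def trajectory(current: list[int], forced: int) -> tuple[float, list[int]]:
        """Force one split, then greedy positive-gain splits restricted to
        the forced node's subtree; return the cumulative-max prefix
        (gain, partition).  The restriction makes this a test of whether
        the forced cluster itself hides structure; splitting unrelated
        clusters under increasingly fragmented conditioning would
        reinforce over-resolution instead."""
        subtree: set[int] = set()
        stack = [forced]
        while stack:
            nid = stack.pop()
            subtree.add(nid)
            node = dend.nodes[nid]
            if node.left is not None:
                stack.extend((node.left, node.right))
        cur = list(current)
        cum = 0.0
        best_gain, best_part = 0.0, list(cur)
        nid = forced
        while True:
            cum += split_gain(cur, nid)
            cur = apply_split(cur, nid)
            if cum > best_gain:
                best_gain, best_part = cum, list(cur)
            cands = [
                (split_gain(cur, c), min(dend.nodes[c].members), c)
                for c in cur
                if c in subtree and dend.nodes[c].left is not None
            ]
            cands = [c for c in cands if c[0] >= 0.0]
            if not cands:
                return best_gain, best_part
            nid = min(cands, key=lambda c: (-c[0], c[1]))[2]

    current: list[int] = sorted(dend.roots)
    while True:
        best: tuple[float, str] | None = None
        best_part: list[int] | None = None
        for nid in current:
            if dend.nodes[nid].left is None:
                continue
            gain, part = trajectory(current, nid)
            if gain > 0.0:
                key = (-gain, min(dend.nodes[nid].members))
                if best is None or key < best:
                    best, best_part = key, part
        if best is None:
            return [dend.nodes[nid].members for nid in current]
        current = best_part  # type: ignore[assignment]


def run_hac(
    net,
    method: str = "ml",
    collapse: bool = True,
    stop_criterion: str = "first-drop",
    max_merges: int | None = None,
    seed: int | None = None,
    audit: bool = False,
) -> HacResult:
    """Greedy agglomerative clustering of a Network or MultiNetwork.

    Pops the best merge candidate under ``method`` until no candidates
    remain (disconnected inputs end as a forest).  Every accepted merge is
    scored with the Bayesian ratios: lambda^C collapses the new node into a
    homogeneous terminal when both children are collapsed and the flat
    model is favored, and the stopping evidence (:func:`stop_score`)
    identifies the reported top-level partition.

    Under the default ``first-drop`` criterion, the model-based methods
    (``ml``, ``bayes``) accept only merges whose stopping evidence favors
    merging, deferring the rest; the top level is the partition reached
    when the best remaining candidate's evidence first drops below one.
    Deferred merges are then applied (without further collapsing) so the
    guide tree is always completed for link prediction.  The heuristic
    methods (``e``, ``es``, ``q``) never reorder on Bayesian scores: their
    top level is the state before the first accepted merge with
    non-favorable evidence.  ``stop_criterion='none'`` reports the final
    roots.

    ``seed`` is accepted for interface symmetry; the algorithm is
    deterministic, with ties broken on the lexicographically smallest pair
    of cluster minimum-member ids.
    """
    del seed  # deterministic: lexicographic tie-breaking needs no RNG
    if stop_criterion not in ("first-drop", "none"):
        raise ValueError(f"unknown stop_criterion {stop_criterion!r}")
    score_fn = _scorer(method)
    state = ClusterState(net)
    use_epoch = method in ("bayes", "bayes-stop")
    gating = stop_criterion == "first-drop" and method in ("ml", "bayes", "bayes-stop")
    recorded_stop = stop_criterion == "first-drop" and not gating
    epoch = 0

    dend = Dendrogram(n_layers=state.n_layers)
    leaf_of: dict[str, int] = {}
    for cid, mem in state.members.items():
        (v,) = mem
        dend.add_leaf(cid, v)
        leaf_of[v] = cid
    is_collapsed: dict[int, bool] = {cid: True for cid in state.members}

    def stamp(cid: int) -> int:
        return epoch if use_epoch else state.version[cid]

    def tiebreak(i: int, j: int) -> tuple[str, str]:
        a, b = state.min_member[i], state.min_member[j]
        return (a, b) if a <= b else (b, a)

    heap: list[tuple[float, tuple[str, str], int, int, int, int]] = []

    def push(i: int, j: int) -> None:
        heapq.heappush(
            heap, (-score_fn(state, i, j), tiebreak(i, j), i, j, stamp(i), stamp(j))
        )

    # candidate partner index: merge scores are not monotone over time (a
    # pair can become a better merge as the rest of the network coarsens),
    # so every candidate touching a modified cluster is rescored and
    # re-pushed right away; entries left behind are skipped as stale.
    partners: dict[int, set[int]] = {cid: set() for cid in state.members}
    for i, j in candidate_pairs(state):
        partners[i].add(j)
        partners[j].add(i)
        push(i, j)

    records: list[MergeRecord] = []
    deferred: set[tuple[int, int]] = set()
    stopped = False
    step = 0

    while True:
        if not heap:
            if gating and not stopped:
                # no Bayesian-favored candidate remains: merging is no
                # longer justified; deferred merges then complete the
                # guide tree (without further collapsing)
                stopped = True
                log.info("stopping criterion met after %d merges (K=%d)",
                         step, state.K)
                for pair in sorted(deferred):
                    if state.alive(pair[0]) and state.alive(pair[1]):
                        push(*pair)
                deferred.clear()
                if heap:
                    continue
            break
        if max_merges is not None and step >= max_merges:
            break
        neg, _, i, j, si, sj = heapq.heappop(heap)
        if not (state.alive(i) and state.alive(j)):
            continue
        if si != stamp(i) or sj != stamp(j):
            push(i, j)  # lazy evaluation: rescore, never act on stale entries
            continue
        score = -neg
        lml = score if method == "ml" else merge_score_ml(state, i, j)
        lb = score if use_epoch else merge_score_bayes(state, i, j)
        local = collapse_score(state, i, j)
        evidence = lb + local
        key = _pairkey(i, j)
        # strictly negative evidence defers: an evidence-neutral merge (e.g.
        # two singletons, where lambda^C = 1) is always carried out
        if gating and not stopped and evidence < 0.0:
            deferred.add(key)
            continue
        deferred.discard(key)
        step += 1
        if recorded_stop and not stopped and evidence < 0.0:
            stopped = True
            log.info("stopping criterion met at merge %d (K=%d)", step, state.K)
        both_collapsed = is_collapsed[i] and is_collapsed[j]
        lc = local if both_collapsed else None
        do_collapse = collapse and both_collapsed and lc >= 0.0 and not stopped

        if do_collapse:
            n_i, n_j = state.size(i), state.size(j)
            t_w = (n_i + n_j) * (n_i + n_j - 1) // 2
            counts = tuple(
                PairCounts.from_totals(
                    state.within[li][i] + state.within[li][j] + state.cross_count(li, i, j),
                    t_w,
                )
                for li in range(state.n_layers)
            )
        else:
            t_ij = state.size(i) * state.size(j)
            counts = tuple(
                PairCounts.from_totals(state.cross_count(li, i, j), t_ij)
                for li in range(state.n_layers)
            )

        r, touched = state.merge(i, j)
        epoch += 1
        dend.add_merge(r, i, j, counts, do_collapse, step, lml, lb, lc)
        is_collapsed.pop(i)
        is_collapsed.pop(j)
        is_collapsed[r] = do_collapse
        records.append(
            MergeRecord(step, (i, j), r, score, lml, lb, evidence, lc, do_collapse)
        )

        # candidate status is monotone: pairs inherited from the children
        # stay candidates of the merged cluster, and clusters sharing the
        # new cluster as a neighbor become candidates of each other
        part_r = (partners.pop(i) | partners.pop(j)) - {i, j}
        for x in part_r:
            partners[x].discard(i)
            partners[x].discard(j)
        new_nbrs = sorted(state.all_neighbors(r))
        part_r.update(new_nbrs)
        for a, x in enumerate(new_nbrs):
            for y in new_nbrs[a + 1:]:
                partners[x].add(y)
                partners[y].add(x)
        partners[r] = part_r
        for x in part_r:
            partners[x].add(r)

        if use_epoch:
            touched = set(state.members)  # Bayesian scores shift globally
        touched.add(r)
        pushed: set[tuple[int, int]] = set()
        for c in touched:
            for p in partners.get(c, ()):
                key = _pairkey(c, p)
                if key not in pushed:
                    pushed.add(key)
                    push(*key)

    if audit:
        state.recount_audit()

    if stop_criterion == "first-drop":
        # the reported partition comes from top-down model selection on the
        # finished forest; the gate's phase-1 state shaped the tree itself
        top = bayesian_tree_cut(dend, state.networks)
    else:
        top = state.snapshot()

    cross_keys = set().union(*(state.cross[li].keys() for li in range(state.n_layers)))
    root_cross = {
        key: [state.cross[li].get(key, 0) for li in range(state.n_layers)]
        for key in cross_keys
    }
    result = HacResult(
        dendrogram=dend,
        merge_sequence=records,
        top_level_clusters=[],
        bottom_level_clusters=[n.members for n in dend.terminals()],
        networks=state.networks,
        method=method,
        root_cross=root_cross,
        leaf_of=leaf_of,
    )
    result.top_level_clusters = top
    log.info(
        "%s clustering: %d merges, %d top-level, %d bottom-level clusters",
        method, len(records), len(result.top_level_clusters),
        len(result.bottom_level_clusters),
    )
    return result
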