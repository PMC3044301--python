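"""Heuristic merge scores: edge density, shared-neighbor density, modularity.

These drive the HAC-E (edge density rho_e), HAC-ES (rho_e + rho_s) and HAC-Q
(greedy modularity increment) variants of the agglomerative engine.  They
reorder the guide tree only; the Bayesian stopping and collapse ratios are
still recorded for reporting.
"""

from __future__ import annotations

from .blockmodel import ClusterState

__all__ = ["rho_e", "rho_s", "delta_q"]


def rho_e(state: ClusterState, i: int, j: int, layer: int = 0) -> float:
    """Edge density between clusters i and j: e_ij / t_ij, in [0, 1]."""
    t = state.size(i) * state.size(j)
    if t == 0:
        return 0.0
    return state.cross_count(layer, i, j) / t


def rho_s(state: ClusterState, i: int, j: int, layer: int = 0) -> float:
    """Shared-neighbor density between clusters i and j.

    Fraction of outside vertices u (not in i or j) adjacent to at least one
    member of i AND at least one member of j; the indicator normalization
    divides by the number of eligible outside vertices.
    """
    net = state.networks[layer]
    mi, mj = state.members[i], state.members[j]
    denom = state.n_vertices - len(mi) - len(mj)
    if denom <= 0:
        return 0.0
    excluded = mi | mj
    touch_i: set[str] = set()
    for u in mi:
        touch_i |= net.neighbors(u)
    touch_j: set[str] = set()
    for u in mj:
        touch_j |= net.neighbors(u)
    shared = (touch_i & touch_j) - excluded
    return len(shared) / denom


def delta_q(state: ClusterState, i: int, j: int, layer: int = 0) -> float:
    """Newman modularity change for merging clusters i and j.

    ``e_ij/E - D_i D_j / (2 E^2)`` with D the within-cluster degree sums over
    the full network and E the total edge count.
    """
    e_total = state.total_edges[layer]
    if e_total == 0:
        raise ValueError("modularity undefined for an empty network")
    e_ij = state.cross_count(layer, i, j)
    d_i = state.deg_sum[layer][i]
    d_j = state.deg_sum[layer][j]
    return e_ij / e_total - d_i * d_j / (2.0 * e_total * e_total)
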