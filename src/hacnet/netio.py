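"""Reading, validating, filtering and writing interaction networks.

Networks are simple undirected graphs over opaque string vertex ids, with
unweighted edges and no self-loops.  A :class:`MultiNetwork` holds one
:class:`Network` per edge type (layer), e.g. a physical-interaction layer and
a genetic-interaction layer over the same genes.

The on-disk formats are deliberately plain: whitespace-separated edge lists
in, TSV cluster assignments and a JSON dendrogram out.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger("hacnet")

__all__ = [
    "Network",
    "MultiNetwork",
    "EdgeListParseError",
    "read_edge_list",
    "iterative_low_degree_filter",
    "intersect_layers",
    "write_clustering",
    "write_tree",
    "read_tree",
    "write_edge_list",
]


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list input (message names the line number)."""


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Unordered-pair canonical form: (min, max) by string order."""
    return (u, v) if u <= v else (v, u)


class Network:
    """Simple undirected graph over string vertex ids.

    Invariants: no self-loops, no duplicate edges (unordered-pair semantics),
    and every edge endpoint belongs to the vertex set.
    """

    __slots__ = ("layer_label", "_adj")

    def __init__(
        self,
        vertices: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
        layer_label: str = "default",
    ) -> None:
        self.layer_label = layer_label
        self._adj: dict[str, set[str]] = {}
        for v in vertices:
            self.add_vertex(v)
        for u, v in edges:
            self.add_vertex(u)
            self.add_vertex(v)
            self.add_edge(u, v)

    # -- construction -------------------------------------------------------

    def add_vertex(self, v: str) -> None:
        self._adj.setdefault(v, set())

    def add_edge(self, u: str, v: str) -> bool:
        """Insert an edge; returns False for self-loops and duplicates."""
        if u == v:
            return False
        if u not in self._adj or v not in self._adj:
            raise KeyError(f"edge endpoint not in vertex set: {(u, v)!r}")
        if v in self._adj[u]:
            return False
        self._adj[u].add(v)
        self._adj[v].add(u)
        return True

    def remove_vertex(self, v: str) -> None:
        for w in self._adj.pop(v):
            self._adj[w].discard(v)

    def remove_edge(self, u: str, v: str) -> None:
        self._adj[u].remove(v)
        self._adj[v].remove(u)

    # -- queries ------------------------------------------------------------

    @property
    def vertices(self) -> set[str]:
        return set(self._adj)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {canonical_edge(u, v) for u, nb in self._adj.items() for v in nb if u <= v}

    def iter_edges(self):
        for u, nb in self._adj.items():
            for v in nb:
                if u <= v:
                    yield (u, v)

    def neighbors(self, v: str) -> set[str]:
        return self._adj[v]

    def degree(self, v: str) -> int:
        return len(self._adj[v])

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, ())

    @property
    def num_vertices(self) -> int:
        return len(self._adj)

    @property
    def num_edges(self) -> int:
        return sum(len(nb) for nb in self._adj.values()) // 2

    def copy(self, layer_label: str | None = None) -> "Network":
        net = Network(layer_label=layer_label or self.layer_label)
        net._adj = {v: set(nb) for v, nb in self._adj.items()}
        return net

    def subgraph(self, keep: set[str]) -> "Network":
        net = Network(layer_label=self.layer_label)
        net._adj = {v: self._adj[v] & keep for v in self._adj if v in keep}
        return net

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Network)
            and self._adj == other._adj
            and self.layer_label == other.layer_label
        )

    def __repr__(self) -> str:
        return (
            f"Network(layer={self.layer_label!r}, V={self.num_vertices}, "
            f"E={self.num_edges})"
        )


class MultiNetwork:
    """Ordered collection of layers (one :class:`Network` per edge type)."""

    def __init__(self, layers: Sequence[Network]) -> None:
        if not layers:
            raise ValueError("MultiNetwork requires at least one layer")
        labels = [lay.layer_label for lay in layers]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate layer labels: {labels}")
        self.layers = list(layers)

    @property
    def labels(self) -> list[str]:
        return [lay.layer_label for lay in self.layers]

    def layer(self, label: str) -> Network:
        for lay in self.layers:
            if lay.layer_label == label:
                return lay
        raise KeyError(f"no layer {label!r}; have {self.labels}")

    @property
    def vertices(self) -> set[str]:
        out: set[str] = set()
        for lay in self.layers:
            out |= lay.vertices
        return out

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)

    def __repr__(self) -> str:
        return f"MultiNetwork({', '.join(map(repr, self.layers))})"


# ---------------------------------------------------------------------------
# readers / filters
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path, layer_column: int | None = None) -> MultiNetwork:
    """Read a whitespace/tab-separated edge list into a :class:`MultiNetwork`.

    Each non-comment line carries two vertex ids; with ``layer_column`` (a
    1-based column index) the indicated token keys the edge into a layer.
    Lines starting with ``#`` are skipped; extra columns are ignored.
    Self-loops and duplicate pairs are dropped (with a logged count);
    ``(a, b)`` and ``(b, a)`` are the same pair.
    """
    path = Path(path)
    if layer_column is not None and layer_column < 3:
        raise ValueError("layer_column is a 1-based index and must be >= 3")
    layers: dict[str, Network] = {}
    n_dropped = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            need = 2 if layer_column is None else layer_column
            if len(tokens) < need:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected >= {need} columns, got {len(tokens)}"
                )
            n_lines += 1
            u, v = tokens[0], tokens[1]
            label = "default" if layer_column is None else tokens[layer_column - 1]
            net = layers.get(label)
            if net is None:
                net = layers[label] = Network(layer_label=label)
            net.add_vertex(u)
            net.add_vertex(v)
            if u == v or not net.add_edge(u, v):
                n_dropped += 1
    if n_lines == 0:
        raise EdgeListParseError(f"{path}: no edges found")
    if n_dropped:
        log.info("%s: dropped %d self-loop/duplicate pair(s)", path, n_dropped)
    return MultiNetwork(list(layers.values()))


def iterative_low_degree_filter(net: Network) -> Network:
    """Iteratively delete vertices of degree <= 1 until none remain.

    Isolated and degree-1 vertices carry almost no information for block
    clustering; removal cascades, so the result has minimum degree >= 2 or
    is empty.  The input network is not modified.
    """
    out = net.copy()
    queue = [v for v in out.vertices if out.degree(v) <= 1]
    removed = 0
    while queue:
        nxt: set[str] = set()
        for v in queue:
            if v not in out._adj:
                continue
            nbrs = set(out.neighbors(v))
            out.remove_vertex(v)
            removed += 1
            nxt |= {w for w in nbrs if w in out._adj and out.degree(w) <= 1}
        queue = sorted(nxt)
    if removed:
        log.info("low-degree filter removed %d vertex(es) from layer %s",
                 removed, net.layer_label)
    return out


def intersect_layers(mnet: MultiNetwork) -> MultiNetwork:
    """Restrict every layer to the common intersection of vertex sets.

    Edges with a removed endpoint are dropped.  The low-degree filter is NOT
    re-applied; callers decide whether to filter afterwards.
    """
    common = set(mnet.layers[0].vertices)
    for lay in mnet.layers[1:]:
        common &= lay.vertices
    if not common:
        raise ValueError("layer vertex sets have empty intersection")
    return MultiNetwork([lay.subgraph(common) for lay in mnet.layers])


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_edge_list(net: Network | MultiNetwork, path: str | Path,
                    with_layer: bool | None = None) -> None:
    """Write a canonical (sorted, deduplicated) edge list."""
    layers = net.layers if isinstance(net, MultiNetwork) else [net]
    if with_layer is None:
        with_layer = isinstance(net, MultiNetwork) and len(layers) > 1
    with open(path, "w") as fh:
        for lay in layers:
            for u, v in sorted(lay.edges):
                if with_layer:
                    fh.write(f"{u}\t{v}\t{lay.layer_label}\n")
                else:
                    fh.write(f"{u}\t{v}\n")


def write_clustering(assignment: Mapping[str, tuple[int, int]], path: str | Path) -> None:
    """Write a TSV of vertex, top-level cluster id, bottom-level cluster id.

    Rows are sorted by vertex id for deterministic output.
    """
    for v in assignment:
        if "\t" in v or "\n" in v:
            raise ValueError(f"vertex id contains tab/newline: {v!r}")
    with open(path, "w") as fh:
        fh.write("vertex\ttop_cluster\tbottom_cluster\n")
        for v in sorted(assignment):
            top, bottom = assignment[v]
            fh.write(f"{v}\t{top}\t{bottom}\n")


def write_tree(dendrogram, path: str | Path) -> None:
    """Serialize a dendrogram (merge forest) to a documented JSON file.

    Per node: children (or the member list for collapsed/terminal nodes),
    per-layer crossing/within edge and hole counts, merge-step index, the
    merge log-ratios, and the collapsed flag.  ``read_tree`` restores the
    structure losslessly.
    """
    records = []
    for node in dendrogram.iter_reachable():
        rec: dict = {
            "id": node.id,
            "collapsed": node.collapsed,
            "e": [c.e for c in node.counts],
            "h": [c.h for c in node.counts],
            "step": node.step,
            "log_ml": node.log_ml,
            "log_bayes": node.log_bayes,
            "log_collapse": node.log_collapse,
        }
        if node.left is None:
            rec["members"] = sorted(node.members)
            rec["children"] = None
        else:
            rec["children"] = [node.left, node.right]
        records.append(rec)
    payload = {
        "format": "hacnet-tree",
        "version": 1,
        "n_layers": dendrogram.n_layers,
        "roots": sorted(dendrogram.roots),
        "nodes": records,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_tree(path: str | Path):
    """Read a dendrogram written by :func:`write_tree`."""
    from .blockmodel import Dendrogram, PairCounts, TreeNode

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "hacnet-tree":
        raise ValueError(f"{path}: not a hacnet tree file")
    dend = Dendrogram(n_layers=payload["n_layers"])
    # two passes: childless nodes carry members; branching members are unions
    by_id = {rec["id"]: rec for rec in payload["nodes"]}

    def build(nid: int) -> frozenset:
        rec = by_id[nid]
        if nid in dend.nodes:
            return dend.nodes[nid].members
        if rec["children"] is None:
            members = frozenset(rec["members"])
            left = right = None
        else:
            left, right = rec["children"]
            members = build(left) | build(right)
        dend.nodes[nid] = TreeNode(
            id=nid,
            left=left,
            right=right,
            members=frozenset(members),
            counts=tuple(PairCounts(e, h) for e, h in zip(rec["e"], rec["h"])),
            collapsed=rec["collapsed"],
            step=rec["step"],
            log_ml=rec["log_ml"],
            log_bayes=rec["log_bayes"],
            log_collapse=rec["log_collapse"],
        )
        return dend.nodes[nid].members

    for rid in payload["roots"]:
        build(rid)
        dend.roots.add(rid)
    return dend
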