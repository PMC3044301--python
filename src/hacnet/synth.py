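"""Synthetic network generators: planted partitions and hierarchical graphs.

These provide seeded test fixtures that emulate the generative reading of
the block model: every vertex pair is an independent Bernoulli trial whose
rate depends only on the groups (or the governing dendrogram node) of its
endpoints.  Generators return ground-truth labels alongside the graph so
recovered partitions can be scored (e.g. with the adjusted Rand index).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .netio import MultiNetwork, Network

__all__ = [
    "PlantedSpec",
    "HrgNode",
    "LayerSpec",
    "sample_planted",
    "sample_hrg",
    "sample_multilayer",
]


@dataclass(frozen=True)
class PlantedSpec:
    """Planted-partition model: within-block rate p_in, between-block p_out."""

    block_sizes: tuple[int, ...]
    p_in: float
    p_out: float
    seed: int = 0
    layer_label: str = "default"

    def __post_init__(self) -> None:
        if not self.block_sizes or any(s <= 0 for s in self.block_sizes):
            raise ValueError(f"invalid block sizes: {self.block_sizes}")
        for p in (self.p_in, self.p_out):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")


def _vertex_ids(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"v{i:0{width}d}" for i in range(n)]


def sample_planted(spec: PlantedSpec, rng=None) -> tuple[Network, dict[str, int]]:
    """Sample one planted-partition graph; returns (network, true labels)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        spec.seed if rng is None else rng
    )
    n = sum(spec.block_sizes)
    verts = _vertex_ids(n)
    labels = np.repeat(np.arange(len(spec.block_sizes)), spec.block_sizes)
    iu, ju = np.triu_indices(n, k=1)
    probs = np.where(labels[iu] == labels[ju], spec.p_in, spec.p_out)
    draws = rng.random(iu.size) < probs
    net = Network(vertices=verts, layer_label=spec.layer_label)
    for a, b in zip(iu[draws], ju[draws]):
        net.add_edge(verts[a], verts[b])
    return net, {verts[i]: int(labels[i]) for i in range(n)}


@dataclass
class HrgNode:
    """One node of a generative hierarchy: theta governs its pairs.

    Terminal nodes carry ``members`` (their pairs are edges with probability
    ``theta``); internal nodes carry children, and pairs split between the
    two subtrees are edges with probability ``theta``.
    """

    theta: float
    left: "HrgNode | None" = None
    right: "HrgNode | None" = None
    members: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta out of [0, 1]: {self.theta}")
        terminal = self.members is not None
        if terminal == (self.left is not None or self.right is not None):
            raise ValueError("node must have either members or two children")
        if not terminal and (self.left is None or self.right is None):
            raise ValueError("internal node requires both children")

    def all_members(self) -> list[str]:
        if self.members is not None:
            return list(self.members)
        return self.left.all_members() + self.right.all_members()


def sample_hrg(spec: HrgNode, seed: int = 0) -> Network:
    """Sample a graph where each pair's edge rate is its governing node's theta."""
    rng = np.random.default_rng(seed)
    members = spec.all_members()
    if len(set(members)) != len(members):
        raise ValueError("duplicate vertex ids in hierarchy")
    net = Network(vertices=members)

    def visit(node: HrgNode) -> list[str]:
        if node.members is not None:
            mem = list(node.members)
            for a in range(len(mem)):
                for b in range(a + 1, len(mem)):
                    if rng.random() < node.theta:
                        net.add_edge(mem[a], mem[b])
            return mem
        left = visit(node.left)
        right = visit(node.right)
        for u in left:
            for v in right:
                if rng.random() < node.theta:
                    net.add_edge(u, v)
        return left + right

    visit(spec)
    return net


@dataclass(frozen=True)
class LayerSpec:
    """Edge-type layer of a multi-layer sample: label plus Bernoulli rates."""

    label: str
    p_in: float
    p_out: float


def sample_multilayer(
    block_sizes: Sequence[int], layers: Sequence[LayerSpec], seed: int = 0
) -> tuple[MultiNetwork, dict[str, int]]:
    """Sample independent layers conditioned on one shared block assignment.

    Every layer covers the same vertex set; e.g. an assortative physical
    layer plus a disassortative genetic layer over the same planted blocks.
    """
    if not layers:
        raise ValueError("at least one layer spec required")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(layers))
    nets = []
    labels: dict[str, int] = {}
    for lay, child in zip(layers, children):
        spec = PlantedSpec(
            block_sizes=tuple(block_sizes),
            p_in=lay.p_in,
            p_out=lay.p_out,
            layer_label=lay.label,
        )
        net, labels = sample_planted(spec, rng=np.random.default_rng(child))
        nets.append(net)
    return MultiNetwork(nets), labels
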