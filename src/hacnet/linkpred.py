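"""Missing-link prediction with hold-out cross-validation.

A training network is made by deleting a random fraction of the observed
edges; the test set is the held-out edges plus an equal number of randomly
sampled holes (pairs with no edge in the ORIGINAL network, so a held-out
edge can never be drawn as a negative).  The clustering trained on the
training network scores every test pair with the maximum-likelihood edge
density of the block governing that pair: the within-density of a shared
collapsed terminal, the crossing density of the lowest common ancestor in
the guide tree, or the top-level block density for pairs split across
roots.  Ranked predictions are summarized by precision/recall, the maximal
F-score, and AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .agglomerate import HacResult, run_hac
from .netio import MultiNetwork, Network, canonical_edge

log = logging.getLogger("hacnet")

__all__ = [
    "SplitSpec",
    "TestSet",
    "LinkPredictionResult",
    "split_edges",
    "sample_holes",
    "pair_link_score",
    "LinkScorer",
    "evaluate",
    "cross_validate",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class SplitSpec:
    """One hold-out split: fraction of observed edges removed, RNG seed."""

    holdout_fraction: float
    seed: int
    replicate: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError(f"holdout_fraction must be in (0, 1): {self.holdout_fraction}")


@dataclass
class TestSet:
    """Held-out edges (positives) and an equal number of sampled holes."""

    positives: set[Pair]
    negatives: set[Pair]

    def __post_init__(self) -> None:
        if len(self.negatives) != len(self.positives):
            raise ValueError("test set requires equal positive and negative counts")
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")

    @property
    def pairs(self) -> list[Pair]:
        return sorted(self.positives | self.negatives)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def split_edges(net: Network, spec: SplitSpec | float, seed=None) -> tuple[Network, set[Pair]]:
    """Remove a uniform random sample of edges; return (training, held-out).

    The training network keeps every vertex (no re-filtering), so the test
    universe is unchanged.  At least one edge is always held out.
    """
    if isinstance(spec, SplitSpec):
        fraction, seed = spec.holdout_fraction, spec.seed
    else:
        fraction = float(spec)
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"holdout fraction must be in (0, 1): {fraction}")
    edges = sorted(net.edges)
    n_hold = max(1, round(fraction * len(edges)))
    if n_hold >= len(edges):
        raise ValueError("cannot hold out every edge")
    rng = _rng(seed)
    idx = rng.choice(len(edges), size=n_hold, replace=False)
    heldout = {edges[i] for i in idx}
    train = net.copy()
    for u, v in heldout:
        train.remove_edge(u, v)
    for u, v in heldout:  # training must never see a held-out edge
        assert not train.has_edge(u, v)
    return train, heldout


def sample_holes(net: Network, n: int, seed=None) -> set[Pair]:
    """Sample ``n`` distinct unordered non-edges of ``net`` uniformly."""
    verts = sorted(net.vertices)
    n_verts = len(verts)
    total_pairs = n_verts * (n_verts - 1) // 2
    n_holes = total_pairs - net.num_edges
    if n > n_holes:
        raise ValueError(f"requested {n} holes but only {n_holes} exist")
    rng = _rng(seed)
    if total_pairs <= 500_000:
        holes = [
            (u, v)
            for a, u in enumerate(verts)
            for v in verts[a + 1:]
            if not net.has_edge(u, v)
        ]
        idx = rng.choice(len(holes), size=n, replace=False)
        return {holes[i] for i in idx}
    out: set[Pair] = set()
    while len(out) < n:  # rejection sampling for large sparse networks
        a, b = rng.integers(0, n_verts, size=2)
        if a == b:
            continue
        u, v = verts[a], verts[b]
        pair = canonical_edge(u, v)
        if not net.has_edge(u, v):
            out.add(pair)
    return out


# ---------------------------------------------------------------------------
# model-based pair scores
# ---------------------------------------------------------------------------


class LinkScorer:
    """Scores vertex pairs with the trained model's block densities.

    Densities come from the training counts of the layer being predicted.
    ``smoothed`` switches the raw ML density e/t to the Laplace-smoothed
    (e+1)/(t+2), which breaks the many exact-zero ties; off by default.
    """

    def __init__(self, result: HacResult, layer: int = 0, smoothed: bool = False):
        self.result = result
        self.layer = layer
        self.smoothed = smoothed
        dend = result.dendrogram
        self._parent = dend.parent_map()
        self._terminal_of: dict[str, int] = {}
        self._root_of: dict[int, int] = {}
        for node in dend.terminals():
            for v in node.members:
                self._terminal_of[v] = node.id
        for rid in dend.roots:
            stack = [rid]
            while stack:
                nid = stack.pop()
                self._root_of[nid] = rid
                node = dend.nodes[nid]
                if node.left is not None:
                    stack.extend((node.left, node.right))

    def _density(self, e: int, t: int) -> float:
        if self.smoothed:
            return (e + 1) / (t + 2)
        return e / t if t else 0.0

    def score(self, u: str, v: str) -> float:
        if u == v:
            raise ValueError("cannot score a self pair")
        try:
            tu, tv = self._terminal_of[u], self._terminal_of[v]
        except KeyError as exc:
            raise KeyError(f"vertex not in the trained model: {exc}") from exc
        dend = self.result.dendrogram
        if tu == tv:  # same collapsed terminal: within-group density
            node = dend.nodes[tu]
            return self._density(node.counts[self.layer].e, node.counts[self.layer].t)
        ru, rv = self._root_of[tu], self._root_of[tv]
        if ru != rv:  # different trees: top-level block density
            key = (ru, rv) if ru < rv else (rv, ru)
            e = self.result.root_cross.get(key, [0] * dend.n_layers)[self.layer]
            t = dend.nodes[ru].size * dend.nodes[rv].size
            return self._density(e, t)
        ancestors = {}
        nid, depth = tu, 0
        while nid is not None:
            ancestors[nid] = depth
            nid, depth = self._parent.get(nid), depth + 1
        nid = tv
        while nid not in ancestors:
            nid = self._parent[nid]
        node = dend.nodes[nid]  # lowest common ancestor's crossing density
        return self._density(node.counts[self.layer].e, node.counts[self.layer].t)

    def score_pairs(self, pairs: Iterable[Pair]) -> dict[Pair, float]:
        return {p: self.score(*p) for p in pairs}


def pair_link_score(
    result: HacResult, u: str, v: str, layer: int = 0, smoothed: bool = False
) -> float:
    """Model edge probability for one pair (see :class:`LinkScorer`)."""
    return LinkScorer(result, layer=layer, smoothed=smoothed).score(u, v)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class LinkPredictionResult:
    """Ranked test pairs with precision/recall curve, F-score and AUC."""

    ranked: list[tuple[Pair, float, bool]]
    precision: np.ndarray
    recall: np.ndarray
    fscore: float
    auc: float

    def pr_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_predictions": np.arange(1, len(self.ranked) + 1),
                "precision": self.precision,
                "recall": self.recall,
            }
        )


def evaluate(test: TestSet, scores: Mapping[Pair, float]) -> LinkPredictionResult:
    """Precision/recall at every cutoff, maximal F-score, and midrank AUC.

    Pairs are ranked by descending score with ties broken by canonical pair
    order (deterministic); the AUC uses midranks so score ties do not bias
    it either way.
    """
    pairs = test.pairs
    if not pairs:
        raise ValueError("empty test set")
    missing = [p for p in pairs if p not in scores]
    if missing:
        raise ValueError(f"unscored test pairs, e.g. {missing[0]}")
    ranked = sorted(
        ((p, float(scores[p]), p in test.positives) for p in pairs),
        key=lambda rec: (-rec[1], rec[0]),
    )
    is_pos = np.array([rec[2] for rec in ranked], dtype=bool)
    tp = np.cumsum(is_pos)
    k = np.arange(1, len(ranked) + 1)
    n_pos = int(is_pos.sum())
    precision = tp / k
    recall = tp / n_pos
    with np.errstate(invalid="ignore", divide="ignore"):
        f_at_k = np.where(tp > 0, 2 * precision * recall / (precision + recall), 0.0)
    fscore = float(f_at_k.max())
    vals = np.array([rec[1] for rec in ranked])
    ranks = rankdata(vals)  # midranks
    n_neg = len(ranked) - n_pos
    auc = float((ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    return LinkPredictionResult(ranked, precision, recall, fscore, auc)


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------


@dataclass
class CrossValResult:
    """Per-replicate metrics and their aggregate (mean and SD)."""

    per_replicate: pd.DataFrame
    aggregate: pd.DataFrame


def cross_validate(
    net,
    method: str = "ml",
    fraction: float = 0.075,
    replicates: int = 10,
    seed: int = 0,
    target_layer: str | None = None,
    smoothed: bool = True,
    collapse: bool = True,
    stop_criterion: str = "first-drop",
) -> CrossValResult:
    """Repeat split -> train -> score -> evaluate; summarize F and AUC.

    For a MultiNetwork, edges are held out of ``target_layer`` only, the
    model is trained jointly on all layers, and scoring uses the trained
    densities of the target layer.  Scoring defaults to Laplace-smoothed
    densities: sparse blocks and shared-neighbor terminals frequently have
    a raw training density of exactly zero, and ranking those test pairs
    below every non-empty block badly distorts both AUC and the
    precision/recall curve.  Deterministic given ``seed``.
    """
    if isinstance(net, MultiNetwork):
        layers = net.layers
        if target_layer is None:
            if len(layers) > 1:
                raise ValueError("target_layer is required for multi-layer input")
            target_layer = layers[0].layer_label
        target_idx = net.labels.index(target_layer)
    else:
        layers = [net]
        target_idx = 0
        target_layer = net.layer_label
    original = layers[target_idx]

    rows = []
    for rep in range(replicates):
        ss = np.random.SeedSequence(seed, spawn_key=(rep,))
        rng_split, rng_holes = (np.random.default_rng(c) for c in ss.spawn(2))
        train_target, heldout = split_edges(original, fraction, rng_split)
        holes = sample_holes(original, len(heldout), rng_holes)
        test = TestSet(positives=set(heldout), negatives=holes)
        train_layers = list(layers)
        train_layers[target_idx] = train_target
        train_input = (
            MultiNetwork(train_layers) if len(train_layers) > 1 else train_target
        )
        result = run_hac(
            train_input, method=method, collapse=collapse, stop_criterion=stop_criterion
        )
        scorer = LinkScorer(result, layer=target_idx, smoothed=smoothed)
        metrics = evaluate(test, scorer.score_pairs(test.pairs))
        rows.append(
            {
                "replicate": rep,
                "layer": target_layer,
                "F": metrics.fscore,
                "AUC": metrics.auc,
                "n_test": len(test.pairs),
            }
        )
        log.info(
            "replicate %d (%s): F=%.3f AUC=%.3f on %d test pairs",
            rep, target_layer, metrics.fscore, metrics.auc, len(test.pairs),
        )
    per_rep = pd.DataFrame(rows)
    agg = (
        per_rep.groupby("layer")[["F", "AUC"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    return CrossValResult(per_replicate=per_rep, aggregate=agg)
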