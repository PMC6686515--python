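"""Seed scoring and the seed queue.

Each node is scored once, on the initial weighted network, as

    Score(v) = d_w(v) * NGCC(v)

where ``d_w(v)`` is the weighted degree and ``NGCC(v)`` the neighborhood
graph clustering coefficient: the total weight of the edges among
``V_v = {v} ∪ N(v)`` divided by the number of possible pairs in ``V_v``.
High scores mark nodes that sit centrally inside densely interconnected,
reliably weighted neighborhoods -- the natural cores of complexes.  Scores
are never updated during detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .weighting import WeightedNetwork

__all__ = ["weighted_degree", "ngcc", "seed_score", "build_seed_queue", "SeedQueue"]


@dataclass
class SeedQueue:
    """Nodes ordered by non-increasing score, ties broken by node id."""

    entries: list[tuple[str, float]]
    visited: set[str] = field(default_factory=set)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _check_node(wnet: WeightedNetwork, v: str) -> None:
    if v not in wnet:
        raise ValueError(f"node {v!r} is not in the network")


def weighted_degree(wnet: WeightedNetwork, v: str) -> float:
    """Sum of the weights of the edges incident to ``v``."""
    _check_node(wnet, v)
    return sum(data["weight"] for _, _, data in wnet.edges(v, data=True))


def ngcc(wnet: WeightedNetwork, v: str) -> float:
    """Neighborhood graph clustering coefficient of ``v``, in [0, 1].

    Sum of the weights of all edges with both endpoints in
    ``V_v = {v} ∪ N(v)`` (each edge once) over ``|V_v|·(|V_v|-1)/2``.
    Returns 0 when ``|V_v| < 2``.
    """
    _check_node(wnet, v)
    vv = {v} | set(wnet[v])
    if len(vv) < 2:
        return 0.0
    total = sum(
        data["weight"]
        for a, b, data in wnet.subgraph(vv).edges(data=True)
    )
    return total / (len(vv) * (len(vv) - 1) / 2)


def seed_score(wnet: WeightedNetwork, v: str) -> float:
    """Seed priority of ``v``: weighted degree times NGCC."""
    return weighted_degree(wnet, v) * ngcc(wnet, v)


def build_seed_queue(wnet: WeightedNetwork) -> SeedQueue:
    """Score every node once and queue them by non-increasing score.

    Equal-score nodes are ordered lexicographically by id so the queue (and
    everything downstream) is reproducible across runs and input orderings.
    """
    scores = {v: seed_score(wnet, v) for v in wnet.nodes}
    entries = sorted(scores.items(), key=lambda item: (-item[1], item[0]))
    return SeedQueue(entries)
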