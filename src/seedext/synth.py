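"""Synthetic interaction networks with planted, annotated complexes.

The generator emulates the structure the detection model assumes: groups of
proteins that are densely wired among themselves (edge probability
``p_within``), sparsely wired to the rest of the network (``p_between``),
and functionally coherent -- each planted complex owns a few private GO
terms that most of its members carry, while background proteins draw terms
from a shared noise vocabulary.  Planted complexes may overlap by sharing a
member with the previously planted complex.

Every planted complex is regenerated until its internal edges form a
connected subgraph: a disconnected "complex" could never be recovered as a
single cluster, so it would only measure an impossibility of the benchmark,
not of the detector.  All randomness flows through one ``numpy`` generator
seeded by ``rng_seed``, so outputs are byte-identical across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .ppin_io import AnnotationTable, ComplexSet, RawNetwork

__all__ = ["PlantedNetworkSpec", "generate", "toy_fixtures", "GraphFixture", "PairFixture"]

#: noise terms drawn by each background protein
_NOISE_TERMS_PER_NODE = 2


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Parameters of a planted-complex benchmark network.

    Defaults describe a small benchmark of 10 complexes of 4-8 proteins,
    near-clique internal wiring (p_within = 0.9), weak background noise
    (p_between = 0.02), mostly coherent annotations and a modest pool of
    unaffiliated background proteins.
    """

    n_complexes: int = 10
    size_range: tuple[int, int] = (4, 8)
    overlap_fraction: float = 0.1
    p_within: float = 0.9
    p_between: float = 0.02
    n_background_nodes: int = 20
    terms_per_complex: int = 3
    annotation_coherence: float = 0.9
    noise_terms: int = 15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.size_range[0] < 3 or self.size_range[0] > self.size_range[1]:
            raise ValueError("size_range must satisfy 3 <= min <= max")
        if not (0.0 <= self.p_between < self.p_within <= 1.0):
            raise ValueError("need 0 <= p_between < p_within <= 1")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not (0.0 <= self.annotation_coherence <= 1.0):
            raise ValueError("annotation_coherence must be in [0, 1]")
        if self.n_complexes < 1:
            raise ValueError("n_complexes must be >= 1")
        if self.n_background_nodes < 0 or self.terms_per_complex < 0:
            raise ValueError("counts must be non-negative")


def _connected_internal_edges(
    members: list[str], p_within: float, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Sample within-complex edges, resampling until they connect the members."""
    pairs = list(itertools.combinations(members, 2))
    for _ in range(1000):
        mask = rng.random(len(pairs)) < p_within
        edges = [pair for pair, hit in zip(pairs, mask) if hit]
        sub = nx.Graph()
        sub.add_nodes_from(members)
        sub.add_edges_from(edges)
        if nx.is_connected(sub):
            return edges
    # p_within pathologically low for this size: wire a ring and resample extras
    ring = [(members[i], members[(i + 1) % len(members)]) for i in range(len(members))]
    mask = rng.random(len(pairs)) < p_within
    extra = [pair for pair, hit in zip(pairs, mask) if hit]
    return sorted(set(ring) | set(extra))


def generate(
    spec: PlantedNetworkSpec,
) -> tuple[RawNetwork, AnnotationTable, ComplexSet]:
    """Build (raw network, annotations, ground-truth complexes) from a spec."""
    rng = np.random.default_rng(spec.rng_seed)
    lo, hi = spec.size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_complexes)

    complexes: list[list[str]] = []
    for i, size in enumerate(sizes):
        members = [f"C{i:02d}_{j:02d}" for j in range(size)]
        if i > 0 and rng.random() < spec.overlap_fraction:
            prev = complexes[i - 1]
            members[0] = prev[int(rng.integers(len(prev)))]
        complexes.append(members)
    background = [f"B{j:02d}" for j in range(spec.n_background_nodes)]

    graph = nx.Graph()
    all_nodes = sorted({v for c in complexes for v in c} | set(background))
    graph.add_nodes_from(all_nodes)
    co_members: set[frozenset[str]] = set()
    for members in complexes:
        for a, b in itertools.combinations(members, 2):
            co_members.add(frozenset((a, b)))
    for members in complexes:
        graph.add_edges_from(_connected_internal_edges(members, spec.p_within, rng))
    cross_pairs = [
        (a, b)
        for a, b in itertools.combinations(all_nodes, 2)
        if frozenset((a, b)) not in co_members
    ]
    mask = rng.random(len(cross_pairs)) < spec.p_between
    graph.add_edges_from(pair for pair, hit in zip(cross_pairs, mask) if hit)

    annotations: dict[str, set[str]] = {}
    for i, members in enumerate(complexes):
        terms = [f"T{i:02d}_{t:02d}" for t in range(spec.terms_per_complex)]
        for v in members:
            for term in terms:
                if rng.random() < spec.annotation_coherence:
                    annotations.setdefault(v, set()).add(term)
    noise_pool = [f"NOISE_{t:02d}" for t in range(spec.noise_terms)]
    for v in background:
        if noise_pool:
            k = min(_NOISE_TERMS_PER_NODE, len(noise_pool))
            for term in rng.choice(noise_pool, size=k, replace=False):
                annotations.setdefault(v, set()).add(str(term))

    truth = ComplexSet([frozenset(c) for c in complexes])
    table = AnnotationTable({p: frozenset(t) for p, t in sorted(annotations.items())})
    return graph, table, truth


def default_benchmark(seed: int) -> tuple[RawNetwork, AnnotationTable, ComplexSet]:
    """The default planted benchmark with only the RNG seed varied."""
    return generate(replace(PlantedNetworkSpec(), rng_seed=seed))


# ---------------------------------------------------------------------------
# hand-built worked examples
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GraphFixture:
    """A small pre-weighted graph with its hand-derived detection outcome."""

    name: str
    weighted: nx.Graph
    expected_complexes: tuple[frozenset[str], ...]
    note: str = ""


@dataclass(frozen=True)
class PairFixture:
    """A predicted/reference complex pair with its expected overlap score."""

    name: str
    predicted: frozenset[str]
    reference: frozenset[str]
    expected_os: float


def _unit_clique(labels: list[str]) -> nx.Graph:
    g = nx.Graph()
    for a, b in itertools.combinations(labels, 2):
        g.add_edge(a, b, weight=1.0)
    return g


def toy_fixtures() -> dict[str, GraphFixture | PairFixture]:
    """Named hand-built graphs with expected outputs, used across the tests.

    The weighted graphs are consumed directly by the detection stage (their
    weights are set by hand, bypassing the weighting step).
    """
    fixtures: dict[str, GraphFixture | PairFixture] = {}

    k4 = _unit_clique(["a", "b", "c", "d"])
    k4p = k4.copy()
    k4p.add_edge("a", "p", weight=0.1)
    fixtures["k4_pendant"] = GraphFixture(
        "k4_pendant", k4p, (frozenset("abcd"),),
        "weakly attached pendant is rejected by the fitness test; the "
        "pendant-seeded 5-node cluster is suppressed as redundant",
    )

    two = _unit_clique(["a", "b", "c", "d"])
    two.update(_unit_clique(["w", "x", "y", "z"]))
    fixtures["two_k4"] = GraphFixture(
        "two_k4", two, (frozenset("abcd"), frozenset("wxyz")),
        "disjoint unit cliques are recovered independently",
    )

    tri = _unit_clique(["a", "b", "c"])
    tri.add_edge("a", "p", weight=0.8)
    fixtures["triangle_pendant"] = GraphFixture(
        "triangle_pendant", tri, (frozenset("abc"),),
        "pendant weight 0.8 stalls pendant-seeded growth at size 2, which is "
        "discarded by the minimum-size filter",
    )

    eleven = frozenset(f"RNASE{i:02d}" for i in range(11))
    fixtures["os100"] = PairFixture("os100", eleven, eleven, 1.0)

    fixtures["empty"] = GraphFixture("empty", nx.Graph(), ())
    return fixtures
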