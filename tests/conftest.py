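from __future__ import annotations

import random

import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def random_annotated_graph(seed: int, n_max: int = 50):
    """A random raw graph plus random annotations, for oracle comparisons.

    Returns (edge set, term map, node set).  Self-loop-free by construction;
    some proteins are left unannotated on purpose.
    """
    rng = random.Random(seed)
    n = rng.randint(4, n_max)
    p = rng.uniform(0.05, 0.3)
    graph = nx.gnp_random_graph(n, p, seed=seed)
    mapping = {i: f"P{i:02d}" for i in graph.nodes}
    edges = {tuple(sorted((mapping[a], mapping[b]))) for a, b in graph.edges}
    nodes = {mapping[i] for i in graph.nodes if graph.degree(i) > 0}
    edges = {e for e in edges if e[0] in nodes and e[1] in nodes}
    vocab = [f"T{t}" for t in range(rng.randint(2, 8))]
    terms: dict[str, set[str]] = {}
    for v in sorted(nodes):
        if rng.random() < 0.8:
            k = rng.randint(1, len(vocab))
            terms[v] = set(rng.sample(vocab, k))
    return edges, terms, nodes


def random_weighted_graph(seed: int, n_max: int = 40) -> nx.Graph:
    """A random graph with uniform (0, 1] edge weights."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max))
    p = float(rng.uniform(0.1, 0.4))
    graph = nx.gnp_random_graph(n, p, seed=seed + 1)
    out = nx.Graph()
    out.add_nodes_from(f"N{i:02d}" for i in graph.nodes)
    for a, b in graph.edges:
        out.add_edge(f"N{a:02d}", f"N{b:02d}", weight=float(rng.uniform(0.01, 1.0)))
    return out


@pytest.fixture(scope="session")
def fixtures():
    from seedext.synth import toy_fixtures

    return toy_fixtures()
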