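"""Edge reliability weighting of a protein interaction network.

Each retained edge (v, u) gets a weight in (0, 1] combining two signals:

* a common-neighbor score
  ``CN(v,u) = sqrt(|N(v) ∩ N(u)|^2 / (|N(v)| * |N(u)|))`` -- the topological
  plausibility of the interaction, high when the endpoints share much of
  their neighborhoods;
* a flat GO-term overlap score
  ``GO(v,u) = |GO(v) ∩ GO(u)| / max(min(|GO(v)|, |GO(u)|), Average(GO))``
  when the term sets intersect, else 0.  ``Average(GO)`` is the mean
  annotation count over the network's annotated proteins and penalizes
  similarity claims based on very sparsely annotated proteins.

The edge weight is the arithmetic mean ``w = (CN + GO) / 2``; edges for which
both components vanish are treated as noise and deleted, and nodes isolated
by the pruning are dropped.
"""

from __future__ import annotations

import logging
import math

import networkx as nx

from .ppin_io import AnnotationTable, RawNetwork

__all__ = [
    "DegenerateAnnotationError",
    "common_neighbor_weight",
    "average_annotation_count",
    "go_similarity",
    "build_weighted_network",
]

log = logging.getLogger(__name__)

#: Graph with per-edge reliability ``weight`` attributes in (0, 1].
WeightedNetwork = nx.Graph


class DegenerateAnnotationError(ValueError):
    """No network protein carries any GO annotation."""


def common_neighbor_weight(net: RawNetwork, v: str, u: str) -> float:
    """Common-neighbor reliability of the pair (v, u), in [0, 1].

    ``N(v)`` is the full adjacency set of ``v`` (it includes ``u`` when the
    pair is an edge); the shared neighborhood never contains the endpoints
    themselves.  Returns 0 when either endpoint has no neighbors or the
    neighborhoods are disjoint.
    """
    if v == u:
        raise ValueError("common_neighbor_weight is undefined for v == u")
    nv = set(net[v])
    nu = set(net[u])
    if not nv or not nu:
        return 0.0
    shared = len(nv & nu)
    if shared == 0:
        return 0.0
    return math.sqrt(shared * shared / (len(nv) * len(nu)))


def average_annotation_count(annot: AnnotationTable, net: RawNetwork) -> float:
    """Mean GO-term count over the network proteins that have >= 1 term.

    Only annotated proteins enter both the numerator and the denominator;
    proteins in the annotation table but absent from the network do not
    contribute.

    Raises
    ------
    DegenerateAnnotationError
        If no network protein is annotated; callers fall back to
        topology-only weights (GO component 0 everywhere).
    """
    counts = [annot.n_terms(v) for v in net.nodes if annot.n_terms(v) >= 1]
    if not counts:
        raise DegenerateAnnotationError("no annotated protein in the network")
    return sum(counts) / len(counts)


def go_similarity(annot: AnnotationTable, avg: float, v: str, u: str) -> float:
    """Flat GO-term overlap similarity of proteins v and u, in [0, 1].

    ``avg`` is the network-wide mean annotation count (``Average(GO)``); the
    denominator ``max(min(|GO(v)|, |GO(u)|), avg)`` pulls sparsely annotated
    pairs toward the average so that a single shared term among one-term
    proteins cannot claim perfect similarity.  Zero when the term sets are
    disjoint or either protein is unannotated.
    """
    if avg <= 0:
        raise ValueError("avg must be positive")
    tv = annot.terms(v)
    tu = annot.terms(u)
    shared = len(tv & tu)
    if shared == 0:
        return 0.0
    return shared / max(min(len(tv), len(tu)), avg)


def build_weighted_network(net: RawNetwork, annot: AnnotationTable) -> WeightedNetwork:
    """Weight every edge by (CN + GO) / 2 and prune zero-weight edges.

    ``Average(GO)`` is computed once over the input network before any
    pruning.  Nodes left without incident edges after pruning are removed.
    The result is built in sorted node/edge order so that all later
    floating-point accumulations are independent of input file line order.
    """
    try:
        avg = average_annotation_count(annot, net)
    except DegenerateAnnotationError:
        avg = None
        log.warning("no annotated network protein; using topology-only weights")

    weighted = nx.Graph()
    n_pruned = 0
    for v, u in sorted(tuple(sorted(e)) for e in net.edges):
        cn = common_neighbor_weight(net, v, u)
        go = go_similarity(annot, avg, v, u) if avg is not None else 0.0
        w = (go + cn) / 2.0
        if w > 0.0:
            weighted.add_edge(v, u, weight=w)
        else:
            n_pruned += 1
    # canonical node iteration order for deterministic downstream sums
    canonical = nx.Graph()
    canonical.add_nodes_from(sorted(weighted.nodes))
    canonical.add_edges_from(
        (v, u, {"weight": weighted[v][u]["weight"]})
        for v, u in sorted(tuple(sorted(e)) for e in weighted.edges)
    )
    n_node_drop = net.number_of_nodes() - canonical.number_of_nodes()
    log.info(
        "build_weighted_network: kept %d/%d edges (%d pruned), dropped %d isolated nodes",
        canonical.number_of_edges(), net.number_of_edges(), n_pruned, n_node_drop,
    )
    return canonical
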