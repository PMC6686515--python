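"""Seed-driven greedy growth of protein complexes.

For each seed taken from the score-ordered queue, a cluster is grown by
alternating two phases until a full pass changes nothing:

* **extend** -- among the cluster's outside neighbors, the candidate that
  maximizes ``weight_avg(SG ∪ {p})`` is tried; it is accepted iff the move
  strictly increases the fitness ``F`` *and* its actual edge count into the
  cluster exceeds the expectation edge ``F(SG)·|SG|`` (fitness and size
  taken before the move).  The phase ends the first time the top-priority
  candidate fails.
* **correct** -- symmetric removal of boundary members (members with at least
  one outside neighbor), prioritized by ``weight_avg(SG \\ {p})``; a removal
  must strictly increase ``F`` and satisfy the configured connectivity test
  against the expectation edge.

Because every accepted move strictly increases ``F`` and the subsets of a
finite graph are finite, growth terminates; a pass cap is kept purely as a
safety valve.  Grown clusters below the minimum size are discarded, kept
clusters mark their members as visited (so their nodes are skipped as future
seeds but may still be absorbed by other seeds -- output complexes can
overlap), and finally near-duplicate complexes are suppressed by a pairwise
overlap-score scan in fitness order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .complex_model import Cluster, fitness, weight_avg
from .evaluation import overlap_score
from .ppin_io import ComplexSet
from .seeding import build_seed_queue
from .weighting import WeightedNetwork

__all__ = [
    "DetectionConfig",
    "DetectionResult",
    "neighbors_of_cluster",
    "inner_nodes",
    "grow_cluster",
    "detect_complexes",
    "remove_redundant",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    """Tunables of the detection stage.

    ``removal_connectivity`` selects the direction of the correct-phase
    connectivity test: ``"literal"`` requires the removed node's actual edges
    into the remaining cluster to *exceed* the expectation edge (the same
    direction as the add test), ``"inverted"`` requires them to fall short.
    The fitness-increase condition applies in both modes.
    """

    min_size: int = 3
    redundancy_threshold: float = 0.8
    removal_connectivity: str = "literal"
    max_passes: int = 100

    def __post_init__(self) -> None:
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if not (0.0 < self.redundancy_threshold <= 1.0):
            raise ValueError("redundancy_threshold must be in (0, 1]")
        if self.removal_connectivity not in ("literal", "inverted"):
            raise ValueError("removal_connectivity must be 'literal' or 'inverted'")
        if self.max_passes < 1:
            raise ValueError("max_passes must be >= 1")


@dataclass
class DetectionResult:
    """Final complexes plus provenance diagnostics."""

    complexes: ComplexSet
    seed_of: list[str] = field(default_factory=list)
    passes_of: list[int] = field(default_factory=list)
    n_seeds_grown: int = 0
    n_discarded_small: int = 0
    n_discarded_redundant: int = 0


def neighbors_of_cluster(wnet: WeightedNetwork, cluster: Cluster) -> set[str]:
    """Nodes outside the cluster adjacent to at least one member."""
    out: set[str] = set()
    for v in cluster.members:
        out.update(u for u in wnet[v] if u not in cluster.members)
    return out


def inner_nodes(wnet: WeightedNetwork, cluster: Cluster) -> set[str]:
    """Members with at least one neighbor outside the cluster."""
    return {
        v
        for v in cluster.members
        if any(u not in cluster.members for u in wnet[v])
    }


def _actual_edges(wnet: WeightedNetwork, node: str, members: frozenset[str]) -> int:
    """Number of cluster members adjacent to ``node`` (unweighted count)."""
    return sum(1 for u in wnet[node] if u in members and u != node)


def _extend_phase(wnet: WeightedNetwork, cluster: Cluster, trace: list[float]) -> Cluster:
    while True:
        candidates = neighbors_of_cluster(wnet, cluster)
        if not candidates:
            return cluster
        best = min(
            candidates,
            key=lambda p: (-weight_avg(cluster.with_node(p)), p),
        )
        f_before = fitness(cluster)
        trial = cluster.with_node(best)
        accepted = (
            fitness(trial) > f_before
            and _actual_edges(wnet, best, cluster.members) > f_before * len(cluster)
        )
        if not accepted:
            return cluster
        cluster = trial
        trace.append(fitness(cluster))


def _correct_phase(
    wnet: WeightedNetwork, cluster: Cluster, cfg: DetectionConfig, trace: list[float]
) -> Cluster:
    while True:
        candidates = inner_nodes(wnet, cluster)
        if not candidates:
            return cluster
        best = min(
            candidates,
            key=lambda p: (-weight_avg(cluster.without_node(p)), p),
        )
        f_before = fitness(cluster)
        trial = cluster.without_node(best)
        actual = _actual_edges(wnet, best, trial.members)
        expectation = f_before * len(cluster)
        if cfg.removal_connectivity == "literal":
            connectivity_ok = actual > expectation
        else:
            connectivity_ok = actual < expectation
        if not (fitness(trial) > f_before and connectivity_ok):
            return cluster
        cluster = trial
        trace.append(fitness(cluster))


def _grow_traced(
    wnet: WeightedNetwork, seed: str, cfg: DetectionConfig
) -> tuple[Cluster, int, list[float]]:
    if seed not in wnet:
        raise ValueError(f"seed {seed!r} is not in the network")
    cluster = Cluster(wnet, [seed])
    trace = [fitness(cluster)]
    passes = 0
    for _ in range(cfg.max_passes):
        passes += 1
        before = cluster.members
        cluster = _extend_phase(wnet, cluster, trace)
        cluster = _correct_phase(wnet, cluster, cfg, trace)
        if cluster.members == before:
            break
    else:
        log.warning("grow_cluster hit the pass cap (%d) at seed %r", cfg.max_passes, seed)
    return cluster, passes, trace


def grow_cluster(
    wnet: WeightedNetwork, seed: str, cfg: DetectionConfig | None = None
) -> Cluster:
    """Grow a locally optimal cluster from ``seed``.

    The returned cluster admits no single permitted add or remove move that
    both passes its tests and strictly increases the fitness.
    """
    cluster, _, _ = _grow_traced(wnet, seed, cfg or DetectionConfig())
    return cluster


def remove_redundant(cs: ComplexSet, threshold: float) -> ComplexSet:
    """Suppress near-duplicate complexes by pairwise overlap score.

    Complexes are examined in non-increasing score order (ties: original
    order); a complex is kept iff its overlap score with every already-kept
    complex stays below ``threshold``.  The survivors are returned in their
    original (detection) order with their scores.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    scores = cs.scores if cs.scores is not None else [0.0] * len(cs)
    order = sorted(range(len(cs)), key=lambda i: (-scores[i], i))
    kept: list[int] = []
    for i in order:
        if all(overlap_score(cs[i], cs[j]) < threshold for j in kept):
            kept.append(i)
    kept.sort()
    return ComplexSet([cs[i] for i in kept], [scores[i] for i in kept])


def detect_complexes(
    wnet: WeightedNetwork, cfg: DetectionConfig | None = None
) -> DetectionResult:
    """Run the full seed queue and return the filtered complex list.

    Seeds already inside a kept complex are skipped; clusters discarded for
    size (or exact duplication) do *not* mark their members visited, so those
    nodes remain available as later seeds.  Nodes are never removed from the
    network, hence complexes may overlap.
    """
    cfg = cfg or DetectionConfig()
    queue = build_seed_queue(wnet)
    visited: set[str] = set()
    seen_exact: set[frozenset[str]] = set()
    members_list: list[frozenset[str]] = []
    fitness_list: list[float] = []
    seeds: list[str] = []
    passes: list[int] = []
    n_grown = n_small = 0
    for node, _score in queue:
        if node in visited:
            continue
        cluster, n_passes, _trace = _grow_traced(wnet, node, cfg)
        n_grown += 1
        if len(cluster) < cfg.min_size:
            n_small += 1
            continue
        if cluster.members in seen_exact:
            continue
        seen_exact.add(cluster.members)
        members_list.append(cluster.members)
        fitness_list.append(fitness(cluster))
        seeds.append(node)
        passes.append(n_passes)
        visited |= cluster.members
    candidates = ComplexSet(members_list, fitness_list)
    final = remove_redundant(candidates, cfg.redundancy_threshold)
    kept_members = set(final.complexes)
    kept_idx = [i for i, m in enumerate(members_list) if m in kept_members]
    result = DetectionResult(
        complexes=final,
        seed_of=[seeds[i] for i in kept_idx],
        passes_of=[passes[i] for i in kept_idx],
        n_seeds_grown=n_grown,
        n_discarded_small=n_small,
        n_discarded_redundant=len(candidates) - len(final),
    )
    log.info(
        "detect_complexes: %d seeds grown, %d kept (%d too small, %d redundant)",
        n_grown, len(final), n_small, result.n_discarded_redundant,
    )
    return result
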