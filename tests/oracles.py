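"""Independent naive reference implementations used as test oracles.

Everything here is written from the definitions alone, by direct
enumeration, and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools
import math
from math import comb


# --- weighting -------------------------------------------------------------

def naive_cn(edges: set[tuple[str, str]], v: str, u: str) -> float:
    """Common-neighbor score from an explicit edge set."""
    def neighbors(x):
        out = set()
        for a, b in edges:
            if a == x:
                out.add(b)
            if b == x:
                out.add(a)
        return out

    nv, nu = neighbors(v), neighbors(u)
    if not nv or not nu:
        return 0.0
    shared = len(nv & nu)
    if shared == 0:
        return 0.0
    return math.sqrt(shared**2 / (len(nv) * len(nu)))


def naive_average_go(terms: dict[str, set[str]], nodes: set[str]) -> float:
    counts = [len(terms[v]) for v in nodes if v in terms and len(terms[v]) >= 1]
    return sum(counts) / len(counts)


def naive_go(terms: dict[str, set[str]], avg: float, v: str, u: str) -> float:
    tv = terms.get(v, set())
    tu = terms.get(u, set())
    inter = len(tv & tu)
    if inter == 0:
        return 0.0
    return inter / max(min(len(tv), len(tu)), avg)


def naive_weights(
    edges: set[tuple[str, str]], terms: dict[str, set[str]], nodes: set[str]
) -> dict[frozenset[str], float]:
    """Edge -> weight map after (CN+GO)/2 combination and zero pruning."""
    annotated = [v for v in nodes if terms.get(v)]
    avg = naive_average_go(terms, nodes) if annotated else None
    out: dict[frozenset[str], float] = {}
    for a, b in edges:
        cn = naive_cn(edges, a, b)
        go = naive_go(terms, avg, a, b) if avg is not None else 0.0
        w = (cn + go) / 2
        if w > 0:
            out[frozenset((a, b))] = w
    return out


# --- seeding ---------------------------------------------------------------

def naive_weighted_degree(wedges: dict[frozenset[str], float], v: str) -> float:
    return sum(w for e, w in wedges.items() if v in e)


def naive_ngcc(wedges: dict[frozenset[str], float], v: str) -> float:
    vv = {v} | {next(iter(e - {v})) for e in wedges if v in e}
    if len(vv) < 2:
        return 0.0
    total = sum(w for e, w in wedges.items() if e <= vv)
    return total / (len(vv) * (len(vv) - 1) / 2)


def naive_score(wedges: dict[frozenset[str], float], v: str) -> float:
    return naive_weighted_degree(wedges, v) * naive_ngcc(wedges, v)


# --- complex model ---------------------------------------------------------

def naive_in_out(
    wedges: dict[frozenset[str], float], members: set[str]
) -> tuple[float, float]:
    internal = sum(w for e, w in wedges.items() if e <= members)
    external = sum(w for e, w in wedges.items() if len(e & members) == 1)
    return internal, external


def naive_density(wedges, members) -> float:
    n = len(members)
    if n < 2:
        return 0.0
    internal, _ = naive_in_out(wedges, members)
    return internal / (n * (n - 1) / 2)


def naive_modularity(wedges, members) -> float:
    internal, external = naive_in_out(wedges, members)
    if internal + external == 0:
        return 0.0
    return internal / (internal + external)


def naive_fitness(wedges, members) -> float:
    d = naive_density(wedges, members)
    m = naive_modularity(wedges, members)
    return (d + m + math.sqrt(d * m)) / 3


def naive_weight_avg(wedges, members) -> float:
    internal, _ = naive_in_out(wedges, members)
    return 2 * internal / len(members)


# --- hypergeometric tail by exhaustive enumeration -------------------------

def enumerate_tail(k: int, n_total: int, f_group: int, c_size: int) -> float:
    """P(at least k group members in a random C-subset), by enumeration."""
    population = list(range(n_total))
    group = set(range(f_group))
    hits = total = 0
    for subset in itertools.combinations(population, c_size):
        total += 1
        if len(group.intersection(subset)) >= k:
            hits += 1
    return hits / total if total else 1.0


def tail_table(n_total: int, f_group: int, c_size: int) -> list[float]:
    """P(X >= k) for k = 0..min(F, C), one enumeration pass."""
    group = set(range(f_group))
    kmax = min(f_group, c_size)
    hist = [0] * (kmax + 1)
    total = 0
    for subset in itertools.combinations(range(n_total), c_size):
        total += 1
        hist[len(group.intersection(subset))] += 1
    tails = []
    for k in range(kmax + 1):
        tails.append(sum(hist[k:]) / total)
    return tails


def exact_tail(k: int, n_total: int, f_group: int, c_size: int) -> float:
    """Closed-form tail sum, an independent second oracle."""
    total = comb(n_total, c_size)
    acc = 0
    for i in range(k, min(f_group, c_size) + 1):
        acc += comb(f_group, i) * comb(n_total - f_group, c_size - i)
    return acc / total


# --- local optimality ------------------------------------------------------

def assert_locally_optimal(
    wedges: dict[frozenset[str], float],
    nodes: set[str],
    members: set[str],
    removal_connectivity: str = "literal",
) -> None:
    """Check no single permitted move passing its tests increases fitness."""
    f0 = naive_fitness(wedges, members)
    size = len(members)

    def degree_into(p: str, target: set[str]) -> int:
        return sum(1 for e in wedges if p in e and (e - {p}) <= target)

    neighbors = {
        next(iter(e - {m}))
        for m in members
        for e in wedges
        if m in e and not (e <= members)
    } - members
    for p in neighbors:
        f1 = naive_fitness(wedges, members | {p})
        if f1 > f0 and degree_into(p, members) > f0 * size:
            raise AssertionError(f"add move {p} improves fitness {f0} -> {f1}")
    inner = {
        m for m in members
        if any(m in e and next(iter(e - {m})) not in members for e in wedges)
    }
    for p in inner:
        rest = members - {p}
        f1 = naive_fitness(wedges, rest)
        actual = degree_into(p, rest)
        if removal_connectivity == "literal":
            conn = actual > f0 * size
        else:
            conn = actual < f0 * size
        if f1 > f0 and conn:
            raise AssertionError(f"remove move {p} improves fitness {f0} -> {f1}")
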