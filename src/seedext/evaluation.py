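"""Evaluation of predicted complexes against a reference catalogue.

Matching-based metrics
    A predicted complex ``p`` matches a reference ``g`` when the overlap
    score ``OS(p,g) = |p ∩ g|^2 / (|p|·|g|)`` reaches the threshold ω
    (0.2 by default, matching common practice).  Precision is the fraction
    of predictions matched by some reference, recall the fraction of
    references matched by some prediction, and the F-measure their harmonic
    mean.  Matching is one-to-many: a reference may credit several
    predictions and vice versa.

Size-weighted Jaccard
    For each predicted complex, the best Jaccard coefficient against any
    reference is averaged, weighted by complex size (``JaccardI``); symmetric
    for references (``JaccardS``); ``Jaccard`` is their harmonic mean.  These
    grade the *quality* of overlaps rather than thresholded hits.

Functional enrichment
    For each detected complex and each GO term annotating at least one of
    its members, the hypergeometric tail probability that a random set of
    the same size drawn from the network contains at least as many carriers
    of the term; Bonferroni-corrected per complex, significant below α=0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import hypergeom

from .ppin_io import AnnotationTable, ComplexSet

__all__ = [
    "MatchResult",
    "EvaluationReport",
    "EnrichmentResult",
    "overlap_score",
    "match_and_score",
    "jaccard_measures",
    "enrichment_pvalue",
    "enrich_complexes",
]

log = logging.getLogger(__name__)


def overlap_score(p: frozenset[str] | set[str], g: frozenset[str] | set[str]) -> float:
    """Overlap score |p ∩ g|^2 / (|p|·|g|), in [0, 1]."""
    if not p or not g:
        raise ValueError("overlap_score is undefined for empty sets")
    shared = len(set(p) & set(g))
    return shared * shared / (len(p) * len(g))


@dataclass
class MatchResult:
    """Per-side best overlap scores and match counts at threshold ω."""

    best_os_predicted: list[float]
    best_os_reference: list[float]
    ncp: int
    ncg: int
    precision: float
    recall: float
    f_measure: float


def match_and_score(
    pred: ComplexSet, ref: ComplexSet, omega: float = 0.2
) -> MatchResult:
    """Threshold-based matching of predicted vs reference complexes.

    A predicted complex counts as matched (toward ``ncp``) if *any* reference
    reaches ``OS >= omega`` (inclusive boundary), and symmetrically for
    ``ncg``.  Empty collections yield all-zero metrics with a warning.
    """
    if not (0.0 < omega <= 1.0):
        raise ValueError("omega must be in (0, 1]")
    if len(pred) == 0 or len(ref) == 0:
        log.warning("match_and_score: empty prediction or reference set")
        return MatchResult([], [], 0, 0, 0.0, 0.0, 0.0)
    best_p = [max(overlap_score(p, g) for g in ref) for p in pred]
    best_g = [max(overlap_score(p, g) for p in pred) for g in ref]
    ncp = sum(1 for s in best_p if s >= omega)
    ncg = sum(1 for s in best_g if s >= omega)
    precision = ncp / len(pred)
    recall = ncg / len(ref)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return MatchResult(best_p, best_g, ncp, ncg, precision, recall, f)


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    return len(a & b) / len(a | b)


def jaccard_measures(pred: ComplexSet, ref: ComplexSet) -> tuple[float, float, float]:
    """Size-weighted best-match Jaccard averages and their harmonic mean."""
    if len(pred) == 0 or len(ref) == 0:
        log.warning("jaccard_measures: empty prediction or reference set")
        return 0.0, 0.0, 0.0
    ji_num = sum(len(p) * max(_jaccard(p, g) for g in ref) for p in pred)
    ji = ji_num / sum(len(p) for p in pred)
    js_num = sum(len(g) * max(_jaccard(p, g) for p in pred) for g in ref)
    js = js_num / sum(len(g) for g in ref)
    jac = 2 * ji * js / (ji + js) if ji + js > 0 else 0.0
    return ji, js, jac


@dataclass
class EvaluationReport:
    """All matching metrics of one predicted-vs-reference comparison."""

    precision: float
    recall: float
    f_measure: float
    jaccard_i: float
    jaccard_s: float
    jaccard: float
    ncp: int = 0
    ncg: int = 0
    n_predicted: int = 0
    n_reference: int = 0


def evaluate(pred: ComplexSet, ref: ComplexSet, omega: float = 0.2) -> EvaluationReport:
    """Convenience wrapper combining matching and Jaccard metrics."""
    m = match_and_score(pred, ref, omega)
    ji, js, jac = jaccard_measures(pred, ref)
    return EvaluationReport(
        m.precision, m.recall, m.f_measure, ji, js, jac,
        m.ncp, m.ncg, len(pred), len(ref),
    )


def enrichment_pvalue(k: int, n_network: int, f_group: int, c_size: int) -> float:
    """Hypergeometric tail P(X >= k) for a functional group.

    ``n_network`` proteins in the background, ``f_group`` of them carrying the
    term, a complex of ``c_size`` proteins of which ``k`` carry the term.
    Evaluated as the survival function at k-1 (numerically stable); k = 0
    gives 1 exactly.
    """
    if not (0 <= k <= min(f_group, c_size)):
        raise ValueError("k must satisfy 0 <= k <= min(F, C)")
    if not (0 <= f_group <= n_network and 0 < c_size <= n_network):
        raise ValueError("need F <= N and 0 < C <= N")
    return float(hypergeom.sf(k - 1, n_network, f_group, c_size))


@dataclass
class EnrichmentResult:
    """Per-(complex, term) tests plus per-complex and binned summaries.

    ``rows`` holds tuples
    ``(complex_index, term, k, C, F, N, p_raw, p_corrected)``; the Bonferroni
    factor is the number of terms tested for that complex.  ``min_corrected``
    is the per-complex minimum corrected p (None when no term was testable).
    Binned counts follow the conventional report thresholds
    1e-15, 1e-10, 1e-5 and α.
    """

    rows: list[tuple[int, str, int, int, int, int, float, float]]
    min_corrected: list[float | None]
    significant: list[bool]
    alpha: float
    bins: dict[str, int] = field(default_factory=dict)
    mean_min_pvalue: float | None = None


def enrich_complexes(
    pred: ComplexSet,
    annot: AnnotationTable,
    network_nodes: set[str],
    alpha: float = 0.01,
) -> EnrichmentResult:
    """Hypergeometric GO enrichment of each complex against the network.

    The background ``N`` is the analyzed network's protein count; a term's
    group size ``F`` counts its annotated carriers *within the network*.
    Correction is Bonferroni per complex (over that complex's tested terms).
    """
    network_nodes = set(network_nodes)
    n_network = len(network_nodes)
    term_count: dict[str, int] = {}
    for v in network_nodes:
        for t in annot.terms(v):
            term_count[t] = term_count.get(t, 0) + 1
    rows: list[tuple[int, str, int, int, int, int, float, float]] = []
    min_corr: list[float | None] = []
    significant: list[bool] = []
    for idx, complex_members in enumerate(pred):
        # members outside the analyzed network are not part of the urn model
        inside = complex_members & network_nodes
        c_size = len(inside)
        carriers: dict[str, int] = {}
        for v in inside:
            for t in annot.terms(v):
                carriers[t] = carriers.get(t, 0) + 1
        n_tests = len(carriers)
        best: float | None = None
        for term in sorted(carriers):
            k = carriers[term]
            f_group = term_count[term]
            p = enrichment_pvalue(k, n_network, f_group, c_size)
            p_corr = min(1.0, p * n_tests)
            rows.append((idx, term, k, c_size, f_group, n_network, p, p_corr))
            if best is None or p_corr < best:
                best = p_corr
        min_corr.append(best)
        significant.append(best is not None and best < alpha)
    tested = [p for p in min_corr if p is not None]
    bins = {
        "<1e-15": sum(1 for p in tested if p < 1e-15),
        "<1e-10": sum(1 for p in tested if p < 1e-10),
        "<1e-5": sum(1 for p in tested if p < 1e-5),
        "significant": sum(significant),
    }
    mean_min = sum(tested) / len(tested) if tested else None
    return EnrichmentResult(rows, min_corr, significant, alpha, bins, mean_min)
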