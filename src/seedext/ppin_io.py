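"""Reading and writing the flat-file artifacts of a complex-detection run.

Three formats are supported, all plain text:

* **edge lists** -- two (or more) whitespace/tab-separated columns of protein
  identifiers, ``#`` comment lines allowed.  Loading removes self-interactions
  and collapses repeated interactions, the standard preprocessing for raw
  interaction downloads.
* **annotation tables** -- ``protein<TAB>term[<TAB>namespace]`` rows mapping
  proteins to GO term identifiers, optionally restricted to a set of
  namespaces (e.g. ``{"BP", "MF"}``).
* **complex files** -- one complex per line, whitespace-separated member ids
  (the layout used by CYC2008-style gold standards).

Identifiers are opaque, case-sensitive strings; no id-mapping is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import networkx as nx

__all__ = [
    "ParseError",
    "AnnotationTable",
    "ComplexSet",
    "read_edge_list",
    "read_annotations",
    "read_complexes",
    "write_complexes",
    "write_edge_list",
]

log = logging.getLogger(__name__)

#: A deduplicated simple undirected graph of protein ids (the "raw" network).
RawNetwork = nx.Graph


class ParseError(ValueError):
    """A malformed line in one of the flat-file formats."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class AnnotationTable:
    """Protein -> set-of-GO-term map with opaque term ids.

    Every stored protein maps to a non-empty term set; proteins absent from
    the table are simply unannotated (``terms`` returns an empty set).
    No ontology traversal is performed: two terms are similar iff equal.
    """

    terms_by_protein: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for protein, terms in self.terms_by_protein.items():
            if not terms:
                raise ValueError(f"protein {protein!r} has an empty term set")

    def terms(self, protein: str) -> frozenset[str]:
        return self.terms_by_protein.get(protein, frozenset())

    def n_terms(self, protein: str) -> int:
        return len(self.terms(protein))

    def __contains__(self, protein: str) -> bool:
        return protein in self.terms_by_protein

    def __len__(self) -> int:
        return len(self.terms_by_protein)


@dataclass
class ComplexSet:
    """An ordered collection of complexes (protein-id sets).

    Order is meaningful and stable: detected complexes are listed in detection
    order, reference complexes in file order.  ``scores`` optionally carries a
    per-complex quality value (fitness for detected complexes).
    """

    complexes: list[frozenset[str]] = field(default_factory=list)
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        if any(not c for c in self.complexes):
            raise ValueError("complexes must be non-empty sets")
        if self.scores is not None and len(self.scores) != len(self.complexes):
            raise ValueError("scores length must match complexes length")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.complexes[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ComplexSet):
            return NotImplemented
        return self.complexes == other.complexes


def _iter_lines(source: str | Path | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as handle:
            yield from handle
    else:
        yield from source


def read_edge_list(source: str | Path | IO[str] | Iterable[str]) -> RawNetwork:
    """Load an interaction edge list into a deduplicated simple graph.

    Self-interactions are dropped, repeated interactions (in either node
    order) are collapsed, and the counts of both are logged.  Proteins that
    appear only in self-loops are not added as isolated nodes: they can never
    enter a complex of size >= 3 and carry no usable topology.

    Raises
    ------
    ParseError
        If a non-comment, non-blank line has fewer than two fields.
    """
    graph = nx.Graph()
    n_self = n_dup = 0
    for lineno, line in enumerate(_iter_lines(source), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < 2:
            raise ParseError("expected at least 2 fields", lineno)
        a, b = fields[0], fields[1]
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b)
    log.info(
        "read_edge_list: %d nodes, %d edges (%d self-loops and %d duplicates dropped)",
        graph.number_of_nodes(), graph.number_of_edges(), n_self, n_dup,
    )
    return graph


def read_annotations(
    source: str | Path | IO[str] | Iterable[str],
    namespaces: set[str] | None = None,
) -> AnnotationTable:
    """Load a protein->GO-term table, optionally restricted to namespaces.

    The namespace filter only applies to rows that carry a third column; when
    ``namespaces`` is None every row is kept.  Duplicate (protein, term) pairs
    collapse to one.
    """
    table: dict[str, set[str]] = {}
    for lineno, line in enumerate(_iter_lines(source), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < 2:
            raise ParseError("expected at least 2 fields", lineno)
        protein, term = fields[0], fields[1]
        if namespaces is not None and len(fields) >= 3 and fields[2] not in namespaces:
            continue
        table.setdefault(protein, set()).add(term)
    return AnnotationTable({p: frozenset(t) for p, t in table.items()})


def read_complexes(source: str | Path | IO[str] | Iterable[str]) -> ComplexSet:
    """Load a one-complex-per-line file; blank lines are skipped."""
    complexes: list[frozenset[str]] = []
    for line in _iter_lines(source):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        complexes.append(frozenset(stripped.split()))
    return ComplexSet(complexes)


def write_complexes(cs: ComplexSet, target: str | Path | IO[str]) -> None:
    """Write one complex per line, members sorted lexicographically."""
    lines = [" ".join(sorted(c)) + "\n" for c in cs]
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as handle:
            handle.writelines(lines)
    else:
        target.writelines(lines)


def write_edge_list(
    graph: nx.Graph,
    target: str | Path | IO[str],
    weighted: bool = False,
) -> None:
    """Write a graph as a TSV edge list in canonical (sorted) order.

    With ``weighted=True`` a third column carries the edge ``weight``
    attribute printed with 6 decimals.
    """
    rows = sorted(tuple(sorted(e)) for e in graph.edges())
    lines = []
    for a, b in rows:
        if weighted:
            lines.append(f"{a}\t{b}\t{graph[a][b]['weight']:.6f}\n")
        else:
            lines.append(f"{a}\t{b}\n")
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as handle:
            handle.writelines(lines)
    else:
        target.writelines(lines)


def unannotated_network_proteins(graph: nx.Graph, annot: AnnotationTable) -> set[str]:
    """Network proteins with no GO annotation (treated as term set = {})."""
    missing = {v for v in graph.nodes if v not in annot}
    if missing:
        log.info("%d network proteins have no GO annotation", len(missing))
    return missing
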