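"""Ontology parsing, gene aggregation and term sampling.

Reads OBO 1.2/1.4 structure files and gene annotations (GAF 2.1/2.2 or a
two-column TSV), builds the term DAG over a configurable set of relation
types (``is_a`` and ``part_of`` by default), and exposes the operations the
rest of the pipeline needs: per-term gene aggregation over descendants,
ancestor queries, and seeded sampling of terms by aggregated gene-set size.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, TextIO

import networkx as nx

from gsnamer.errors import OboParseError, OntologyStructureError, UnknownTermError

logger = logging.getLogger(__name__)

#: Relation types followed when building the child->parent graph.
DEFAULT_RELATIONS: tuple[str, ...] = ("is_a", "part_of")

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


@dataclass
class OntologyTerm:
    """A single ontology term (node in the DAG)."""

    term_id: str
    name: str = ""
    namespace: str | None = None
    parent_ids: list[str] = field(default_factory=list)
    obsolete: bool = False


@dataclass
class Ontology:
    """An ontology DAG plus direct (non-propagated) gene annotations.

    ``child_to_parents`` holds (child, parent) edges over retained relation
    types only.  ``direct_annotations`` maps term ids to the genes annotated
    directly to that term; use :func:`aggregate_genes` for the propagated
    gene set.
    """

    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    child_to_parents: list[tuple[str, str]] = field(default_factory=list)
    direct_annotations: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._parents: dict[str, set[str]] = {tid: set() for tid in self.terms}
        self._children: dict[str, set[str]] = {tid: set() for tid in self.terms}
        for child, parent in self.child_to_parents:
            self._parents[child].add(parent)
            self._children[parent].add(child)

    # -- structural queries -------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def parents_of(self, term_id: str) -> set[str]:
        self._require(term_id)
        return set(self._parents[term_id])

    def children_of(self, term_id: str) -> set[str]:
        self._require(term_id)
        return set(self._children[term_id])

    def descendants(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` via child edges (proper)."""
        self._require(term_id)
        seen: set[str] = set()
        stack = list(self._children[term_id])
        while stack:
            node = stack.pop()
            if node not in seen:
                seen.add(node)
                stack.extend(self._children[node])
        return seen

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` via parent edges (proper)."""
        self._require(term_id)
        seen: set[str] = set()
        stack = list(self._parents[term_id])
        while stack:
            node = stack.pop()
            if node not in seen:
                seen.add(node)
                stack.extend(self._parents[node])
        return seen

    def term_pool(self, namespace: str | None = None) -> list[str]:
        """Non-obsolete term ids, optionally restricted to one branch, sorted."""
        return sorted(
            tid
            for tid, term in self.terms.items()
            if not term.obsolete and (namespace is None or term.namespace == namespace)
        )

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise UnknownTermError(term_id)


# ---------------------------------------------------------------------------
# OBO parsing
# ---------------------------------------------------------------------------


def _iter_stanzas(lines: Iterable[str]) -> Iterator[tuple[str, list[tuple[int, str, str]]]]:
    """Yield (stanza_type, [(line_no, tag, value), ...]); header is stanza ''."""
    stanza_type = ""
    tags: list[tuple[int, str, str]] = []
    for line_no, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        # strip trailing OBO comments, respecting escaped '!'
        if "!" in line and not line.lstrip().startswith("!"):
            line = line.split("!", 1)[0]
        line = line.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("[") and line.endswith("]"):
            yield stanza_type, tags
            stanza_type = line[1:-1]
            tags = []
            continue
        if ":" not in line:
            raise OboParseError(f"malformed tag line {line!r}", line_number=line_no)
        tag, value = line.split(":", 1)
        tags.append((line_no, tag.strip(), value.strip()))
    yield stanza_type, tags


def parse_obo(
    stream: TextIO | Iterable[str],
    namespace_filter: str | None = None,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> Ontology:
    """Parse an OBO 1.2/1.4 document into an :class:`Ontology`.

    Parameters
    ----------
    stream:
        Text stream or iterable of lines.
    namespace_filter:
        If given, terms of other branches are dropped entirely.
    relations:
        Relation types retained as child->parent edges.  ``is_a`` is read
        from ``is_a`` tags; everything else from ``relationship`` tags.

    Obsolete terms are retained (flagged, with parents cleared) so that
    look-ups do not fail, but they never enter sampling pools.
    """
    if namespace_filter is not None and namespace_filter not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace_filter!r}")
    relations = tuple(relations)

    terms: dict[str, OntologyTerm] = {}
    default_namespace: str | None = None

    for stanza_type, tags in _iter_stanzas(stream):
        if stanza_type == "":
            for _, tag, value in tags:
                if tag == "default-namespace":
                    default_namespace = value
            continue
        if stanza_type != "Term":
            continue
        term_id: str | None = None
        name = ""
        namespace: str | None = None
        parent_ids: list[str] = []
        obsolete = False
        first_line = tags[0][0] if tags else 0
        for line_no, tag, value in tags:
            if tag == "id":
                term_id = value
            elif tag == "name":
                name = value
            elif tag == "namespace":
                namespace = value
            elif tag == "is_obsolete":
                obsolete = value.lower() == "true"
            elif tag == "is_a" and "is_a" in relations:
                parent_ids.append(value.split()[0])
            elif tag == "relationship":
                parts = value.split()
                if len(parts) < 2:
                    raise OboParseError(
                        f"malformed relationship {value!r}", line_number=line_no
                    )
                rel, target = parts[0], parts[1]
                if rel in relations:
                    parent_ids.append(target)
        if term_id is None:
            raise OboParseError("[Term] stanza without an id", line_number=first_line)
        if namespace is None:
            namespace = default_namespace
        if obsolete:
            parent_ids = []
        if term_id in terms:
            raise OboParseError(f"duplicate term id {term_id}", line_number=first_line)
        terms[term_id] = OntologyTerm(
            term_id=term_id,
            name=name,
            namespace=namespace,
            parent_ids=parent_ids,
            obsolete=obsolete,
        )

    if namespace_filter is not None:
        terms = {
            tid: t for tid, t in terms.items() if t.namespace == namespace_filter
        }

    # drop dangling parent references (cross-branch or filtered-out targets)
    edges: list[tuple[str, str]] = []
    for term in terms.values():
        kept = [p for p in term.parent_ids if p in terms]
        term.parent_ids = kept
        edges.extend((term.term_id, p) for p in kept)

    graph = nx.DiGraph(edges)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise OntologyStructureError(f"ontology graph contains a cycle: {cycle}")

    return Ontology(terms=terms, child_to_parents=edges)


# ---------------------------------------------------------------------------
# Annotation loading
# ---------------------------------------------------------------------------


def parse_gaf(
    stream: TextIO | Iterable[str],
    evidence_codes: Iterable[str] | None = None,
) -> dict[str, set[str]]:
    """Parse GAF 2.1/2.2 into a term_id -> gene-symbol mapping.

    Column 3 is the symbol, column 5 the term, column 7 the evidence code;
    ``!`` lines are comments.  Rows whose qualifier contains ``NOT`` are
    skipped.  ``evidence_codes`` optionally restricts to an allowlist (no
    filtering by default).
    """
    allow = set(evidence_codes) if evidence_codes is not None else None
    annotations: dict[str, set[str]] = {}
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 7:
            continue
        symbol, qualifier, term_id, evidence = cols[2], cols[3], cols[4], cols[6]
        if "NOT" in qualifier.split("|"):
            continue
        if allow is not None and evidence not in allow:
            continue
        symbol = symbol.strip()
        if not symbol or any(ch.isspace() for ch in symbol):
            logger.warning("skipping malformed gene symbol %r", symbol)
            continue
        annotations.setdefault(term_id, set()).add(symbol)
    return annotations


def parse_annotations_tsv(stream: TextIO | Iterable[str]) -> dict[str, set[str]]:
    """Parse a two-column ``term_id<TAB>gene_symbol`` file (``#`` comments)."""
    annotations: dict[str, set[str]] = {}
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise OboParseError(
                f"expected term_id<TAB>gene_symbol, got {line!r}", line_number=line_no
            )
        term_id, symbol = cols[0].strip(), cols[1].strip()
        if not symbol or any(ch.isspace() for ch in symbol):
            logger.warning("skipping malformed gene symbol %r at line %d", symbol, line_no)
            continue
        annotations.setdefault(term_id, set()).add(symbol)
    return annotations


def attach_annotations(
    ont: Ontology, annotations: Mapping[str, Iterable[str]]
) -> Ontology:
    """Attach direct annotations, dropping terms absent from the ontology.

    Unknown term ids are counted and logged (common when annotations span
    all branches but the ontology was branch-filtered).
    """
    dropped = 0
    for term_id, genes in annotations.items():
        if term_id not in ont.terms:
            dropped += 1
            continue
        ont.direct_annotations.setdefault(term_id, set()).update(genes)
    if dropped:
        logger.info("dropped annotations for %d unknown term ids", dropped)
    return ont


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def aggregate_genes(ont: Ontology, term_id: str) -> set[str]:
    """Genes annotated to ``term_id`` or to any of its descendants."""
    if term_id not in ont.terms:
        raise UnknownTermError(term_id)
    genes = set(ont.direct_annotations.get(term_id, ()))
    for descendant in ont.descendants(term_id):
        genes.update(ont.direct_annotations.get(descendant, ()))
    return genes


def is_ancestor(ont: Ontology, candidate: str, query: str) -> bool:
    """True iff ``candidate`` is a proper ancestor of ``query``."""
    if candidate not in ont.terms:
        raise UnknownTermError(candidate)
    if query not in ont.terms:
        raise UnknownTermError(query)
    return candidate in ont.ancestors(query)


def filter_and_sample_terms(
    ont: Ontology,
    min_size: int,
    max_size: int,
    n: int,
    seed: int,
    namespace: str | None = None,
) -> list[str]:
    """Sample ``n`` term ids whose aggregated gene-set size is in bounds.

    Bounds are inclusive.  Obsolete terms are never eligible.  Sampling is
    uniform without replacement and reproducible under ``seed``; if fewer
    than ``n`` terms are eligible, all of them are returned (sorted).
    """
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    if n < 0:
        raise ValueError("n must be >= 0")
    eligible = [
        tid
        for tid in ont.term_pool(namespace)
        if min_size <= len(aggregate_genes(ont, tid)) <= max_size
    ]
    if n >= len(eligible):
        return eligible
    rng = random.Random(seed)
    return rng.sample(eligible, n)


def annotation_pool(ont: Ontology) -> set[str]:
    """Union of all directly annotated genes — the contamination background."""
    pool: set[str] = set()
    for genes in ont.direct_annotations.values():
        pool.update(genes)
    return pool
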