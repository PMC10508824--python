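"""Deterministic test scaffolding: toy ontologies, scripted LLMs, hash embedder.

Everything here is seeded and bit-reproducible so full pipeline runs can be
exercised with zero network access and no model weights.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence
import random

import numpy as np

from gsnamer.citations import PublicationRecord
from gsnamer.errors import GsnamerError
from gsnamer.llm_interface import UNRELATED_SENTINEL
from gsnamer.ontology import Ontology, OntologyTerm, attach_annotations, parse_obo

SENTINEL_RESPONSE = f"Process: {UNRELATED_SENTINEL} (0.00)"


# ---------------------------------------------------------------------------
# Toy ontology generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyOntologySpec:
    """Parameters for a seeded synthetic ontology.

    ``max_aggregate`` caps the gene universe, which bounds every term's
    aggregated gene-set size from above; ``min_genes`` bounds direct (and
    hence aggregated) sizes from below.
    """

    n_terms: int = 12
    depth: int = 3
    min_genes: int = 3
    max_genes: int = 10
    seed: int = 7
    max_aggregate: int = 100
    namespace: str = "biological_process"

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise GsnamerError("n_terms must be >= 1")
        if self.depth < 1 or self.depth > self.n_terms:
            raise GsnamerError("depth must be in [1, n_terms]")
        if not 1 <= self.min_genes <= self.max_genes:
            raise GsnamerError("need 1 <= min_genes <= max_genes")
        if self.max_genes > self.max_aggregate:
            raise GsnamerError("max_genes cannot exceed max_aggregate")


class ToyOntologyResult(NamedTuple):
    ontology: Ontology
    obo_path: Path | None
    annotations_path: Path | None


def make_toy_ontology(
    spec: ToyOntologySpec, out_dir: str | Path | None = None
) -> ToyOntologyResult:
    """Generate a seeded toy ontology; optionally write OBO + TSV files.

    The first ``depth`` terms form a parent chain (guaranteeing the
    requested depth); each later term attaches to a random earlier term, so
    the graph is acyclic by construction.  Direct genes are sampled from a
    universe of ``max_aggregate`` symbols, which keeps every aggregated
    gene set within [min_genes, max_aggregate].
    """
    rng = random.Random(spec.seed)
    universe = [f"GENE{i:04d}" for i in range(spec.max_aggregate)]

    terms: dict[str, OntologyTerm] = {}
    edges: list[tuple[str, str]] = []
    annotations: dict[str, set[str]] = {}
    ids = [f"TOY:{i:07d}" for i in range(spec.n_terms)]
    for i, term_id in enumerate(ids):
        parents: list[str] = []
        if 0 < i < spec.depth:
            parents = [ids[i - 1]]
        elif i >= spec.depth:
            parents = [ids[rng.randrange(i)]]
        terms[term_id] = OntologyTerm(
            term_id=term_id,
            name=f"synthetic process {i:04d}",
            namespace=spec.namespace,
            parent_ids=parents,
        )
        edges.extend((term_id, p) for p in parents)
        n_genes = rng.randint(spec.min_genes, spec.max_genes)
        annotations[term_id] = set(rng.sample(universe, n_genes))

    ontology = Ontology(terms=terms, child_to_parents=edges)
    attach_annotations(ontology, annotations)

    obo_path: Path | None = None
    tsv_path: Path | None = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        obo_path = out_dir / "toy.obo"
        tsv_path = out_dir / "toy_annotations.tsv"
        write_obo(ontology, obo_path)
        write_annotations_tsv(ontology, tsv_path)
    return ToyOntologyResult(ontology, obo_path, tsv_path)


def write_obo(ont: Ontology, path: str | Path) -> None:
    """Serialize an ontology as a minimal OBO 1.2 document."""
    lines = ["format-version: 1.2", ""]
    for term_id in sorted(ont.terms):
        term = ont.terms[term_id]
        lines.append("[Term]")
        lines.append(f"id: {term.term_id}")
        lines.append(f"name: {term.name}")
        if term.namespace:
            lines.append(f"namespace: {term.namespace}")
        for parent in term.parent_ids:
            lines.append(f"is_a: {parent} ! {ont.terms[parent].name}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_annotations_tsv(ont: Ontology, path: str | Path) -> None:
    """Serialize direct annotations as ``term_id<TAB>gene`` lines."""
    lines = []
    for term_id in sorted(ont.direct_annotations):
        for gene in sorted(ont.direct_annotations[term_id]):
            lines.append(f"{term_id}\t{gene}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def load_toy_ontology(obo_path: str | Path, tsv_path: str | Path) -> Ontology:
    """Re-load a written toy ontology (round-trip of :func:`make_toy_ontology`)."""
    from gsnamer.ontology import parse_annotations_tsv

    with open(obo_path) as fh:
        ontology = parse_obo(fh)
    with open(tsv_path) as fh:
        attach_annotations(ontology, parse_annotations_tsv(fh))
    return ontology


# ---------------------------------------------------------------------------
# Scripted LLM backends
# ---------------------------------------------------------------------------


def gene_fingerprint(genes: Iterable[str]) -> str:
    """Stable fingerprint of a gene set (sorted, newline-joined, hashed)."""
    digest = hashlib.sha256("\n".join(sorted(genes)).encode("utf-8")).hexdigest()
    return digest[:16]


_PROTEIN_LINE_RE = re.compile(r"^Proteins:\s*(?P<genes>.+)$", re.MULTILINE)


def genes_from_prompt(prompt: str) -> list[str] | None:
    """Extract the query gene list from a built prompt (last Proteins: line)."""
    matches = _PROTEIN_LINE_RE.findall(prompt)
    if not matches:
        return None
    return [g.strip() for g in matches[-1].split(",") if g.strip()]


class ScriptedLLM:
    """Backend mapping gene-set fingerprints to canned responses.

    Fingerprinting the sorted gene list (rather than the whole prompt)
    keeps scripts valid across prompt-template edits.  Unknown fingerprints
    yield the unrelated-proteins sentinel response.
    """

    def __init__(
        self,
        script: Mapping[str, str] | None = None,
        default: str = SENTINEL_RESPONSE,
        model_id: str = "scripted",
    ):
        self.script = dict(script or {})
        self.default = default
        self.model_id = model_id
        self.calls = 0

    @classmethod
    def from_gene_sets(
        cls, responses: Mapping[tuple[str, ...] | frozenset, str], **kwargs
    ) -> "ScriptedLLM":
        """Build a script keyed by gene collections instead of fingerprints."""
        script = {gene_fingerprint(genes): text for genes, text in responses.items()}
        return cls(script=script, **kwargs)

    def complete(
        self, model: str, prompt: str, temperature: float, seed: int, max_tokens: int
    ) -> str:
        self.calls += 1
        genes = genes_from_prompt(prompt)
        if genes is None:
            return self.default
        return self.script.get(gene_fingerprint(genes), self.default)


class ScriptedResponder:
    """Backend matching prompt substrings to canned replies, in rule order.

    Used for citation-pipeline tests where prompts carry paragraphs rather
    than gene lists.
    """

    def __init__(
        self,
        rules: Sequence[tuple[str, str]],
        default: str = "genes: none | keywords: none",
        model_id: str = "scripted-responder",
    ):
        self.rules = list(rules)
        self.default = default
        self.model_id = model_id
        self.calls = 0

    def complete(
        self, model: str, prompt: str, temperature: float, seed: int, max_tokens: int
    ) -> str:
        self.calls += 1
        for needle, response in self.rules:
            if needle in prompt:
                return response
        return self.default


class FlakyBackend:
    """Raises ``failures`` times before delegating; exercises retry logic."""

    def __init__(self, inner, failures: int):
        self.inner = inner
        self.remaining_failures = failures
        self.model_id = inner.model_id

    def complete(self, model, prompt, temperature, seed, max_tokens):
        if self.remaining_failures > 0:
            self.remaining_failures -= 1
            raise ConnectionError("synthetic transport failure")
        return self.inner.complete(model, prompt, temperature, seed, max_tokens)


# ---------------------------------------------------------------------------
# Hash-bag embedding backend
# ---------------------------------------------------------------------------


class HashEmbedder:
    """Token-hash bag-of-words embedder.

    Tokens are lowercased alphanumeric runs hashed into a fixed-dimension
    count vector.  Identical strings embed identically (cosine 1.0) and
    token-disjoint strings are orthogonal barring hash collisions (the
    default dimension makes collisions negligible for test corpora).
    """

    def __init__(self, dim: int = 65536):
        if dim < 1:
            raise GsnamerError("dim must be positive")
        self.dim = dim

    def _index(self, token: str) -> int:
        digest = hashlib.blake2s(token.encode("utf-8"), digest_size=4).digest()
        return int.from_bytes(digest, "big") % self.dim

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        vectors = np.zeros((len(texts), self.dim))
        for row, text in enumerate(texts):
            for token in re.findall(r"[a-z0-9]+", text.lower()):
                vectors[row, self._index(token)] += 1.0
        return vectors


# ---------------------------------------------------------------------------
# Canned PubMed client
# ---------------------------------------------------------------------------


class CannedPubMedClient:
    """PubMed stand-in serving pre-recorded records.

    ``records`` maps query expressions to hit lists; unknown queries return
    no hits.  ``default`` serves as a fallback corpus for any query.
    """

    def __init__(
        self,
        records: Mapping[str, Sequence[PublicationRecord]] | None = None,
        default: Sequence[PublicationRecord] = (),
    ):
        self.records = {k: list(v) for k, v in (records or {}).items()}
        self.default = list(default)
        self.queries: list[str] = []

    def search(self, query: str, retmax: int = 20) -> list[PublicationRecord]:
        self.queries.append(query)
        hits = self.records.get(query, self.default)
        return list(hits[:retmax])
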