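"""Literature support for analysis essays: a five-step citation pipeline.

Per essay paragraph: (1) an LLM extracts gene symbols and up to three
function keywords; (2) the keywords are assembled into a PubMed query;
(3) the query is run, sorted by relevance; (4) hits are re-ranked by the
number of query genes mentioned in the abstract; (5) the LLM judges
whether each of the top hits supports the paragraph.  Paragraphs lacking
a gene symbol or a keyword are skipped with the ``unknown`` sentinel.
"""

from __future__ import annotations

import logging
import re
import time
from dataclasses import dataclass, replace
from typing import Protocol, Sequence, runtime_checkable

from gsnamer.errors import GsnamerError, ResponseParseError
from gsnamer.llm_interface import LLMBackend, PromptConfig, query

logger = logging.getLogger(__name__)

#: Sentinel returned for paragraphs that cannot be queried.
UNKNOWN = "unknown"

MAX_KEYWORDS = 3
DEFAULT_TOP_K = 3
DEFAULT_RETMAX = 20

KEYWORD_PROMPT_TEMPLATE = """\
You are an assistant to a molecular biologist annotating an analysis paragraph.
From the paragraph below, extract two types of keywords:
(1) gene symbols explicitly mentioned in the paragraph, and
(2) up to three keywords associated with gene functions or biological processes, ordered by importance.
Reply on a single line in exactly this format:
genes: <comma-separated gene symbols or 'none'> | keywords: <semicolon-separated keywords or 'none'>
Example paragraph: "SNX6 and SNX12 are sorting nexins acting in retromer-dependent endosomal sorting."
Example reply: genes: SNX6, SNX12 | keywords: endosomal sorting; retromer
Paragraph:
{paragraph}"""

SUPPORT_PROMPT_TEMPLATE = """\
You are an assistant to a molecular biologist verifying citations.
Decide whether the publication's title or abstract provides evidence for one
or more statements of fact in the analysis paragraph.  The publication need
not be primarily about the statement; a supporting fact is sufficient.
Reply on a single line in exactly this format:
support: <yes|no> | basis: <title|abstract|both|none>
Title: {title}
Abstract: {abstract}
Paragraph:
{paragraph}"""


@dataclass(frozen=True)
class KeywordExtraction:
    """Gene symbols and ordered function keywords extracted from a paragraph."""

    gene_symbols: tuple[str, ...]
    function_keywords: tuple[str, ...]

    @property
    def valid(self) -> bool:
        return len(self.gene_symbols) >= 1 and len(self.function_keywords) >= 1


@dataclass(frozen=True)
class PublicationRecord:
    """A PubMed hit with its search rank and gene-mention re-ranking count."""

    pmid: str
    title: str
    abstract: str = ""
    relevance_rank: int = 0
    gene_mention_count: int = 0


@dataclass(frozen=True)
class CitationVerdict:
    pmid: str
    supported: bool
    basis: str = "none"

    def __post_init__(self) -> None:
        if self.basis not in ("title", "abstract", "both", "none"):
            raise GsnamerError(f"invalid basis {self.basis!r}")
        if self.supported and self.basis == "none":
            raise GsnamerError("a supported verdict requires a basis")


@runtime_checkable
class PubMedClient(Protocol):
    """Contract: run a relevance-sorted search, return publication records."""

    def search(self, query: str, retmax: int = DEFAULT_RETMAX) -> list[PublicationRecord]: ...


# ---------------------------------------------------------------------------
# Step 1: keyword extraction
# ---------------------------------------------------------------------------

_EXTRACTION_RE = re.compile(
    r"genes\s*:\s*(?P<genes>.*?)\s*\|\s*keywords\s*:\s*(?P<keywords>.*)",
    re.IGNORECASE | re.DOTALL,
)


def parse_extraction_reply(reply: str) -> KeywordExtraction:
    """Parse a ``genes: ... | keywords: ...`` backend reply."""
    match = _EXTRACTION_RE.search(reply)
    if match is None:
        raise ResponseParseError("no 'genes: ... | keywords: ...' line found", raw=reply)

    def _split(text: str, sep: str) -> tuple[str, ...]:
        if text.strip().lower() in ("", "none", "n/a"):
            return ()
        return tuple(part.strip() for part in text.split(sep) if part.strip())

    genes = _split(match.group("genes"), ",")
    keywords = _split(match.group("keywords"), ";")
    if len(keywords) > MAX_KEYWORDS:
        logger.warning(
            "truncating %d keywords to the first %d", len(keywords), MAX_KEYWORDS
        )
        keywords = keywords[:MAX_KEYWORDS]
    return KeywordExtraction(gene_symbols=genes, function_keywords=keywords)


def extract_keywords(
    backend: LLMBackend,
    paragraph: str,
    cfg: PromptConfig | None = None,
) -> KeywordExtraction | str:
    """Extract symbols/keywords from a paragraph; ``UNKNOWN`` when invalid.

    An invalid extraction (missing genes or keywords) yields the sentinel;
    an unparsable reply raises :class:`ResponseParseError`.
    """
    if not paragraph.strip():
        raise GsnamerError("paragraph must be non-empty")
    cfg = cfg or PromptConfig()
    prompt = KEYWORD_PROMPT_TEMPLATE.format(paragraph=paragraph)
    reply = query(backend, cfg, prompt)
    extraction = parse_extraction_reply(reply)
    if not extraction.valid:
        return UNKNOWN
    return extraction


# ---------------------------------------------------------------------------
# Step 2: query assembly
# ---------------------------------------------------------------------------


def _sanitize_phrase(phrase: str) -> str:
    cleaned = phrase.replace('"', "").strip()
    if cleaned != phrase:
        logger.warning("sanitized keyword %r -> %r", phrase, cleaned)
    return cleaned


def build_query(extraction: KeywordExtraction) -> str:
    """PubMed expression: (genes OR'd) AND (quoted keywords OR'd)."""
    if not extraction.valid:
        raise GsnamerError("cannot build a query from an invalid extraction")
    gene_clause = " OR ".join(
        f"{gene}[Title/Abstract]" for gene in extraction.gene_symbols
    )
    keyword_clause = " OR ".join(
        f'"{_sanitize_phrase(kw)}"[Title/Abstract]'
        for kw in extraction.function_keywords
    )
    return f"({gene_clause}) AND ({keyword_clause})"


# ---------------------------------------------------------------------------
# Step 4: re-ranking by gene mentions
# ---------------------------------------------------------------------------


def count_gene_mentions(text: str, genes: Sequence[str]) -> int:
    """Distinct query genes matched case-insensitively at word boundaries."""
    count = 0
    for gene in genes:
        if re.search(rf"\b{re.escape(gene)}\b", text, re.IGNORECASE):
            count += 1
    return count


def rank_publications(
    records: Sequence[PublicationRecord],
    genes: Sequence[str],
    top_k: int = DEFAULT_TOP_K,
) -> list[PublicationRecord]:
    """Sort by (gene mentions in abstract desc, relevance rank asc), truncate."""
    annotated = [
        replace(r, gene_mention_count=count_gene_mentions(r.abstract, genes))
        for r in records
    ]
    annotated.sort(key=lambda r: (-r.gene_mention_count, r.relevance_rank))
    return annotated[:top_k]


# ---------------------------------------------------------------------------
# Step 5: support judgment
# ---------------------------------------------------------------------------

_VERDICT_RE = re.compile(
    r"support\s*:\s*(?P<support>yes|no)\s*(?:\|\s*basis\s*:\s*(?P<basis>title|abstract|both|none))?",
    re.IGNORECASE,
)


def parse_verdict_reply(reply: str, pmid: str) -> CitationVerdict:
    match = _VERDICT_RE.search(reply)
    if match is None:
        raise ResponseParseError("no 'support: yes|no' line found", raw=reply)
    supported = match.group("support").lower() == "yes"
    basis = (match.group("basis") or "").lower()
    if supported and basis in ("", "none"):
        raise ResponseParseError(
            "affirmative verdict without a title/abstract basis", raw=reply
        )
    if not supported:
        basis = "none"
    return CitationVerdict(pmid=pmid, supported=supported, basis=basis)


def judge_support(
    backend: LLMBackend,
    record: PublicationRecord,
    paragraph: str,
    cfg: PromptConfig | None = None,
) -> CitationVerdict:
    """Ask the backend whether a publication supports the paragraph."""
    if not record.title:
        raise GsnamerError("publication record must carry a title")
    cfg = cfg or PromptConfig()
    prompt = SUPPORT_PROMPT_TEMPLATE.format(
        title=record.title, abstract=record.abstract or "(no abstract)", paragraph=paragraph
    )
    reply = query(backend, cfg, prompt)
    return parse_verdict_reply(reply, pmid=record.pmid)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def cite_paragraph(
    backend: LLMBackend,
    pubmed_client: PubMedClient,
    paragraph: str,
    cfg: PromptConfig | None = None,
    top_k: int = DEFAULT_TOP_K,
    retmax: int = DEFAULT_RETMAX,
) -> list[PublicationRecord] | str:
    """Run steps 1-5 for one paragraph.

    Returns the verdict-supported records among the top ``top_k``
    re-ranked hits, an empty list when the search finds nothing, or the
    ``UNKNOWN`` sentinel when the paragraph yields no usable keywords.
    """
    extraction = extract_keywords(backend, paragraph, cfg=cfg)
    if extraction == UNKNOWN:
        return UNKNOWN
    assert isinstance(extraction, KeywordExtraction)
    pubmed_query = build_query(extraction)
    records = pubmed_client.search(pubmed_query, retmax=retmax)
    if not records:
        return []
    ranked = rank_publications(records, extraction.gene_symbols, top_k=top_k)
    supported: list[PublicationRecord] = []
    for record in ranked:
        verdict = judge_support(backend, record, paragraph, cfg=cfg)
        if verdict.supported:
            supported.append(record)
    return supported


def cite_essay(
    backend: LLMBackend,
    pubmed_client: PubMedClient,
    paragraphs: Sequence[str],
    cfg: PromptConfig | None = None,
    top_k: int = DEFAULT_TOP_K,
    retmax: int = DEFAULT_RETMAX,
) -> list[dict]:
    """Cite every paragraph, isolating per-paragraph failures."""
    results: list[dict] = []
    for index, paragraph in enumerate(paragraphs):
        entry: dict = {"paragraph_index": index, "paragraph": paragraph}
        try:
            outcome = cite_paragraph(
                backend, pubmed_client, paragraph, cfg=cfg, top_k=top_k, retmax=retmax
            )
        except GsnamerError as exc:
            logger.warning("paragraph %d failed: %s", index, exc)
            entry["error"] = str(exc)
            results.append(entry)
            continue
        if outcome == UNKNOWN:
            entry["status"] = UNKNOWN
            entry["citations"] = []
        else:
            assert isinstance(outcome, list)
            entry["status"] = "cited" if outcome else "no_support"
            entry["citations"] = [
                {
                    "pmid": r.pmid,
                    "title": r.title,
                    "gene_mention_count": r.gene_mention_count,
                }
                for r in outcome
            ]
        results.append(entry)
    return results


class EntrezPubMedClient:
    """Live PubMed E-utilities client (requires ``biopython`` and network).

    Results are relevance-sorted; a polite delay is inserted between
    requests.  Not exercised by the offline test suite.
    """

    def __init__(self, email: str, api_key: str | None = None, delay: float = 0.4):
        try:
            from Bio import Entrez
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise GsnamerError("EntrezPubMedClient requires 'biopython'") from exc
        self._entrez = Entrez
        self._entrez.email = email
        if api_key:
            self._entrez.api_key = api_key
        self.delay = delay

    def search(
        self, query: str, retmax: int = DEFAULT_RETMAX
    ) -> list[PublicationRecord]:  # pragma: no cover - network
        entrez = self._entrez
        handle = entrez.esearch(db="pubmed", term=query, sort="relevance", retmax=retmax)
        pmids = entrez.read(handle)["IdList"]
        handle.close()
        if not pmids:
            return []
        time.sleep(self.delay)
        handle = entrez.efetch(db="pubmed", id=",".join(pmids), rettype="xml")
        articles = entrez.read(handle)["PubmedArticle"]
        handle.close()
        time.sleep(self.delay)
        records = []
        for rank, article in enumerate(articles):
            citation = article["MedlineCitation"]
            art = citation["Article"]
            abstract = ""
            if "Abstract" in art:
                abstract = " ".join(str(t) for t in art["Abstract"]["AbstractText"])
            records.append(
                PublicationRecord(
                    pmid=str(citation["PMID"]),
                    title=str(art.get("ArticleTitle", "")),
                    abstract=abstract,
                    relevance_rank=rank,
                )
            )
        return records
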