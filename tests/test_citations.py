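import pytest

from gsnamer.citations import (
    UNKNOWN,
    CitationVerdict,
    KeywordExtraction,
    PublicationRecord,
    build_query,
    cite_essay,
    cite_paragraph,
    count_gene_mentions,
    extract_keywords,
    judge_support,
    parse_extraction_reply,
    parse_verdict_reply,
    rank_publications,
)
from gsnamer.errors import GsnamerError, ResponseParseError
from gsnamer.fixtures import CannedPubMedClient, ScriptedResponder

PARAGRAPH = (
    "SNX6 and SNX12 are members of the sorting nexin family involved in "
    "endosomal sorting via the retromer complex."
)

RECORDS = [
    PublicationRecord(pmid="1", title="Retromer", abstract="Retromer coats endosomes.", relevance_rank=0),
    PublicationRecord(pmid="2", title="SNX6 in transport", abstract="SNX6 mediates endosomal sorting.", relevance_rank=1),
    PublicationRecord(pmid="3", title="Sorting nexins", abstract="SNX6 and SNX12 act in the retromer pathway.", relevance_rank=2),
    PublicationRecord(pmid="4", title="Golgi dynamics", abstract="The Golgi apparatus is dynamic.", relevance_rank=3),
    PublicationRecord(pmid="5", title="SNX12 function", abstract="SNX12 regulates sorting.", relevance_rank=4),
]


class TestParseExtractionReply:
    def test_scripted_format(self):
        extraction = parse_extraction_reply(
            "genes: SNX6, SNX12 | keywords: endosomal sorting; retromer"
        )
        assert extraction.gene_symbols == ("SNX6", "SNX12")
        assert extraction.function_keywords == ("endosomal sorting", "retromer")
        assert extraction.valid

    def test_keywords_only_invalid(self):
        extraction = parse_extraction_reply("genes: none | keywords: sorting")
        assert not extraction.valid

    def test_five_keywords_truncated_to_three(self):
        extraction = parse_extraction_reply(
            "genes: A | keywords: k1; k2; k3; k4; k5"
        )
        assert extraction.function_keywords == ("k1", "k2", "k3")

    def test_unstructured_reply_is_parse_error(self):
        with pytest.raises(ResponseParseError):
            parse_extraction_reply("I could not find anything useful.")


class TestExtractKeywords:
    def test_scripted_extraction(self):
        backend = ScriptedResponder(
            [(PARAGRAPH, "genes: SNX6, SNX12 | keywords: endosomal sorting; retromer")]
        )
        extraction = extract_keywords(backend, PARAGRAPH)
        assert isinstance(extraction, KeywordExtraction)
        assert extraction.gene_symbols == ("SNX6", "SNX12")

    def test_no_genes_returns_unknown(self):
        backend = ScriptedResponder([], default="genes: none | keywords: sorting")
        assert extract_keywords(backend, "A paragraph without genes.") == UNKNOWN

    def test_empty_paragraph_rejected(self):
        with pytest.raises(GsnamerError):
            extract_keywords(ScriptedResponder([]), "  ")


class TestBuildQuery:
    def test_single_gene_single_keyword(self):
        extraction = KeywordExtraction(("SNX6",), ("retromer",))
        assert build_query(extraction) == '(SNX6[Title/Abstract]) AND ("retromer"[Title/Abstract])'

    def test_groups_or_within_and_between(self):
        extraction = KeywordExtraction(("A", "B"), ("k1", "k2"))
        query = build_query(extraction)
        assert query == (
            '(A[Title/Abstract] OR B[Title/Abstract]) AND '
            '("k1"[Title/Abstract] OR "k2"[Title/Abstract])'
        )

    def test_quotes_sanitized(self):
        extraction = KeywordExtraction(("A",), ('sorting "nexin"',))
        assert '"sorting nexin"[Title/Abstract]' in build_query(extraction)

    def test_invalid_extraction_rejected(self):
        with pytest.raises(GsnamerError):
            build_query(KeywordExtraction((), ("k",)))


class TestRankPublications:
    def test_more_gene_mentions_first(self):
        ranked = rank_publications(RECORDS, ["SNX6", "SNX12"])
        assert ranked[0].pmid == "3"  # two genes mentioned
        assert ranked[0].gene_mention_count == 2

    def test_tie_preserves_relevance_order(self):
        ranked = rank_publications(RECORDS, ["SNX6", "SNX12"])
        # single-mention records keep search order: pmid 2 before pmid 5
        singles = [r.pmid for r in ranked if r.gene_mention_count == 1]
        assert singles == ["2", "5"]

    def test_top_k_truncation(self):
        assert len(rank_publications(RECORDS * 2, ["SNX6"], top_k=3)) == 3

    def test_output_subset_no_duplicates(self):
        ranked = rank_publications(RECORDS, ["SNX6"])
        pmids = [r.pmid for r in ranked]
        assert len(set(pmids)) == len(pmids)
        assert set(pmids) <= {r.pmid for r in RECORDS}

    def test_word_boundary_matching(self):
        assert count_gene_mentions("The SNX6-positive endosome", ["SNX6"]) == 1
        assert count_gene_mentions("snx6 acts here", ["SNX6"]) == 1
        assert count_gene_mentions("The SNX60 protein", ["SNX6"]) == 0


class TestJudgeSupport:
    def test_affirmative(self):
        backend = ScriptedResponder([("Sorting nexins", "support: yes | basis: abstract")])
        verdict = judge_support(backend, RECORDS[2], PARAGRAPH)
        assert verdict.supported and verdict.basis == "abstract"

    def test_negative(self):
        backend = ScriptedResponder([("Golgi dynamics", "support: no | basis: none")])
        verdict = judge_support(backend, RECORDS[3], PARAGRAPH)
        assert not verdict.supported and verdict.basis == "none"

    def test_title_basis_with_empty_abstract(self):
        record = PublicationRecord(pmid="9", title="SNX6 sorts cargo", abstract="")
        backend = ScriptedResponder([("SNX6 sorts cargo", "support: yes | basis: title")])
        verdict = judge_support(backend, record, PARAGRAPH)
        assert verdict.supported and verdict.basis == "title"

    def test_affirmative_without_basis_is_parse_error(self):
        with pytest.raises(ResponseParseError):
            parse_verdict_reply("support: yes", pmid="1")

    def test_supported_requires_basis_invariant(self):
        with pytest.raises(GsnamerError):
            CitationVerdict(pmid="1", supported=True, basis="none")


def _pipeline_backend():
    """Judge rules first: judge prompts also contain the paragraph, so the
    extraction rule must come last."""
    return ScriptedResponder(
        [
            ("Title: Sorting nexins", "support: yes | basis: abstract"),
            ("Title: SNX6 in transport", "support: yes | basis: both"),
            ("Title: SNX12 function", "support: no | basis: none"),
            ("Title: Retromer", "support: no | basis: none"),
            ("Title: Golgi dynamics", "support: no | basis: none"),
            (PARAGRAPH, "genes: SNX6, SNX12 | keywords: endosomal sorting; retromer"),
        ]
    )


class TestCiteParagraph:
    def test_end_to_end_two_supported(self):
        client = CannedPubMedClient(default=RECORDS)
        citations = cite_paragraph(_pipeline_backend(), client, PARAGRAPH)
        assert [c.pmid for c in citations] == ["3", "2"]

    def test_paragraph_without_genes_unknown(self):
        backend = ScriptedResponder([], default="genes: none | keywords: trafficking")
        client = CannedPubMedClient(default=RECORDS)
        assert cite_paragraph(backend, client, "No genes here.") == UNKNOWN

    def test_zero_search_results_empty_list(self):
        backend = ScriptedResponder(
            [(PARAGRAPH, "genes: SNX6 | keywords: retromer")]
        )
        client = CannedPubMedClient(default=[])
        assert cite_paragraph(backend, client, PARAGRAPH) == []

    def test_never_returns_unsupported(self):
        client = CannedPubMedClient(default=RECORDS)
        citations = cite_paragraph(_pipeline_backend(), client, PARAGRAPH)
        assert "5" not in [c.pmid for c in citations]
        assert "4" not in [c.pmid for c in citations]

    def test_deterministic_across_reruns(self):
        client = CannedPubMedClient(default=RECORDS)
        first = cite_paragraph(_pipeline_backend(), client, PARAGRAPH)
        second = cite_paragraph(_pipeline_backend(), client, PARAGRAPH)
        assert first == second


class TestCiteEssay:
    def test_failures_isolated_per_paragraph(self):
        backend = ScriptedResponder(
            [
                (PARAGRAPH, "genes: SNX6, SNX12 | keywords: retromer"),
                ("Title: Sorting nexins", "support: yes | basis: abstract"),
                ("Title: SNX6 in transport", "support: no | basis: none"),
                ("Title: SNX12 function", "support: no | basis: none"),
            ],
            default="total gibberish",
        )
        # judge prompts for records 1 and 4 fall through to gibberish -> error,
        # but only for the first paragraph; the second still returns unknown
        client = CannedPubMedClient(default=RECORDS)
        results = cite_essay(backend, client, [PARAGRAPH, "no genes"])
        assert len(results) == 2
        assert "error" in results[0]
        assert "error" in results[1]  # gibberish extraction is a parse error

    def test_mixed_essay(self):
        client = CannedPubMedClient(default=RECORDS)
        backend = ScriptedResponder(
            [
                ("Title: Sorting nexins", "support: yes | basis: abstract"),
                ("Title: SNX6 in transport", "support: no | basis: none"),
                ("Title: SNX12 function", "support: no | basis: none"),
                (PARAGRAPH, "genes: SNX6, SNX12 | keywords: retromer"),
                ("no genes", "genes: none | keywords: none"),
            ]
        )
        results = cite_essay(backend, client, [PARAGRAPH, "no genes here"])
        assert results[0]["status"] == "cited"
        assert [c["pmid"] for c in results[0]["citations"]] == ["3"]
        assert results[1]["status"] == UNKNOWN
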