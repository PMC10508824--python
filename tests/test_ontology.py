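import io
import random

import pytest

from gsnamer.errors import OboParseError, OntologyStructureError, UnknownTermError
from gsnamer.ontology import (
    Ontology,
    OntologyTerm,
    aggregate_genes,
    annotation_pool,
    attach_annotations,
    filter_and_sample_terms,
    is_ancestor,
    parse_gaf,
    parse_annotations_tsv,
    parse_obo,
)

TWO_TERM_OBO = """\
format-version: 1.2

[Term]
id: T:1
name: parent
namespace: biological_process

[Term]
id: T:2
name: child
namespace: biological_process
is_a: T:1 ! parent
"""

MIXED_BRANCH_OBO = """\
[Term]
id: T:1
name: bp one
namespace: biological_process

[Term]
id: T:2
name: bp two
namespace: biological_process
is_a: T:1

[Term]
id: T:3
name: bp three
namespace: biological_process
is_a: T:2

[Term]
id: T:4
name: mf one
namespace: molecular_function

[Term]
id: T:5
name: mf two
namespace: molecular_function
is_a: T:4
"""


class TestParseObo:
    def test_minimal_document(self):
        ont = parse_obo(io.StringIO(TWO_TERM_OBO))
        assert len(ont.terms) == 2
        assert ont.child_to_parents == [("T:2", "T:1")]
        assert ont.terms["T:2"].parent_ids == ["T:1"]

    def test_obsolete_term_retained_but_not_in_pool(self):
        obo = TWO_TERM_OBO + "\n[Term]\nid: T:9\nname: gone\nnamespace: biological_process\nis_obsolete: true\n"
        ont = parse_obo(io.StringIO(obo))
        assert ont.terms["T:9"].obsolete
        assert ont.terms["T:9"].parent_ids == []
        assert "T:9" not in ont.term_pool()

    def test_namespace_filter_hand_count(self):
        # hand count on the fixture: 3 BP terms (T:1, T:2, T:3), 2 MF terms
        ont = parse_obo(io.StringIO(MIXED_BRANCH_OBO), namespace_filter="biological_process")
        assert sorted(ont.terms) == ["T:1", "T:2", "T:3"]

    def test_malformed_tag_line_names_line(self):
        bad = "[Term]\nid: T:1\nname parent\n"
        with pytest.raises(OboParseError, match="line 3"):
            parse_obo(io.StringIO(bad))

    def test_cycle_raises_structural_error(self):
        cyclic = (
            "[Term]\nid: T:1\nname: a\nnamespace: biological_process\nis_a: T:2\n\n"
            "[Term]\nid: T:2\nname: b\nnamespace: biological_process\nis_a: T:1\n"
        )
        with pytest.raises(OntologyStructureError):
            parse_obo(io.StringIO(cyclic))

    def test_part_of_relationship_followed_by_default(self):
        obo = (
            "[Term]\nid: T:1\nname: whole\nnamespace: cellular_component\n\n"
            "[Term]\nid: T:2\nname: part\nnamespace: cellular_component\n"
            "relationship: part_of T:1\n\n"
            "[Term]\nid: T:3\nname: reg\nnamespace: cellular_component\n"
            "relationship: regulates T:1\n"
        )
        ont = parse_obo(io.StringIO(obo))
        assert ("T:2", "T:1") in ont.child_to_parents
        assert ("T:3", "T:1") not in ont.child_to_parents
        # is_a-only traversal drops the part_of edge
        ont_isa = parse_obo(io.StringIO(obo), relations=("is_a",))
        assert ont_isa.child_to_parents == []

    def test_default_namespace_header(self):
        obo = "default-namespace: molecular_function\n\n[Term]\nid: T:1\nname: x\n"
        ont = parse_obo(io.StringIO(obo))
        assert ont.terms["T:1"].namespace == "molecular_function"


class TestAnnotations:
    def test_parse_gaf_columns(self):
        gaf = (
            "!gaf-version: 2.2\n"
            "UniProtKB\tP1\tTP53\t\tGO:1\tREF\tIDA\t\tP\t\t\tprotein\ttaxon:9606\t1\tX\n"
            "UniProtKB\tP2\tBRCA1\tNOT\tGO:1\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t1\tX\n"
            "UniProtKB\tP3\tEGFR\t\tGO:2\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t1\tX\n"
        )
        parsed = parse_gaf(io.StringIO(gaf))
        assert parsed == {"GO:1": {"TP53"}, "GO:2": {"EGFR"}}

    def test_parse_gaf_evidence_allowlist(self):
        gaf = (
            "U\tP1\tTP53\t\tGO:1\tREF\tIDA\t\tP\t\t\tp\tt\t1\tX\n"
            "U\tP3\tEGFR\t\tGO:1\tREF\tIEA\t\tP\t\t\tp\tt\t1\tX\n"
        )
        parsed = parse_gaf(io.StringIO(gaf), evidence_codes={"IDA"})
        assert parsed == {"GO:1": {"TP53"}}

    def test_tsv_and_unknown_terms_dropped(self):
        ont = parse_obo(io.StringIO(TWO_TERM_OBO))
        parsed = parse_annotations_tsv(io.StringIO("T:1\tA\nT:2\tB\nT:99\tC\n"))
        attach_annotations(ont, parsed)
        assert ont.direct_annotations == {"T:1": {"A"}, "T:2": {"B"}}
        assert annotation_pool(ont) == {"A", "B"}


class TestAggregateGenes:
    def test_single_edge_union(self):
        ont = parse_obo(io.StringIO(TWO_TERM_OBO))
        attach_annotations(ont, {"T:1": {"a"}, "T:2": {"b"}})
        assert aggregate_genes(ont, "T:1") == {"a", "b"}

    def test_leaf_unchanged(self):
        ont = parse_obo(io.StringIO(TWO_TERM_OBO))
        attach_annotations(ont, {"T:1": {"a"}, "T:2": {"b"}})
        assert aggregate_genes(ont, "T:2") == {"b"}

    def test_diamond_counts_once(self, diamond_ontology):
        # brute-force reachability over the diamond: T:0 reaches all four nodes
        assert aggregate_genes(diamond_ontology, "T:0") == {"a", "b", "c", "d"}

    def test_unknown_term(self, diamond_ontology):
        with pytest.raises(UnknownTermError):
            aggregate_genes(diamond_ontology, "T:404")


def _random_dag(seed):
    """Toy DAG with random edges (child index > parent index) and genes."""
    rng = random.Random(seed)
    n = rng.randint(5, 30)
    terms, edges, annotations = {}, [], {}
    for i in range(n):
        tid = f"R:{i}"
        parents = [f"R:{j}" for j in range(i) if rng.random() < 0.25]
        terms[tid] = OntologyTerm(tid, name=f"node {i}", namespace="biological_process",
                                  parent_ids=parents)
        edges.extend((tid, p) for p in parents)
        annotations[tid] = {f"g{rng.randrange(60)}" for _ in range(rng.randint(0, 4))}
    ont = Ontology(terms=terms, child_to_parents=edges)
    attach_annotations(ont, annotations)
    return ont


@pytest.mark.parametrize("seed", range(15))
def test_aggregate_matches_bruteforce_reachability(seed):
    ont = _random_dag(seed)
    # oracle: fixed-point transitive closure over child edges
    children = {t: set() for t in ont.terms}
    for child, parent in ont.child_to_parents:
        children[parent].add(child)
    for tid in ont.terms:
        reach = {tid}
        changed = True
        while changed:
            changed = False
            for node in list(reach):
                new = children[node] - reach
                if new:
                    reach |= new
                    changed = True
        expected = set().union(*(ont.direct_annotations.get(t, set()) for t in reach))
        assert aggregate_genes(ont, tid) == expected


@pytest.mark.parametrize("seed", range(5))
def test_aggregate_monotone_along_edges(seed):
    ont = _random_dag(seed + 100)
    for child, parent in ont.child_to_parents:
        assert aggregate_genes(ont, parent) >= aggregate_genes(ont, child)


class TestFilterAndSample:
    @pytest.fixture
    def sized_ontology(self):
        terms = {}
        annotations = {}
        for i, size in enumerate([2, 3, 100, 101]):
            tid = f"S:{i}"
            terms[tid] = OntologyTerm(tid, name=f"sized {i}", namespace="biological_process")
            annotations[tid] = {f"g{i}_{k}" for k in range(size)}
        ont = Ontology(terms=terms)
        return attach_annotations(ont, annotations)

    def test_inclusive_boundaries(self, sized_ontology):
        eligible = filter_and_sample_terms(sized_ontology, 3, 100, n=10, seed=0)
        assert sorted(eligible) == ["S:1", "S:2"]

    def test_exhaustion_returns_all(self, sized_ontology):
        for seed in (0, 1, 99):
            assert sorted(filter_and_sample_terms(sized_ontology, 3, 100, 2, seed)) == ["S:1", "S:2"]

    def test_seeded_determinism(self, toy):
        a = filter_and_sample_terms(toy, 3, 100, n=5, seed=42)
        b = filter_and_sample_terms(toy, 3, 100, n=5, seed=42)
        assert a == b

    def test_coverage_over_200_seeds(self):
        terms = {f"C:{i}": OntologyTerm(f"C:{i}", name=str(i), namespace="biological_process")
                 for i in range(10)}
        ont = attach_annotations(
            Ontology(terms=terms), {f"C:{i}": {f"x{i}", f"y{i}", f"z{i}"} for i in range(10)}
        )
        seen = set()
        for seed in range(200):
            seen.update(filter_and_sample_terms(ont, 1, 10, n=1, seed=seed))
        assert seen == set(terms)


class TestIsAncestor:
    def test_direct_parent(self, diamond_ontology):
        assert is_ancestor(diamond_ontology, "T:1", "T:3")

    def test_not_own_ancestor(self, diamond_ontology):
        assert not is_ancestor(diamond_ontology, "T:3", "T:3")

    def test_grandparent_via_closure_oracle(self, diamond_ontology):
        # oracle: transitive closure over parent edges computed by hand walk
        closure = {"T:3": {"T:1", "T:2", "T:0"}, "T:1": {"T:0"}, "T:2": {"T:0"}, "T:0": set()}
        for query, ancestors in closure.items():
            for candidate in diamond_ontology.terms:
                assert is_ancestor(diamond_ontology, candidate, query) == (candidate in ancestors)

    def test_unknown_id(self, diamond_ontology):
        with pytest.raises(UnknownTermError):
            is_ancestor(diamond_ontology, "T:404", "T:3")
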