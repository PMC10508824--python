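"""Native over-representation analysis with a Jaccard effect size.

Each library term overlapping the query is scored with an upper-tail
hypergeometric p-value, corrected across tested terms with
Benjamini-Hochberg, and paired with the Jaccard index.  A query is called
annotated when a significant term (adjusted p <= alpha) reaches the
Jaccard threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from gsnamer.errors import GsnamerError
from gsnamer.geneset_io import GeneSet


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    p_value: float
    adjusted_p: float
    overlap: int
    term_size: int
    query_size: int
    jaccard: float


def hypergeometric_pvalue(
    overlap: int, term_size: int, query_size: int, universe: int
) -> float:
    """Upper-tail P(X >= overlap) drawing ``query_size`` from ``universe``
    with ``term_size`` successes."""
    if min(overlap, term_size, query_size, universe) < 0:
        raise GsnamerError("all counts must be non-negative")
    if overlap > min(term_size, query_size):
        raise GsnamerError("overlap cannot exceed term or query size")
    if max(term_size, query_size) > universe:
        raise GsnamerError("term and query sizes cannot exceed the universe")
    if overlap < query_size + term_size - universe:
        raise GsnamerError("overlap below the feasible minimum")
    # sf(k-1) gives P(X >= k)
    return float(stats.hypergeom.sf(overlap - 1, universe, term_size, query_size))


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Step-up FDR adjustment, capped at 1, aligned with the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any(p <= 0) or np.any(p > 1):
        raise GsnamerError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted.tolist()


def jaccard(a: GeneSet | Iterable[str], b: Iterable[str]) -> float:
    """|A ∩ B| / |A ∪ B| over gene symbols."""
    set_a = a.as_set() if isinstance(a, GeneSet) else set(a)
    set_b = set(b)
    if not set_a or not set_b:
        raise GsnamerError("both gene sets must be non-empty")
    return len(set_a & set_b) / len(set_a | set_b)


def enrich_and_decide(
    query: GeneSet,
    library: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    min_ji: float = 0.1,
) -> tuple[list[EnrichmentResult], bool, EnrichmentResult | None]:
    """Test ``query`` against every overlapping library term and decide.

    The query is restricted to the universe before testing; BH correction
    spans all tested terms (those with >= 1 overlapping gene).  ``best`` is
    the significant term with maximal Jaccard index (ties: smaller adjusted
    p, then lexicographic term id); the query is annotated when ``best``
    exists and its Jaccard index reaches ``min_ji``.  Results are ordered
    by adjusted p, then term id.
    """
    if not library:
        raise GsnamerError("library must be non-empty")
    universe_set = set(universe)
    query_genes = query.as_set() & universe_set
    if not query_genes:
        raise GsnamerError("query does not intersect the universe")

    tested: list[EnrichmentResult] = []
    raw_p: list[float] = []
    for term_id in sorted(library):
        term_genes = set(library[term_id]) & universe_set
        overlap = len(term_genes & query_genes)
        if overlap == 0:
            continue
        p = hypergeometric_pvalue(
            overlap, len(term_genes), len(query_genes), len(universe_set)
        )
        ji = len(term_genes & query_genes) / len(term_genes | query_genes)
        tested.append(
            EnrichmentResult(
                term_id=term_id,
                p_value=p,
                adjusted_p=p,  # placeholder, replaced after BH
                overlap=overlap,
                term_size=len(term_genes),
                query_size=len(query_genes),
                jaccard=ji,
            )
        )
        raw_p.append(p)

    adjusted = benjamini_hochberg(raw_p)
    tested = [
        EnrichmentResult(
            term_id=r.term_id,
            p_value=r.p_value,
            adjusted_p=adj,
            overlap=r.overlap,
            term_size=r.term_size,
            query_size=r.query_size,
            jaccard=r.jaccard,
        )
        for r, adj in zip(tested, adjusted)
    ]
    tested.sort(key=lambda r: (r.adjusted_p, r.term_id))

    significant = [r for r in tested if r.adjusted_p <= alpha]
    best: EnrichmentResult | None = None
    if significant:
        best = min(significant, key=lambda r: (-r.jaccard, r.adjusted_p, r.term_id))
    annotated = best is not None and best.jaccard >= min_ji
    return tested, annotated, best
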