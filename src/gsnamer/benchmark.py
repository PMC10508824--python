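"""Confidence benchmarks on real, contaminated (50/50) and random gene sets.

For each origin term three same-size probes are generated: the term's own
aggregated genes ("real"), a set keeping floor(n/2) term genes topped up
with background genes ("mix5050"), and a fully background-sampled set
("random").  Parsed confidences are binned and tabulated per condition;
condition distributions are compared with a chi-squared test (or
Mann-Whitney U on raw score lists).
"""

from __future__ import annotations

import hashlib
import logging
import math
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gsnamer.errors import BenchmarkError, DegenerateTableError, GsnamerError
from gsnamer.llm_interface import (
    LLMBackend,
    PromptConfig,
    ResponseCache,
    build_prompt,
    parse_response,
    query,
)
from gsnamer.ontology import Ontology, aggregate_genes, annotation_pool
from gsnamer.similarity import EmbeddingBackend, name_similarity

logger = logging.getLogger(__name__)

CONDITIONS = ("real", "mix5050", "random")
BIN_LABELS = ("high", "medium", "low", "not_assigned")


@dataclass(frozen=True)
class BenchmarkSet:
    """One probe gene set tied to its origin term and condition."""

    origin_term: str
    condition: str
    genes: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise BenchmarkError(f"unknown condition {self.condition!r}")
        if len(set(self.genes)) != len(self.genes):
            raise BenchmarkError("benchmark set contains duplicate genes")


def bin_confidence(score: float) -> str:
    """Map a confidence score to its bin.

    Partition of [0, 1]: ``not_assigned`` = {0}; ``low`` = (0, 0.80);
    ``medium`` = [0.80, 0.87); ``high`` = [0.87, 1.00].
    """
    if not 0.0 <= score <= 1.0:
        raise GsnamerError(f"confidence {score} outside [0, 1]")
    if score == 0.0:
        return "not_assigned"
    if score < 0.80:
        return "low"
    if score < 0.87:
        return "medium"
    return "high"


def make_contaminated_set(
    term_genes: Iterable[str],
    pool: Iterable[str],
    fraction: float = 0.5,
    seed: int = 0,
    origin_term: str = "",
) -> BenchmarkSet:
    """Build a contaminated probe of the same size as ``term_genes``.

    Keeps ``floor(fraction * n)`` genes sampled from the term and fills the
    remainder from ``pool`` minus the term's genes, so the contamination
    fraction is exact.  ``fraction=1`` reproduces the real condition,
    ``fraction=0`` a fully background set.
    """
    if not 0.0 <= fraction <= 1.0:
        raise BenchmarkError("fraction must lie in [0, 1]")
    term_list = sorted(set(term_genes))
    n = len(term_list)
    if n == 0:
        raise BenchmarkError("term gene set is empty")
    n_keep = math.floor(fraction * n)
    n_fill = n - n_keep
    background = sorted(set(pool) - set(term_list))
    if len(background) < n_fill:
        raise BenchmarkError(
            f"background pool too small: need {n_fill} genes outside the term, "
            f"have {len(background)}"
        )
    rng = random.Random(seed)
    kept = rng.sample(term_list, n_keep)
    filled = rng.sample(background, n_fill)
    condition = "real" if fraction == 1.0 else ("random" if fraction == 0.0 else "mix5050")
    return BenchmarkSet(
        origin_term=origin_term,
        condition=condition,
        genes=tuple(sorted(kept + filled)),
        seed=seed,
    )


def make_random_set(
    n: int, pool: Iterable[str], seed: int = 0, origin_term: str = ""
) -> BenchmarkSet:
    """Sample ``n`` genes uniformly from the full background pool.

    Unlike :func:`make_contaminated_set` with ``fraction=0``, origin-term
    genes may enter by chance.
    """
    pool_list = sorted(set(pool))
    if len(pool_list) < n:
        raise BenchmarkError(
            f"background pool too small: need {n} genes, have {len(pool_list)}"
        )
    rng = random.Random(seed)
    return BenchmarkSet(
        origin_term=origin_term,
        condition="random",
        genes=tuple(sorted(rng.sample(pool_list, n))),
        seed=seed,
    )


def _term_offset(term_id: str) -> int:
    """Stable per-term seed offset derived from the term id."""
    digest = hashlib.blake2s(term_id.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "big")


def benchmark_sets_for_term(
    ont: Ontology, term_id: str, pool: Iterable[str], seed: int
) -> dict[str, BenchmarkSet]:
    """The three probes (real / mix5050 / random) for one origin term.

    Seeds are ``seed + offset(term)`` for the mix and ``seed + offset + 1``
    for the random probe, so compositions are reproducible per term.
    """
    genes = sorted(aggregate_genes(ont, term_id))
    if not genes:
        raise BenchmarkError(f"term {term_id} has no aggregated genes")
    offset = _term_offset(term_id)
    return {
        "real": BenchmarkSet(
            origin_term=term_id, condition="real", genes=tuple(genes), seed=seed
        ),
        "mix5050": make_contaminated_set(
            genes, pool, fraction=0.5, seed=seed + offset, origin_term=term_id
        ),
        "random": make_random_set(
            len(genes), pool, seed=seed + offset + 1, origin_term=term_id
        ),
    }


@dataclass
class BenchmarkRun:
    """Outcome of a benchmark: contingency table plus per-set records."""

    table: pd.DataFrame
    records: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)


def run_benchmark(
    ont: Ontology,
    terms: Sequence[str],
    backend: LLMBackend,
    embedder: EmbeddingBackend | None = None,
    seed: int = 0,
    cfg: PromptConfig | None = None,
    cache: ResponseCache | None = None,
) -> BenchmarkRun:
    """Query the backend on all probes of every term and bin confidences.

    Table rows are conditions, columns confidence bins; row sums equal the
    number of successfully processed terms per condition.  Backend or parse
    failures are recorded per probe and excluded from the table.  When an
    embedder is supplied, each record also carries the similarity of the
    proposed name to the origin term's curated name.
    """
    cfg = cfg or PromptConfig()
    pool = sorted(annotation_pool(ont))
    counts = pd.DataFrame(
        0, index=list(CONDITIONS), columns=list(BIN_LABELS), dtype=int
    )
    records: list[dict] = []
    failures: list[dict] = []
    for term_id in terms:
        try:
            probes = benchmark_sets_for_term(ont, term_id, pool, seed)
        except GsnamerError as exc:
            failures.append({"term": term_id, "condition": "*", "error": str(exc)})
            continue
        for condition in CONDITIONS:
            probe = probes[condition]
            try:
                prompt = build_prompt(cfg, probe.genes)
                raw = query(backend, cfg, prompt, cache=cache)
                annotation = parse_response(raw, model_id=backend.model_id)
            except GsnamerError as exc:
                failures.append(
                    {"term": term_id, "condition": condition, "error": str(exc)}
                )
                continue
            label = bin_confidence(annotation.confidence)
            counts.loc[condition, label] += 1
            record = {
                "term": term_id,
                "condition": condition,
                "seed": probe.seed,
                "n_genes": len(probe.genes),
                "genes": list(probe.genes),
                "name": annotation.name,
                "confidence": annotation.confidence,
                "bin": label,
            }
            if embedder is not None:
                record["target_name_similarity"] = name_similarity(
                    embedder, annotation.name, ont.terms[term_id].name
                )
            records.append(record)
    if failures:
        logger.warning("%d probe(s) failed and were excluded", len(failures))
    return BenchmarkRun(table=counts, records=records, failures=failures)


def compare_distributions(
    table_a: Sequence[int], table_b: Sequence[int]
) -> tuple[float, float]:
    """Chi-squared test between two binned count vectors.

    Columns with zero total across both vectors are dropped; the statistic
    uses (k - 1) degrees of freedom with no continuity correction.
    """
    a = np.asarray(table_a, dtype=float)
    b = np.asarray(table_b, dtype=float)
    if a.shape != b.shape:
        raise GsnamerError("count vectors must have equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise GsnamerError("counts must be non-negative")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise DegenerateTableError(
            "fewer than two informative columns after dropping empty ones"
        )
    if a.sum() == 0 or b.sum() == 0:
        raise DegenerateTableError("each table needs at least one positive count")
    result = stats.chi2_contingency(np.vstack([a, b]), correction=False)
    return float(result.statistic), float(result.pvalue)


def compare_scores(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test on raw confidence/similarity scores."""
    if len(scores_a) == 0 or len(scores_b) == 0:
        raise GsnamerError("score lists must be non-empty")
    result = stats.mannwhitneyu(scores_a, scores_b, alternative="two-sided")
    return float(result.statistic), float(result.pvalue)
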