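"""Name embedding, cosine similarity, percentile calibration, classification.

A proposed name is scored against the curated name of its target term and
calibrated against the names of every other term in the same ontology
branch: the percentile is the percentage of corpus names strictly less
similar to the proposed name than the target is.  Outcomes are classified
as ``recovered`` (percentile above threshold), ``generalized`` (best
corpus match is a proper ancestor of the target), ``other``, or
``not_named`` (zero-confidence annotation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from gsnamer.errors import GsnamerError, SimilarityError
from gsnamer.llm_interface import LLMAnnotation
from gsnamer.ontology import Ontology, is_ancestor

logger = logging.getLogger(__name__)

CATEGORIES = ("recovered", "generalized", "other", "not_named")


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Contract: embed a batch of texts into fixed-dimension vectors."""

    def embed(self, texts: Sequence[str]) -> np.ndarray: ...


@dataclass(frozen=True)
class CalibratedSimilarity:
    """A name-similarity score with its percentile against a branch corpus."""

    llm_name: str
    target_name: str
    target_term: str
    score: float
    percentile: float | None = None
    best_match_term: str | None = None
    best_match_name: str | None = None
    best_match_score: float | None = None
    category: str | None = None


def _unit_rows(vectors: np.ndarray) -> np.ndarray:
    vectors = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise SimilarityError("zero-norm embedding vector")
    return vectors / norms[:, None]


def name_similarity(backend: EmbeddingBackend, a: str, b: str) -> float:
    """Cosine similarity between the embeddings of two names."""
    if not a or not b:
        raise GsnamerError("names must be non-empty")
    unit = _unit_rows(backend.embed([a, b]))
    return float(unit[0] @ unit[1])


def percentile_rank(actual: float, background: Sequence[float]) -> float:
    """Percentage of background values strictly less than ``actual``.

    Ties do not count toward the percentile.
    """
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise GsnamerError("background must be non-empty")
    return 100.0 * float(np.count_nonzero(background < actual)) / background.size


def calibrate(
    backend: EmbeddingBackend,
    llm_name: str,
    target_term: str,
    ont: Ontology,
) -> CalibratedSimilarity:
    """Score ``llm_name`` against the target term name and the branch corpus.

    The background excludes the target's own name; the best-match search
    includes it.  All corpus names are embedded in one batch.
    """
    if target_term not in ont.terms:
        raise GsnamerError(f"unknown target term {target_term!r}")
    target = ont.terms[target_term]
    corpus_ids = ont.term_pool(target.namespace)
    if target_term not in corpus_ids:
        raise GsnamerError(f"target term {target_term!r} not in the corpus pool")
    if len(corpus_ids) < 2:
        raise GsnamerError("branch corpus is empty apart from the target")
    corpus_names = [ont.terms[tid].name for tid in corpus_ids]

    unit = _unit_rows(backend.embed([llm_name, *corpus_names]))
    similarities = unit[1:] @ unit[0]

    target_index = corpus_ids.index(target_term)
    score = float(similarities[target_index])
    background = np.delete(similarities, target_index)
    percentile = percentile_rank(score, background)

    # best match over the full corpus (target included); ties -> first id
    order = np.lexsort((corpus_ids, -similarities))
    best_index = int(order[0])
    return CalibratedSimilarity(
        llm_name=llm_name,
        target_name=target.name,
        target_term=target_term,
        score=score,
        percentile=percentile,
        best_match_term=corpus_ids[best_index],
        best_match_name=corpus_names[best_index],
        best_match_score=float(similarities[best_index]),
    )


def classify_naming(
    result: CalibratedSimilarity,
    annotation: LLMAnnotation,
    ont: Ontology,
    threshold: float = 95.0,
) -> str:
    """Assign one of ``recovered``/``generalized``/``other``/``not_named``.

    Zero-confidence annotations are ``not_named`` regardless of percentile;
    names at or above the percentile threshold are ``recovered``; otherwise
    a best match that is a proper ancestor of the target yields
    ``generalized``.
    """
    if annotation.confidence == 0.0:
        return "not_named"
    if result.percentile is None:
        raise GsnamerError("result was not calibrated against a corpus")
    if result.percentile >= threshold:
        return "recovered"
    if result.best_match_term is not None and is_ancestor(
        ont, result.best_match_term, result.target_term
    ):
        return "generalized"
    return "other"


def classify(
    result: CalibratedSimilarity,
    annotation: LLMAnnotation,
    ont: Ontology,
    threshold: float = 95.0,
) -> CalibratedSimilarity:
    """Return a copy of ``result`` with its ``category`` filled in."""
    return replace(
        result, category=classify_naming(result, annotation, ont, threshold)
    )


class SapBertEmbedder:
    """Biomedical-name embedder using a pretrained transformer.

    CLS-token pooling of the final hidden layer.  Requires the optional
    ``torch`` and ``transformers`` dependencies plus a one-time model
    download; intended for real evaluation runs, not the test suite.
    """

    DEFAULT_MODEL = "cambridgeltl/SapBERT-from-PubMedBERT-fulltext"

    def __init__(self, model_name: str = DEFAULT_MODEL, batch_size: int = 64):
        try:
            import torch
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise GsnamerError(
                "SapBertEmbedder requires 'torch' and 'transformers'"
            ) from exc
        self._torch = torch
        self.model_name = model_name
        self.batch_size = batch_size
        self._tokenizer = AutoTokenizer.from_pretrained(model_name)
        self._model = AutoModel.from_pretrained(model_name)
        self._model.eval()

    def embed(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover - heavy
        torch = self._torch
        chunks = []
        with torch.no_grad():
            for start in range(0, len(texts), self.batch_size):
                batch = list(texts[start : start + self.batch_size])
                encoded = self._tokenizer(
                    batch, padding=True, truncation=True, return_tensors="pt"
                )
                output = self._model(**encoded)
                chunks.append(output.last_hidden_state[:, 0, :].cpu().numpy())
        return np.vstack(chunks)
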