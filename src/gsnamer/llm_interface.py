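"""Prompt construction, LLM querying with caching/retries, response parsing.

The prompt is assembled from seven ordered sections: system content, task
instructions, confidence-score instructions, format instructions, the
analytical-approach guidance, a one-shot worked example, and finally the
query gene list.  Backends are pluggable objects with a ``complete`` method;
scripted backends for tests live in :mod:`gsnamer.fixtures`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

from gsnamer.errors import BackendError, GsnamerError, ResponseParseError
from gsnamer.geneset_io import GeneSet

logger = logging.getLogger(__name__)

#: Name an LLM must return (with confidence 0.00) when it declines to name.
UNRELATED_SENTINEL = "System of unrelated proteins"

DEFAULT_SYSTEM_CONTENT = (
    "You are an efficient and insightful assistant to a molecular biologist"
)

DEFAULT_TASK_INSTRUCTIONS = """\
Write a critical analysis of the biological processes performed by this system of interacting proteins.
Base your analysis on prior knowledge available in your training data.
After completing your analysis, propose a brief and detailed name for the most prominent biological process performed by the system."""

DEFAULT_CONFIDENCE_INSTRUCTIONS = """\
After completing your analysis, please also assign a confidence score to the process name you selected.
This score should follow the name in parentheses and range from 0.00 to 1.00. A score of 0.00 indicates the
lowest confidence, while 1.00 reflects the highest confidence. This score helps gauge how accurately the chosen
name represents the functions and activities within the system of interacting proteins. When determining your
score, consider the proportion of genes in the protein system that participate in the identified biological process.
For instance, if you select "Ribosome biogenesis" as the process name but only a few genes in the system
contribute to this process, the score should be lower compared to a scenario where a majority of the genes are involved in "Ribosome biogenesis"."""

DEFAULT_FORMAT_INSTRUCTIONS = (
    "Put your chosen name at the top of the analysis as 'Process: <name>'."
)

DEFAULT_ANALYTICAL_APPROACH = """\
Be concise, do not use unnecessary words.
Be factual, do not editorialize.
Be specific, avoid overly general statements such as 'the proteins are involved in various cellular processes'.
Avoid listing facts about individual proteins. Instead, try to group proteins with similar functions and discuss their
interplay, synergistic or antagonistic effects and functional integration within the system.
Also avoid choosing generic process names such as 'Cellular Signaling and Regulation'.
If you cannot identify a prominent biological process for the proteins in the system, I want you to communicate this in you analysis and name the process: "System of unrelated proteins". Provide a score of 0.00 for a "System of unrelated proteins"."""

DEFAULT_ONE_SHOT_EXAMPLE = """\
To help you in your work, I am providing an example system of interacting proteins and the corresponding example analysis output.
The example system of interacting proteins is: PDX1, SLC2A2, NKX6–1, GLP1, GCG.
The example analysis output is:
Process: Pancreatic development and glucose homeostasis (0.96)
1. PDX1 is a homeodomain transcription factor involved in the specification of the early pancreatic epithelium and its subsequent differentiation.
It activates the transcription of several genes including insulin, somatostatin, glucokinase and glucose transporter type 2.
It is essential for maintenance of the normal hormone-producing phenotype in the pancreatic beta-cell.
In pancreatic acinar cells, it forms a complex with PBX1b and MEIS2b and mediates the activation of the ELA1 enhancer.
2. NKX6–1 is also a transcription factor involved in the development of pancreatic beta-cells during the secondary transition.
Together with NKX2–2 and IRX3, controls the generation of motor neurons in the neural tube and belongs to the neural progenitor
factors induced by Sonic Hedgehog (SHH) signals.
3. GCG and GLP1, respectively glucagon and glucagon-like peptide 1, are involved in glucose metabolism and homeostasis.
GCG raises blood glucose levels by promoting gluconeogenesis and is the counter regulatory hormone of Insulin.
GLP1 is a potent stimulator of Glucose-Induced Insulin Secretion (GSIS). Plays roles in gastric motility and suppresses blood glucagon levels.
Promotes growth of the intestinal epithelium and pancreatic islet mass both by islet neogenesis and islet cell proliferation.
4. SLC2A2, also known as GLUT2, is a facilitative hexose transporter. In hepatocytes, it mediates bi-directional transport of glucose across the plasma membranes,
while in the pancreatic beta-cell, it is the main transporter responsible for glucose uptake and part of the cell's glucose-sensing mechanism.
It is involved in glucose transport in the small intestine and kidney too.
To summarize, the genes in this set are involved in the specification, differentiation, growth and functionality of the pancreas, with a particular emphasis on the pancreatic beta-cell. Particularly, the architecture of the pancreatic
islet ensures proper glucose sensing and homeostasis via a number of different hormones and receptors that can elicit both synergistic and antagonistic effects in the pancreas itself and other peripheral tissues."""


@dataclass(frozen=True)
class PromptConfig:
    """The seven-section prompt template plus decoding parameters.

    Defaults: temperature 0.0, seed 42, max_tokens 1000.
    """

    system_content: str = DEFAULT_SYSTEM_CONTENT
    task_instructions: str = DEFAULT_TASK_INSTRUCTIONS
    confidence_instructions: str = DEFAULT_CONFIDENCE_INSTRUCTIONS
    format_instructions: str = DEFAULT_FORMAT_INSTRUCTIONS
    analytical_approach: str = DEFAULT_ANALYTICAL_APPROACH
    one_shot_example: str = DEFAULT_ONE_SHOT_EXAMPLE
    temperature: float = 0.0
    seed: int = 42
    max_tokens: int = 1000

    def __post_init__(self) -> None:
        for name in (
            "system_content",
            "task_instructions",
            "confidence_instructions",
            "format_instructions",
            "analytical_approach",
            "one_shot_example",
        ):
            if not getattr(self, name).strip():
                raise GsnamerError(f"prompt section {name!r} must be non-empty")
        if not 0.0 <= self.temperature <= 2.0:
            raise GsnamerError("temperature must be within [0, 2]")
        if self.max_tokens <= 0:
            raise GsnamerError("max_tokens must be positive")


@dataclass(frozen=True)
class LLMAnnotation:
    """Structured LLM output: proposed name, confidence, essay paragraphs."""

    name: str
    confidence: float
    paragraphs: tuple[str, ...] = ()
    raw_response: str = ""
    model_id: str = ""

    @property
    def is_named(self) -> bool:
        return self.confidence > 0.0


@runtime_checkable
class LLMBackend(Protocol):
    """Contract every LLM backend implements."""

    model_id: str

    def complete(
        self, model: str, prompt: str, temperature: float, seed: int, max_tokens: int
    ) -> str: ...


def build_prompt(cfg: PromptConfig, genes: GeneSet | Iterable[str]) -> str:
    """Assemble the full prompt with the gene list substituted at the end.

    Gene symbols are joined comma-space separated; output is byte-stable
    for fixed inputs.
    """
    symbols = list(genes.genes) if isinstance(genes, GeneSet) else list(genes)
    if not symbols:
        raise GsnamerError("cannot build a prompt for an empty gene set")
    sections = (
        cfg.system_content,
        cfg.task_instructions,
        cfg.confidence_instructions,
        cfg.format_instructions,
        cfg.analytical_approach,
        cfg.one_shot_example,
        "Here are the interacting proteins:\nProteins: " + ", ".join(symbols),
    )
    return "\n".join(sections)


# ---------------------------------------------------------------------------
# Caching and querying
# ---------------------------------------------------------------------------


class ResponseCache:
    """Disk cache holding one JSON record per response, keyed by digest."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _path(self, key: str) -> Path:
        return self.directory / f"{key}.json"

    def get(self, key: str) -> str | None:
        path = self._path(key)
        if not path.exists():
            return None
        try:
            record = json.loads(path.read_text())
            return record["response"]
        except (json.JSONDecodeError, KeyError, OSError):
            logger.warning("corrupt cache record %s; bypassing cache", path)
            return None

    def put(self, key: str, response: str, metadata: dict | None = None) -> None:
        record = {"key": key, "response": response}
        if metadata:
            record["metadata"] = metadata
        self._path(key).write_text(json.dumps(record, indent=1))


def cache_key(
    model_id: str, prompt: str, temperature: float, seed: int, max_tokens: int
) -> str:
    prompt_digest = hashlib.sha256(prompt.encode("utf-8")).hexdigest()
    payload = json.dumps(
        [model_id, prompt_digest, temperature, seed, max_tokens], sort_keys=True
    )
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def query(
    backend: LLMBackend,
    cfg: PromptConfig,
    prompt: str,
    cache: ResponseCache | None = None,
    retries: int = 3,
    retry_delay: float = 0.0,
) -> str:
    """Query a backend, short-circuiting through the cache when possible.

    The cache key is (model id, prompt digest, temperature, seed,
    max_tokens).  Transport failures are retried up to ``retries`` attempts
    before a :class:`BackendError` is raised.
    """
    key = cache_key(backend.model_id, prompt, cfg.temperature, cfg.seed, cfg.max_tokens)
    if cache is not None:
        hit = cache.get(key)
        if hit is not None:
            logger.debug("cache hit %s", key[:12])
            return hit
    last_error: Exception | None = None
    for attempt in range(1, retries + 1):
        try:
            response = backend.complete(
                backend.model_id, prompt, cfg.temperature, cfg.seed, cfg.max_tokens
            )
            break
        except Exception as exc:  # backend transport errors are opaque to us
            last_error = exc
            logger.warning("backend attempt %d/%d failed: %s", attempt, retries, exc)
            if attempt < retries and retry_delay:
                time.sleep(retry_delay)
    else:
        raise BackendError(
            f"backend {backend.model_id!r} failed after {retries} attempts"
        ) from last_error
    if cache is not None:
        cache.put(key, response, metadata={"model_id": backend.model_id})
    return response


# ---------------------------------------------------------------------------
# Response parsing
# ---------------------------------------------------------------------------

# Tolerates leading whitespace and markdown bolding around the header line.
_HEADER_RE = re.compile(
    r"^\s*(?:[#*_]+\s*)?Process\s*:\s*(?P<name>.+?)\s*\(\s*(?P<score>-?\d+(?:\.\d+)?)\s*\)\s*[*_]*\s*$"
)


def parse_response(raw: str, model_id: str = "") -> LLMAnnotation:
    """Parse raw LLM text into an :class:`LLMAnnotation`.

    The first line matching ``Process: <name> (<score>)`` wins.  The
    confidence is clamped into [0, 1] with a warning if out of range; the
    remaining text is split into paragraphs on blank lines.  A response
    naming the unrelated-proteins sentinel is forced to confidence 0.
    """
    header_match = None
    header_index = -1
    lines = raw.splitlines()
    for i, line in enumerate(lines):
        m = _HEADER_RE.match(line)
        if m:
            header_match, header_index = m, i
            break
    if header_match is None:
        raise ResponseParseError("no 'Process: <name> (<score>)' header found", raw=raw)
    name = header_match.group("name").strip().strip("*_").strip()
    try:
        confidence = float(header_match.group("score"))
    except ValueError as exc:  # pragma: no cover - regex restricts to decimals
        raise ResponseParseError("unparsable confidence score", raw=raw) from exc
    if not 0.0 <= confidence <= 1.0:
        logger.warning("confidence %.3f outside [0, 1]; clamping", confidence)
        confidence = min(max(confidence, 0.0), 1.0)
    if name.casefold() == UNRELATED_SENTINEL.casefold():
        name = UNRELATED_SENTINEL
        confidence = 0.0
    body = "\n".join(lines[header_index + 1 :])
    paragraphs = tuple(
        block.strip() for block in re.split(r"\n\s*\n", body) if block.strip()
    )
    return LLMAnnotation(
        name=name,
        confidence=confidence,
        paragraphs=paragraphs,
        raw_response=raw,
        model_id=model_id,
    )


def render_annotation(annotation: LLMAnnotation) -> str:
    """Render an annotation back into response text; inverse of parsing."""
    header = f"Process: {annotation.name} ({annotation.confidence:.2f})"
    if annotation.paragraphs:
        return header + "\n\n" + "\n\n".join(annotation.paragraphs)
    return header


class OpenAIBackend:
    """Chat-completions backend (requires the optional ``openai`` extra)."""

    def __init__(self, model_id: str, api_key: str | None = None, base_url: str | None = None):
        try:
            from openai import OpenAI
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise BackendError(
                "the 'openai' package is required for OpenAIBackend"
            ) from exc
        self.model_id = model_id
        self._client = OpenAI(api_key=api_key, base_url=base_url)

    def complete(
        self, model: str, prompt: str, temperature: float, seed: int, max_tokens: int
    ) -> str:  # pragma: no cover - network
        response = self._client.chat.completions.create(
            model=model,
            messages=[{"role": "user", "content": prompt}],
            temperature=temperature,
            seed=seed,
            max_tokens=max_tokens,
        )
        return response.choices[0].message.content or ""
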