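"""Gene-set containers, GMT read/write, and size filtering."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from gsnamer.errors import GmtFormatError, GsnamerError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique gene symbols."""

    set_id: str
    label: str = ""
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise GsnamerError(f"gene set {self.set_id!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise GsnamerError(f"gene set {self.set_id!r} contains duplicate genes")

    @classmethod
    def from_genes(cls, set_id: str, genes: Iterable[str], label: str = "") -> "GeneSet":
        """Build a gene set, collapsing duplicates while preserving order."""
        seen: dict[str, None] = {}
        duplicates = 0
        for gene in genes:
            if gene in seen:
                duplicates += 1
            else:
                seen[gene] = None
        if duplicates:
            logger.warning(
                "gene set %r: collapsed %d duplicate gene(s)", set_id, duplicates
            )
        return cls(set_id=set_id, label=label, genes=tuple(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def as_set(self) -> set[str]:
        return set(self.genes)


def read_gmt(stream: TextIO | Iterable[str]) -> list[GeneSet]:
    """Read a GMT file: ``set_id<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are collapsed with a warning; lines with
    fewer than three fields raise :class:`GmtFormatError` with the line
    number.
    """
    sets: list[GeneSet] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise GmtFormatError(
                f"expected at least 3 tab-separated fields, got {len(fields)}",
                line_number=line_no,
            )
        set_id, label, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        sets.append(GeneSet.from_genes(set_id, genes, label=label))
    return sets


def write_gmt(sets: Sequence[GeneSet], stream: TextIO) -> None:
    """Write gene sets in GMT format; inverse of :func:`read_gmt`."""
    for gs in sets:
        if len(gs.genes) == 0:
            raise GsnamerError(f"refusing to write empty gene set {gs.set_id!r}")
        for text in (gs.set_id, gs.label, *gs.genes):
            if "\t" in text or "\n" in text:
                raise GsnamerError(
                    f"gene set {gs.set_id!r}: field {text!r} contains a tab/newline"
                )
        stream.write("\t".join((gs.set_id, gs.label, *gs.genes)) + "\n")


def filter_by_size(
    sets: Iterable[GeneSet], min_size: int, max_size: int
) -> list[GeneSet]:
    """Keep gene sets with ``min_size <= len <= max_size`` (inclusive)."""
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    return [gs for gs in sets if min_size <= len(gs) <= max_size]


def read_gene_list(
    stream: TextIO | Iterable[str], set_id: str = "gene_list", label: str = ""
) -> GeneSet:
    """Read a plain one-symbol-per-line gene list (``#`` comments ignored)."""
    genes = []
    for raw in stream:
        gene = raw.strip()
        if gene and not gene.startswith("#"):
            genes.append(gene)
    return GeneSet.from_genes(set_id, genes, label=label)


def threshold_scores(
    stream: TextIO | Iterable[str],
    threshold: float = 2.0,
    set_id: str = "thresholded",
    label: str = "",
    absolute: bool = True,
) -> GeneSet:
    """Turn a ``gene<TAB>score`` table into a gene set by score threshold.

    Genes with ``|score| >= threshold`` are kept (``score >= threshold``
    when ``absolute=False``).
    """
    genes = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise GmtFormatError("expected gene<TAB>score", line_number=line_no)
        try:
            score = float(cols[1])
        except ValueError as exc:
            raise GmtFormatError(f"bad score {cols[1]!r}", line_number=line_no) from exc
        value = abs(score) if absolute else score
        if value >= threshold:
            genes.append(cols[0].strip())
    return GeneSet.from_genes(set_id, genes, label=label)
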