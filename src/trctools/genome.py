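"""Genome layout, gene/origin annotations, and shared annotation-level filters.

Coordinate convention: 0-based, half-open ``[start, end)`` (BED-style)
everywhere. A gene's TSS is its transcription-direction-first base
(``start`` on +, ``end - 1`` on -) and the TES is the last transcribed base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class AnnotationError(ValueError):
    """An annotation violates its invariants."""


class BedParseError(ValueError):
    """A BED/chrom.sizes line could not be parsed; message names the line."""


class ConfigurationError(ValueError):
    """A parameter value outside its documented domain."""


GENE_CLASSES = ("mRNA", "rDNA", "other")


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths (bp)."""

    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise AnnotationError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths


@dataclass(frozen=True)
class GeneAnnotation:
    """Stranded gene interval with a class label (mRNA / rDNA / other)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_class: str = "mRNA"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise AnnotationError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id!r}: strand must be + or -, got {self.strand!r}")
        if self.gene_class not in GENE_CLASSES:
            raise AnnotationError(
                f"gene {self.gene_id!r}: unknown gene_class {self.gene_class!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class OriginAnnotation:
    """Replication origin as a 0-based point position."""

    origin_id: str
    chrom: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 0:
            raise AnnotationError(f"origin {self.origin_id!r}: negative position")


def anchor_points(gene: GeneAnnotation) -> tuple[int, int]:
    """Return ``(tss, tes)`` base positions of a gene, strand-aware.

    For a + gene on ``[start, end)`` the TSS is ``start`` and the TES is
    ``end - 1``; a - gene mirrors this.
    """
    return gene.tss, gene.tes


def filter_isolated_genes(
    genes: Sequence[GeneAnnotation], min_gap: int = 500
) -> list[GeneAnnotation]:
    """Keep genes whose same-strand, same-chromosome neighbours are >= ``min_gap`` bp away.

    The gap between two half-open intervals is ``next.start - this.end``;
    overlapping same-strand annotations have gap 0 and exclude each other.
    Genes with no same-strand neighbour pass. ``min_gap`` is inclusive:
    a gap of exactly ``min_gap`` passes. Input order is preserved.
    """
    if min_gap < 0:
        raise ConfigurationError(f"min_gap must be >= 0, got {min_gap}")
    groups: dict[tuple[str, str], list[int]] = {}
    for i, g in enumerate(genes):
        groups.setdefault((g.chrom, g.strand), []).append(i)

    keep = [True] * len(genes)
    for idxs in groups.values():
        order = sorted(idxs, key=lambda i: (genes[i].start, genes[i].end))
        # gap to the left neighbourhood: start - max(end of any earlier gene);
        # a long earlier gene can be the binding constraint, hence running max
        max_end_before = None
        for i in order:
            if max_end_before is not None:
                gap = genes[i].start - max_end_before
                if gap < min_gap or gap < 0:  # overlaps excluded even at min_gap 0
                    keep[i] = False
            max_end_before = (
                genes[i].end if max_end_before is None else max(max_end_before, genes[i].end)
            )
        min_start_after = None
        for i in reversed(order):
            if min_start_after is not None:
                gap = min_start_after - genes[i].end
                if gap < min_gap or gap < 0:
                    keep[i] = False
            min_start_after = (
                genes[i].start if min_start_after is None else min(min_start_after, genes[i].start)
            )
    return [g for i, g in enumerate(genes) if keep[i]]


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a two-column (name, length) chrom.sizes TSV."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: length not an integer") from exc
            if name in lengths:
                raise BedParseError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            lengths[name] = length
    return GenomeLayout(lengths)


def _parse_bed6_line(line: str, lineno: int, path: str) -> tuple[str, int, int, str, str, str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise BedParseError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
    chrom, start_s, end_s, name, score, strand = fields[:6]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start < 0 or start > end:
        raise BedParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
    if strand not in ("+", "-", "."):
        raise BedParseError(f"{path}:{lineno}: strand must be +, - or ., got {strand!r}")
    return chrom, start, end, name, score, strand


def read_annotations(
    path: str | Path, layout: GenomeLayout | None = None
) -> list[GeneAnnotation]:
    """Read gene annotations from BED6.

    Gene class encoding: a name field of the form ``id|class`` sets the
    class explicitly (``class`` one of mRNA/rDNA/other); otherwise the
    class defaults to mRNA. Records with "." strand or degenerate
    intervals are rejected with the offending line number.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, strand = _parse_bed6_line(line, lineno, str(path))
            if strand == ".":
                raise BedParseError(f"{path}:{lineno}: unstranded record unusable as a gene")
            if start == end:
                raise BedParseError(f"{path}:{lineno}: zero-length gene interval")
            gene_id, _, cls = name.partition("|")
            gene_class = cls if cls else "mRNA"
            if gene_class not in GENE_CLASSES:
                raise BedParseError(f"{path}:{lineno}: unknown gene class {gene_class!r}")
            if gene_id in seen:
                raise BedParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            if layout is not None:
                if chrom not in layout:
                    raise BedParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > layout.length(chrom):
                    raise BedParseError(f"{path}:{lineno}: interval exceeds chromosome length")
            genes.append(GeneAnnotation(gene_id, chrom, start, end, strand, gene_class))
    return genes


def read_origins(path: str | Path, layout: GenomeLayout | None = None) -> list[OriginAnnotation]:
    """Read origins from BED6; each origin is the start of a 1-bp interval."""
    origins: list[OriginAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, _end, name, _score, _strand = _parse_bed6_line(line, lineno, str(path))
            if layout is not None and (chrom not in layout or start >= layout.length(chrom)):
                raise BedParseError(f"{path}:{lineno}: origin outside genome layout")
            origins.append(OriginAnnotation(name, chrom, start))
    return origins


def write_annotations(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}|{g.gene_class}\t0\t{g.strand}\n")


def write_origins(origins: Iterable[OriginAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for o in origins:
            fh.write(f"{o.chrom}\t{o.position}\t{o.position + 1}\t{o.origin_id}\t0\t.\n")


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chrom_lengths.items():
            fh.write(f"{name}\t{length}\n")
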