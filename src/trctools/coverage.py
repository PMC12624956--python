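"""Stranded single-nucleotide event tracks, normalization, and metagene matrices.

A :class:`StrandedCoverage` holds one dense base-resolution vector per
chromosome per strand together with a normalization state. Event tracks are
built by clipping stranded reads to single positions: the read 5' end for
nascent-transcription (PRO-seq-style) libraries, or the templated 3'-OH
position on the opposite strand for ligation-based end capture
(GLOE-seq-style) libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .genome import (
    BedParseError,
    ConfigurationError,
    GeneAnnotation,
    GenomeLayout,
    _parse_bed6_line,
)

RAW = "raw"
RPM = "RPM"
LOG2RATIO = "log2ratio"
DIFFERENCE = "difference"


class StrandedRead(NamedTuple):
    chrom: str
    start: int
    end: int  # half-open
    strand: str


class LayoutMismatchError(ValueError):
    """Two coverage tracks do not share a genome layout."""


class ReadOutOfBoundsError(ValueError):
    pass


class EmptyLibraryError(ValueError):
    pass


@dataclass
class StrandedCoverage:
    """Per-chromosome, per-strand base-resolution value vectors."""

    layout: GenomeLayout
    data: dict[str, dict[str, np.ndarray]]
    total_events: float
    norm_state: str = RAW
    n_dropped: int = 0

    @classmethod
    def zeros(cls, layout: GenomeLayout, norm_state: str = RAW) -> "StrandedCoverage":
        data = {
            c: {"+": np.zeros(n, dtype=float), "-": np.zeros(n, dtype=float)}
            for c, n in layout.chrom_lengths.items()
        }
        return cls(layout=layout, data=data, total_events=0, norm_state=norm_state)

    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[chrom][strand]

    def same_layout(self, other: "StrandedCoverage") -> bool:
        return self.layout.chrom_lengths == other.layout.chrom_lengths

    def copy(self) -> "StrandedCoverage":
        return StrandedCoverage(
            layout=self.layout,
            data={c: {s: v.copy() for s, v in d.items()} for c, d in self.data.items()},
            total_events=self.total_events,
            norm_state=self.norm_state,
            n_dropped=self.n_dropped,
        )

    def sum(self) -> float:
        return float(sum(v.sum() for d in self.data.values() for v in d.values()))


def reads_to_5prime_events(
    reads: Sequence[StrandedRead], layout: GenomeLayout
) -> StrandedCoverage:
    """One count per read at its 5'-most base on the read's own strand.

    ``+`` read on ``[s, e)`` -> count at ``(+, s)``; ``-`` read -> ``(-, e-1)``.
    Conserves counts exactly: the track total equals the number of reads.
    """
    cov = StrandedCoverage.zeros(layout)
    per_key: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(reads):
        if r.chrom not in layout:
            raise ReadOutOfBoundsError(f"read {i}: unknown chromosome {r.chrom!r}")
        if r.start < 0 or r.end > layout.length(r.chrom) or r.start >= r.end:
            raise ReadOutOfBoundsError(f"read {i}: interval [{r.start}, {r.end}) outside {r.chrom}")
        pos = r.start if r.strand == "+" else r.end - 1
        per_key.setdefault((r.chrom, r.strand), []).append(pos)
    for (chrom, strand), positions in per_key.items():
        np.add.at(cov.data[chrom][strand], np.asarray(positions, dtype=np.intp), 1.0)
    cov.total_events = len(reads)
    return cov


def reads_to_3oh_events(
    reads: Sequence[StrandedRead],
    layout: GenomeLayout,
    shift_mode: str = "adjacent",
) -> StrandedCoverage:
    """Place the free 3'-OH position implied by each captured read.

    The 3'-OH lies on the strand opposite the read. In ``adjacent`` mode
    (default) it is one base 5'-ward of the read start along the read's
    orientation: ``+`` read ``[s, e)`` -> ``(-, s-1)``; ``-`` read ->
    ``(+, e)``. In ``coincident`` mode no shift is applied: ``(-, s)`` and
    ``(+, e-1)``. Events shifted off-chromosome are dropped and counted in
    ``n_dropped``.
    """
    if shift_mode not in ("adjacent", "coincident"):
        raise ConfigurationError(f"unknown shift_mode {shift_mode!r}")
    cov = StrandedCoverage.zeros(layout)
    dropped = 0
    per_key: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(reads):
        if r.chrom not in layout:
            raise ReadOutOfBoundsError(f"read {i}: unknown chromosome {r.chrom!r}")
        if r.strand == "+":
            pos = r.start - 1 if shift_mode == "adjacent" else r.start
            strand = "-"
        else:
            pos = r.end if shift_mode == "adjacent" else r.end - 1
            strand = "+"
        if pos < 0 or pos >= layout.length(r.chrom):
            dropped += 1
            continue
        per_key.setdefault((r.chrom, strand), []).append(pos)
    for (chrom, strand), positions in per_key.items():
        np.add.at(cov.data[chrom][strand], np.asarray(positions, dtype=np.intp), 1.0)
    cov.total_events = len(reads) - dropped
    cov.n_dropped = dropped
    if dropped:
        warnings.warn(f"{dropped} 3'-OH events shifted off-chromosome were dropped")
    return cov


def rpm_normalize(cov: StrandedCoverage, library_total: int | None = None) -> StrandedCoverage:
    """Scale raw counts by 1e6 / library size (reads-per-million)."""
    if cov.norm_state != RAW:
        raise ConfigurationError(f"rpm_normalize requires a raw track, got {cov.norm_state}")
    total = cov.total_events if library_total is None else library_total
    if total <= 0:
        raise EmptyLibraryError("cannot RPM-normalize an empty library")
    out = cov.copy()
    scale = 1e6 / total
    for d in out.data.values():
        for s in d:
            d[s] = d[s] * scale
    out.norm_state = RPM
    return out


def log2_ratio(
    a: StrandedCoverage,
    b: StrandedCoverage,
    pseudocount: float = 1.0,
    strand_summed: bool = False,
) -> StrandedCoverage:
    """Per-base log2((a + pc) / (b + pc)); both tracks must be RPM-normalized.

    With ``strand_summed`` the two strands are pooled before the ratio (the
    pooled value is stored on both strand vectors), matching strand-agnostic
    enrichment heatmaps; the default keeps strands separate.
    """
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be > 0")
    if a.norm_state != RPM or b.norm_state != RPM:
        raise ConfigurationError("log2_ratio requires RPM-normalized tracks")
    if not a.same_layout(b):
        raise LayoutMismatchError("tracks have different genome layouts")
    out = StrandedCoverage.zeros(a.layout, norm_state=LOG2RATIO)
    for chrom in a.data:
        if strand_summed:
            num = a.data[chrom]["+"] + a.data[chrom]["-"] + pseudocount
            den = b.data[chrom]["+"] + b.data[chrom]["-"] + pseudocount
            ratio = np.log2(num / den)
            out.data[chrom]["+"] = ratio
            out.data[chrom]["-"] = ratio.copy()
        else:
            for s in ("+", "-"):
                out.data[chrom][s] = np.log2(
                    (a.data[chrom][s] + pseudocount) / (b.data[chrom][s] + pseudocount)
                )
    out.total_events = a.total_events
    return out


def subtract(a: StrandedCoverage, b: StrandedCoverage) -> StrandedCoverage:
    """Per-base difference a - b of two tracks in the same normalization state."""
    if not a.same_layout(b):
        raise LayoutMismatchError("tracks have different genome layouts")
    if a.norm_state != b.norm_state:
        raise ConfigurationError(
            f"cannot subtract {b.norm_state} track from {a.norm_state} track"
        )
    out = StrandedCoverage.zeros(a.layout, norm_state=DIFFERENCE)
    for chrom in a.data:
        for s in ("+", "-"):
            out.data[chrom][s] = a.data[chrom][s] - b.data[chrom][s]
    out.total_events = a.total_events
    return out


@dataclass
class MetaMatrix:
    """Genes x bins matrix: upstream flank bins, collapsed body bins, downstream flank bins."""

    gene_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_up + n_body + n_down)
    n_up: int
    n_body: int
    n_down: int
    flank_bin: int
    dropped_gene_ids: list[str] = field(default_factory=list)

    @property
    def column_labels(self) -> list[str]:
        return (
            [f"up{i}" for i in range(self.n_up)]
            + [f"body{i}" for i in range(self.n_body)]
            + [f"down{i}" for i in range(self.n_down)]
        )

    def mean_profile(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0) if len(self.gene_ids) else np.array([])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\t" + "\t".join(self.column_labels) + "\n")
            for gid, row in zip(self.gene_ids, self.values):
                fh.write(gid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def _interval_means(vec: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Mean per-base value over each real-valued interval [edges[i], edges[i+1]).

    Fractional bases are weighted by overlap via a linearly interpolated
    cumulative sum; positions outside the chromosome contribute 0.
    """
    n = len(vec)
    cum = np.concatenate(([0.0], np.cumsum(vec)))
    s = np.interp(np.clip(edges, 0, n), np.arange(n + 1), cum)
    widths = np.diff(edges)
    return np.diff(s) / widths


def metaplot_matrix(
    cov: StrandedCoverage,
    genes: Sequence[GeneAnnotation],
    up: int = 500,
    down: int = 500,
    body_bins: int = 100,
    flank_bin: int = 10,
    orientation: str = "sense",
) -> MetaMatrix:
    """Project coverage onto a collapsed-gene-body (scale-regions) matrix.

    Per gene: ``up/flank_bin`` fixed-width upstream bins, ``body_bins``
    equal real-valued spans over the gene body, ``down/flank_bin``
    downstream bins; each cell is the mean per-base value. Columns are in
    transcription order (upstream -> TSS -> ... -> TES -> downstream) for
    both strands. ``orientation`` selects the coverage strand relative to
    the gene: ``sense`` (same strand), ``antisense``, or ``both`` (sum).
    Genes with body shorter than ``body_bins`` bases are dropped with a
    warning.
    """
    if up % flank_bin or down % flank_bin:
        raise ConfigurationError("up/down flank lengths must be multiples of flank_bin")
    if orientation not in ("sense", "antisense", "both"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    if body_bins < 1 or flank_bin < 1:
        raise ConfigurationError("body_bins and flank_bin must be >= 1")
    n_up, n_down = up // flank_bin, down // flank_bin

    kept_ids: list[str] = []
    dropped: list[str] = []
    rows: list[np.ndarray] = []
    for g in genes:
        if g.length < body_bins:
            dropped.append(g.gene_id)
            continue
        if orientation == "both":
            vec = cov.data[g.chrom]["+"] + cov.data[g.chrom]["-"]
        else:
            strand = g.strand if orientation == "sense" else ("-" if g.strand == "+" else "+")
            vec = cov.data[g.chrom][strand]

        body_edges = g.start + g.length * np.arange(body_bins + 1) / body_bins
        if g.strand == "+":
            up_edges = np.arange(g.start - up, g.start + 1, flank_bin, dtype=float)
            down_edges = np.arange(g.end, g.end + down + 1, flank_bin, dtype=float)
            row = np.concatenate(
                [
                    _interval_means(vec, up_edges),
                    _interval_means(vec, body_edges),
                    _interval_means(vec, down_edges),
                ]
            )
        else:
            # genomic blocks, each reversed into transcription order
            up_edges = np.arange(g.end, g.end + up + 1, flank_bin, dtype=float)
            down_edges = np.arange(g.start - down, g.start + 1, flank_bin, dtype=float)
            row = np.concatenate(
                [
                    _interval_means(vec, up_edges)[::-1],
                    _interval_means(vec, body_edges)[::-1],
                    _interval_means(vec, down_edges)[::-1],
                ]
            )
        kept_ids.append(g.gene_id)
        rows.append(row)
    if dropped:
        warnings.warn(f"{len(dropped)} genes shorter than {body_bins} bp dropped from metaplot")
    values = np.vstack(rows) if rows else np.empty((0, n_up + body_bins + n_down))
    return MetaMatrix(kept_ids, values, n_up, body_bins, n_down, flank_bin, dropped)


def filter_srna_reads(
    reads: Sequence[str], min_len: int = 20, max_len: int = 70
) -> list[str]:
    """Drop exact-sequence duplicates (first kept), then out-of-range lengths.

    Deduplication runs before the length filter; order is preserved. The
    operation is idempotent.
    """
    seen: set[str] = set()
    deduped: list[str] = []
    for seq in reads:
        if seq not in seen:
            seen.add(seq)
            deduped.append(seq)
    return [s for s in deduped if min_len <= len(s) <= max_len]


# ---------------------------------------------------------------------------
# I/O helpers: BED6 reads, bedGraph tracks, FASTQ


def read_bed_reads(path: str | Path) -> list[StrandedRead]:
    """Read stranded reads from BED6 (strand must be + or -)."""
    reads: list[StrandedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, _name, _score, strand = _parse_bed6_line(line, lineno, str(path))
            if strand == ".":
                raise BedParseError(f"{path}:{lineno}: reads must be stranded")
            reads.append(StrandedRead(chrom, start, end, strand))
    return reads


def write_bed_reads(reads: Iterable[StrandedRead], path: str | Path, name_prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name_prefix}{i}\t0\t{r.strand}\n")


def write_bedgraph(cov: StrandedCoverage, prefix: str | Path) -> tuple[Path, Path]:
    """Write one bedGraph per strand: ``<prefix>.plus.bedgraph`` / ``.minus.bedgraph``.

    Runs of equal values are merged; zero runs are omitted.
    """
    paths = (Path(f"{prefix}.plus.bedgraph"), Path(f"{prefix}.minus.bedgraph"))
    for strand, path in zip(("+", "-"), paths):
        with open(path, "w") as fh:
            for chrom in cov.data:
                vec = cov.data[chrom][strand]
                if not len(vec):
                    continue
                change = np.flatnonzero(np.diff(vec)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(vec)]))
                for s, e in zip(starts, ends):
                    v = vec[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
    return paths


def read_fastq(path: str | Path) -> list[str]:
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(seqs: Sequence[str], path: str | Path, id_prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(seqs):
            fh.write(f"@{id_prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")
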