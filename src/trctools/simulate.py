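"""Seedable simulators for every assay the pipeline consumes.

One shared toy-genome model produces ground-truth-labelled inputs emulating:

* nascent-transcription 5'-end libraries with a promoter-proximal pause
  pileup of designed pause/body density ratio ``r``;
* 3'-OH end-capture libraries whose strand bias diverges from replication
  origins (Okazaki-fragment ends on the lagging strand) with configurable
  strand noise;
* BrdU pulse-chase single-molecule signals with trapezoidal fork tracks;
* ChIP input/IP read pairs with fold enrichment over target intervals;
* size-selected small-RNA libraries with duplicates.

Every simulator draws from its own pseudo-random stream derived from the
master seed, so adding one assay never perturbs another, and identical
seed + config give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .coverage import StrandedCoverage, StrandedRead
from .forks import BrdURead
from .genome import (
    ConfigurationError,
    GeneAnnotation,
    GenomeLayout,
    OriginAnnotation,
)

_STREAMS = {"genome": 0, "proseq": 1, "gloeseq": 2, "brdu": 3, "chip": 4, "srna": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


class StrandedEvent(NamedTuple):
    chrom: str
    pos: int
    strand: str


@dataclass
class ForkTruth:
    read_id: str
    chrom: str
    direction: str  # 'left' | 'right'
    speed: float  # kb/min
    track_start: int
    track_end: int
    truncated: bool = False
    relation: str | None = None  # head_on / co_directional when genes overlap


@dataclass
class GroundTruth:
    """Per-record truth the simulators emit alongside their outputs."""

    gene_pause_ratio: dict[str, float] = field(default_factory=dict)
    region_directions: list[tuple[str, int, int, str]] = field(default_factory=list)
    forks: list[ForkTruth] = field(default_factory=list)
    chip_targets: list[tuple[str, int, int, float]] = field(default_factory=list)


def toy_genome(
    seed: int = 0,
    n_chroms: int = 2,
    chrom_length: int = 1_000_000,
    n_genes: int = 200,
    gene_length_range: tuple[int, int] = (1000, 4000),
    origins_per_chrom: tuple[int, int] = (3, 5),
) -> tuple[GenomeLayout, list[GeneAnnotation], list[OriginAnnotation]]:
    """Desk-scale genome: a few 1-Mb chromosomes, kb-scale genes on random
    strands, and a handful of origins per chromosome."""
    rng = _rng(seed, "genome")
    layout = GenomeLayout({f"chr{i + 1}": chrom_length for i in range(n_chroms)})
    genes: list[GeneAnnotation] = []
    per_chrom = n_genes // n_chroms
    for ci, chrom in enumerate(layout.chroms):
        # lay genes left to right with random intergenic gaps; no overlaps
        pos = int(rng.integers(1000, 5000))
        for gi in range(per_chrom):
            length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            if pos + length > chrom_length - 1000:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneAnnotation(f"gene_{ci}_{gi}", chrom, pos, pos + length, strand, "mRNA")
            )
            pos += length + int(rng.integers(200, 3000))
    origins: list[OriginAnnotation] = []
    for ci, chrom in enumerate(layout.chroms):
        k = int(rng.integers(origins_per_chrom[0], origins_per_chrom[1] + 1))
        positions = np.sort(rng.choice(np.arange(50_000, chrom_length - 50_000), size=k, replace=False))
        # enforce spacing so inter-origin structure is resolvable
        positions = positions[np.concatenate(([True], np.diff(positions) > 100_000))]
        for oi, p in enumerate(positions):
            origins.append(OriginAnnotation(f"ori_{ci}_{oi}", chrom, int(p)))
    return layout, genes, origins


@dataclass
class SimConfig:
    """Study conditions for all simulated assays.

    Pulse-chase defaults mirror a 2-minute BrdU pulse followed by a
    thymidine chase, with forks near the eukaryotic-typical 1.8 kb/min.
    """

    seed: int = 0
    layout: GenomeLayout | None = None
    genes: list[GeneAnnotation] = field(default_factory=list)
    origins: list[OriginAnnotation] = field(default_factory=list)
    # library sizes
    n_reads_proseq: int = 200_000
    n_reads_gloeseq: int = 200_000
    n_reads_chip: int = 100_000
    n_reads_srna: int = 5_000
    n_brdu_reads: int = 200
    # nascent transcription
    pause_ratio: float = 5.0
    pause_width: int = 100
    read_length: int = 30
    background_fraction: float = 0.05
    # replication end capture
    strand_noise: float = 0.05
    # pulse-chase
    fork_speed_mean: float = 1.8  # kb/min
    fork_speed_sd: float = 0.4
    t_pulse: float = 2.0  # min
    t_fall: float = 1.0  # min
    rise_width: int = 100  # bp
    brdu_high: float = 0.8
    brdu_background: float = 0.02
    brdu_read_length: int = 50_000
    brdu_bernoulli: bool = True
    headon_multiplier: float = 1.0  # speed factor applied to head-on forks
    # ChIP
    chip_enrichment: float = 4.0
    chip_targets: list[tuple[str, int, int]] | None = None
    chip_read_length: int = 50
    # small RNA
    srna_length_weights: dict[int, float] = field(
        default_factory=lambda: {n: 1.0 for n in range(20, 31)}
    )
    duplicate_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.layout is None:
            self.layout, genes, origins = toy_genome(self.seed)
            if not self.genes:
                self.genes = genes
            if not self.origins:
                self.origins = origins
        for name in ("background_fraction", "brdu_high", "brdu_background", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.strand_noise <= 0.5:
            raise ConfigurationError(
                f"strand_noise must be in [0, 0.5] (the sign convention inverts beyond 0.5), got {self.strand_noise}"
            )
        if self.fork_speed_mean <= 0 or self.t_pulse <= 0:
            raise ConfigurationError("fork_speed_mean and t_pulse must be > 0")
        if self.pause_width < 1:
            raise ConfigurationError("pause_width must be >= 1")
        if self.chip_enrichment <= 0:
            raise ConfigurationError("chip_enrichment must be > 0")
        if self.headon_multiplier <= 0:
            raise ConfigurationError("headon_multiplier must be > 0")


def simulate_proseq(cfg: SimConfig) -> tuple[list[StrandedRead], GroundTruth]:
    """Nascent 5'-end reads with a designed pause-window/body density ratio.

    Within a gene of length L, a read's single-nucleotide position falls in
    the pause window [tss, tss + w_p) with probability
    q = r*w_p / (r*w_p + (L - w_p)), else uniformly over the body, so the
    expected pause/body density ratio is exactly r. A ``background_fraction``
    of reads is uniform genome-wide on random strands. Reads extend
    3'-ward (fixed length) from the position.
    """
    rng = _rng(cfg.seed, "proseq")
    w_p = cfg.pause_width
    genes = cfg.genes
    for g in genes:
        if g.length <= 2 * w_p:
            raise ConfigurationError(
                f"gene {g.gene_id!r} (length {g.length}) is too short for pause_width {w_p}"
            )
    layout = cfg.layout
    n = cfg.n_reads_proseq
    bg_mask = rng.random(n) < cfg.background_fraction
    n_gene = int((~bg_mask).sum())

    starts = np.array([g.start for g in genes])
    ends = np.array([g.end for g in genes])
    lengths = ends - starts
    plus = np.array([g.strand == "+" for g in genes])
    q = cfg.pause_ratio * w_p / (cfg.pause_ratio * w_p + (lengths - w_p))

    gi = rng.integers(0, len(genes), size=n_gene)
    in_pause = rng.random(n_gene) < q[gi]
    off = np.where(
        in_pause,
        rng.integers(0, w_p, size=n_gene),
        w_p + rng.integers(0, (lengths - w_p)[gi].clip(min=1)),
    )
    pos = np.where(plus[gi], starts[gi] + off, ends[gi] - 1 - off)

    chrom_names = layout.chroms
    chrom_lens = np.array([layout.length(c) for c in chrom_names])
    reads: list[StrandedRead] = []
    gene_chroms = [g.chrom for g in genes]
    for k in range(n_gene):
        g_idx = gi[k]
        chrom = gene_chroms[g_idx]
        clen = layout.length(chrom)
        p = int(pos[k])
        if plus[g_idx]:
            reads.append(StrandedRead(chrom, p, min(p + cfg.read_length, clen), "+"))
        else:
            reads.append(StrandedRead(chrom, max(p - cfg.read_length + 1, 0), p + 1, "-"))

    n_bg = n - n_gene
    if n_bg:
        ci = rng.choice(len(chrom_names), size=n_bg, p=chrom_lens / chrom_lens.sum())
        bpos = rng.integers(0, chrom_lens[ci])
        bstrand = rng.random(n_bg) < 0.5
        for k in range(n_bg):
            chrom = chrom_names[ci[k]]
            clen = int(chrom_lens[ci[k]])
            p = int(bpos[k])
            if bstrand[k]:
                reads.append(StrandedRead(chrom, p, min(p + cfg.read_length, clen), "+"))
            else:
                reads.append(StrandedRead(chrom, max(p - cfg.read_length + 1, 0), p + 1, "-"))

    truth = GroundTruth(gene_pause_ratio={g.gene_id: cfg.pause_ratio for g in genes})
    return reads, truth


def _fork_direction_regions(
    origins: Sequence[int], chrom_length: int
) -> list[tuple[int, int, str]]:
    """Partition a chromosome into rightward/leftward fork regions: forks move
    away from each origin and terminate at inter-origin midpoints; the
    leftmost/rightmost regions point outward."""
    o = sorted(origins)
    regions: list[tuple[int, int, str]] = []
    regions.append((0, o[0], "left"))
    for a, b in zip(o, o[1:]):
        mid = (a + b) // 2
        regions.append((a, mid, "right"))
        regions.append((mid, b, "left"))
    regions.append((o[-1], chrom_length, "right"))
    return [(s, e, d) for s, e, d in regions if e > s]


def simulate_gloeseq(cfg: SimConfig) -> tuple[list[StrandedEvent], GroundTruth]:
    """3'-OH end events whose strand reports fork direction.

    Okazaki-fragment 3'-OH ends of a rightward-moving fork lie on the
    Crick (reverse) strand; each event keeps that strand with probability
    1 - eps and is flipped with probability eps (``strand_noise``), so the
    expected strand-bias statistic (rev - fwd)/(rev + fwd) in a purely
    rightward region is 1 - 2*eps. Event positions are uniform along the
    chromosome (end density carries no fragment-length structure).
    """
    rng = _rng(cfg.seed, "gloeseq")
    layout = cfg.layout
    by_chrom: dict[str, list[int]] = {}
    for o in cfg.origins:
        by_chrom.setdefault(o.chrom, []).append(o.position)
    for chrom in layout.chroms:
        if chrom not in by_chrom:
            raise ConfigurationError(f"chromosome {chrom!r} has no origin")

    chrom_names = layout.chroms
    chrom_lens = np.array([layout.length(c) for c in chrom_names], dtype=float)
    counts = rng.multinomial(cfg.n_reads_gloeseq, chrom_lens / chrom_lens.sum())

    events: list[StrandedEvent] = []
    truth = GroundTruth()
    eps = cfg.strand_noise
    for chrom, n_c in zip(chrom_names, counts):
        clen = layout.length(chrom)
        regions = _fork_direction_regions(by_chrom[chrom], clen)
        truth.region_directions.extend((chrom, s, e, d) for s, e, d in regions)
        pos = np.sort(rng.integers(0, clen, size=n_c))
        o = np.array(sorted(by_chrom[chrom]))
        j = np.searchsorted(o, pos, side="right")
        rightward = np.empty(n_c, dtype=bool)
        rightward[j == 0] = False  # left of the first origin: outward = leftward
        rightward[j == len(o)] = True
        mid_mask = (j > 0) & (j < len(o))
        jm = j[mid_mask]
        mids = (o[jm - 1] + o[jm]) // 2
        rightward[mid_mask] = pos[mid_mask] < mids
        flip = rng.random(n_c) < eps
        # rightward fork -> lagging-strand 3'-OH on the reverse (Crick) strand
        on_reverse = rightward ^ flip
        for p, rev in zip(pos, on_reverse):
            events.append(StrandedEvent(chrom, int(p), "-" if rev else "+"))
    return events, truth


def events_to_coverage(events: Sequence[StrandedEvent], layout: GenomeLayout) -> StrandedCoverage:
    """Accumulate point events into a raw stranded coverage track."""
    cov = StrandedCoverage.zeros(layout)
    per_key: dict[tuple[str, str], list[int]] = {}
    for ev in events:
        per_key.setdefault((ev.chrom, ev.strand), []).append(ev.pos)
    for (chrom, strand), positions in per_key.items():
        np.add.at(cov.data[chrom][strand], np.asarray(positions, dtype=np.intp), 1.0)
    cov.total_events = len(events)
    return cov


def trapezoid_profile(
    track_len_fn_args: tuple[float, float, float, int],
    background: float,
    high: float,
    length: int,
    x0: int,
) -> np.ndarray:
    """Noiseless per-base BrdU probability for a rightward fork anchored at
    x0 (read coordinates): linear rise over rise_width, plateau over
    s*t_pulse, linear fall over s*t_fall."""
    s_nt, t_pulse, t_fall, r_w = track_len_fn_args
    x = np.arange(length, dtype=float)
    p = np.full(length, background)
    rise_end = x0 + r_w
    plat_end = rise_end + s_nt * t_pulse
    fall_end = plat_end + s_nt * t_fall
    m = (x >= x0) & (x < rise_end)
    p[m] = background + (high - background) * (x[m] - x0) / r_w
    m = (x >= rise_end) & (x < plat_end)
    p[m] = high
    m = (x >= plat_end) & (x < fall_end)
    p[m] = high - (high - background) * (x[m] - plat_end) / (s_nt * t_fall)
    return p


def simulate_brdu_reads(cfg: SimConfig) -> tuple[list[BrdURead], GroundTruth]:
    """Single-molecule BrdU signals: one trapezoidal fork track per read.

    True speeds are drawn from a normal (mean ``fork_speed_mean``, sd
    ``fork_speed_sd`` kb/min) truncated at 0.2 kb/min; directions are
    random. When ``headon_multiplier`` != 1 and the track overlaps a gene,
    the speed of head-on forks (travel opposing transcription) is scaled
    by the multiplier before the track is laid down. Observed per-base
    values are Bernoulli draws from the trapezoid probability
    (``brdu_bernoulli=False`` gives the noiseless probabilities). Tracks
    longer than the read are truncated and flagged in the truth table.
    """
    rng = _rng(cfg.seed, "brdu")
    layout = cfg.layout
    chrom_names = layout.chroms
    chrom_lens = np.array([layout.length(c) for c in chrom_names], dtype=float)
    reads: list[BrdURead] = []
    truth = GroundTruth()
    rl = cfg.brdu_read_length
    for i in range(cfg.n_brdu_reads):
        ci = int(rng.choice(len(chrom_names), p=chrom_lens / chrom_lens.sum()))
        chrom = chrom_names[ci]
        clen = int(chrom_lens[ci])
        read_start = int(rng.integers(0, max(1, clen - rl)))
        speed = 0.0
        while speed < 0.2:
            speed = float(rng.normal(cfg.fork_speed_mean, cfg.fork_speed_sd))
        direction = "right" if rng.random() < 0.5 else "left"

        s_nt = speed * 1000.0
        track_len = int(cfg.rise_width + s_nt * (cfg.t_pulse + cfg.t_fall))
        truncated = track_len > rl
        x0 = 0 if truncated else int(rng.integers(0, rl - track_len + 1))

        relation = None
        if cfg.headon_multiplier != 1.0 and cfg.genes:
            g_start, g_end = read_start + x0, read_start + x0 + min(track_len, rl)
            best = None
            for g in cfg.genes:
                if g.chrom != chrom:
                    continue
                ov = min(g_end, g.end) - max(g_start, g.start)
                if ov > 0 and (best is None or ov > best[0]):
                    best = (ov, g)
            if best is not None:
                g = best[1]
                co = (direction == "right" and g.strand == "+") or (
                    direction == "left" and g.strand == "-"
                )
                relation = "co_directional" if co else "head_on"
                if relation == "head_on":
                    speed *= cfg.headon_multiplier
                    s_nt = speed * 1000.0
                    track_len = int(cfg.rise_width + s_nt * (cfg.t_pulse + cfg.t_fall))
                    truncated = track_len > rl
                    if not truncated:
                        x0 = min(x0, rl - track_len)

        prob = trapezoid_profile(
            (s_nt, cfg.t_pulse, cfg.t_fall, cfg.rise_width),
            cfg.brdu_background,
            cfg.brdu_high,
            rl,
            x0,
        )
        if direction == "left":
            prob = prob[::-1].copy()
            t_start = read_start + rl - (x0 + min(track_len, rl))
        else:
            t_start = read_start + x0
        values = (rng.random(rl) < prob).astype(float) if cfg.brdu_bernoulli else prob
        rid = f"brdu_{i}"
        reads.append(BrdURead(rid, chrom, read_start, values))
        truth.forks.append(
            ForkTruth(
                read_id=rid,
                chrom=chrom,
                direction=direction,
                speed=speed,
                track_start=t_start,
                track_end=t_start + min(track_len, rl),
                truncated=truncated,
                relation=relation,
            )
        )
    return reads, truth


def simulate_chip_pair(
    cfg: SimConfig,
) -> tuple[list[StrandedRead], list[StrandedRead], GroundTruth]:
    """IP/input read pair: input uniform, IP density multiplied by
    ``chip_enrichment`` inside target intervals."""
    rng = _rng(cfg.seed, "chip")
    layout = cfg.layout
    fold = cfg.chip_enrichment
    targets = cfg.chip_targets
    if targets is None:
        candidates = [g for g in cfg.genes][:10]
        targets = [(g.chrom, g.start, g.end) for g in candidates]
    truth = GroundTruth(chip_targets=[(c, s, e, fold) for c, s, e in targets])

    chrom_names = layout.chroms
    chrom_lens = np.array([layout.length(c) for c in chrom_names], dtype=float)
    genome_len = chrom_lens.sum()
    t_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for c, s, e in targets:
        if c not in layout or s < 0 or e > layout.length(c):
            raise ConfigurationError(f"ChIP target ({c}, {s}, {e}) outside genome layout")
        t_by_chrom[c].append((s, e))
    target_len = float(sum(e - s for _, s, e in targets))

    def uniform_reads(n: int) -> list[StrandedRead]:
        if n == 0:
            return []
        ci = rng.choice(len(chrom_names), size=n, p=chrom_lens / genome_len)
        out = []
        for k in range(n):
            chrom = chrom_names[ci[k]]
            clen = int(chrom_lens[ci[k]])
            p = int(rng.integers(0, clen))
            strand = "+" if rng.random() < 0.5 else "-"
            out.append(_read_at(chrom, p, strand, cfg.chip_read_length, clen))
        return out

    def in_target(chrom: str, p: int) -> bool:
        return any(s <= p < e for s, e in t_by_chrom[chrom])

    n = cfg.n_reads_chip
    input_reads = uniform_reads(n)

    p_in = fold * target_len / (genome_len + (fold - 1) * target_len) if target_len else 0.0
    n_in = int(rng.binomial(n, p_in)) if target_len else 0
    ip_reads: list[StrandedRead] = []
    if n_in:
        spans = [(c, s, e) for c, ivs in t_by_chrom.items() for s, e in ivs]
        span_lens = np.array([e - s for _, s, e in spans], dtype=float)
        si = rng.choice(len(spans), size=n_in, p=span_lens / span_lens.sum())
        for k in range(n_in):
            c, s, e = spans[si[k]]
            p = int(rng.integers(s, e))
            strand = "+" if rng.random() < 0.5 else "-"
            ip_reads.append(_read_at(c, p, strand, cfg.chip_read_length, layout.length(c)))
    n_out = n - n_in
    while n_out > 0:
        batch = uniform_reads(n_out)
        kept = [r for r in batch if not in_target(r.chrom, r.start if r.strand == "+" else r.end - 1)]
        ip_reads.extend(kept)
        n_out -= len(kept)
    return ip_reads, input_reads, truth


def _read_at(chrom: str, pos: int, strand: str, length: int, clen: int) -> StrandedRead:
    if strand == "+":
        return StrandedRead(chrom, pos, min(pos + length, clen), "+")
    return StrandedRead(chrom, max(pos - length + 1, 0), pos + 1, "-")


def simulate_srna(cfg: SimConfig) -> list[str]:
    """Small-RNA sequences: lengths from the configured weight distribution;
    each read after the first is an exact copy of a random earlier read
    with probability ``duplicate_fraction``."""
    rng = _rng(cfg.seed, "srna")
    weights = cfg.srna_length_weights
    if not weights or all(w <= 0 for w in weights.values()):
        raise ConfigurationError("srna_length_weights must contain a positive weight")
    lens = np.array(sorted(weights))
    w = np.array([weights[l] for l in lens], dtype=float)
    if (w < 0).any():
        raise ConfigurationError("srna_length_weights must be non-negative")
    w /= w.sum()
    reads: list[str] = []
    bases = np.array(list("ACGT"))
    for _ in range(cfg.n_reads_srna):
        if reads and rng.random() < cfg.duplicate_fraction:
            reads.append(reads[int(rng.integers(0, len(reads)))])
        else:
            length = int(rng.choice(lens, p=w))
            reads.append("".join(bases[rng.integers(0, 4, size=length)]))
    return reads


def simulate_paired_speed_study(
    seed: int,
    n_genes: int = 300,
    multiplier: float = 0.8,
    base_mean: float = 1.8,
    base_sd: float = 0.3,
    measurement_sd: float = 0.06,
) -> tuple[dict[str, float], dict[str, float]]:
    """Paired per-gene median fork speeds for head-on vs co-directional forks.

    Each gene g carries a true speed v_g ~ Normal(base_mean, base_sd)
    truncated at 0.2 kb/min; each arm observes v_g (times ``multiplier``
    for the head-on arm) with independent lognormal measurement noise of
    scale ``measurement_sd``, emulating per-gene medians over a few forks.
    Returns ``(head_on, co_directional)`` keyed by gene id; multiplier 1
    gives an exchangeable (null) pair.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(17,)))
    head: dict[str, float] = {}
    co: dict[str, float] = {}
    for i in range(n_genes):
        v = 0.0
        while v < 0.2:
            v = float(rng.normal(base_mean, base_sd))
        co[f"g{i}"] = v * float(np.exp(rng.normal(0, measurement_sd)))
        head[f"g{i}"] = multiplier * v * float(np.exp(rng.normal(0, measurement_sd)))
    return head, co
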