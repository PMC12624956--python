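"""Single-molecule replication fork detection and speed estimation.

A pulse of BrdU followed by a thymidine chase leaves a characteristic
asymmetric track of analog incorporation on each replicated single
molecule: a steep rise of fixed width where the fork sat when the pulse
began, a plateau laid down during the pulse, and a shallow decay during
the chase as intracellular BrdU is diluted. We model the track as a
trapezoid, which gives a closed-form speed estimator from the
half-amplitude width of the track:

    span = x_R - x_L = r_w/2 + s * (t_pulse + t_fall/2)
    s    = (span - r_w/2) / (t_pulse + t_fall/2)

where ``r_w`` is the rise width (bp), ``t_pulse`` the pulse duration and
``t_fall`` the effective chase decay time (both minutes). Fork direction
comes from edge-steepness asymmetry: the shallow (chase) edge points in
the direction of travel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genome import ConfigurationError, GeneAnnotation


@dataclass
class BrdURead:
    """Per-base BrdU signal on one sequenced molecule."""

    read_id: str
    chrom: str
    read_start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ConfigurationError(f"read {self.read_id!r}: values must be a non-empty 1-D array")
        if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1:
            raise ConfigurationError(f"read {self.read_id!r}: BrdU values must lie in [0, 1]")


@dataclass(frozen=True)
class ForkConfig:
    """Detection parameters; t_pulse/t_fall/rise_width are shared with the simulator."""

    bin_size: int = 100
    t_pulse: float = 2.0
    t_fall: float = 1.0
    rise_width: int = 100
    min_amplitude: float = 0.3
    edge_ratio: float = 1.5  # min shallow/steep width ratio for a confident direction
    min_run_bins: int = 2

    def __post_init__(self) -> None:
        if self.bin_size < 1 or self.t_pulse <= 0 or self.t_fall < 0:
            raise ConfigurationError("bin_size >= 1, t_pulse > 0, t_fall >= 0 required")
        if not 0 < self.min_amplitude <= 1:
            raise ConfigurationError("min_amplitude must be in (0, 1]")


@dataclass
class ForkCall:
    """One detected replication track on one read."""

    read_id: str
    chrom: str
    track_start: int
    track_end: int
    direction: str | None  # 'left' | 'right' | None (ambiguous edges)
    speed: float | None  # kb/min; None when truncated
    amplitude: float
    truncated: bool = False
    bubble: bool = False


@dataclass(frozen=True)
class ForkGeneAssignment:
    fork: ForkCall
    gene_id: str
    relation: str  # 'head_on' | 'co_directional'
    overlap_bp: int
    primary: bool = False


def _cross_outward(binned: np.ndarray, peak: int, level: float, step: int, bin_size: int):
    """Walk from ``peak`` in ``step`` direction until the signal drops below
    ``level``; return the interpolated crossing position (bp, bin-centre
    coordinates) or None if the read edge is reached first (truncation)."""
    i = peak
    while 0 <= i + step < len(binned):
        j = i + step
        if binned[j] < level:
            # linear interpolation between bin centres i and j
            frac = (binned[i] - level) / (binned[i] - binned[j])
            return (i + 0.5 + step * frac) * bin_size
        i = j
    return None


def detect_forks(read: BrdURead, cfg: ForkConfig = ForkConfig()) -> list[ForkCall]:
    """Call BrdU tracks on one read and estimate per-track direction and speed.

    The signal is averaged in fixed bins; the background is the median bin.
    Maximal runs of bins exceeding background + min_amplitude/2 are track
    candidates. Half-amplitude crossings located by linear interpolation
    give the track span and hence the speed; 25%/75%-amplitude crossings
    give per-edge widths for the direction call. Tracks touching a read
    end are flagged truncated with undefined speed.
    """
    n = len(read.values)
    if n < 10 * cfg.bin_size:
        raise ConfigurationError(
            f"read {read.read_id!r}: length {n} < 10 bins of {cfg.bin_size} bp"
        )
    nb = n // cfg.bin_size
    binned = read.values[: nb * cfg.bin_size].reshape(nb, cfg.bin_size).mean(axis=1)
    background = float(np.median(binned))
    threshold = background + cfg.min_amplitude / 2.0

    above = binned > threshold
    # maximal runs of above-threshold bins
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    runs = list(zip(edges[::2], edges[1::2]))  # [start, end) in bins

    calls: list[ForkCall] = []
    for rs, re in runs:
        if re - rs < cfg.min_run_bins:
            continue
        seg = binned[rs:re]
        raw_amp = float(seg.max() - background)
        plateau_bins = seg[seg >= background + 0.5 * raw_amp]
        amplitude = float(np.median(plateau_bins) - background)
        if amplitude < cfg.min_amplitude:
            continue
        peak = rs + int(np.argmax(seg))

        def level(frac: float) -> float:
            return background + frac * amplitude

        x_l = _cross_outward(binned, peak, level(0.5), -1, cfg.bin_size)
        x_r = _cross_outward(binned, peak, level(0.5), +1, cfg.bin_size)
        truncated = x_l is None or x_r is None

        # edge widths from quarter-amplitude crossings
        direction = None
        if not truncated:
            l75 = _cross_outward(binned, peak, level(0.75), -1, cfg.bin_size)
            l25 = _cross_outward(binned, peak, level(0.25), -1, cfg.bin_size)
            r75 = _cross_outward(binned, peak, level(0.75), +1, cfg.bin_size)
            r25 = _cross_outward(binned, peak, level(0.25), +1, cfg.bin_size)
            if None not in (l75, l25, r75, r25):
                w_left = abs(l75 - l25)
                w_right = abs(r25 - r75)
                wide, narrow = max(w_left, w_right), min(w_left, w_right)
                if narrow == 0 or wide / narrow >= cfg.edge_ratio:
                    direction = "right" if w_right > w_left else "left"

        speed = None
        if not truncated:
            span = x_r - x_l
            s_nt = (span - cfg.rise_width / 2.0) / (cfg.t_pulse + cfg.t_fall / 2.0)
            if s_nt > 0:
                speed = s_nt / 1000.0  # kb/min

        calls.append(
            ForkCall(
                read_id=read.read_id,
                chrom=read.chrom,
                track_start=read.read_start + rs * cfg.bin_size,
                track_end=read.read_start + re * cfg.bin_size,
                direction=direction,
                speed=speed,
                amplitude=amplitude,
                truncated=truncated,
            )
        )

    # diverging pair (replication bubble): leftward track followed by rightward
    calls.sort(key=lambda c: c.track_start)
    for a, b in zip(calls, calls[1:]):
        if a.direction == "left" and b.direction == "right":
            a.bubble = b.bubble = True
    return calls


def classify_fork(
    fork: ForkCall, genes: Sequence[GeneAnnotation]
) -> list[ForkGeneAssignment]:
    """Relate a fork to every gene it overlaps: co-directional when fork
    travel matches the gene's transcription direction, head-on otherwise.

    The primary assignment is the gene with maximal overlap (ties broken by
    longer gene, then lexicographic gene_id). Forks with undefined
    direction cannot be classified.
    """
    if fork.direction not in ("left", "right"):
        raise ConfigurationError("classify_fork requires a fork with a defined direction")
    assignments: list[ForkGeneAssignment] = []
    for g in genes:
        if g.chrom != fork.chrom:
            continue
        overlap = min(fork.track_end, g.end) - max(fork.track_start, g.start)
        if overlap <= 0:
            continue
        co = (fork.direction == "right" and g.strand == "+") or (
            fork.direction == "left" and g.strand == "-"
        )
        assignments.append(
            ForkGeneAssignment(
                fork=fork,
                gene_id=g.gene_id,
                relation="co_directional" if co else "head_on",
                overlap_bp=overlap,
            )
        )
    if assignments:
        best = max(
            assignments,
            key=lambda a: (a.overlap_bp, _gene_length(genes, a.gene_id), _neg_lex(a.gene_id)),
        )
        assignments = [
            ForkGeneAssignment(a.fork, a.gene_id, a.relation, a.overlap_bp, a is best)
            for a in assignments
        ]
    return assignments


def _gene_length(genes: Sequence[GeneAnnotation], gene_id: str) -> int:
    return next(g.length for g in genes if g.gene_id == gene_id)


class _neg_lex(str):
    """Reverse lexicographic comparison so max() prefers the smaller gene_id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def trim_extremes(values: Sequence[float], fraction: float = 0.01) -> list[float]:
    """Drop the ``floor(n * fraction)`` smallest and largest values."""
    if not 0 <= fraction < 0.5:
        raise ConfigurationError("fraction must be in [0, 0.5)")
    vals = sorted(values)
    k = int(len(vals) * fraction)
    return vals[k : len(vals) - k] if k else vals


def speed_summary(
    forks: Sequence[ForkCall], group_labels: Sequence[str], trim: float = 0.01
) -> dict[str, dict[str, float]]:
    """Per-group median and quartiles of fork speeds, after trimming the
    extreme ``trim`` fraction from each tail; undefined speeds are excluded
    and counted."""
    if len(forks) != len(group_labels):
        raise ConfigurationError("forks and group_labels must be parallel")
    groups: dict[str, list[ForkCall]] = {}
    for f, lab in zip(forks, group_labels):
        groups.setdefault(lab, []).append(f)
    out: dict[str, dict[str, float]] = {}
    for lab, fs in groups.items():
        speeds = [f.speed for f in fs if f.speed is not None]
        if not speeds:
            raise ConfigurationError(f"group {lab!r} has no defined fork speeds")
        trimmed = trim_extremes(speeds, trim)
        q1, med, q3 = np.percentile(trimmed, [25, 50, 75])
        out[lab] = {
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "n": len(trimmed),
            "n_undefined": len(fs) - len(speeds),
        }
    return out


@dataclass(frozen=True)
class ComparisonResult:
    design: str
    statistic: float
    p_value: float
    n: int
    median_difference: float | None = None
    direction: str | None = None  # sign of median(a - b) for paired designs

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "median_difference": self.median_difference,
            "direction": self.direction,
        }


def compare_groups(
    groups: Sequence[Sequence[float]] | tuple[Mapping, Mapping],
    design: str = "unpaired",
) -> ComparisonResult:
    """Statistical comparison of speed (or index) groups.

    ``paired_by_gene``: ``groups`` is a pair of mappings key -> value
    (per-gene medians); a Wilcoxon signed-rank test is run on the paired
    differences over the key intersection. ``unpaired``: ``groups`` is a
    sequence of >= 2 value vectors; a one-way ANOVA F-test is run.
    """
    if design == "paired_by_gene":
        a, b = groups
        keys = sorted(set(a) & set(b))
        if not keys:
            raise ConfigurationError("paired design: empty key intersection")
        diffs = np.array([a[k] - b[k] for k in keys], dtype=float)
        stat, p = stats.wilcoxon(diffs, zero_method="zsplit")
        med = float(np.median(diffs))
        return ComparisonResult(
            design=design,
            statistic=float(stat),
            p_value=float(p),
            n=len(keys),
            median_difference=med,
            direction="negative" if med < 0 else ("positive" if med > 0 else "zero"),
        )
    if design == "unpaired":
        arrays = [np.asarray(g, dtype=float) for g in groups]
        if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
            raise ConfigurationError("unpaired design requires >= 2 groups with n >= 2 each")
        stat, p = stats.f_oneway(*arrays)
        return ComparisonResult(
            design=design, statistic=float(stat), p_value=float(p), n=sum(map(len, arrays))
        )
    raise ConfigurationError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# TSV I/O for BrdU signal and fork calls


def write_brdu_tsv(reads: Iterable[BrdURead], path, stride: int = 1) -> None:
    """Write per-base (or strided per-bin mean) signal as
    read_id, chrom, read_start, offset, value rows."""
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tread_start\toffset\tvalue\n")
        for r in reads:
            if stride == 1:
                vals = r.values
                offsets = range(len(vals))
            else:
                nb = len(r.values) // stride
                vals = r.values[: nb * stride].reshape(nb, stride).mean(axis=1)
                offsets = range(0, nb * stride, stride)
            for off, v in zip(offsets, vals):
                fh.write(f"{r.read_id}\t{r.chrom}\t{r.read_start}\t{off}\t{v:.4g}\n")


def read_brdu_tsv(path) -> list[BrdURead]:
    """Read BrdU signal TSV back into reads (values at the stored stride)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    reads = []
    for (rid, chrom, rstart), sub in df.groupby(["read_id", "chrom", "read_start"], sort=False):
        sub = sub.sort_values("offset")
        offs = sub["offset"].to_numpy()
        stride = int(offs[1] - offs[0]) if len(offs) > 1 else 1
        vals = np.repeat(sub["value"].to_numpy(), stride) if stride > 1 else sub["value"].to_numpy()
        reads.append(BrdURead(str(rid), str(chrom), int(rstart), vals))
    return reads


def write_fork_calls_tsv(calls: Sequence[ForkCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\ttrack_start\ttrack_end\tdirection\tspeed_kb_min\tamplitude\ttruncated\tbubble\n")
        for c in calls:
            speed = "" if c.speed is None else f"{c.speed:.4f}"
            fh.write(
                f"{c.read_id}\t{c.chrom}\t{c.track_start}\t{c.track_end}\t"
                f"{c.direction or 'NA'}\t{speed}\t{c.amplitude:.4f}\t{int(c.truncated)}\t{int(c.bubble)}\n"
            )
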