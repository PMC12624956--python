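"""Promoter-proximal pausing and termination indices from 5'-end tracks.

The pausing index (PI) is the ratio of event density in the
promoter-proximal pause window to the density over the remainder of the
gene body; the termination index (TI) compares the window just past the
TES to the body. Both are density ratios, hence invariant to library
scaling; genes with too few body events, too-short bodies, or (for TI)
insufficient isolation from same-strand neighbours are reported as
undefined with a reason code rather than as 0 or infinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import RAW, StrandedCoverage
from .genome import ConfigurationError, GeneAnnotation, filter_isolated_genes


@dataclass(frozen=True)
class PauseConfig:
    pause_width: int = 100  # bp past the TSS
    term_width: int = 200  # bp past the TES
    min_body_events: float = 10  # threshold applied on the raw-count scale
    numerator: str = "mean"  # 'mean' or 'max' in-window density
    isolation_gap: int = 500  # bp, same-strand isolation required for TI

    def __post_init__(self) -> None:
        if self.pause_width < 1 or self.term_width < 1:
            raise ConfigurationError("pause_width and term_width must be >= 1")
        if self.numerator not in ("mean", "max"):
            raise ConfigurationError("numerator must be 'mean' or 'max'")


@dataclass
class GeneMetrics:
    gene_id: str
    pi: float | None
    ti: float | None
    pause_events: float
    body_events: float
    term_events: float
    pi_reason: str | None = None  # reason code when pi undefined
    ti_reason: str | None = None


def _raw_scale(cov: StrandedCoverage) -> float:
    """Factor converting track values back to raw counts."""
    if cov.norm_state == RAW:
        return 1.0
    if cov.norm_state == "RPM" and cov.total_events > 0:
        return cov.total_events / 1e6
    return 1.0


def _windows(gene: GeneAnnotation, w_p: int, w_t: int):
    """Genomic [start, end) spans of pause window, body, and downstream
    termination window, in transcription direction."""
    if gene.strand == "+":
        pause = (gene.start, gene.start + w_p)
        body = (gene.start + w_p, gene.end)
        term = (gene.end, gene.end + w_t)
    else:
        pause = (gene.end - w_p, gene.end)
        body = (gene.start, gene.end - w_p)
        term = (gene.start - w_t, gene.start)
    return pause, body, term


def _window_events(cov: StrandedCoverage, gene: GeneAnnotation, span: tuple[int, int]) -> float:
    vec = cov.data[gene.chrom][gene.strand]
    s, e = max(span[0], 0), min(span[1], len(vec))
    return float(vec[s:e].sum()) if e > s else 0.0


def pausing_index(
    cov: StrandedCoverage, gene: GeneAnnotation, cfg: PauseConfig = PauseConfig()
) -> tuple[float | None, str | None]:
    """PI = pause-window density / body density on the gene's strand.

    Returns ``(pi, reason)``; ``pi`` is None with a reason code when the
    gene is shorter than twice the pause window or the body carries fewer
    than ``min_body_events`` raw events.
    """
    w_p = cfg.pause_width
    if gene.length <= 2 * w_p:
        return None, "too_short"
    pause, body, _ = _windows(gene, w_p, cfg.term_width)
    body_events = _window_events(cov, gene, body)
    if body_events * _raw_scale(cov) < cfg.min_body_events or body_events == 0:
        return None, "low_body"
    body_density = body_events / (body[1] - body[0])
    if cfg.numerator == "max":
        vec = cov.data[gene.chrom][gene.strand]
        pause_density = float(vec[pause[0] : pause[1]].max())
    else:
        pause_density = _window_events(cov, gene, pause) / w_p
    return pause_density / body_density, None


def termination_index(
    cov: StrandedCoverage,
    gene: GeneAnnotation,
    cfg: PauseConfig = PauseConfig(),
    genes_for_isolation: Sequence[GeneAnnotation] | None = None,
) -> tuple[float | None, str | None]:
    """TI = downstream-window density / body density, for isolated genes only.

    A gene qualifies only if its nearest same-strand annotation (among
    ``genes_for_isolation``) is at least ``cfg.isolation_gap`` bp away on
    both sides, so readthrough signal is not confounded by a downstream
    neighbour's own transcription.
    """
    if genes_for_isolation is not None:
        isolated = {
            g.gene_id for g in filter_isolated_genes(genes_for_isolation, cfg.isolation_gap)
        }
        if gene.gene_id not in isolated:
            return None, "not_isolated"
    w_p, w_t = cfg.pause_width, cfg.term_width
    if gene.length <= 2 * w_p:
        return None, "too_short"
    _, body, term = _windows(gene, w_p, w_t)
    chrom_len = cov.layout.length(gene.chrom)
    if term[0] < 0 or term[1] > chrom_len:
        return None, "off_chromosome"
    body_events = _window_events(cov, gene, body)
    if body_events * _raw_scale(cov) < cfg.min_body_events or body_events == 0:
        return None, "low_body"
    body_density = body_events / (body[1] - body[0])
    term_density = _window_events(cov, gene, term) / w_t
    return term_density / body_density, None


def compute_gene_metrics(
    cov: StrandedCoverage,
    genes: Sequence[GeneAnnotation],
    cfg: PauseConfig = PauseConfig(),
    genes_for_isolation: Sequence[GeneAnnotation] | None = None,
) -> pd.DataFrame:
    """Per-gene PI/TI table with event counts and reason codes."""
    iso = genes if genes_for_isolation is None else genes_for_isolation
    rows = []
    for g in genes:
        pi, pi_reason = pausing_index(cov, g, cfg)
        ti, ti_reason = termination_index(cov, g, cfg, iso)
        pause, body, term = _windows(g, cfg.pause_width, cfg.term_width)
        rows.append(
            {
                "gene_id": g.gene_id,
                "pi": pi,
                "ti": ti,
                "pause_events": _window_events(cov, g, pause),
                "body_events": _window_events(cov, g, body),
                "term_events": _window_events(cov, g, term),
                "pi_reason": pi_reason,
                "ti_reason": ti_reason,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def normalize_to_reference(
    test: pd.DataFrame, ref: pd.DataFrame, metric: str = "pi"
) -> tuple[pd.Series, float, int]:
    """Per-gene log2(test / reference) for genes defined in both tables.

    Returns ``(log2_ratios, median, n_excluded)`` where ``n_excluded``
    counts genes defined in only one table (undefined metrics propagate as
    missing, never as 0 or infinity).
    """
    a = test[metric].dropna()
    b = ref[metric].dropna()
    a = a[a > 0]  # a zero index has no defined log ratio
    b = b[b > 0]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ConfigurationError("no gene has a defined metric in both tables")
    ratios = np.log2(a.loc[common] / b.loc[common])
    n_excluded = len(a.index.union(b.index)) - len(common)
    return ratios, float(ratios.median()), n_excluded


def fraction_decreased(ratios: pd.Series | Sequence[float]) -> float:
    """Fraction of genes whose log2 ratio is strictly negative."""
    arr = np.asarray(ratios, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ConfigurationError("fraction_decreased requires at least one defined ratio")
    return float((arr < 0).mean())
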