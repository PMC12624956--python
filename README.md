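# trctools

Quantitative genomics of transcription–replication conflicts, as a tested,
seedable Python pipeline. The package is aimed at researchers analysing
fission-yeast-scale functional genomics experiments that probe how
transcription and DNA replication interfere: nascent-transcription maps of
paused RNA polymerase II, strand-specific maps of free 3′-OH DNA ends
reporting replication fork direction, and single-molecule BrdU pulse-chase
signals reporting replication fork speed.

## What it computes

**Pausing and termination indices.** Stranded reads are clipped to their 5′
base, giving single-nucleotide polymerase-position tracks (RPM-normalized).
For a gene with TSS-anchored pause window of width *w<sub>p</sub>* and body
*B*,

&nbsp;&nbsp;PI = (pause-window events / *w<sub>p</sub>*) ÷ (body events / |*B*|),

with the body excluding the pause window; the termination index (TI)
replaces the numerator with the window just past the TES and is computed
only for genes ≥ 500 bp from any same-strand annotation. Per-genotype
tables are normalized to a reference genotype as per-gene log₂ ratios, with
the median shift and the fraction of genes decreased.

**Replication fork directionality (RFD).** Ligation-captured 3′-OH ends are
placed on the strand opposite the read, binned, and summarised per bin as

&nbsp;&nbsp;RFD = (REV − FWD)/(REV + FWD),

so rightward-replicated regions (Okazaki 3′-OH ends on the Crick strand)
have positive RFD. Replication origins appear as ascending zero-crossings
of the smoothed profile and are called with a flank-asymmetry gate
(ΔRFD = mean right-flank − mean left-flank); the same Δ statistic is
reported at annotated origins.

**Single-molecule fork speed.** BrdU tracks are modelled as trapezoids (a
fixed-width rise where the pulse caught the fork, a plateau laid down during
the pulse of duration *t<sub>pulse</sub>*, a decay of duration
*t<sub>fall</sub>* during the chase). The half-amplitude track width
(span) gives a closed-form speed estimator

&nbsp;&nbsp;s = (span − r<sub>w</sub>/2)/(t<sub>pulse</sub> + t<sub>fall</sub>/2),

with direction from edge-steepness asymmetry. Forks overlapping genes are
classified head-on or co-directional relative to transcription, and group
speeds are compared by paired Wilcoxon tests (per-gene medians) or one-way
ANOVA.

**Simulators.** Every assay has a seeded simulator that emits
ground-truth-labelled inputs (pause-ratio-designed 5′-end reads,
origin-diverging strand-biased end events with tunable noise, trapezoidal
BrdU reads, ChIP IP/input pairs, small-RNA libraries with duplicates), so
every stage is checked by parameter recovery without any external data.

## Worked example

```python
from trctools import (SimConfig, toy_genome, simulate_gloeseq,
                      events_to_coverage, rfd_profile, detect_origins)
from trctools.genome import GenomeLayout, OriginAnnotation

layout = GenomeLayout({"chr1": 1_000_000})
origins = [OriginAnnotation(f"o{i}", "chr1", p)
           for i, p in enumerate((200_000, 500_000, 800_000))]
cfg = SimConfig(seed=42, layout=layout, genes=[], origins=origins,
                n_reads_gloeseq=200_000, strand_noise=0.05)
events, truth = simulate_gloeseq(cfg)
profile = rfd_profile(events_to_coverage(events, layout), bin_size=1000)
calls, _ = detect_origins(profile, min_delta=0.5, smooth_bins=5)
for c in calls:
    print(c.chrom, c.position, round(c.delta_rfd, 2))
```

prints

```
chr1 199933 1.8
chr1 500350 1.79
chr1 800117 1.8
```

— the three simulated origins recovered within one 1-kb bin, each with a
flank ΔRFD near its noiseless expectation 2·(1 − 2ε) = 1.8 at strand-noise
ε = 0.05.

The same workflow is available from the shell:

```sh
trctools run-all --outdir out --seed 1          # simulate + analyse a 2-genotype demo study
trctools validate --config my_run.yaml          # check a configuration
trctools rfd --events ends.bed --chrom-sizes genome.chrom.sizes --out-prefix out/rfd
```

`run-all` writes per-genotype tracks (bedGraph), per-gene PI/TI tables
(TSV), RFD profiles and origin calls (TSV/BED6), fork calls (TSV), and a
deterministic `report.json` whose every number traces to one of those
files.

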