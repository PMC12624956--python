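# Methods

This note records the models, conventions, parameter choices, and known
limitations behind each stage of the pipeline.

## Coordinates and annotations

All coordinates are 0-based, half-open `[start, end)` (BED-style). A gene's
TSS is `start` on the + strand and `end − 1` on the − strand; the TES is the
opposite end. The same-strand isolation filter measures gaps between
interval boundaries (`next.start − this.end`); "at least `min_gap` away" is
inclusive, so a gap of exactly 500 bp passes the default filter. Overlapping
same-strand annotations exclude each other at any threshold, including
`min_gap = 0`. Different chromosomes never constrain each other. Gene class
(mRNA / rDNA / other) is encoded in the BED name field as `id|class`,
defaulting to mRNA.

## Event tracks

5′-end tracks place one count per read at the read's 5′-most base on the
read's own strand — the literal single-nucleotide polymerase position for
run-on libraries. Whether a library's read 5′ end coincides with the
nascent-RNA 3′ end depends on the library chemistry and read orientation;
this implementation performs the literal 5′ clip, and a library whose
orientation is inverted should have its read strands flipped upstream.

3′-OH end tracks place the free-end position on the strand *opposite* the
read. The default `adjacent` mode shifts one base 5′-ward of the read start
(the captured end abuts the read); `coincident` applies no shift. Events
shifted off-chromosome are dropped and counted, never clamped.

RPM normalization scales by 10⁶/library size. Log₂ ratios use a 1.0 RPM
pseudocount (standard; avoids infinities at empty bases) and can pool
strands for strand-agnostic enrichment heatmaps; differential tracks are
plain per-base subtractions of same-state tracks.

## Metagene matrices

Scale-regions projection: 500 bp of upstream flank in fixed 10-bp bins, the
gene body collapsed to 100 equal real-valued spans, 500 bp of downstream
flank. Body bin edges are real-valued with fractional-base weighting via a
linearly interpolated cumulative sum, so any body ≥ 100 bp bins
deterministically; shorter genes are dropped with a warning. Columns are
reported in transcription order for both strands. Bases beyond a chromosome
edge contribute zero coverage to a flank bin. Flank bin width and body bin
count are configurable; the defaults mirror common scale-regions practice.

## Pausing and termination indices

PI is the pause-window density (default 100 bp past the TSS) over body
density, the body *excluding* the pause window so the pause signal does not
dilute its own denominator. TI uses a 200-bp window past the TES. The
window sizes are package defaults, configurable and echoed in output
metadata. The numerator uses the mean in-window density; a max-in-window
variant is available as a config option. The `min_body_events` threshold
(default 10) is applied on the raw-count scale even for RPM tracks —
dividing two RPM-rescaled noise counts would otherwise produce stable-looking
garbage ratios. Undefined indices carry a reason code
(`too_short` / `low_body` / `not_isolated` / `off_chromosome`) and propagate
as missing, never as 0 or ∞. Reference normalization takes per-gene
log₂(test/ref) over genes with defined, strictly positive values in both
tables (a zero index has no defined log ratio) and reports the median and
the fraction of genes strictly decreased.

## RFD and origin calling

Per non-overlapping bin (default 1 kb), RFD = (REV − FWD)/(REV + FWD);
empty bins are undefined, never zero-filled. Sign convention: Okazaki
3′-OH ends of a rightward fork lie on the Crick strand, so rightward
regions have positive RFD and origins are ascending transitions; an
`invert` flag accommodates end-capture chemistries that report the other
strand.

Origin detection smooths RFD with a centred moving average over defined
bins (default 5), finds sign changes, and gates each candidate on the
unsmoothed flank asymmetry Δ = mean RFD over the right flank − left flank
(flank = smoothing window × bin size, default 5 kb), calling origins where
Δ ≥ 0.5. Runs of exactly-zero bins yield a call at the run's centre bin;
otherwise the crossing position is linearly interpolated between bin
midpoints. Descending crossings are reported separately as termination-zone
candidates. At annotated origins both the flank-difference Δ (10-kb flanks
by default) and the single-bin RFD are reported, since either may be the
quantity of interest for origin-activity distributions.

## Fork speed from BrdU pulse-chase

The BrdU track is modelled as a trapezoid: linear rise of fixed width
r_w = 100 bp (where the fork sat when the pulse began), plateau of length
s·t_pulse, linear fall of length s·t_fall as the label is diluted during
the chase. Half-amplitude crossings then satisfy

    span = x_R − x_L = r_w/2 + s·(t_pulse + t_fall/2)

giving the closed-form estimator s = (span − r_w/2)/(t_pulse + t_fall/2).
Defaults t_pulse = 2 min (the pulse duration), t_fall = 1 min and r_w =
100 bp are shared constants between the simulator and the estimator. This
deliberately replaces the empirical incorporation kinetics of dedicated
nanopore fork-speed callers with a shape whose estimator is exactly
invertible; bit-compatibility with any external caller is a non-goal.

Detection: per-read signal is averaged in 100-nt bins; background is the
median bin (valid while tracks occupy a minority of the read); candidate
tracks are maximal runs of bins above background + min_amplitude/2 (default
min_amplitude 0.3); track amplitude is the median of near-plateau bins,
robust to single-bin noise spikes. Half- and quarter-amplitude crossings
are located by linear interpolation walking outward from the peak, bounding
the span error by about one bin (≈ 0.04 kb/min at the default timing
constants). Direction is the side of the shallower edge (the chase edge is
s·t_fall ≫ r_w wide); edges whose 25–75% widths differ by less than 1.5×
leave the direction undefined and the fork unclassified. Tracks touching a
read end are flagged truncated with undefined speed. A leftward call
immediately followed by a rightward call is flagged as a diverging pair
(replication bubble). Cohort summaries trim the top and bottom 1% of
speeds before reporting medians and quartiles.

Fork–gene classification: co-directional iff fork travel matches the
overlapped gene's transcription direction. The primary assignment is the
gene with maximal overlap, ties broken by longer gene then lexicographic
id — one relation per fork for group comparisons.

## Statistics

Paired comparisons (head-on vs co-directional speeds) use the Wilcoxon
signed-rank test on per-gene paired medians (`zsplit` zero handling, so
identical vectors give p ≈ 1 rather than an error); the pairing unit being
the gene is this package's choice and is flagged in reports. Unpaired
multi-group comparisons use one-way ANOVA. Results carry the statistic, p,
n, design, and the direction of the median paired difference.

## Simulators and what they do and do not emulate

All simulators draw from per-assay pseudo-random streams spawned from the
master seed, so adding one assay never perturbs another, and identical
seed + config give byte-identical outputs. Read/event counts are exact.

* **5′-end libraries**: within a gene of length L, a read's position falls
  in the pause window with probability q = r·w_p/(r·w_p + (L − w_p)),
  making the designed pause/body density ratio exactly r; reads are
  distributed uniformly across genes, with a configurable genome-wide
  background fraction (default 5%). Not emulated: expression-level
  variation between genes, readthrough past the TES, sequence bias.
* **3′-OH end events**: fork direction partitions each chromosome at
  origins and inter-origin midpoints (outermost regions point outward);
  event positions are uniform (no Okazaki fragment-length structure, since
  RFD depends only on the strand ratio); each event's strand is flipped
  with probability ε, so rightward-region RFD has expectation 1 − 2ε.
  ε is a free noise parameter, not an estimate of any real library.
* **BrdU reads**: 50-kb reads, one trapezoidal track each, speeds from a
  normal (mean 1.8, sd 0.4 kb/min — typical eukaryotic fork rates)
  truncated at 0.2; per-base observations are Bernoulli draws with
  in-track probability 0.8 and background 0.02. A `headon_multiplier`
  scales the speed of forks laid down head-on to an overlapping gene,
  emulating conflict-induced slowdown. Tracks longer than the read are
  truncated and flagged in the truth table. Not emulated: raw nanopore
  signal, basecalling error structure, multi-fork interference beyond two
  tracks per read.
* **ChIP pairs**: input uniform; IP density multiplied by the configured
  fold inside target intervals. The in-target log₂(IP/input) approaches
  log₂(fold) only when targets are small relative to the genome (RPM
  renormalization deflates it otherwise) — tests use small targets.
* **Small RNA**: lengths from a configurable weight table (default uniform
  20–30 nt); each read after the first duplicates a random earlier read
  with the configured probability; random sequence content.
* **Paired speed study**: per-gene true speeds with independent lognormal
  measurement noise per arm (sd 0.06, emulating per-gene medians over a
  few forks) and a head-on multiplier; used for power/level checks of the
  paired test without simulating thousands of reads.

Because the simulators realise exactly the models the estimators invert,
passing recovery tests demonstrates internal consistency and correct
implementation — not that real libraries satisfy these models. Real data
add alignment artefacts, copy-number and replication-timing structure,
expression heterogeneity and batch effects that are out of scope here.

## Pipeline and problem sizes

The orchestrated run simulates each genotype with a child seed spawned from
the master seed, analyses every stage, and writes a report whose JSON is
byte-identical across repeated runs with the same config and seed
(timestamps excluded). The default demo study uses 50k 5′-end reads, 50k
end events and 60 BrdU reads per genotype on a 2×1-Mb toy genome with ~200
genes — sizes chosen so a full two-genotype run completes in seconds on one
CPU while leaving every statistic well-resolved. The acceptance script uses
larger cohorts (2×10⁵ end events, ≥600 genes × ~130 reads, 500 BrdU reads,
50 noise-control replicates) as its standard conditions.

## Known limitations

* The TI definition depends on an upstream-published window convention the
  pipeline cannot recover; the 200-bp default is a documented choice.
* Origin calls are limited to bin resolution; sub-kilobase origin mapping
  would need smaller bins and correspondingly more events.
* The fork caller assumes at most modest track overlap; heavily fused
  diverging tracks merge into one run and are reported as a single call.
* BAM input is out of scope; the tested I/O surface is BED6 / TSV / FASTQ /
  bedGraph.
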