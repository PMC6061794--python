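# Methods

This note documents the statistical conventions, models and design
choices behind `poreqc`, in the order a reader meets them: per-read
metrics, aggregate statistics, run-level QC, the streaming processors,
and the synthetic-data generators the tests are built on.

## Per-read metrics

**Mean read quality.** A Phred score `q` encodes an error probability
`p = 10^(-q/10)`. Because the scale is logarithmic, averaging Phred
values arithmetically biases the result upward (a read that is half Q5
and half Q30 is far closer to Q8 than to Q17.5). The package therefore
always averages in probability space:

    Q_mean = -10 · log10( (1/L) Σ_b 10^(-q_b/10) )

This value is bounded by the minimum and maximum per-base score and
equals the common value for a constant-quality read. FASTQ qualities
are decoded at Phred+33; offset-64 encodings are deliberately out of
scope (they do not occur in modern long-read data). Sequencing-summary
input carries no per-base qualities, so its `mean_qscore` column is
taken verbatim; `ReadTable.source_kind` records the provenance so the
two definitions are never silently mixed.

**GC content** is computed over unambiguous A/C/G/T only: ambiguous
bases are excluded from both numerator and denominator, and a read with
no unambiguous bases has *absent* GC rather than 0 or 0.5. This keeps a
GC filter from systematically misclassifying N-rich reads.

**N50** follows the standard assembly convention: sort lengths
descending, accumulate, and return the first (largest) length at which
the running sum reaches at least half the total (ties broken by
inclusion, `≥`). The result is always an element of the input.

**Percent identity** uses the aligner's edit distance (`NM` tag) over
all alignment columns: `100·(1 − NM / Σ len(M/=/X/I/D))`. Soft clips are
excluded. This convention counts every error the aligner reports exactly
once; alternatives that divide by matched columns only (excluding
indels) give slightly higher values on indel-rich long reads, so the
choice is documented rather than asserted as universal.

**Aligned length** is measured on the query: the sum of CIGAR M/I/=/X
operation lengths, excluding soft clips. Read length is the stored query
length including soft clips, so `aligned_length ≤ length` always holds
and both quantities live on the same axis — the gap between them
identifies partially aligned reads. Hard-clipped bases are unrecoverable
from the file and are not counted in either quantity; this is the one
caveat of BAM-derived lengths.

**Caveat on BAM input.** One record is emitted per primary alignment;
secondary and supplementary records are skipped, and unmapped reads
contribute a length-only record.

## Aggregate statistics

`summarize` reports read/base counts, mean and median length, N50, the
top-5 longest reads, and quality statistics computed over the per-read
mean qualities (each of which is already probability-space averaged):
the dataset-level mean and median are plain arithmetic over those
per-read values, since a dataset has no single base-level error pool to
average. Reads lacking a field are skipped and the count used is
reported (`n_with_quality`). Threshold tiers default to Q5/7/10/12/15 —
a configurable choice spanning the practically interesting range
(Q7 ≈ 20% error, Q12 ≈ 6%); counts are non-increasing in the threshold
by construction.

Start times are normalized to seconds since the earliest read in the
dataset, because basecaller versions differ in whether stamps are
absolute or run-relative. Time bins are contiguous half-open intervals
`[0, w), [w, 2w), …` with `w = 6 h` by default, the interval at which
quality drift over a run is conventionally inspected.

## Flow-cell geometry

A MinION flow cell addresses 512 channels on a 16×32 physical grid. The
channel→cell wiring is vendor data, not an algorithm, so it ships as a
TSV (`channel`, `row`, `col`) that users can replace. The packaged map
is a best-effort reconstruction — four horizontal blocks of 128
channels, filled column-major within each block — and every layout is
validated as a bijection onto its grid at load time. A placeholder
3000-channel grid is provided for PromethION-scale channel ids; when a
dataset's channels exceed the active layout the error suggests the
larger layout rather than silently truncating.

## Plot payloads and rendering

Plot *computation* is separated from *rendering*: each plot is first a
`PlotData` of plain numeric arrays, so tests assert on bin counts and
density integrals instead of pixels. Conservation invariants hold
throughout: histogram and hexbin counts sum to the contributing reads,
with excluded reads (missing fields, non-positive lengths under log10)
tallied explicitly in the payload. The 2D KDE uses Scott's-rule
bandwidths per axis (recorded in the payload annotations), evaluated on
a 128×128 grid extended 5 bandwidths beyond the data range so the
trapezoid-rule integral is 1 within 1%. Hexbin grids default to 35
cells across; marginal histograms reuse the main-axis bin count. Violin
payloads store the raw per-bin values; the renderer computes the violin
shapes. SVG output uses a fixed hash salt and stripped date metadata so
repeated renders are byte-identical.

## Streaming filter

The filter trims `headcrop`/`tailcrop` bases first and then evaluates
all predicates on the **trimmed** read: trimming exists to remove
low-quality ends, so the retained read is judged as it will be emitted.
(Whether to judge before or after trimming is a genuine design fork;
the post-trim choice is documented here as deliberate.) Each read is
counted under exactly one rejection reason — the first failing test in
the fixed order trim → length → quality → GC — making the report
additive: `input = emitted + Σ rejections`. A read with no unambiguous
bases fails a GC bound (the bound expresses intent to screen on
composition) but passes when no bound is set. Headers are preserved
verbatim, including comments after the id; processing is strictly one
record at a time, so memory use is independent of stream length.

## Contaminant screen

A read is dropped as soon as the aligner reports ≥1 mapping to the
contaminant reference — no identity or length threshold, because even
partial homology to a spike-in control is grounds for removal in the
intended use; this knowingly sacrifices reads from genome regions
homologous to the contaminant. The aligner is a port with two backends:

- the Minimap2 `mappy` binding (used when importable, preset
  `map-ont`), and
- a built-in exact-seed screen: a table of all reference 15-mers on
  both strands; a read maps when at least `min_seeds = 3` of its k-mers
  hit, optionally required to fall within a window of the read
  (`window = None`, i.e. the whole read, by default — the simplest rule
  that is exact on the test fixtures).

The seed screen is deterministic, dependency-free and strand-aware; its
15-mer seeds make false positives impossible against any reference
sharing no 15-mers with the reads' source. The packaged default
reference is a clearly labelled *synthetic* stand-in for the lambda
phage control (the CLI warns when it is used); pass `--reference` with
the real contaminant genome in production.

## Synthetic data generators

Every generator is a pure function of its parameters and seed
(byte-identical reruns) and writes a truth table alongside its output,
so downstream statistics are checked against bookkeeping rather than
re-derived. Defaults emulate a typical nanopore run:

- **lengths**: lognormal with `mu = 8.5`, `sigma = 1.0` in log-bases
  (median ≈ 4.9 kb, long right tail into the hundreds of kb);
- **per-base qualities**: Gaussian around Q12 (sd 3), clipped to
  [1, 60];
- **run summaries**: start times uniform over the run, channels uniform
  over 1..512, mean qscore `base − drift·hours + noise` to emulate
  late-run quality decline;
- **alignments**: reads sampled from a generated reference with point
  substitutions at rate `1 − identity`, NM and CIGAR consistent with
  the introduced edits by construction; a configurable fraction of
  reads receives soft-clipped ends to model partial alignment;
- **contaminated mixtures**: contaminant reads are substrings (with 5%
  point errors) of a generated 10 kb stand-in genome; clean reads are
  verbatim substrings of an independent genome regenerated until its
  15-mer set (both strands) is disjoint from the stand-in's, which
  guarantees the seed screen cannot produce false positives and makes
  the expected screen outcome exact, not statistical.

What these generators do **not** model: nanopore homopolymer bias,
indel-dominated error profiles, signal-level artefacts, pore-death
channel dynamics, or correlated quality/length structure. Passing tests
therefore demonstrate correctness of the computations and conservation
properties, not robustness to every real-world pathology.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale by design:
10⁴ reads for reader/filter checks, 10³ simulated alignments, 5·10³
summary rows, 500/500 contaminated mixtures, KDE on ≤1500 points. These
sizes make sampling-based assertions tight (3-standard-error bounds)
while completing in seconds. Degenerate inputs follow a uniform policy:
empty statistics inputs are errors with a message naming the dataset;
empty files parse to empty tables; zero-length reads are excluded from
log-scale plots and tallied; absent optional fields propagate as absent
statistics, never as sentinel numbers. Downsampling uses a seeded
generator (default seed 1) with order-preserving selection, exposed as
a global `--seed` on the CLI.
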