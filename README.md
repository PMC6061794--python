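# poreqc

Quality control, filtering and decontamination for long-read sequencing
data (Oxford Nanopore / PacBio style reads).

Long-read runs differ from short-read data in every way that matters for
QC: read lengths are log-normally long-tailed (routinely 10 kb, up to
megabases), per-base accuracy is in the 85–95% range, and run metadata
(flow-cell channel, start time) carries as much diagnostic signal as the
reads themselves. `poreqc` is a library plus a small CLI for exactly this
setting, for sequencing-facility staff and bioinformaticians triaging
runs before alignment and assembly.

## What it computes

- **Per-read features** from FASTQ/FASTA (plain or gzipped), SAM/BAM, or
  basecaller sequencing-summary TSVs: length, GC, mean quality, start
  time, channel, barcode, aligned length, percent identity, MAPQ.
- **Mean read quality in probability space.** Phred scores are
  log-scaled error probabilities, so a read's mean quality is
  `Q = -10·log10( mean_b 10^(-q_b/10) )`, never the arithmetic mean of
  Phred values (which overstates accuracy).
- **N50**: the largest length `L` such that reads of length ≥ `L`
  contain at least half of all sequenced bases.
- **Percent identity** from the alignment: `100·(1 − NM/columns)` where
  `columns` counts M/=/X/I/D CIGAR operations — an accuracy proxy that
  counts every reported error exactly once.
- **Run-level QC plots** as numeric payloads first, images second:
  length histograms (linear or log10, optional N50 marker), cumulative
  yield over time, the 512-channel flow-cell activity heatmap, quality
  violins per 6 h interval, bivariate hexbin/KDE plots, cross-run
  comparisons — all assembled into a self-contained HTML report.
- **Streaming processors** for pipelines: a constant-memory FASTQ
  filter/trimmer (quality, length, GC, head/tail crop) and a contaminant
  screen that drops any read mapping to a contaminant reference (for
  example, the lambda phage spike-in control).

## Worked example

```python
from poreqc import fixtures, metrics, readers

path, truth = fixtures.make_fastq("run.fastq", n=2000, seed=1)
table = readers.read_fastq(path, label="example run")
stats = metrics.summarize(table)
print(stats.n_reads, stats.total_bases, stats.n50, round(stats.mean_quality, 1))
```

prints (seed 1):

```
2000 16230625 12852 11.0
```

i.e. 2000 reads totalling 16.2 Mb; half of those bases are in reads of
at least 12,852 b (the N50); the average read quality is Q11.0,
corresponding to an expected per-base error of about 8%. The
`examples/` directory holds one short narrative script per capability
(statistics, run QC plots, run comparison, filter + decontaminate), and
the same stack is available from the shell:

```sh
poreqc stats --fastq run.fastq
poreqc plot --summary sequencing_summary.txt -o qc/
poreqc filt -q 9 -l 500 < in.fastq | poreqc lyse --reference lambda.fasta > clean.fastq
```

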