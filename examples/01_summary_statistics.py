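"""Summary statistics for one sequencing run.

Generates a small synthetic FASTQ, parses it, and prints the aggregate
statistics block: read/base counts, length distribution (N50), and the
probability-space quality summary with threshold tiers.
"""

import tempfile
from pathlib import Path

from poreqc import fixtures, metrics, readers, report

with tempfile.TemporaryDirectory() as tmp:
    fastq, _ = fixtures.make_fastq(Path(tmp) / "run.fastq", n=2000, seed=1)
    table = readers.read_fastq(fastq, label="example run")

stats = metrics.summarize(table)
print(report.stats_to_frame(stats).to_string())
print()
print(
    f"N50 = {stats.n50} b: half of all {stats.total_bases} sequenced bases "
    f"are in reads at least this long. Mean quality Q{stats.mean_quality:.1f} "
    f"corresponds to ~{100 * 10 ** (-stats.mean_quality / 10):.1f}% expected base error."
)
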