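"""Compare two sequencing runs side by side.

Simulates a long-read run and a shorter, higher-quality run, then builds
the grouped comparison payloads and the per-run summary table — the
numbers behind a run-comparison violin plot.
"""

import tempfile
from pathlib import Path

from poreqc import fixtures, readers, report

with tempfile.TemporaryDirectory() as tmp:
    a, _ = fixtures.make_fastq(
        Path(tmp) / "a.fastq", n=800, length_dist=("lognormal", 8.8, 1.0),
        quality_dist=("normal", 11, 3), seed=3,
    )
    b, _ = fixtures.make_fastq(
        Path(tmp) / "b.fastq", n=800, length_dist=("lognormal", 7.8, 0.8),
        quality_dist=("normal", 13, 2), seed=4,
    )
    tables = [
        readers.read_fastq(a, label="ultra-long prep"),
        readers.read_fastq(b, label="ligation prep"),
    ]

plots, frame = report.compare(tables, log_length=True)
print(frame.to_string())
print()
row = frame.loc["ultra-long prep"]
print(
    f"the ultra-long prep trades quality (Q{row.mean_quality:.1f} vs "
    f"Q{frame.loc['ligation prep'].mean_quality:.1f}) for length "
    f"(N50 {row.n50} vs {frame.loc['ligation prep'].n50} b)"
)
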