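"""Stream-filter a read set and strip spike-in control reads.

Mirrors the shell pipeline

    poreqc filt -q 9 -l 500 --headcrop 20 < in.fastq | poreqc lyse --reference control.fasta > out.fastq

on a synthetic mixture of genomic reads and reads from a stand-in
control genome, where the truth labels are known.
"""

import tempfile
from pathlib import Path

from poreqc import decontam, filtering, fixtures
from poreqc.model import FilterSpec

with tempfile.TemporaryDirectory() as tmp:
    fastq, reference, truth = fixtures.make_contaminated_set(
        tmp, n_clean=400, n_contaminant=100, seed=5
    )

    spec = FilterSpec(min_quality=9.0, min_length=500, headcrop=20)
    filt_report = filtering.FilterReport()
    with open(fastq) as fh:
        filtered = list(
            filtering.filter_stream(filtering.parse_fastq_stream(fh), spec, filt_report)
        )

    aligner = decontam.build_aligner(reference, prefer_mappy=False)
    screen_report = decontam.ScreenReport()
    kept = list(decontam.screen_stream(filtered, aligner, screen_report))

print("filter: ", " ".join(filt_report.as_lines()))
print("screen: ", " ".join(screen_report.as_lines()))
n_true = truth.is_contaminant.sum()
print(
    f"\n{filt_report.emitted}/{filt_report.input} reads passed the quality/length "
    f"filter; the contaminant screen then removed {screen_report.removed} reads "
    f"(the mixture contained {n_true} control-derived reads, some of which the "
    "length filter had already dropped)."
)
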