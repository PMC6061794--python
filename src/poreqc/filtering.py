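"""Streaming FASTQ filtering and trimming.

Designed for use inside shell pipelines ahead of alignment: reads FASTQ
record by record (constant memory), trims a fixed number of bases from
either end, then tests the *trimmed* read against length, mean-quality
and GC bounds — trimming exists to remove low-quality ends, so the
retained read is judged as it will be emitted. Each rejected read is
counted under exactly one reason, the first failing test in the fixed
order trim -> length -> quality -> gc, so the report is additive:
input = emitted + sum of rejections.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import metrics
from .model import FilterSpec

# (title, sequence, quality) with the original header preserved verbatim
FastqRecord = tuple[str, str, str]

REJECTION_ORDER = ("trim", "length", "quality", "gc")


@dataclass
class FilterReport:
    input: int = 0
    emitted: int = 0
    rejected: dict[str, int] = field(
        default_factory=lambda: {reason: 0 for reason in REJECTION_ORDER}
    )

    def as_lines(self) -> list[str]:
        lines = [f"input={self.input}", f"emitted={self.emitted}"]
        lines += [f"rejected_{k}={v}" for k, v in self.rejected.items()]
        return lines


def trim_read(record: FastqRecord, headcrop: int = 0, tailcrop: int = 0) -> FastqRecord | None:
    """Crop sequence and quality identically; None when nothing survives."""
    title, seq, qual = record
    if headcrop + tailcrop >= len(seq):
        return None
    end = len(seq) - tailcrop
    return (title, seq[headcrop:end], qual[headcrop:end])


def _passes(seq: str, qual: str, spec: FilterSpec) -> str | None:
    """First failing criterion of the trimmed read, or None if it passes."""
    if spec.min_length is not None and len(seq) < spec.min_length:
        return "length"
    if spec.max_length is not None and len(seq) > spec.max_length:
        return "length"
    if spec.min_quality is not None:
        if metrics.mean_read_quality(metrics.phred_from_string(qual)) < spec.min_quality:
            return "quality"
    if spec.has_gc_bound:
        gc = metrics.gc_fraction(seq)
        if gc is None:
            # a GC bound expresses intent to screen on composition;
            # a read with no unambiguous bases cannot satisfy it
            return "gc"
        if spec.min_gc is not None and gc < spec.min_gc:
            return "gc"
        if spec.max_gc is not None and gc > spec.max_gc:
            return "gc"
    return None


def filter_stream(records: Iterable[FastqRecord], spec: FilterSpec, report: FilterReport | None = None) -> Iterator[FastqRecord]:
    """Lazily yield the trimmed records that pass the FilterSpec.

    Order-preserving subsequence of the trimmed input; the report (if
    given) is updated as records are consumed.
    """
    if report is None:
        report = FilterReport()
    for record in records:
        report.input += 1
        trimmed = trim_read(record, spec.headcrop, spec.tailcrop)
        if trimmed is None:
            report.rejected["trim"] += 1
            continue
        reason = _passes(trimmed[1], trimmed[2], spec)
        if reason is not None:
            report.rejected[reason] += 1
            continue
        report.emitted += 1
        yield trimmed


def parse_fastq_stream(handle: IO[str]) -> Iterator[FastqRecord]:
    """FASTQ records from a text stream; malformed input names the ordinal."""
    ordinal = 0
    try:
        for record in FastqGeneralIterator(handle):
            ordinal += 1
            yield record
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ after record {ordinal}: {exc}") from exc


def write_fastq_record(handle: IO[str], record: FastqRecord) -> None:
    title, seq, qual = record
    handle.write(f"@{title}\n{seq}\n+\n{qual}\n")


def filter_fastq(instream: IO[str], outstream: IO[str], spec: FilterSpec, report_stream: IO[str] = sys.stderr) -> FilterReport:
    """stdin->stdout streaming entry point used by the CLI.

    Writes passing records to ``outstream`` one at a time and the
    key=value report to ``report_stream`` when the stream ends.
    """
    report = FilterReport()
    for record in filter_stream(parse_fastq_stream(instream), spec, report):
        write_fastq_record(outstream, record)
    for line in report.as_lines():
        print(line, file=report_stream)
    return report
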