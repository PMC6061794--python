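"""Streaming removal of contaminant reads.

A typical nanopore run spikes in lambda phage DNA as a calibration
control; those reads must be dropped before analysis. Reads are streamed
one at a time and a read is removed as soon as the aligner reports at
least one mapping to the contaminant reference — no identity or length
threshold by default, because reads from genome regions homologous to the
contaminant are deliberately (if regrettably) sacrificed.

The aligner is a port with two implementations: the Minimap2 binding
(mappy) when importable, and a built-in exact-seed screen (sorted table
of reference 15-mers on both strands; a read maps when at least
``min_seeds`` of its k-mers hit). The seed screen has no native
dependencies and is fully deterministic.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Protocol

from Bio import SeqIO
from Bio.Seq import Seq

from .filtering import FastqRecord, parse_fastq_stream, write_fastq_record

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Mapping:
    """One reported placement of a read on the contaminant reference."""

    target: str
    strand: int  # +1 / -1
    identity: float  # approximate, in [0, 1]


class AlignerPort(Protocol):
    """Contract every aligner backend satisfies: deterministic mapping lookup."""

    def map(self, sequence: str) -> list[Mapping]: ...


class KmerSeedAligner:
    """Exact-seed contaminant screen.

    Indexes every k-mer (default k=15) of the reference on both strands;
    a read maps when >= ``min_seeds`` of its k-mers hit, optionally
    required to fall within a ``window``-base stretch of the read.
    Reported identity is the fraction of read k-mers that hit — a crude
    proxy, adequate for a presence/absence screen.
    """

    def __init__(self, references: dict[str, str], k: int = 15, min_seeds: int = 3, window: int | None = None):
        if not references or all(len(s) < k for s in references.values()):
            raise ValueError("empty contaminant reference: nothing to screen against")
        self.k = k
        self.min_seeds = min_seeds
        self.window = window
        self._index: dict[str, tuple[str, int]] = {}
        for name, seq in references.items():
            seq = seq.upper()
            for strand, s in ((1, seq), (-1, reverse_complement(seq))):
                for i in range(len(s) - k + 1):
                    self._index.setdefault(s[i : i + k], (name, strand))

    def map(self, sequence: str) -> list[Mapping]:
        seq = sequence.upper()
        k = self.k
        n_kmers = len(seq) - k + 1
        if n_kmers < 1:
            return []
        hits: list[tuple[int, str, int]] = []  # (position, target, strand)
        for i in range(n_kmers):
            entry = self._index.get(seq[i : i + k])
            if entry is not None:
                hits.append((i, *entry))
        if len(hits) < self.min_seeds:
            return []
        if self.window is not None:
            positions = [p for p, _, _ in hits]
            ok = any(
                positions[j + self.min_seeds - 1] - positions[j] < self.window
                for j in range(len(positions) - self.min_seeds + 1)
            )
            if not ok:
                return []
        target, strand = hits[0][1], hits[0][2]
        return [Mapping(target=target, strand=strand, identity=len(hits) / n_kmers)]


class MappyAligner:
    """Minimap2-backed port (production path); requires the mappy binding."""

    def __init__(self, reference_path: str, preset: str = "map-ont"):
        import mappy  # deferred: optional dependency

        self._aligner = mappy.Aligner(str(reference_path), preset=preset)
        if not self._aligner:
            raise ValueError(f"could not index contaminant reference {reference_path}")

    def map(self, sequence: str) -> list[Mapping]:
        return [
            Mapping(
                target=hit.ctg,
                strand=hit.strand,
                identity=hit.mlen / hit.blen if hit.blen else 0.0,
            )
            for hit in self._aligner.map(sequence)
        ]


def load_reference(path) -> dict[str, str]:
    """Contaminant reference FASTA as {name: sequence}; empty file is an error."""
    refs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not refs:
        raise ValueError(f"unreadable or empty contaminant reference: {path}")
    return refs


def build_aligner(reference_path, prefer_mappy: bool = True, **kwargs) -> AlignerPort:
    """Minimap2 binding when importable, otherwise the built-in seed screen."""
    if prefer_mappy:
        try:
            return MappyAligner(str(reference_path))
        except ImportError:
            pass
    return KmerSeedAligner(load_reference(reference_path), **kwargs)


@dataclass
class ScreenReport:
    input: int = 0
    kept: int = 0
    removed: int = 0

    def as_lines(self) -> list[str]:
        return [f"input={self.input}", f"kept={self.kept}", f"removed={self.removed}"]


def screen_stream(records: Iterable[FastqRecord], aligner: AlignerPort, report: ScreenReport | None = None) -> Iterator[FastqRecord]:
    """Yield reads with no mapping to the contaminant, unchanged and in order."""
    if report is None:
        report = ScreenReport()
    for record in records:
        report.input += 1
        try:
            mappings = aligner.map(record[1])
        except Exception as exc:  # aligner failure must name the read
            raise RuntimeError(
                f"aligner failed on read {record[0].split()[0]!r}: {exc}"
            ) from exc
        if mappings:
            report.removed += 1
        else:
            report.kept += 1
            yield record


def screen_fastq(instream: IO[str], outstream: IO[str], aligner: AlignerPort, report_stream: IO[str] = sys.stderr) -> ScreenReport:
    """stdin->stdout streaming entry point used by the CLI."""
    report = ScreenReport()
    for record in screen_stream(parse_fastq_stream(instream), aligner, report):
        write_fastq_record(outstream, record)
    for line in report.as_lines():
        print(line, file=report_stream)
    return report
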