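"""Build ReadTables from FASTQ, FASTA, SAM/BAM and sequencing-summary files.

All text inputs may be gzip-compressed (detected by magic bytes, not file
extension), and several files of the same type may be concatenated. The
per-read quality of FASTQ input is always recomputed from the quality
string (probability-space average); the mean qscore of a sequencing
summary is trusted verbatim because no per-base qualities exist there —
`ReadTable.source_kind` records which definition a table carries.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
from typing import Iterable

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import metrics
from .model import ReadRecord, ReadTable

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"

# Column aliases across basecaller dialects; first entry is the albacore name.
SUMMARY_ALIASES: dict[str, tuple[str, ...]] = {
    "read_id": ("read_id", "read_name"),
    "channel": ("channel", "ch"),
    "start_time": ("start_time", "template_start"),
    "length": ("sequence_length_template", "sequence_length", "seqlen"),
    "quality": ("mean_qscore_template", "mean_qscore", "mean_q"),
    "barcode": ("barcode_arrangement", "barcode", "barcode_id"),
}


def _open_text(path: str | os.PathLike) -> io.TextIOBase:
    """Open plain or gzip-compressed text transparently (magic-byte sniff)."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _as_list(paths) -> list:
    if isinstance(paths, (str, os.PathLike)):
        return [paths]
    paths = list(paths)
    if not paths:
        raise ValueError("no input files given")
    return paths


def read_fastq(paths, label: str = "dataset") -> ReadTable:
    """One ReadRecord per FASTQ record, files concatenated in path order.

    length, GC fraction and probability-space mean quality are computed
    from the sequence and quality strings.
    """
    records: list[ReadRecord] = []
    for path in _as_list(paths):
        with _open_text(path) as handle:
            try:
                for title, seq, qual in FastqGeneralIterator(handle):
                    read_id = title.split()[0] if title else ""
                    if len(seq) != len(qual):
                        raise ValueError(
                            f"malformed FASTQ record {read_id!r} in {path}: "
                            f"sequence length {len(seq)} != quality length {len(qual)}"
                        )
                    records.append(
                        ReadRecord(
                            read_id=read_id,
                            length=len(seq),
                            mean_quality=(
                                metrics.mean_read_quality(metrics.phred_from_string(qual))
                                if seq
                                else None
                            ),
                            gc_fraction=metrics.gc_fraction(seq),
                        )
                    )
            except ValueError as exc:
                raise ValueError(f"{path}: {exc}") from exc
    return ReadTable(label=label, records=records, source_kind="fastq")


_IUPAC = set("ACGTURYSWKMBDHVN")


def read_fasta(paths, label: str = "dataset") -> ReadTable:
    """ReadRecords with length and GC fraction only; no qualities exist.

    Characters outside the IUPAC nucleotide alphabet trigger a warning;
    they count toward length but never toward GC content.
    """
    records: list[ReadRecord] = []
    for path in _as_list(paths):
        with _open_text(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                seq = str(rec.seq)
                bad = set(seq.upper()) - _IUPAC
                if bad:
                    logger.warning(
                        "read %s in %s contains non-IUPAC characters %s; "
                        "counted in length, excluded from GC",
                        rec.id, path, "".join(sorted(bad)),
                    )
                records.append(
                    ReadRecord(
                        read_id=rec.id,
                        length=len(seq),
                        gc_fraction=metrics.gc_fraction(seq),
                    )
                )
    return ReadTable(label=label, records=records, source_kind="fasta")


def read_alignments(path, label: str = "dataset") -> ReadTable:
    """One ReadRecord per primary alignment; unmapped reads keep length only.

    Secondary and supplementary records are skipped so each query
    contributes exactly one record. Read length is the stored query length
    including soft clips (hard-clipped bases are unrecoverable from the
    file and excluded; see docs). Percent identity needs the NM tag; reads
    without it get an absent identity and one per-file warning.
    """
    records: list[ReadRecord] = []
    missing_nm = 0
    save = pysam.set_verbosity(0)  # silence index warning on SAM input
    try:
        with pysam.AlignmentFile(str(path), "rb" if str(path).endswith(".bam") else "r") as af:
            for aln in af:
                if aln.is_secondary or aln.is_supplementary:
                    continue
                if aln.is_unmapped:
                    records.append(
                        ReadRecord(read_id=aln.query_name, length=aln.query_length)
                    )
                    continue
                if not aln.cigarstring:
                    raise ValueError(
                        f"{path}: mapped read {aln.query_name!r} has no CIGAR"
                    )
                identity = None
                if aln.has_tag("NM"):
                    identity = metrics.percent_identity(
                        aln.cigarstring, int(aln.get_tag("NM"))
                    )
                else:
                    missing_nm += 1
                records.append(
                    ReadRecord(
                        read_id=aln.query_name,
                        length=aln.query_length,
                        aligned_length=metrics.aligned_length_from_cigar(aln.cigarstring),
                        percent_identity=identity,
                        mapping_quality=aln.mapping_quality,
                    )
                )
    finally:
        pysam.set_verbosity(save)
    if missing_nm:
        logger.warning(
            "%s: %d mapped reads without NM tag; percent identity absent for those",
            path, missing_nm,
        )
    return ReadTable(label=label, records=records, source_kind="bam")


def _resolve_columns(columns: list[str], barcoded: bool) -> dict[str, str]:
    resolved: dict[str, str] = {}
    for key, aliases in SUMMARY_ALIASES.items():
        for alias in aliases:
            if alias in columns:
                resolved[key] = alias
                break
    required = ["read_id", "channel", "start_time", "length", "quality"]
    if barcoded:
        required.append("barcode")
    missing = [k for k in required if k not in resolved]
    if missing:
        wanted = ", ".join("|".join(SUMMARY_ALIASES[k]) for k in missing)
        raise ValueError(
            f"summary file lacks required column(s) [{wanted}]; found: {columns}"
        )
    return resolved


def read_summary(paths, barcoded: bool = False, label: str = "dataset") -> ReadTable:
    """ReadRecords from a basecaller sequencing-summary TSV.

    The mean qscore column is taken verbatim (not recomputed). Start times
    are normalized to seconds since the earliest read across all input
    files, because different basecaller versions emit absolute or
    run-relative stamps.
    """
    frames = []
    for path in _as_list(paths):
        with _open_text(path) as handle:
            df = pd.read_csv(handle, sep="\t")
        cols = _resolve_columns(list(df.columns), barcoded)
        sub = pd.DataFrame(
            {
                "read_id": df[cols["read_id"]].astype(str),
                "channel": df[cols["channel"]],
                "start_time": df[cols["start_time"]],
                "length": df[cols["length"]],
                "quality": df[cols["quality"]],
            }
        )
        for numeric in ("channel", "start_time", "length", "quality"):
            coerced = pd.to_numeric(sub[numeric], errors="coerce")
            if coerced.isna().any():
                line = int(coerced.index[coerced.isna()][0]) + 2  # +header +1-based
                raise ValueError(
                    f"{path}: non-numeric value in column {cols[numeric]!r} at line {line}"
                )
            sub[numeric] = coerced
        sub["barcode"] = (
            df[cols["barcode"]].astype(str) if "barcode" in cols and cols["barcode"] in df
            else None
        )
        frames.append(sub)
    merged = pd.concat(frames, ignore_index=True)
    t0 = float(merged["start_time"].min()) if len(merged) else 0.0
    records = [
        ReadRecord(
            read_id=row.read_id,
            length=int(row.length),
            mean_quality=float(row.quality),
            start_time=float(row.start_time) - t0,
            channel=int(row.channel),
            barcode=row.barcode if isinstance(row.barcode, str) else None,
        )
        for row in merged.itertuples(index=False)
    ]
    return ReadTable(label=label, records=records, source_kind="summary")


def split_by_barcode(table: ReadTable) -> dict[str, ReadTable]:
    """Partition a barcoded table into one ReadTable per barcode label.

    Reads without a barcode are grouped under "unclassified". Record order
    is preserved within each partition.
    """
    if not any(r.barcode is not None for r in table.records):
        raise ValueError(f"table {table.label!r} has no barcode labels to split on")
    groups: dict[str, list] = {}
    for r in table.records:
        key = r.barcode if r.barcode is not None else UNCLASSIFIED
        groups.setdefault(key, []).append(r)
    return {
        bc: ReadTable(label=bc, records=recs, source_kind=table.source_kind)
        for bc, recs in groups.items()
    }
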