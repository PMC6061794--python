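"""Per-read and aggregate statistics.

The quality average is the single most consequential formula in the
package: Phred scores are log-scaled error probabilities, so the mean
quality of a read is computed in probability space,

    Q_mean = -10 * log10( mean_b 10^(-q_b / 10) ),

never as the arithmetic mean of the Phred values (which systematically
overstates accuracy). Percent identity is derived from the aligner's
reported edit distance (NM tag) over all alignment columns, including
indel columns: 100 * (1 - NM / columns).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .model import (
    DEFAULT_QUALITY_TIERS,
    PlotData,
    ReadRecord,
    ReadTable,
    SummaryStats,
)

PHRED_OFFSET = 33  # Sanger / modern long-read convention; offset-64 is out of scope

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR operations that consume the query / that count as alignment columns
_QUERY_ALIGNED_OPS = frozenset("MI=X")
_COLUMN_OPS = frozenset("M=XID")


def phred_from_string(qual: str) -> np.ndarray:
    """Decode a FASTQ quality string (Phred+33) to integer scores."""
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int32) - PHRED_OFFSET


def mean_read_quality(phred_scores) -> float:
    """Probability-space mean of per-base Phred scores.

    Bounded by [min(q), max(q)]; equals q exactly for constant input.
    """
    q = np.asarray(phred_scores, dtype=float)
    if q.size == 0:
        raise ValueError("read has no bases")
    if np.any(q < 0):
        raise ValueError("negative Phred score")
    return float(-10.0 * np.log10(np.mean(np.power(10.0, -q / 10.0))))


def gc_fraction(sequence: str) -> float | None:
    """GC content over unambiguous bases only.

    Ambiguous (non-ACGT) bases are excluded from both numerator and
    denominator; a read with no unambiguous bases has no defined GC
    content and returns None.
    """
    seq = sequence.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return None
    gc = seq.count("G") + seq.count("C")
    return gc / acgt


def n50(lengths) -> int:
    """N50: the largest length L such that reads >= L hold at least half of all bases.

    Standard assembly-statistics convention (ties broken by inclusion, >=).
    The returned value is always an element of the input.
    """
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("n50 of empty length list")
    if np.any(arr <= 0):
        raise ValueError("n50 requires positive lengths")
    srt = np.sort(arr)[::-1]
    csum = np.cumsum(srt)
    half = csum[-1] / 2.0
    idx = int(np.searchsorted(csum, half, side="left"))
    return int(srt[idx])


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR string {cigar!r}")
    return ops


def aligned_length_from_cigar(cigar: str) -> int:
    """Query bases actually placed in the alignment (M/I/=/X; clips excluded)."""
    return sum(n for n, op in parse_cigar(cigar) if op in _QUERY_ALIGNED_OPS)


def percent_identity(cigar: str, edit_distance: int) -> float:
    """Percent identity from the CIGAR and the aligner's edit distance.

    columns = M/=/X/I/D operation lengths; identity = 100*(1 - NM/columns),
    clipped to [0, 100]. Counts every reported error exactly once; see the
    methods note for how this compares with match-column-only conventions.
    """
    if edit_distance < 0:
        raise ValueError(f"negative edit distance {edit_distance}")
    columns = sum(n for n, op in parse_cigar(cigar) if op in _COLUMN_OPS)
    if columns == 0:
        raise ValueError(f"CIGAR {cigar!r} has no aligned columns")
    return float(np.clip(100.0 * (1.0 - edit_distance / columns), 0.0, 100.0))


def summarize(table: ReadTable, quality_tiers=DEFAULT_QUALITY_TIERS, top_k: int = 5) -> SummaryStats:
    """Aggregate statistics for one dataset.

    Quality statistics aggregate the per-read mean qualities arithmetically
    (each per-read value is already probability-space averaged); they are
    None when no read carries a quality.
    """
    if len(table) == 0:
        raise ValueError(f"cannot summarize empty table {table.label!r}")
    lengths = np.asarray(table.lengths(), dtype=np.int64)
    quals = np.asarray(table.values("mean_quality"), dtype=float)

    longest = sorted(table.records, key=lambda r: r.length, reverse=True)[:top_k]

    stats = SummaryStats(
        n_reads=len(table),
        total_bases=int(lengths.sum()),
        mean_length=float(lengths.mean()),
        median_length=float(np.median(lengths)),
        n50=n50(lengths[lengths > 0]) if np.any(lengths > 0) else 0,
        longest_reads=[(r.read_id, r.length) for r in longest],
    )
    if quals.size:
        stats.mean_quality = float(quals.mean())
        stats.median_quality = float(np.median(quals))
        stats.n_with_quality = int(quals.size)
        stats.reads_over_quality_thresholds = {
            float(t): int(np.sum(quals >= t)) for t in quality_tiers
        }
    return stats


def cumulative_yield(table: ReadTable) -> PlotData:
    """Cumulative sequenced bases over run time, in hours.

    Monotone non-decreasing in both coordinates; the final value equals
    the dataset's total bases from timed reads.
    """
    timed = [(r.start_time, r.length) for r in table.records if r.start_time is not None]
    if not timed:
        raise ValueError(f"table {table.label!r} has no start times; cannot compute yield")
    timed.sort(key=lambda p: p[0])
    hours = np.asarray([t for t, _ in timed]) / 3600.0
    cum = np.cumsum([ln for _, ln in timed])
    return PlotData(
        plot_kind="cumulative_yield",
        payload={"hours": hours, "cumulative_bases": cum},
        annotations={"label": table.label},
    )


@dataclass
class TimeBin:
    """Reads falling in one half-open time interval [start, end), hours."""

    index: int
    start: float
    end: float
    values: list[float] = field(default_factory=list)


def bin_by_time(table: ReadTable, field_name: str = "mean_quality", interval_hours: float = 6.0) -> list[TimeBin]:
    """Partition reads into contiguous half-open time bins of fixed width.

    Default width 6 h, matching the interval at which base-call quality
    drift over a run is conventionally inspected.
    """
    if interval_hours <= 0:
        raise ValueError(f"interval_hours must be > 0, got {interval_hours}")
    if field_name not in ("mean_quality", "length"):
        raise ValueError(f"cannot bin field {field_name!r}")
    pairs = [
        (r.start_time / 3600.0, getattr(r, field_name))
        for r in table.records
        if r.start_time is not None and getattr(r, field_name) is not None
    ]
    if not pairs:
        raise ValueError(
            f"table {table.label!r} has no reads with both start_time and {field_name}"
        )
    last = max(h for h, _ in pairs)
    n_bins = int(last // interval_hours) + 1
    bins = [
        TimeBin(index=i, start=i * interval_hours, end=(i + 1) * interval_hours)
        for i in range(n_bins)
    ]
    for h, v in pairs:
        bins[int(h // interval_hours)].values.append(float(v))
    return bins


def downsample(table: ReadTable, n: int, seed: int = 1) -> ReadTable:
    """Uniform sample of min(n, size) records without replacement.

    Input order is preserved among kept records; identical seed gives an
    identical sample.
    """
    if n < 0:
        raise ValueError(f"sample size must be >= 0, got {n}")
    if n >= len(table):
        return table.with_records(list(table.records))
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(table), size=n, replace=False))
    return table.with_records([table.records[i] for i in keep])


def apply_plot_cutoffs(table: ReadTable, max_length: int | None = None, min_quality: float | None = None) -> ReadTable:
    """Drop reads above a length cutoff or below a quality cutoff.

    Each test is skipped when its bound is None. Reads without a mean
    quality pass the quality test only when no quality bound is set.
    """
    kept = []
    for r in table.records:
        if max_length is not None and r.length > max_length:
            continue
        if min_quality is not None and (r.mean_quality is None or r.mean_quality < min_quality):
            continue
        kept.append(r)
    return table.with_records(kept)
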