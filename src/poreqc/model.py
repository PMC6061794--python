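"""Core domain types shared by every other module.

Everything here is a plain in-memory container with validation; no I/O.
Optional per-read features are represented as ``None`` (never sentinel
numbers) so that downstream statistics can skip absent values explicitly
and report how many reads contributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any, Iterator, Optional

SOURCE_KINDS = ("fastq", "fasta", "bam", "summary")

PLOT_KINDS = (
    "length_histogram",
    "log_length_histogram",
    "cumulative_yield",
    "flowcell_heatmap",
    "time_violin",
    "bivariate_hexbin",
    "bivariate_kde",
    "comparison",
)


@dataclass
class ReadRecord:
    """Features of one sequenced read.

    length is always present; everything else depends on the input source:
    FASTA gives length and GC only, sequencing summaries give time/channel
    but no alignment metrics, and BAM gives alignment metrics but no GC.

    Units: ``length``/``aligned_length`` in bases, ``mean_quality`` and
    ``mapping_quality`` in Phred units, ``start_time`` in seconds since the
    first read of the run, ``percent_identity`` in percent (0-100),
    ``gc_fraction`` as a fraction (0-1).
    """

    read_id: str
    length: int
    mean_quality: Optional[float] = None
    start_time: Optional[float] = None
    channel: Optional[int] = None
    barcode: Optional[str] = None
    aligned_length: Optional[int] = None
    percent_identity: Optional[float] = None
    mapping_quality: Optional[int] = None
    gc_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"read {self.read_id!r}: negative length {self.length}")
        if self.aligned_length is not None:
            if not (0 <= self.aligned_length <= self.length):
                raise ValueError(
                    f"read {self.read_id!r}: aligned_length {self.aligned_length} "
                    f"outside [0, length={self.length}]"
                )
        if self.percent_identity is not None and not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(
                f"read {self.read_id!r}: percent_identity {self.percent_identity} not in [0, 100]"
            )
        if self.gc_fraction is not None and not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError(
                f"read {self.read_id!r}: gc_fraction {self.gc_fraction} not in [0, 1]"
            )
        if self.start_time is not None and self.start_time < 0:
            raise ValueError(f"read {self.read_id!r}: negative start_time {self.start_time}")


# field names of ReadRecord in declaration order, reused by serialization
READ_FIELDS = tuple(f.name for f in fields(ReadRecord))


@dataclass
class ReadTable:
    """Ordered collection of ReadRecords from one dataset.

    ``source_kind`` records provenance: it determines which optional fields
    can legitimately be populated (a FASTA table never carries quality; a
    summary table never carries percent identity) so that differently
    defined quantities are never mixed silently.
    """

    label: str
    records: list[ReadRecord] = field(default_factory=list)
    source_kind: str = "fastq"

    def __post_init__(self) -> None:
        if self.source_kind not in SOURCE_KINDS:
            raise ValueError(
                f"unknown source_kind {self.source_kind!r}; expected one of {SOURCE_KINDS}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReadRecord]:
        return iter(self.records)

    def lengths(self) -> list[int]:
        return [r.length for r in self.records]

    def values(self, field_name: str) -> list[Any]:
        """Values of one record field, skipping absent (None) entries."""
        if field_name not in READ_FIELDS:
            raise KeyError(f"unknown ReadRecord field {field_name!r}")
        out = []
        for r in self.records:
            v = getattr(r, field_name)
            if v is not None:
                out.append(v)
        return out

    def with_records(self, records: list[ReadRecord]) -> "ReadTable":
        """A new table with the same label/provenance and different records."""
        return ReadTable(label=self.label, records=list(records), source_kind=self.source_kind)


@dataclass
class SummaryStats:
    """Aggregate statistics block for one dataset.

    Quality statistics are None when the source carries no qualities;
    ``n_with_quality`` says how many reads contributed to them.
    ``reads_over_quality_thresholds`` maps each Phred threshold to the
    number of reads whose mean quality is >= that threshold.
    """

    n_reads: int
    total_bases: int
    mean_length: float
    median_length: float
    n50: int
    mean_quality: Optional[float] = None
    median_quality: Optional[float] = None
    n_with_quality: int = 0
    reads_over_quality_thresholds: dict[float, int] = field(default_factory=dict)
    longest_reads: list[tuple[str, int]] = field(default_factory=list)


DEFAULT_QUALITY_TIERS = (5.0, 7.0, 10.0, 12.0, 15.0)


@dataclass
class FilterSpec:
    """Predicate plus trim parameters applied to a read stream.

    Bounds are inclusive; a ``None`` bound means the test is skipped.
    headcrop/tailcrop are bases removed from the 5'/3' end before any
    predicate is evaluated.
    """

    min_quality: Optional[float] = None
    min_length: Optional[int] = None
    max_length: Optional[int] = None
    min_gc: Optional[float] = None
    max_gc: Optional[float] = None
    headcrop: int = 0
    tailcrop: int = 0

    def __post_init__(self) -> None:
        if self.headcrop < 0 or self.tailcrop < 0:
            raise ValueError("headcrop and tailcrop must be >= 0")
        if (
            self.min_length is not None
            and self.max_length is not None
            and self.min_length > self.max_length
        ):
            raise ValueError(
                f"min_length {self.min_length} > max_length {self.max_length}"
            )
        if self.min_gc is not None and self.max_gc is not None and self.min_gc > self.max_gc:
            raise ValueError(f"min_gc {self.min_gc} > max_gc {self.max_gc}")

    @property
    def has_gc_bound(self) -> bool:
        return self.min_gc is not None or self.max_gc is not None


@dataclass
class PlotData:
    """Rendered-format-independent numeric content of one plot.

    ``payload`` holds numeric arrays specific to the kind (bin edges and
    counts for histograms, a density grid for KDEs, a per-cell matrix for
    the flow-cell heatmap, per-group value lists for comparisons).
    ``annotations`` carries scalar marks such as an N50 line position or
    the KDE bandwidths, so rendered figures are reproducible from the
    payload alone.
    """

    plot_kind: str
    payload: dict[str, Any] = field(default_factory=dict)
    annotations: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.plot_kind not in PLOT_KINDS:
            raise ValueError(
                f"unknown plot_kind {self.plot_kind!r}; expected one of {PLOT_KINDS}"
            )
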