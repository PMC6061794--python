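"""Flow-cell channel geometry and per-channel activity matrices.

A MinION flow cell addresses 512 channels whose physical positions form a
16x32 grid; plotting per-channel activity on that grid exposes spatial
artefacts such as air bubbles or uneven loading. The channel-to-cell
wiring is vendor data, not an algorithm, so the layout is shipped as a
TSV (columns: channel, row, col) and users may substitute their own.
The packaged MinION map is a best-effort reconstruction: four horizontal
blocks of 128 channels, filled column-major within each block.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .model import PlotData, ReadTable

STATISTICS = ("read_count", "total_bases")


@dataclass(frozen=True)
class FlowcellLayout:
    """Bijective map from channel ids 1..rows*cols onto a grid."""

    name: str
    rows: int
    cols: int
    channel_map: dict[int, tuple[int, int]]

    def __post_init__(self) -> None:
        n = self.rows * self.cols
        if set(self.channel_map) != set(range(1, n + 1)):
            raise ValueError(
                f"layout {self.name!r}: channel ids must be exactly 1..{n}"
            )
        cells = set(self.channel_map.values())
        if len(cells) != n or not all(
            0 <= r < self.rows and 0 <= c < self.cols for r, c in cells
        ):
            raise ValueError(
                f"layout {self.name!r}: channel map is not a bijection onto the "
                f"{self.rows}x{self.cols} grid"
            )

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols


def load_layout_tsv(path, name: str = "custom") -> FlowcellLayout:
    """Load a layout from a TSV with columns channel, row, col (0-based cells)."""
    channel_map: dict[int, tuple[int, int]] = {}
    with open(path, newline="") as fh:
        for line in csv.DictReader(fh, delimiter="\t"):
            channel_map[int(line["channel"])] = (int(line["row"]), int(line["col"]))
    rows = 1 + max(r for r, _ in channel_map.values())
    cols = 1 + max(c for _, c in channel_map.values())
    return FlowcellLayout(name=name, rows=rows, cols=cols, channel_map=channel_map)


def minion_layout() -> FlowcellLayout:
    """The packaged 512-channel MinION layout (16x32 grid, four 4-row blocks)."""
    path = resources.files("poreqc.data").joinpath("minion_r9_layout.tsv")
    with resources.as_file(path) as p:
        return load_layout_tsv(p, name="minion_r9")


def promethion_layout() -> FlowcellLayout:
    """Placeholder 3000-channel grid (50x60, row-major); not vendor wiring."""
    cmap = {ch: ((ch - 1) // 60, (ch - 1) % 60) for ch in range(1, 3001)}
    return FlowcellLayout(name="promethion_placeholder", rows=50, cols=60, channel_map=cmap)


def channel_to_cell(layout: FlowcellLayout, channel: int) -> tuple[int, int]:
    """Grid cell of one channel; out-of-range channels are an error."""
    if channel not in layout.channel_map:
        raise ValueError(
            f"channel {channel} outside layout {layout.name!r} "
            f"(valid: 1..{layout.n_channels})"
        )
    return layout.channel_map[channel]


def activity_matrix(table: ReadTable, layout: FlowcellLayout, statistic: str = "read_count") -> PlotData:
    """Per-channel activity on the physical grid.

    Cell value is the chosen statistic (read count or total bases) over
    reads of that channel; channels without reads are 0. Channels outside
    the layout are an error, with a hint toward the larger packaged layout
    rather than silent truncation.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    matrix = np.zeros((layout.rows, layout.cols), dtype=np.int64)
    bad = sorted(
        {
            r.channel
            for r in table.records
            if r.channel is not None and r.channel not in layout.channel_map
        }
    )
    if bad:
        raise ValueError(
            f"channels {bad} outside layout {layout.name!r} "
            f"({layout.n_channels} channels); if this is a PromethION run, "
            "use the promethion_placeholder layout or supply a layout TSV"
        )
    for r in table.records:
        if r.channel is None:
            continue
        row, col = layout.channel_map[r.channel]
        matrix[row, col] += 1 if statistic == "read_count" else r.length
    return PlotData(
        plot_kind="flowcell_heatmap",
        payload={"matrix": matrix},
        annotations={"layout": layout.name, "statistic": statistic, "label": table.label},
    )
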