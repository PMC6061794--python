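"""Plot-data computation, figure rendering and the combined HTML report.

Plot *computation* is strictly separated from *rendering*: every plot is
first reduced to a PlotData payload of plain numeric arrays (bin edges
and counts, density grids, per-cell matrices, per-group value lists) so
the test surface is numeric rather than pixel-based; rendering then maps
a payload to matplotlib figures in any of png/jpg/pdf/svg.
"""

from __future__ import annotations

import base64
import html
import io
import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats as sps

from . import metrics
from .model import READ_FIELDS, PlotData, ReadRecord, ReadTable, SummaryStats

RENDER_FORMATS = ("png", "jpg", "pdf", "svg")

# fixed hash salt so repeated SVG renders are byte-identical
matplotlib.rcParams["svg.hashsalt"] = "poreqc"

HEXBIN_GRIDSIZE = 35
KDE_GRID = 128


# ---------------------------------------------------------------------------
# plot-data computation


def length_histogram(table: ReadTable, bins: int = 50, log_scale: bool = False, mark_n50: bool = False) -> PlotData:
    """Read-length histogram, optionally binned uniformly in log10(length).

    Zero-length reads cannot be log-transformed; they are excluded from
    the log-scale histogram and reported in the excluded tally.
    """
    if bins < 1:
        raise ValueError(f"bins must be >= 1, got {bins}")
    if len(table) == 0:
        raise ValueError("cannot histogram an empty table")
    lengths = np.asarray(table.lengths(), dtype=float)
    excluded = 0
    if log_scale:
        excluded = int(np.sum(lengths <= 0))
        data = np.log10(lengths[lengths > 0])
        kind = "log_length_histogram"
    else:
        data = lengths
        kind = "length_histogram"
    counts, edges = np.histogram(data, bins=bins)
    annotations: dict = {"label": table.label, "log10": log_scale}
    if mark_n50:
        annotations["n50_marker"] = metrics.n50([l for l in table.lengths() if l > 0])
    return PlotData(
        plot_kind=kind,
        payload={"bin_edges": edges, "counts": counts, "excluded": excluded},
        annotations=annotations,
    )


def _xy(table: ReadTable, x_field: str, y_field: str, log_x: bool) -> tuple[np.ndarray, np.ndarray, int]:
    pairs = [
        (getattr(r, x_field), getattr(r, y_field))
        for r in table.records
        if getattr(r, x_field) is not None and getattr(r, y_field) is not None
    ]
    excluded = len(table) - len(pairs)
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if log_x:
        keep = x > 0
        excluded += int(np.sum(~keep))
        x, y = np.log10(x[keep]), y[keep]
    return x, y, excluded


def bivariate(table: ReadTable, x_field: str, y_field: str, style: str = "hexbin", log_x: bool = False, gridsize: int = HEXBIN_GRIDSIZE) -> PlotData:
    """Joint distribution of two per-read fields as hexagonal bins or a 2D KDE.

    Hexbin payload: cell centers and counts summing to the usable reads,
    plus marginal histograms at the same bin count. KDE payload: a density
    grid whose trapezoid-rule integral is 1 within 1%, plus marginal
    densities; the Scott-rule bandwidths are recorded in annotations.
    Reads missing either field are excluded and tallied.
    """
    if style not in ("hexbin", "kde"):
        raise ValueError(f"unknown bivariate style {style!r}")
    x, y, excluded = _xy(table, x_field, y_field, log_x)
    if x.size < 2:
        raise ValueError(
            f"need >= 2 reads with both {x_field} and {y_field}; have {x.size}"
        )
    annotations = {
        "label": table.label,
        "x_field": ("log10_" if log_x else "") + x_field,
        "y_field": y_field,
    }
    if style == "hexbin":
        fig, ax = plt.subplots()
        try:
            hb = ax.hexbin(x, y, gridsize=gridsize)
            counts = np.asarray(hb.get_array())
            centers = np.asarray(hb.get_offsets())
        finally:
            plt.close(fig)
        mx_counts, mx_edges = np.histogram(x, bins=gridsize)
        my_counts, my_edges = np.histogram(y, bins=gridsize)
        return PlotData(
            plot_kind="bivariate_hexbin",
            payload={
                "x": x,
                "y": y,
                "cell_centers": centers,
                "cell_counts": counts,
                "marginal_x": (mx_edges, mx_counts),
                "marginal_y": (my_edges, my_counts),
                "excluded": excluded,
            },
            annotations=annotations,
        )
    # 2D KDE; degenerate (zero-variance) axes cannot support a KDE
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("KDE requires variation on both axes")
    kde = sps.gaussian_kde(np.vstack([x, y]))  # Scott's rule
    bw_x = float(kde.factor * np.std(x, ddof=1))
    bw_y = float(kde.factor * np.std(y, ddof=1))
    gx = np.linspace(x.min() - 5 * bw_x, x.max() + 5 * bw_x, KDE_GRID)
    gy = np.linspace(y.min() - 5 * bw_y, y.max() + 5 * bw_y, KDE_GRID)
    xx, yy = np.meshgrid(gx, gy)
    density = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    kde_x, kde_y = sps.gaussian_kde(x), sps.gaussian_kde(y)
    annotations["bandwidth"] = (bw_x, bw_y)
    return PlotData(
        plot_kind="bivariate_kde",
        payload={
            "grid_x": gx,
            "grid_y": gy,
            "density": density,
            "marginal_x": (gx, kde_x(gx)),
            "marginal_y": (gy, kde_y(gy)),
            "excluded": excluded,
        },
        annotations=annotations,
    )


def aligned_vs_effective(table: ReadTable) -> PlotData:
    """Aligned length against full read length; points below the identity
    diagonal are reads only partially placed on the reference."""
    pairs = [
        (r.length, r.aligned_length)
        for r in table.records
        if r.aligned_length is not None
    ]
    if not pairs:
        raise ValueError(f"table {table.label!r} has no aligned reads")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    return PlotData(
        plot_kind="bivariate_hexbin",
        payload={"x": x, "y": y, "excluded": len(table) - len(pairs)},
        annotations={
            "label": table.label,
            "x_field": "length",
            "y_field": "aligned_length",
            "diagonal": True,
        },
    )


def time_violin(table: ReadTable, field_name: str = "mean_quality", interval_hours: float = 6.0) -> PlotData:
    """Raw per-interval value lists for violin plots of quality (or length)
    over run time; the renderer computes the violin shapes."""
    bins = metrics.bin_by_time(table, field_name, interval_hours)
    return PlotData(
        plot_kind="time_violin",
        payload={
            "bin_starts": [b.start for b in bins],
            "bin_ends": [b.end for b in bins],
            "values": [b.values for b in bins],
        },
        annotations={
            "label": table.label,
            "field": field_name,
            "interval_hours": interval_hours,
        },
    )


COMPARE_FIELDS = ("length", "mean_quality", "percent_identity")


def compare(tables: list[ReadTable], log_length: bool = False) -> tuple[list[PlotData], pd.DataFrame]:
    """Cross-dataset comparison of length/quality/identity distributions.

    Returns one grouped PlotData per field (a dataset lacking the field
    contributes an explicit absence flag, not an error) and a per-label
    summary DataFrame (reads, bases, N50, means/medians).
    """
    if len(tables) < 2:
        raise ValueError("comparison needs at least 2 datasets")
    labels = [t.label for t in tables]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate dataset labels: {labels}")
    plots = []
    for field_name in COMPARE_FIELDS:
        groups: dict[str, list | None] = {}
        for t in tables:
            vals = t.values(field_name)
            if field_name == "length" and log_length:
                vals = [math.log10(v) for v in vals if v > 0]
            groups[t.label] = vals if vals else None  # None = field absent
        plots.append(
            PlotData(
                plot_kind="comparison",
                payload={"groups": groups},
                annotations={
                    "field": ("log10_" if field_name == "length" and log_length else "")
                    + field_name,
                    "label": "comparison",
                },
            )
        )
    rows = []
    for t in tables:
        s = metrics.summarize(t)
        ident = t.values("percent_identity")
        rows.append(
            {
                "label": t.label,
                "n_reads": s.n_reads,
                "total_bases": s.total_bases,
                "mean_length": s.mean_length,
                "median_length": s.median_length,
                "n50": s.n50,
                "mean_quality": s.mean_quality,
                "median_quality": s.median_quality,
                "mean_identity": float(np.mean(ident)) if ident else None,
            }
        )
    return plots, pd.DataFrame(rows).set_index("label")


# ---------------------------------------------------------------------------
# rendering


def _draw(plot: PlotData, ax) -> None:
    kind, p, a = plot.plot_kind, plot.payload, plot.annotations
    if kind in ("length_histogram", "log_length_histogram"):
        ax.stairs(p["counts"], p["bin_edges"], fill=True)
        ax.set_xlabel("log10(read length)" if a.get("log10") else "read length (b)")
        ax.set_ylabel("reads")
        if "n50_marker" in a:
            mark = math.log10(a["n50_marker"]) if a.get("log10") else a["n50_marker"]
            ax.axvline(mark, color="crimson", ls="--", label=f"N50 = {a['n50_marker']}")
            ax.legend()
    elif kind == "cumulative_yield":
        ax.plot(p["hours"], p["cumulative_bases"])
        ax.set_xlabel("run time (h)")
        ax.set_ylabel("cumulative bases")
    elif kind == "flowcell_heatmap":
        im = ax.imshow(p["matrix"], aspect="auto", cmap="viridis")
        ax.figure.colorbar(im, ax=ax, label=a.get("statistic", "read_count"))
        ax.set_xlabel("column")
        ax.set_ylabel("row")
    elif kind == "time_violin":
        nonempty = [(s, v) for s, v in zip(p["bin_starts"], p["values"]) if v]
        if nonempty:
            ax.violinplot([v for _, v in nonempty], positions=[s for s, _ in nonempty], widths=0.8 * a.get("interval_hours", 6.0))
        ax.set_xlabel("run time (h)")
        ax.set_ylabel(a.get("field", "value"))
    elif kind == "bivariate_hexbin":
        ax.hexbin(p["x"], p["y"], gridsize=HEXBIN_GRIDSIZE, cmap="viridis")
        if a.get("diagonal"):
            lim = max(float(np.max(p["x"])), float(np.max(p["y"])))
            ax.plot([0, lim], [0, lim], color="crimson", ls="--", lw=1)
        ax.set_xlabel(a.get("x_field", "x"))
        ax.set_ylabel(a.get("y_field", "y"))
    elif kind == "bivariate_kde":
        ax.contourf(p["grid_x"], p["grid_y"], p["density"], levels=12, cmap="viridis")
        ax.set_xlabel(a.get("x_field", "x"))
        ax.set_ylabel(a.get("y_field", "y"))
    elif kind == "comparison":
        groups = {k: v for k, v in p["groups"].items() if v}
        if groups:
            ax.violinplot(list(groups.values()), positions=range(len(groups)))
            ax.set_xticks(range(len(groups)), labels=list(groups.keys()))
        ax.set_ylabel(a.get("field", "value"))
    else:  # pragma: no cover - PLOT_KINDS is closed
        raise ValueError(f"cannot render plot kind {kind!r}")
    ax.set_title(a.get("label", ""))


def _figure(plot: PlotData):
    fig, ax = plt.subplots(figsize=(7, 5))
    _draw(plot, ax)
    fig.tight_layout()
    return fig


def render(plots: list[PlotData], formats=("png",), out_dir=".") -> list[Path]:
    """One image file per plot per format, named ``label_plotkind.ext``.

    Unknown format tokens fail before anything is written; re-rendering
    overwrites, leaving exactly the same file set.
    """
    if not plots:
        raise ValueError("no plots to render")
    formats = list(formats)
    if not formats:
        raise ValueError("no output formats requested")
    bad = [f for f in formats if f not in RENDER_FORMATS]
    if bad:
        raise ValueError(f"unknown format(s) {bad}; supported: {RENDER_FORMATS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for plot in plots:
        label = str(plot.annotations.get("label", "dataset")).replace(" ", "_")
        fig = _figure(plot)
        try:
            for fmt in formats:
                path = out_dir / f"{label}_{plot.plot_kind}.{fmt}"
                # strip volatile metadata so svg/pdf reruns are byte-identical
                meta = {"Date": None} if fmt == "svg" else (
                    {"CreationDate": None} if fmt == "pdf" else None
                )
                fig.savefig(path, format=fmt, metadata=meta)
                written.append(path)
        finally:
            plt.close(fig)
    return written


# ---------------------------------------------------------------------------
# per-read TSV and summary serialization

_INT_FIELDS = {"length", "channel", "aligned_length", "mapping_quality"}


def write_read_tsv(table: ReadTable, path) -> Path:
    """Machine-readable per-read table; absent fields are empty cells.

    Two comment lines preserve the dataset label and provenance so the
    table round-trips losslessly through :func:`read_read_tsv`.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# label={table.label}\n# source_kind={table.source_kind}\n")
        fh.write("\t".join(READ_FIELDS) + "\n")
        for r in table.records:
            cells = []
            for name in READ_FIELDS:
                v = getattr(r, name)
                cells.append("" if v is None else (repr(v) if isinstance(v, float) else str(v)))
            fh.write("\t".join(cells) + "\n")
    return path


def read_read_tsv(path) -> ReadTable:
    """Inverse of :func:`write_read_tsv`."""
    with open(path) as fh:
        label = fh.readline().strip().removeprefix("# label=")
        source_kind = fh.readline().strip().removeprefix("# source_kind=")
        header = fh.readline().rstrip("\n").split("\t")
        records = []
        for line in fh:
            cells = dict(zip(header, line.rstrip("\n").split("\t")))
            kwargs = {}
            for name, cell in cells.items():
                if cell == "":
                    kwargs[name] = None
                elif name == "read_id" or name == "barcode":
                    kwargs[name] = cell
                elif name in _INT_FIELDS:
                    kwargs[name] = int(cell)
                else:
                    kwargs[name] = float(cell)
            records.append(ReadRecord(**kwargs))
    return ReadTable(label=label, records=records, source_kind=source_kind)


def stats_to_frame(stats: SummaryStats) -> pd.DataFrame:
    rows = [
        ("number_of_reads", stats.n_reads),
        ("total_bases", stats.total_bases),
        ("mean_read_length", round(stats.mean_length, 1)),
        ("median_read_length", round(stats.median_length, 1)),
        ("read_length_n50", stats.n50),
    ]
    if stats.mean_quality is not None:
        rows += [
            ("mean_read_quality", round(stats.mean_quality, 2)),
            ("median_read_quality", round(stats.median_quality, 2)),
            ("reads_with_quality", stats.n_with_quality),
        ]
        rows += [
            (f"reads_above_q{t:g}", c)
            for t, c in stats.reads_over_quality_thresholds.items()
        ]
    rows += [
        (f"longest_read_{i + 1}", f"{rid} ({ln} b)")
        for i, (rid, ln) in enumerate(stats.longest_reads)
    ]
    return pd.DataFrame(rows, columns=["metric", "value"]).set_index("metric")


# ---------------------------------------------------------------------------
# HTML report

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; max-width: 70em; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #999; padding: 0.3em 0.8em; text-align: left; }}
img {{ max-width: 100%; }}
</style></head>
<body>
<h1>{title}</h1>
<h2>Summary statistics</h2>
{stats_html}
<h2>Plots</h2>
{plots_html}
</body></html>
"""


def _png_data_uri(plot: PlotData) -> str:
    fig = _figure(plot)
    try:
        buf = io.BytesIO()
        fig.savefig(buf, format="png", dpi=90)
    finally:
        plt.close(fig)
    return "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode("ascii")


def html_report(stats, plots: list[PlotData], out_path, table: ReadTable | None = None, title: str = "Long-read sequencing QC report") -> Path:
    """Self-contained HTML report: every statistic plus every plot, images
    embedded as data URIs. When a ReadTable is given, the machine-readable
    per-read TSV and a summary TSV are written alongside the report.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    frame = stats_to_frame(stats) if isinstance(stats, SummaryStats) else stats
    sections = []
    for plot in plots:
        name = html.escape(f"{plot.annotations.get('label', '')} {plot.plot_kind}")
        sections.append(
            f'<h3 id="{plot.plot_kind}">{name}</h3>\n'
            f'<img alt="{plot.plot_kind}" src="{_png_data_uri(plot)}"/>'
        )
    out_path.write_text(
        _PAGE.format(
            title=html.escape(title),
            stats_html=frame.to_html(),
            plots_html="\n".join(sections) if sections else "<p>no plots</p>",
        )
    )
    frame.to_csv(out_path.with_suffix(".stats.tsv"), sep="\t")
    if table is not None:
        write_read_tsv(table, out_path.with_suffix(".reads.tsv"))
    return out_path
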