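"""Plot-data conservation, rendering determinism, HTML assembly."""

import math

import numpy as np
import pytest

from poreqc import metrics, readers, report
from poreqc.model import PlotData, ReadRecord, ReadTable


@pytest.fixture(scope="module")
def fastq_table(fastq_small):
    path, _ = fastq_small
    return readers.read_fastq(path, label="sample")


class TestLengthHistogram:
    def test_known_bins(self):
        t = ReadTable(
            label="t",
            records=[ReadRecord(read_id=f"r{i}", length=ln) for i, ln in enumerate([10, 10, 1000])],
        )
        plot = report.length_histogram(t, bins=2)
        assert list(plot.payload["counts"]) == [2, 1]

    def test_counts_conserve_reads(self, fastq_table):
        plot = report.length_histogram(fastq_table, bins=30)
        assert plot.payload["counts"].sum() == len(fastq_table)

    def test_log_scale_bin_assignment_matches_per_read_oracle(self, fastq_table):
        bins = 25
        plot = report.length_histogram(fastq_table, bins=bins, log_scale=True)
        edges = plot.payload["bin_edges"]
        width = edges[1] - edges[0]
        oracle = np.zeros(bins, dtype=int)
        for ln in fastq_table.lengths():
            idx = min(int((math.log10(ln) - edges[0]) / width), bins - 1)
            oracle[idx] += 1
        np.testing.assert_array_equal(plot.payload["counts"], oracle)

    def test_n50_marker_annotation(self, fastq_table):
        plot = report.length_histogram(fastq_table, mark_n50=True)
        assert plot.annotations["n50_marker"] == metrics.n50(fastq_table.lengths())

    def test_bad_bin_count_is_an_error(self, fastq_table):
        with pytest.raises(ValueError):
            report.length_histogram(fastq_table, bins=0)


class TestBivariate:
    def test_identical_points_occupy_single_hex_cell(self):
        recs = [ReadRecord(read_id=f"r{i}", length=100, mean_quality=10.0) for i in range(10)]
        plot = report.bivariate(ReadTable(label="t", records=recs), "length", "mean_quality")
        counts = plot.payload["cell_counts"]
        assert counts.sum() == 10 and np.count_nonzero(counts) == 1

    def test_hexbin_conserves_usable_reads(self, fastq_table):
        plot = report.bivariate(fastq_table, "length", "mean_quality", log_x=True)
        assert plot.payload["cell_counts"].sum() + plot.payload["excluded"] == len(fastq_table)

    def test_kde_integrates_to_one(self, fastq_table):
        plot = report.bivariate(fastq_table, "length", "mean_quality", style="kde", log_x=True)
        p = plot.payload
        integral = np.trapezoid(
            np.trapezoid(p["density"], p["grid_x"], axis=1), p["grid_y"]
        )
        assert 0.99 <= integral <= 1.01
        assert "bandwidth" in plot.annotations

    def test_reads_missing_a_field_are_tallied(self):
        recs = [ReadRecord(read_id="a", length=100, mean_quality=9.0),
                ReadRecord(read_id="b", length=200, mean_quality=11.0),
                ReadRecord(read_id="c", length=300)]
        plot = report.bivariate(ReadTable(label="t", records=recs), "length", "mean_quality")
        assert plot.payload["excluded"] == 1

    def test_too_few_usable_reads_is_an_error(self):
        recs = [ReadRecord(read_id="a", length=100)]
        with pytest.raises(ValueError, match=">= 2"):
            report.bivariate(ReadTable(label="t", records=recs), "length", "mean_quality")


class TestAlignedVsEffective:
    def test_points_never_exceed_diagonal(self, sam_small):
        path, _ = sam_small
        table = readers.read_alignments(path, label="aln")
        plot = report.aligned_vs_effective(table)
        assert np.all(plot.payload["y"] <= plot.payload["x"])
        assert plot.annotations["diagonal"] is True

    def test_fully_aligned_reads_sit_on_diagonal(self):
        recs = [ReadRecord(read_id=f"r{i}", length=100, aligned_length=100) for i in range(5)]
        plot = report.aligned_vs_effective(ReadTable(label="t", records=recs, source_kind="bam"))
        np.testing.assert_array_equal(plot.payload["x"], plot.payload["y"])

    def test_unaligned_table_is_an_error(self, fastq_table):
        with pytest.raises(ValueError, match="aligned"):
            report.aligned_vs_effective(fastq_table)


class TestTimeViolin:
    def test_values_partition_reads(self, timed_table):
        plot = report.time_violin(timed_table)
        assert sum(len(v) for v in plot.payload["values"]) == len(timed_table)


class TestCompare:
    def test_group_sizes_and_cross_module_n50(self, fastq_table, sam_small):
        path, _ = sam_small
        aln = readers.read_alignments(path, label="aln")
        plots, frame = report.compare([fastq_table, aln])
        length_plot = plots[0]
        assert len(length_plot.payload["groups"]["sample"]) == len(fastq_table)
        assert len(length_plot.payload["groups"]["aln"]) == len(aln)
        assert frame.loc["sample", "n50"] == metrics.n50(fastq_table.lengths())
        assert frame.loc["aln", "n50"] == metrics.n50(aln.lengths())

    def test_identical_tables_give_identical_summaries(self, fastq_table):
        twin = ReadTable(label="twin", records=fastq_table.records, source_kind="fastq")
        _, frame = report.compare([fastq_table, twin])
        a, b = frame.loc["sample"], frame.loc["twin"]
        assert a.tolist() == b.tolist()

    def test_absent_field_flags_not_errors(self, fastq_table, sam_small):
        path, _ = sam_small
        aln = readers.read_alignments(path, label="aln")
        plots, _ = report.compare([fastq_table, aln])
        identity_plot = plots[2]
        assert identity_plot.payload["groups"]["sample"] is None
        assert identity_plot.payload["groups"]["aln"]

    def test_duplicate_labels_are_an_error(self, fastq_table):
        with pytest.raises(ValueError, match="duplicate"):
            report.compare([fastq_table, fastq_table])

    def test_single_table_is_an_error(self, fastq_table):
        with pytest.raises(ValueError):
            report.compare([fastq_table])


@pytest.fixture(scope="module")
def plots(fastq_table):
    return [
        report.length_histogram(fastq_table, mark_n50=True),
        report.bivariate(fastq_table, "length", "mean_quality"),
    ]


class TestRender:
    def test_one_file_per_plot_per_format(self, plots, tmp_path):
        files = report.render(plots, formats=("png", "svg"), out_dir=tmp_path)
        assert len(files) == 4
        assert all(f.exists() for f in files)

    def test_unknown_format_fails_before_writing(self, plots, tmp_path):
        with pytest.raises(ValueError, match="bmp"):
            report.render(plots, formats=("png", "bmp"), out_dir=tmp_path / "x")
        assert not (tmp_path / "x").exists()

    def test_empty_format_set_is_an_error(self, plots, tmp_path):
        with pytest.raises(ValueError):
            report.render(plots, formats=(), out_dir=tmp_path)

    def test_rerender_is_idempotent_and_svg_byte_identical(self, plots, tmp_path):
        first = report.render(plots, formats=("svg",), out_dir=tmp_path)
        blobs = [f.read_bytes() for f in first]
        second = report.render(plots, formats=("svg",), out_dir=tmp_path)
        assert first == second
        assert [f.read_bytes() for f in second] == blobs


class TestReadTsvRoundTrip:
    def test_lossless_for_all_source_kinds(self, tmp_path, fastq_table, sam_small, summary_small):
        sam_path, _ = sam_small
        sum_path, _ = summary_small
        tables = [
            fastq_table,
            readers.read_alignments(sam_path, label="aln"),
            readers.read_summary(sum_path, label="summ"),
        ]
        for i, table in enumerate(tables):
            p = report.write_read_tsv(table, tmp_path / f"t{i}.tsv")
            back = report.read_read_tsv(p)
            assert back.label == table.label
            assert back.source_kind == table.source_kind
            assert back.records == table.records


class TestHtmlReport:
    def test_contains_stats_and_every_plot_kind(self, fastq_table, tmp_path):
        stats = metrics.summarize(fastq_table)
        plots = [
            report.length_histogram(fastq_table),
            report.bivariate(fastq_table, "length", "mean_quality"),
        ]
        page = report.html_report(stats, plots, tmp_path / "r.html", table=fastq_table)
        text = page.read_text()
        assert "number_of_reads" in text and str(stats.n_reads) in text
        for plot in plots:
            assert f'id="{plot.plot_kind}"' in text
        reads_tsv = tmp_path / "r.reads.tsv"
        n_rows = sum(1 for line in reads_tsv.open() if not line.startswith("#")) - 1
        assert n_rows == stats.n_reads

    def test_stats_only_report_is_valid(self, fastq_table, tmp_path):
        page = report.html_report(metrics.summarize(fastq_table), [], tmp_path / "s.html")
        text = page.read_text()
        assert text.startswith("<!DOCTYPE html>") and "no plots" in text
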