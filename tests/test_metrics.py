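"""Statistics against independent oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poreqc import metrics
from poreqc.model import ReadRecord, ReadTable


def oracle_mean_quality(scores):
    """Direct probability-space arithmetic, independent of the implementation."""
    probs = [10 ** (-q / 10) for q in scores]
    return -10 * math.log10(sum(probs) / len(probs))


def oracle_n50(lengths):
    """Sort descending, cumulative sum, first length where cumsum >= total/2."""
    srt = sorted(lengths, reverse=True)
    total = sum(srt)
    cum = 0
    for ln in srt:
        cum += ln
        if cum >= total / 2:
            return ln
    raise AssertionError("unreachable")


class TestMeanReadQuality:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([10, 10, 10], 10.0),
            ([10, 20], -10 * math.log10((0.1 + 0.01) / 2)),  # 12.596...
            ([40] * 4, 40.0),
        ],
    )
    def test_known_values(self, scores, expected):
        assert metrics.mean_read_quality(scores) == pytest.approx(expected, abs=1e-12)

    def test_empty_read_is_an_error(self):
        with pytest.raises(ValueError, match="no bases"):
            metrics.mean_read_quality([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=0, max_value=60), min_size=1, max_size=200))
    def test_matches_oracle_and_is_bounded(self, scores):
        q = metrics.mean_read_quality(scores)
        assert q == pytest.approx(oracle_mean_quality(scores), abs=1e-9)
        assert min(scores) - 1e-9 <= q <= max(scores) + 1e-9

    def test_probability_mean_below_arithmetic_mean(self):
        # the log-scale pitfall: arithmetic Phred averaging overstates accuracy
        scores = [5, 30]
        assert metrics.mean_read_quality(scores) < np.mean(scores)


class TestN50:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([8, 8, 4, 3, 3, 2, 2, 2], 8), ([5], 5), ([1, 1, 1, 1], 1)],
    )
    def test_known_values(self, lengths, expected):
        assert metrics.n50(lengths) == expected

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            metrics.n50([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=1, max_value=100_000), min_size=1, max_size=100))
    def test_matches_oracle_and_is_permutation_invariant(self, lengths):
        value = metrics.n50(lengths)
        assert value == oracle_n50(lengths)
        assert value in lengths
        assert metrics.n50(lengths[::-1]) == value


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "cigar,nm,expected",
        [
            ("100M", 0, 100.0),
            ("100M", 10, 90.0),
            ("50M10I40M", 12, 88.0),  # columns = 50+10+40 = 100
            ("10S80M5D10S", 5, 100 * (1 - 5 / 85)),  # clips excluded from columns
        ],
    )
    def test_known_values(self, cigar, nm, expected):
        assert metrics.percent_identity(cigar, nm) == pytest.approx(expected)

    def test_no_aligned_columns_is_an_error(self):
        with pytest.raises(ValueError, match="columns"):
            metrics.percent_identity("50S", 0)

    def test_monotone_nonincreasing_in_edit_distance(self):
        values = [metrics.percent_identity("30M2I50M4D", nm) for nm in range(0, 40, 3)]
        assert all(a >= b for a, b in zip(values, values[1:]))


def _table(lengths, qualities=None):
    recs = [
        ReadRecord(
            read_id=f"r{i}",
            length=ln,
            mean_quality=None if qualities is None else qualities[i],
        )
        for i, ln in enumerate(lengths)
    ]
    return ReadTable(label="t", records=recs)


class TestSummarize:
    def test_basic_arithmetic(self):
        s = metrics.summarize(_table([100, 200, 300]))
        assert (s.n_reads, s.total_bases) == (3, 600)
        assert s.mean_length == 200 and s.median_length == 200
        assert s.mean_quality is None and s.n_with_quality == 0

    def test_quality_tier_counts(self):
        s = metrics.summarize(_table([10, 10], [6.0, 12.0]), quality_tiers=(5, 10))
        assert s.reads_over_quality_thresholds == {5.0: 2, 10.0: 1}

    def test_tier_counts_nonincreasing_and_n50_cross_check(self):
        rng = np.random.default_rng(0)
        lengths = rng.integers(1, 50_000, size=500).tolist()
        quals = rng.uniform(2, 20, size=500).tolist()
        s = metrics.summarize(_table(lengths, quals))
        counts = [s.reads_over_quality_thresholds[t] for t in sorted(s.reads_over_quality_thresholds)]
        assert counts == sorted(counts, reverse=True)
        assert s.n50 == metrics.n50(lengths)
        assert len(s.longest_reads) == 5
        assert s.longest_reads[0][1] == max(lengths)

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            metrics.summarize(_table([]))


class TestCumulativeYield:
    def test_running_sum(self):
        recs = [
            ReadRecord(read_id=f"r{i}", length=ln, start_time=h * 3600.0)
            for i, (ln, h) in enumerate(zip([100, 200, 300], [0, 1, 2]))
        ]
        plot = metrics.cumulative_yield(ReadTable(label="t", records=recs))
        assert list(plot.payload["cumulative_bases"]) == [100, 300, 600]

    def test_order_invariant_and_ends_at_total(self, timed_table):
        plot = metrics.cumulative_yield(timed_table)
        shuffled = timed_table.with_records(timed_table.records[::-1])
        plot2 = metrics.cumulative_yield(shuffled)
        np.testing.assert_array_equal(
            plot.payload["cumulative_bases"], plot2.payload["cumulative_bases"]
        )
        assert plot.payload["cumulative_bases"][-1] == sum(timed_table.lengths())
        assert np.all(np.diff(plot.payload["hours"]) >= 0)

    def test_no_times_is_an_error(self):
        with pytest.raises(ValueError, match="start times"):
            metrics.cumulative_yield(_table([10, 20]))


class TestBinByTime:
    def test_half_open_convention(self):
        recs = [
            ReadRecord(read_id=f"r{i}", length=10, mean_quality=9.0, start_time=h * 3600)
            for i, h in enumerate([0.0, 5.9, 6.1])
        ]
        bins = metrics.bin_by_time(ReadTable(label="t", records=recs))
        assert [len(b.values) for b in bins] == [2, 1]
        assert bins[0].start == 0 and bins[0].end == 6 and bins[1].end == 12

    def test_partition_and_constant_field(self, timed_table):
        for r in timed_table.records:
            r.mean_quality = 8.5
        bins = metrics.bin_by_time(timed_table, "mean_quality", 6.0)
        assert sum(len(b.values) for b in bins) == len(timed_table)
        for b in bins:
            if b.values:
                assert np.mean(b.values) == pytest.approx(8.5)

    def test_nonpositive_interval_is_an_error(self, timed_table):
        with pytest.raises(ValueError):
            metrics.bin_by_time(timed_table, interval_hours=0)


class TestDownsample:
    def test_identity_empty_and_determinism(self, timed_table):
        assert metrics.downsample(timed_table, len(timed_table), 1).records == timed_table.records
        empty = metrics.downsample(timed_table, 0, 1)
        assert len(empty) == 0 and empty.label == timed_table.label
        a = metrics.downsample(timed_table, 10, seed=42)
        b = metrics.downsample(timed_table, 10, seed=42)
        assert [r.read_id for r in a] == [r.read_id for r in b]

    def test_preserves_input_order(self, timed_table):
        sample = metrics.downsample(timed_table, 20, seed=5)
        ids = [r.read_id for r in timed_table]
        kept = [r.read_id for r in sample]
        assert kept == [i for i in ids if i in set(kept)]


class TestPlotCutoffs:
    def test_bounds_and_identity(self):
        t = _table([10, 20, 30])
        assert len(metrics.apply_plot_cutoffs(t, max_length=20)) == 2
        assert metrics.apply_plot_cutoffs(t).records == t.records

    def test_matches_brute_force(self, timed_table):
        out = metrics.apply_plot_cutoffs(timed_table, max_length=3000, min_quality=8.0)
        expected = [
            r for r in timed_table.records if r.length <= 3000 and r.mean_quality >= 8.0
        ]
        assert out.records == expected

    def test_quality_bound_drops_reads_without_quality(self):
        t = _table([10, 20])  # no qualities
        assert len(metrics.apply_plot_cutoffs(t, min_quality=5.0)) == 0
        assert len(metrics.apply_plot_cutoffs(t)) == 2
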