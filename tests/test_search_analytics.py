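import numpy as np
import pytest
from hypothesis import given, strategies as st

from vigitrends.quarters import QuarterSeries
from vigitrends.search_analytics import (
    DEFAULT_BLOCKLIST,
    QueryRecord,
    SpsSeries,
    apply_volume_floor,
    compute_sps,
    cumulative_abuse_sps,
    drug_sps_series,
    filter_abuse_queries,
    read_query_log_csv,
    summarize_sps,
    write_sps_csv,
)
from vigitrends.vocab import DrugEntry, QueryTermSet

PREGABALIN = DrugEntry("pregabalin", ("lyrica",))
CLONAZEPAM = DrugEntry("clonazepam", ("klonopin",))
TERM_SETS = [
    QueryTermSet("drug_abuse_and_dependence", ("abuse", "dependence")),
    QueryTermSet("overdose", ("overdose",)),
    QueryTermSet("euphoria", ("high",)),
]


def rec(query, period="2010Q1", count=10.0):
    return QueryRecord(query=query, period=period, count=count)


class TestFilterAbuseQueries:
    def test_abuse_collocation_is_kept_and_tagged(self):
        out = filter_abuse_queries([rec("can you get high of pregabalin")], PREGABALIN, TERM_SETS)
        assert len(out) == 1 and out[0].term_sets == frozenset({"euphoria"})

    def test_blocklisted_collocation_is_dropped(self):
        out = filter_abuse_queries(
            [rec("clonazepam and high blood pressure")], CLONAZEPAM, TERM_SETS
        )
        assert out == []

    def test_query_without_abuse_term_is_dropped(self):
        assert filter_abuse_queries([rec("pregabalin dosage")], PREGABALIN, TERM_SETS) == []

    def test_query_without_drug_name_is_dropped(self):
        assert filter_abuse_queries([rec("drug abuse help")], PREGABALIN, TERM_SETS) == []

    def test_brand_name_matches(self):
        out = filter_abuse_queries([rec("lyrica overdose")], PREGABALIN, TERM_SETS)
        assert len(out) == 1 and out[0].term_sets == frozenset({"overdose"})

    def test_query_may_tag_multiple_term_sets(self):
        out = filter_abuse_queries([rec("pregabalin abuse and overdose")], PREGABALIN, TERM_SETS)
        assert out[0].term_sets == frozenset({"drug_abuse_and_dependence", "overdose"})

    def test_substring_inside_word_does_not_match(self):
        # "highway" contains "high" only as a fragment, not as a word
        assert filter_abuse_queries([rec("pregabalin highway")], PREGABALIN, TERM_SETS) == []

    def test_pure_filter_output_subset_of_input(self):
        records = [rec("pregabalin abuse"), rec("pregabalin dosage"), rec("lyrica high")]
        out = filter_abuse_queries(records, PREGABALIN, TERM_SETS)
        assert {o.query for o in out} <= {r.query for r in records}


class TestComputeSps:
    def test_half_the_top_volume_scores_fifty(self):
        series = compute_sps([rec("q", count=100.0)], {"2010Q1": 200.0})
        assert series.values[0] == 50.0

    def test_top_volume_scores_one_hundred(self):
        series = compute_sps([rec("q", count=200.0)], {"2010Q1": 200.0})
        assert series.values[0] == 100.0

    def test_sub_one_percent_share_is_suppressed_to_zero(self):
        series = compute_sps(
            [rec("q", count=5.0)],
            {"2010Q1": 1000.0},
            total_related_counts={"2010Q1": 1000.0},
        )
        assert series.values[0] == 0.0 and bool(series.suppressed[0])

    def test_zero_reference_volume_yields_missing_not_error(self):
        series = compute_sps([rec("q", count=5.0)], {"2010Q1": 0.0})
        assert np.isnan(series.values[0]) and not series.suppressed[0]

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    def test_scale_invariance_under_uniform_volume_rescaling(self, scale):
        base = compute_sps(
            [rec("q", count=40.0), rec("q2", "2010Q2", 10.0)],
            {"2010Q1": 200.0, "2010Q2": 300.0},
        )
        scaled = compute_sps(
            [rec("q", count=40.0 * scale), rec("q2", "2010Q2", 10.0 * scale)],
            {"2010Q1": 200.0 * scale, "2010Q2": 300.0 * scale},
        )
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-9)
        assert (scaled.suppressed == base.suppressed).all()

    @given(
        volumes=st.lists(st.floats(min_value=0, max_value=500), min_size=1, max_size=6),
        top=st.floats(min_value=1, max_value=500),
    )
    def test_per_term_values_stay_in_unit_interval(self, volumes, top):
        records = [rec(f"q{i}", count=v) for i, v in enumerate(volumes)]
        series = compute_sps(records, {"2010Q1": top})
        finite = series.values[np.isfinite(series.values)]
        assert ((finite >= 0) & (finite <= 100)).all()


class TestCumulative:
    def _series(self, values, suppressed=None, term_set="a"):
        values = np.asarray(values, float)
        if suppressed is None:
            suppressed = np.zeros(len(values), bool)
        quarters = tuple(f"2010Q{i+1}" for i in range(len(values)))
        return SpsSeries("pregabalin", term_set, quarters, values, np.asarray(suppressed))

    def test_additivity(self):
        total = cumulative_abuse_sps([self._series([30.0]), self._series([40.0], term_set="b")])
        assert total.values[0] == 70.0

    def test_sum_may_exceed_one_hundred(self):
        total = cumulative_abuse_sps(
            [self._series([25.0], term_set=str(i)) for i in range(5)]
        )
        assert total.values[0] == 125.0

    def test_all_components_suppressed_gives_zero(self):
        total = cumulative_abuse_sps(
            [self._series([0.0], [True]), self._series([0.0], [True], term_set="b")]
        )
        assert total.values[0] == 0.0

    def test_window_mismatch_is_an_error(self):
        a = self._series([1.0, 2.0])
        b = SpsSeries("pregabalin", "b", ("2011Q1", "2011Q2"), np.array([1.0, 2.0]), np.zeros(2, bool))
        with pytest.raises(ValueError, match="window"):
            cumulative_abuse_sps([a, b])

    def test_drug_mismatch_is_an_error(self):
        a = self._series([1.0])
        b = SpsSeries("gabapentin", "b", ("2010Q1",), np.array([1.0]), np.zeros(1, bool))
        with pytest.raises(ValueError, match="drug"):
            cumulative_abuse_sps([a, b])

    def test_cumulative_at_least_max_component(self):
        parts = [self._series([10.0, 0.0]), self._series([15.0, 5.0], term_set="b")]
        total = cumulative_abuse_sps(parts)
        stacked = np.vstack([p.values for p in parts])
        assert (total.values >= stacked.max(axis=0)).all()


class TestSummarize:
    def test_constant_series(self):
        s = QuarterSeries(("2010Q1", "2010Q2"), np.array([10.0, 10.0]))
        summary = summarize_sps(s)
        assert (summary.mean, summary.median, summary.iqr) == (10.0, 10.0, (10.0, 10.0))

    def test_even_length_median_interpolates(self):
        s = QuarterSeries(tuple(f"2010Q{i+1}" for i in range(4)), np.array([1.0, 2.0, 3.0, 4.0]))
        assert summarize_sps(s).median == 2.5

    def test_all_missing_is_an_error(self):
        s = QuarterSeries(("2010Q1",), np.array([np.nan]))
        with pytest.raises(ValueError, match="insufficient data"):
            summarize_sps(s)


class TestVolumeFloor:
    def test_zero_volume_flags_insufficient_data(self):
        out = apply_volume_floor([], 1.0)
        assert out.insufficient_data and out.records == ()

    def test_volume_exactly_at_floor_is_reported(self):
        out = apply_volume_floor([rec("q", count=50.0)], 50.0)
        assert not out.insufficient_data and len(out.records) == 1

    def test_below_floor_is_suppressed(self):
        out = apply_volume_floor([rec("q", count=49.0)], 50.0)
        assert out.insufficient_data


class TestQueryLogIO:
    def test_monthly_records_aggregate_to_quarters_by_mean(self, tmp_path):
        path = tmp_path / "log.csv"
        path.write_text(
            "query,period,count,context_tag\n"
            "pregabalin abuse,2010-01,10,prescription_drug\n"
            "pregabalin abuse,2010-02,20,prescription_drug\n"
            "pregabalin abuse,2010-03,30,prescription_drug\n",
            encoding="utf-8",
        )
        (record,) = read_query_log_csv(path)
        assert record.period == "2010Q1" and record.count == 20.0
        (summed,) = read_query_log_csv(path, monthly_aggregation="sum")
        assert summed.count == 60.0

    def test_sps_csv_round_trippable_shape(self, tmp_path):
        series = SpsSeries(
            "pregabalin", "overdose", ("2010Q1",), np.array([12.5]), np.array([False])
        )
        path = tmp_path / "sps.csv"
        write_sps_csv([series], path)
        header, row = path.read_text().strip().splitlines()
        assert header == "drug,term_set,quarter,sps,suppressed"
        assert row.startswith("pregabalin,overdose,2010Q1,12.5")


class TestDrugSpsPipeline:
    def _log(self):
        out = []
        for q, trend in (("2010Q1", 1.0), ("2010Q2", 2.0)):
            out.append(rec("pregabalin", q, 1000.0))
            out.append(rec("pregabalin abuse", q, 100.0 * trend))
            out.append(rec("can you get high of pregabalin", q, 50.0 * trend))
            out.append(rec("pregabalin and high blood pressure", q, 500.0))
        return out

    def test_series_per_term_set_with_top_query_reference(self):
        series, floored = drug_sps_series(self._log(), PREGABALIN, TERM_SETS)
        assert not floored.insufficient_data
        by_name = {s.term_set: s for s in series}
        np.testing.assert_allclose(
            by_name["drug_abuse_and_dependence"].values, [10.0, 20.0]
        )
        np.testing.assert_allclose(by_name["euphoria"].values, [5.0, 10.0])

    def test_volume_floor_suppresses_whole_drug(self):
        series, floored = drug_sps_series(
            self._log(), PREGABALIN, TERM_SETS, volume_floor=1e9
        )
        assert series == [] and floored.insufficient_data
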