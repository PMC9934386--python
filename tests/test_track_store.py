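"""Fix-table IO, filtering rules, fate criteria and cohort arithmetic."""

import io
import textwrap
from datetime import date

import numpy as np
import pandas as pd
import pytest

from gulltrack import track_store
from gulltrack.table1 import load_table1
from gulltrack.track_store import (
    ConfigurationError, Deployment, apply_inclusion_filter, classify_fate,
    cohort_summary, filter_fixes, monitored_days, read_fix_table,
    round_half_away, select_subsample, summarize_deployment,
)

from conftest import make_track


def _csv(text):
    return io.StringIO(textwrap.dedent(text))


class TestReadFixTable:
    def test_single_bird_identity(self):
        tracks, rep = read_fix_table(_csv("""\
            bird_id,timestamp,lat,lon
            b1,2016-01-01 00:00,37.0,129.0
            b1,2016-01-01 02:00,37.1,129.1
            b1,2016-01-01 04:00,37.2,129.2
        """))
        assert len(tracks) == 1 and len(tracks[0]) == 3
        assert rep.bad_rows == 0

    def test_out_of_order_rows_sorted(self):
        tracks, _ = read_fix_table(_csv("""\
            bird_id,timestamp,lat,lon
            b1,2016-01-01 04:00,37.2,129.2
            b1,2016-01-01 00:00,37.0,129.0
        """))
        assert tracks[0].fixes["timestamp"].is_monotonic_increasing

    def test_interleaved_birds_partitioned(self):
        # oracle: brute-force partition of the same toy file
        rows = [("b1", "2016-01-01 00:00"), ("b2", "2016-01-01 01:00"),
                ("b1", "2016-01-01 02:00"), ("b2", "2016-01-01 03:00")]
        body = "\n".join(f"{b},{t},37.0,129.0" for b, t in rows)
        tracks, _ = read_fix_table(_csv("bird_id,timestamp,lat,lon\n" + body))
        expected = {b: sorted(t for bb, t in rows if bb == b) for b in ("b1", "b2")}
        assert {t.bird_id: len(t) for t in tracks} == {"b1": 2, "b2": 2}
        for t in tracks:
            got = t.fixes["timestamp"].dt.strftime("%Y-%m-%d %H:%M").tolist()
            assert got == expected[t.bird_id]

    def test_missing_required_column_raises(self):
        with pytest.raises(ConfigurationError):
            read_fix_table(_csv("bird_id,timestamp,lat\nb1,2016-01-01,37.0\n"))

    def test_malformed_timestamp_counted_not_dropped_silently(self):
        tracks, rep = read_fix_table(_csv("""\
            bird_id,timestamp,lat,lon
            b1,2016-01-01 00:00,37.0,129.0
            b1,not-a-time,37.1,129.1
        """))
        assert rep.bad_rows == 1 and len(tracks[0]) == 1

    def test_movebank_preset(self):
        tracks, _ = read_fix_table(_csv("""\
            individual-local-identifier,timestamp,location-lat,location-long
            b1,2016-01-01 00:00,37.0,129.0
        """), column_map=track_store.MOVEBANK_COLUMNS)
        assert tracks[0].bird_id == "b1"


class TestFilterFixes:
    def test_failed_fix_removed(self):
        t = make_track("b", pd.date_range("2016-01-01", periods=5, freq="2h"),
                       [37, 37, 0, 37, 37], [129, 129, 0, 129, 129])
        out, rep = filter_fixes(t)
        assert len(out) == 4 and rep.failed == 1 and rep.duplicate == 0

    def test_duplicate_timestamp_keeps_first(self):
        times = ["2016-01-01 00:00", "2016-01-01 02:00", "2016-01-01 02:00"]
        t = make_track("b", times, [37.0, 37.1, 99.0], [129, 129, 129])
        out, rep = filter_fixes(t)
        assert rep.duplicate == 1
        assert out.fixes["lat"].tolist() == [37.0, 37.1]

    def test_same_place_different_time_kept(self):
        t = make_track("b", ["2016-01-01 00:00", "2016-01-01 02:00"],
                       [37.0, 37.0], [129.0, 129.0])
        out, rep = filter_fixes(t)
        assert len(out) == 2 and rep.duplicate == 0

    def test_idempotent_and_conserves_counts(self, noisy_cohort):
        _, (tracks, _, truth) = noisy_cohort
        for t in tracks:
            out, rep = filter_fixes(t)
            assert len(out) + rep.failed + rep.duplicate == len(t)
            again, rep2 = filter_fixes(out)
            assert len(again) == len(out)
            assert rep2.failed == 0 and rep2.duplicate == 0

    def test_injected_artifact_counts_recovered_exactly(self, noisy_cohort):
        _, (tracks, _, truth) = noisy_cohort
        inj = truth.injected.set_index("bird_id")
        for t in tracks:
            _, rep = filter_fixes(t)
            assert rep.failed == inj.loc[t.bird_id, "failed"]
            assert rep.duplicate == inj.loc[t.bird_id, "duplicate"]


class TestInclusionFilter:
    @pytest.mark.parametrize("days,included", [(99, False), (100, True)])
    def test_threshold_boundary(self, days, included):
        times = [pd.Timestamp("2016-01-01", tz="UTC") + pd.Timedelta(days=d)
                 for d in (0, days)]
        t = make_track("b", times, [37, 38], [129, 130])
        assert monitored_days(t) == days
        inc, exc = apply_inclusion_filter([t])
        assert (len(inc) == 1) is included


class TestClassifyFate:
    def _dep(self, duty=12):
        return Deployment(bird_id="b", duty_cycle_h=duty)

    def test_terminal_stationarity_means_dead_or_lost(self):
        times = pd.date_range("2016-01-01", periods=60, freq="12h", tz="UTC")
        lat = np.concatenate([np.linspace(37, 45, 50), np.full(10, 45.0)])
        lon = np.full(60, 129.0)
        rec = classify_fate(make_track("b", times, lat, lon), self._dep())
        assert rec.fate == "dead_or_tag_lost"

    def test_low_completeness_is_technical_failure(self):
        times = pd.date_range("2016-01-01", periods=60, freq="12h", tz="UTC")
        keep = np.arange(60) % 3 != 0  # ~67% of expected fixes
        rng = np.random.default_rng(0)
        lat = np.cumsum(rng.normal(0.3, 0.1, 60)) + 37
        t = make_track("b", times[keep], lat[keep], np.full(keep.sum(), 129.0))
        rec = classify_fate(t, self._dep())
        assert rec.fate == "technical_failure" and "low_completeness" in rec.evidence

    def test_healthy_moving_track_is_unknown(self):
        times = pd.date_range("2016-01-01", periods=60, freq="12h", tz="UTC")
        rng = np.random.default_rng(1)
        lat = np.cumsum(rng.normal(0.3, 0.1, 60)) + 37
        t = make_track("b", times, lat, np.full(60, 129.0),
                       volts=np.full(60, 4.1))
        rec = classify_fate(t, self._dep())
        assert rec.fate == "unknown"

    def test_low_voltage_flagged(self):
        times = pd.date_range("2016-01-01", periods=60, freq="12h", tz="UTC")
        rng = np.random.default_rng(2)
        lat = np.cumsum(rng.normal(0.3, 0.1, 60)) + 37
        t = make_track("b", times, lat, np.full(60, 129.0), volts=np.full(60, 3.8))
        rec = classify_fate(t, self._dep())
        assert rec.fate == "technical_failure" and "low_voltage" in rec.evidence

    def test_transmitting_at_study_end_is_censored(self):
        times = pd.date_range("2016-01-01", periods=10, freq="12h", tz="UTC")
        t = make_track("b", times, np.linspace(37, 38, 10), np.full(10, 129.0))
        rec = classify_fate(t, self._dep(), study_end=date(2016, 1, 5))
        assert rec.fate == "alive_at_censoring"


class TestSummaries:
    def test_identical_points_zero_distance(self):
        t = make_track("b", ["2016-01-01", "2016-01-02"], [37.0, 37.0], [129.0, 129.0])
        assert summarize_deployment(t)["total_track_km"] == 0.0

    def test_table1_mean_km_per_day_reproduced_per_row(self):
        t1 = load_table1()
        recomputed = round_half_away(t1["total_track_km"] / t1["n_days"], 1)
        np.testing.assert_allclose(recomputed, t1["mean_km_per_day"], atol=1e-9)

    def test_table1_day_counts_from_dates(self):
        t1 = load_table1()
        spans = (t1["end_date"] - t1["start_date"]).dt.days
        np.testing.assert_array_equal(spans, t1["n_days"])

    @pytest.mark.parametrize("bird,km_day", [("ke1511", 26.6), ("br1428", 75.3)])
    def test_reference_birds(self, bird, km_day):
        row = load_table1().set_index("bird_id").loc[bird]
        assert round_half_away(row["total_track_km"] / row["n_days"], 1) == km_day

    def test_cohort_summary_totals_and_means(self):
        cs = cohort_summary(load_table1())
        assert cs["total_fixes"] == 94017
        assert cs["total_days"] == 10736
        assert round_half_away(cs["mean_fixes_per_bird"]) == 3358
        assert round_half_away(cs["mean_days_per_bird"]) == 383
        assert round_half_away(cs["mean_track_km_per_bird"]) == 18709
        assert round_half_away(cs["grand_mean_km_per_day"], 1) == 48.8
        assert round_half_away(cs["longest_gc_mean_km"]) == 3709
        assert round_half_away(cs["longest_gc_sd_km"]) == 940

    def test_cohort_totals_are_exact_sums(self, quiet_cohort):
        _, (tracks, _, _) = quiet_cohort
        rows = pd.DataFrame([summarize_deployment(t) for t in tracks])
        cs = cohort_summary(rows)
        assert cs["total_fixes"] == rows["n_fixes"].sum()
        assert cs["total_days"] == rows["n_days"].sum()
        assert cs["total_track_km"] == pytest.approx(rows["total_track_km"].sum(), rel=1e-12)

    def test_single_bird_sd_flagged(self):
        rows = pd.DataFrame([{"bird_id": "b", "n_days": 100, "n_fixes": 10,
                              "total_track_km": 50.0, "longest_gc_km": 20.0}])
        cs = cohort_summary(rows)
        assert np.isnan(cs["longest_gc_sd_km"])
        assert cs["mean_days_per_bird"] == 100

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary(pd.DataFrame(columns=["n_days"]))

    @pytest.mark.parametrize("x,nd,expected", [
        (3357.75, 0, 3358), (18708.6, 0, 18709), (-1.5, 0, -2), (75.25, 1, 75.3),
    ])
    def test_round_half_away(self, x, nd, expected):
        assert round_half_away(x, nd) == expected


class TestSubsamples:
    def test_rule_A_drops_nonbreeders(self, noisy_cohort):
        _, (tracks, deployments, truth) = noisy_cohort
        sel = select_subsample(tracks, deployments, "A")
        expected = set(truth.birds.loc[truth.birds["breeder"], "bird_id"])
        assert {t.bird_id for t in sel} == expected

    def test_rule_B_empty_when_no_2h_tags(self):
        t = make_track("b", ["2016-01-01", "2016-01-02"], [37, 38], [129, 130])
        deps = [Deployment(bird_id="b", duty_cycle_h=12)]
        assert select_subsample([t], deps, "B") == []

    def test_rule_C_keeps_first_year_only(self, two_year_cohort):
        _, (tracks, deployments, _) = two_year_cohort
        filtered = [track_store.filter_fixes(t)[0] for t in tracks]
        sel = select_subsample(filtered, deployments, "C")
        assert len(sel) == len(filtered)
        for t in sel:
            # trimmed at the end of the first full-cycle winter
            assert t.local_dates.max() < pd.Timestamp("2017-04-13")

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            select_subsample([], {}, "Z")
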