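"""Activity normalization, colony-visit detection and phenology summaries."""

import numpy as np
import pandas as pd
import pytest

from petrelpop.phenology import (
    ActivityTrace,
    classify_colony_visits,
    first_arrival,
    incubation_bouts,
    night_mask_from_hours,
    night_mask_from_light,
    normalize_activity,
    read_activity_tsv,
    write_activity_tsv,
)
from petrelpop.simulate import ActivitySimConfig, gen_activity


class TestNormalize:
    def test_counts_dialect_scales_to_fraction(self):
        raw = pd.DataFrame(
            {"timestamp": pd.date_range("2013-08-01", periods=3, freq="10min"),
             "value": [200, 0, 50]}
        )
        tr = normalize_activity(raw, "counts-0-200")
        assert tr.wet.tolist() == [1.0, 0.0, 0.25]

    def test_state_change_integrates_within_bins(self):
        raw = pd.DataFrame(
            {"timestamp": [pd.Timestamp("2013-08-01 00:00"),
                           pd.Timestamp("2013-08-01 00:05")],
             "state": ["wet", "dry"]}
        )
        tr = normalize_activity(raw, "state-change",
                                period=("2013-08-01 00:00", "2013-08-01 00:30"))
        assert tr.wet.tolist() == [0.5, 0.0, 0.0]

    def test_state_change_synthesis_inversion(self):
        """Events synthesized from a known fraction series normalize back to
        the same series (to one 3-second tick per bin)."""
        rng = np.random.default_rng(0)
        bins = pd.date_range("2013-08-01", periods=48, freq="10min")
        target = np.round(rng.uniform(0, 1, len(bins)) * 200) / 200
        events = []
        for t, frac in zip(bins, target):
            if frac > 0:
                events.append((t, "wet"))
            if frac < 1:
                events.append((t + pd.Timedelta(seconds=600 * frac), "dry"))
        raw = pd.DataFrame(events, columns=["timestamp", "state"])
        tr = normalize_activity(raw, "state-change",
                                period=(bins[0], bins[-1] + pd.Timedelta(minutes=10)))
        assert np.abs(tr.wet.to_numpy() - target).max() <= 3 / 600 + 1e-9

    def test_unknown_dialect_and_unordered_timestamps_raise(self):
        raw = pd.DataFrame({"timestamp": [pd.Timestamp("2013-08-01")],
                            "value": [3]})
        with pytest.raises(ValueError, match="dialect"):
            normalize_activity(raw, "morse")
        bad = pd.DataFrame(
            {"timestamp": [pd.Timestamp("2013-08-01 00:10"),
                           pd.Timestamp("2013-08-01 00:00")],
             "value": [0, 0]}
        )
        with pytest.raises(ValueError, match="monotonic|non-decreasing"):
            normalize_activity(bad, "counts-0-200")


def _trace_with_dry_night_run(hours=6.0):
    bins = pd.date_range("2013-08-01", "2013-08-03", freq="10min",
                         inclusive="left")
    wet = np.ones(len(bins))
    start = pd.Timestamp("2013-08-01 21:00")
    sel = (bins >= start) & (bins < start + pd.Timedelta(hours=hours))
    wet[sel] = 0.0
    return ActivityTrace("b", pd.Series(wet, index=bins)), start, hours


class TestVisitClassification:
    def test_single_long_dry_night_run_is_one_visit(self):
        tr, start, hours = _trace_with_dry_night_run(6.0)
        visits = classify_colony_visits(tr, night_mask_from_hours(tr.wet.index))
        assert len(visits) == 1
        v = visits[0]
        assert v.start == start
        assert v.duration == pd.Timedelta(hours=6)
        assert v.kind == "night-visit"

    def test_fully_wet_trace_has_no_visits(self):
        bins = pd.date_range("2013-08-01", periods=288, freq="10min")
        tr = ActivityTrace("b", pd.Series(np.ones(288), index=bins))
        assert classify_colony_visits(tr, night_mask_from_hours(bins)) == []

    def test_threshold_is_strict(self):
        tr, _, _ = _trace_with_dry_night_run(4.0)  # exactly 4 h: not a visit
        assert classify_colony_visits(
            tr, night_mask_from_hours(tr.wet.index)) == []

    def test_scripted_visits_recovered_exactly(self):
        """Fifty scripted night visits in a month-long wet trace are all
        recovered with no false positives."""
        starts = pd.date_range("2013-08-01 21:00", periods=25, freq="D")
        script = {
            "bird1": [(t, 5.0) for t in starts],
            "bird2": [(t + pd.Timedelta(minutes=30), 6.0) for t in starts],
        }
        cfg = ActivitySimConfig(
            n_birds=2, season_start="2013-08-01", season_end="2013-09-01",
            scripted_visits=script, scripted_bouts={},
        )
        traces, truth = gen_activity(cfg, seed=1)
        found = 0
        for bird, tr in traces.items():
            visits = classify_colony_visits(
                tr, night_mask_from_hours(tr.wet.index))
            want = truth[bird]
            assert len(visits) == len(want)
            for got, exp in zip(visits, want):
                assert got.start == exp.start and got.end == exp.end
            found += len(visits)
        assert found == 50

    def test_recall_with_dry_flight_noise(self):
        cfg = ActivitySimConfig(
            n_birds=3, season_start="2013-09-01", season_end="2013-10-01",
            dry_noise_rate=0.05,
            scripted_visits={
                f"bird{i}": [
                    (pd.Timestamp(f"2013-09-{d:02d} 20:30"), 5.5)
                    for d in range(2, 28, 3)
                ]
                for i in (1, 2, 3)
            },
            scripted_bouts={},
        )
        traces, truth = gen_activity(cfg, seed=2)
        hits = total = 0
        for bird, tr in traces.items():
            visits = classify_colony_visits(
                tr, night_mask_from_hours(tr.wet.index))
            for exp in truth[bird]:
                total += 1
                if any(v.start <= exp.start and v.end >= exp.end for v in visits):
                    hits += 1
        assert hits / total >= 0.95

    def test_burrow_day_merges_with_adjacent_night_visit(self):
        cfg = ActivitySimConfig(
            n_birds=1, season_start="2013-09-01", season_end="2013-09-20",
            scripted_visits={"bird1": [("2013-09-04 20:00", 10.0)]},
            scripted_bouts={"bird1": [("2013-09-05", 3)]},
        )
        traces, _ = gen_activity(cfg, seed=3)
        tr = traces["bird1"]
        visits = classify_colony_visits(tr, night_mask_from_hours(tr.wet.index))
        assert len(visits) == 1
        assert visits[0].kind == "burrow-day"
        assert visits[0].start == pd.Timestamp("2013-09-04 20:00")

    def test_classification_idempotent_under_renormalization(self):
        tr, _, _ = _trace_with_dry_night_run(5.0)
        raw = pd.DataFrame({"timestamp": tr.wet.index,
                            "value": tr.wet.to_numpy() * 200})
        tr2 = normalize_activity(raw, "counts-0-200", bird_id="b")
        mask = night_mask_from_hours(tr.wet.index)
        v1 = classify_colony_visits(tr, mask)
        v2 = classify_colony_visits(tr2, mask)
        assert [(v.start, v.end) for v in v1] == [(v.start, v.end) for v in v2]

    def test_invalid_threshold(self):
        tr, _, _ = _trace_with_dry_night_run()
        with pytest.raises(ValueError):
            classify_colony_visits(tr, night_mask_from_hours(tr.wet.index),
                                   dry_threshold_hours=0)


class TestNightMaskFromLight:
    def test_matches_clock_night_for_clean_trace(self):
        cfg = ActivitySimConfig(n_birds=1, season_start="2013-09-01",
                                season_end="2013-09-08",
                                scripted_visits={"bird1": []},
                                scripted_bouts={"bird1": [("2013-09-03", 2)]})
        traces, _ = gen_activity(cfg, seed=4)
        tr = traces["bird1"]
        from_light = night_mask_from_light(tr)
        from_clock = night_mask_from_hours(tr.wet.index)
        assert (from_light == from_clock).mean() > 0.99


class TestSummaries:
    def test_first_arrival_arithmetic(self):
        from petrelpop.phenology import ColonyVisit

        mk = lambda b, day: ColonyVisit(
            b, pd.Timestamp("2013-01-01") + pd.Timedelta(days=day - 1),
            pd.Timestamp("2013-01-01") + pd.Timedelta(days=day - 1, hours=5),
            "night-visit")
        visits = {"a": [mk("a", 260)], "b": [mk("b", 270)], "c": [mk("c", 280)]}
        df = first_arrival(visits, "2013-01-01")
        mean_doy = (df.attrs["mean_date"] - pd.Timestamp("2013-01-01")).days + 1
        assert mean_doy == 270
        assert df.attrs["sd_days"] == pytest.approx(10.0)
        assert df.attrs["n"] == 3

    def test_single_bird_has_zero_sd(self):
        from petrelpop.phenology import ColonyVisit

        v = ColonyVisit("a", pd.Timestamp("2013-09-17 21:00"),
                        pd.Timestamp("2013-09-18 02:00"), "night-visit")
        df = first_arrival({"a": [v]}, "2013-08-01")
        assert df.attrs["sd_days"] == 0.0

    def test_bird_without_visits_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="no visits"):
            df = first_arrival({"a": []}, "2013-08-01")
        assert len(df) == 0

    def test_incubation_bout_durations(self):
        cfg = ActivitySimConfig(
            n_birds=1, season_start="2013-09-01", season_end="2013-11-30",
            scripted_visits={"bird1": []},
            scripted_bouts={"bird1": [("2013-09-10", 10), ("2013-10-01", 14),
                                      ("2013-10-25", 10), ("2013-11-10", 14)]},
        )
        traces, _ = gen_activity(cfg, seed=5)
        tr = traces["bird1"]
        visits = classify_colony_visits(tr, night_mask_from_hours(tr.wet.index))
        bouts = incubation_bouts(visits, ("2013-09-01", "2013-11-29"))
        assert sorted(bouts["days"]) == [10, 10, 14, 14]
        assert bouts.attrs["mean_days"] == pytest.approx(12.0)

    def test_alternating_days_give_unit_bouts(self):
        from petrelpop.phenology import ColonyVisit

        visits = [
            ColonyVisit("a", pd.Timestamp(f"2013-10-{d:02d}"),
                        pd.Timestamp(f"2013-10-{d + 1:02d}"), "burrow-day")
            for d in (1, 3, 5, 7)
        ]
        bouts = incubation_bouts(visits, ("2013-10-01", "2013-10-31"))
        assert bouts["days"].tolist() == [1, 1, 1, 1]

    def test_bouts_partition_burrow_days(self):
        cfg = ActivitySimConfig(
            n_birds=1, season_start="2013-09-01", season_end="2013-10-20",
            scripted_visits={"bird1": []},
            scripted_bouts={"bird1": [("2013-09-05", 12), ("2013-09-25", 5)]},
        )
        traces, _ = gen_activity(cfg, seed=6)
        tr = traces["bird1"]
        visits = classify_colony_visits(tr, night_mask_from_hours(tr.wet.index))
        window = ("2013-09-01", "2013-10-19")
        bouts = incubation_bouts(visits, window)
        n_days = sum(
            1
            for v in visits if v.kind == "burrow-day"
            for d in v.dates()
            if pd.Timestamp(window[0]) <= pd.Timestamp(d) <= pd.Timestamp(window[1])
        )
        assert bouts["days"].sum() == n_days

    def test_empty_window_empty_result(self):
        assert len(incubation_bouts([], ("2013-09-01", "2013-09-02"))) == 0


def test_activity_tsv_round_trip(tmp_path):
    s = pd.Series([0.0, 0.5, 1.0],
                  index=pd.date_range("2013-08-01", periods=3, freq="10min"))
    p = tmp_path / "b.wet.tsv"
    write_activity_tsv(s, p)
    back = read_activity_tsv(p)
    assert (back.values == s.values).all()
    assert (back.index == s.index).all()
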