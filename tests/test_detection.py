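import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ftcflux import DetectorConfig, annual_ftc_days, classify_soil_state, detect_events

from conftest import make_series
from oracles import oracle_detect


def detect_tuples(ts_values, **cfg):
    """(freeze_start, freeze_end, thaw_end, frozen_days) index tuples."""
    series = make_series(ts_values)
    events = detect_events(series, DetectorConfig(**cfg))
    if not events:
        return []
    d0 = series.dates[0]
    return [
        ((e.freeze_start - d0).days, (e.freeze_end - d0).days,
         (e.thaw_end - d0).days, e.frozen_days)
        for e in events
    ]


class TestClassifySoilState:
    def test_all_warm_days_unfrozen(self):
        s = make_series([5.0] * 30)
        state = classify_soil_state(s.ts)
        assert (state == "unfrozen").all()

    def test_freeze_then_thaw_labelling(self):
        # 7 sub-zero days then 7 above-zero: days 0-6 frozen, 7-11 thawing
        s = make_series([-1.0] * 7 + [1.0] * 7)
        state = classify_soil_state(s.ts).tolist()
        assert state[:7] == ["frozen"] * 7
        assert state[7:12] == ["thawing"] * 5
        assert state[12:] == ["unfrozen"] * 2

    def test_short_cold_snap_not_frozen(self):
        s = make_series([2.0] * 5 + [-1.0] * 3 + [2.0] * 5)
        assert (classify_soil_state(s.ts) == "frozen").sum() == 0

    def test_missing_days_undetermined_and_break_runs(self):
        s = make_series([-1.0] * 3 + [None] + [-1.0] * 3 + [1.0] * 6)
        state = classify_soil_state(s.ts)
        assert state.iloc[3] == "undetermined"
        assert (state == "frozen").sum() == 0  # both fragments < 5 days

    def test_unconfirmed_frozen_run_at_record_end_still_frozen(self):
        s = make_series([2.0] * 5 + [-1.0] * 8)
        state = classify_soil_state(s.ts)
        assert (state == "frozen").sum() == 8
        assert detect_events(s) == []

    def test_empty_input(self):
        s = make_series([])
        assert len(classify_soil_state(s.ts)) == 0


class TestDetectEvents:
    def test_constant_warm_series_no_events(self):
        assert detect_tuples([5.0] * 60) == []

    def test_single_clean_event(self):
        # 20 frozen days + 20 thaw days: one event, duration 25 at defaults
        t = detect_tuples([-2.0] * 20 + [2.0] * 20)
        assert t == [(0, 19, 24, 20)]

    def test_two_runs_split_by_qualifying_thaw(self):
        seq = [-1.0] * 10 + [1.0] * 6 + [-1.0] * 10 + [1.0] * 10
        t = detect_tuples(seq)
        assert t == [(0, 9, 14, 10), (16, 25, 30, 10)]

    def test_short_warm_interlude_does_not_thaw(self):
        # 10 frozen, 3 warm, 8 frozen, 10 warm -> ONE event spanning both runs
        seq = [-1.0] * 10 + [1.0] * 3 + [-1.0] * 8 + [1.0] * 10
        t = detect_tuples(seq)
        assert t == [(0, 20, 25, 18)]

    def test_zero_degree_days_break_qualifying_runs(self):
        # zero day splits the sub-zero run into 4+4: no qualifying onset
        assert detect_tuples([-1.0] * 4 + [0.0] + [-1.0] * 4 + [1.0] * 6) == []

    def test_missing_day_aborts_unconfirmed_event(self):
        seq = [-1.0] * 8 + [None] + [1.0] * 8
        assert detect_tuples(seq) == []

    def test_max_gap_tolerates_short_gaps(self):
        seq = [-1.0] * 8 + [None] + [1.0] * 8
        t = detect_tuples(seq, max_gap_days=1)
        assert t == [(0, 7, 13, 8)]

    def test_pre_window_flag(self):
        seq = [-1.0] * 6 + [1.0] * 6 + [5.0] * 30
        series = make_series(seq)
        (event,) = detect_events(series)
        assert not event.pre_ok
        later = make_series([5.0] * 15 + seq)
        (event2,) = detect_events(later)
        assert event2.pre_ok

    def test_events_disjoint_and_ordered(self):
        rng = np.random.default_rng(3)
        vals = np.where(rng.random(400) < 0.5, -1.0, 1.0) * rng.uniform(0.5, 3, 400)
        events = detect_events(make_series(vals))
        for a, b in zip(events, events[1:]):
            assert a.thaw_end < b.freeze_start

    def test_frozen_days_match_frozen_labels_inside_events(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 2, 500)
        series = make_series(vals)
        events = detect_events(series)
        state = classify_soil_state(series.ts)
        for ev in events:
            span = state.loc[ev.freeze_start : ev.freeze_end]
            assert (span == "frozen").sum() == ev.frozen_days

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.sampled_from([-2.0, -0.5, 0.5, 2.0]), min_size=0, max_size=120),
           st.floats(min_value=0.1, max_value=50.0),
           st.floats(min_value=0.1, max_value=50.0))
    def test_threshold_invariance(self, vals, warm_scale, cold_scale):
        """Events depend only on the sign pattern: scaling warm days up and
        cold days down arbitrarily changes nothing."""
        base = detect_tuples(vals)
        morphed = [v * (warm_scale if v > 0 else cold_scale) for v in vals]
        assert detect_tuples(morphed) == base

    def test_agrees_with_bruteforce_oracle_on_structured_noise(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 400))
            amp = rng.uniform(0, 6)
            vals = amp * np.sin(2 * np.pi * (np.arange(n) + rng.uniform(0, 365)) / 365.0)
            vals = vals + rng.normal(0, 1.5, n)
            vals[rng.random(n) < 0.03] = np.nan
            expected = oracle_detect(vals.tolist())
            assert detect_tuples(vals) == expected


class TestAnnualFtcDays:
    def test_no_events_means_zero(self):
        per_year, mean = annual_ftc_days([], ("2000-01-01", "2009-12-31"))
        assert mean == 0.0
        assert len(per_year) == 10

    def test_event_split_across_new_year(self):
        series = make_series([5.0] * 350 + [-1.0] * 30 + [1.0] * 30, start="2000-01-01")
        (ev,) = detect_events(series)  # frozen mid-Dec 2000 through mid-Jan 2001
        per_year, mean = annual_ftc_days([ev], (series.dates[0], series.dates[-1]))
        total = per_year.sum()
        assert total == ev.duration
        assert per_year.loc[2000] + per_year.loc[2001] == total
        assert per_year.loc[2000] > 0 and per_year.loc[2001] > 0

    def test_one_event_per_year_mean(self):
        # 25-day event inside each of 2 calendar years -> mean 25
        year = [5.0] * 100 + [-2.0] * 20 + [2.0] * 20 + [5.0] * 225
        series = make_series(year + year + [5.0] * 1, start="2001-01-01")
        events = detect_events(series)
        assert len(events) == 2
        _, mean = annual_ftc_days(events, (pd.Timestamp("2001-01-01"), pd.Timestamp("2002-12-31")))
        assert mean == 25.0

    def test_zero_length_span_rejected(self):
        with pytest.raises(ValueError):
            annual_ftc_days([], ("2001-01-02", "2001-01-01"))


class TestDetectorConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            DetectorConfig(freeze_run_min=0)
        with pytest.raises(ValueError):
            DetectorConfig(max_gap_days=-1)
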