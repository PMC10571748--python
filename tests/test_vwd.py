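"""Core virtual-walking-distance computation: collapsing, daily and hourly
sums, the whole-stream driver, and the metric-theoretic properties
(oracle equivalence, subsampling monotonicity, reversal invariance)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pigwalk as pw
from pigwalk.vwd import HOUR_COLUMNS

from conftest import LOCS, brute_force_vwd, make_readings, random_sequence


@pytest.fixture
def meta():
    return pw.CohortMeta({"pen1": pd.Timestamp("2023-01-02").date()})


class TestCollapseRuns:
    def test_consecutive_repeats_merge(self):
        readings = make_readings(
            ["trough", "trough", "trough", "playing_device", "playing_device", "trough"]
        )
        visits = pw.collapse_runs(readings)
        assert list(visits["location_id"]) == ["trough", "playing_device", "trough"]

    def test_empty_input(self):
        visits = pw.collapse_runs(make_readings([]))
        assert visits.empty

    def test_run_keeps_first_and_last_timestamp(self):
        readings = make_readings(["trough", "trough", "drinker1"], step_s=10)
        visits = pw.collapse_runs(readings)
        assert visits.loc[0, "t_first"] == readings["timestamp"].iloc[0]
        assert visits.loc[0, "t_last"] == readings["timestamp"].iloc[1]
        assert visits.loc[1, "t_first"] == visits.loc[1, "t_last"]

    def test_collapsing_never_changes_vwd(self, table2):
        """Collapsing is a pure optimisation: d(x, x) = 0 makes the raw and
        collapsed sums identical, checked on 1,000 random sequences."""
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            seq = random_sequence(rng, int(rng.integers(0, 60)))
            if not seq:
                continue
            readings = make_readings(seq, step_s=30)
            assert pw.daily_vwd(readings, table2).vwd_m == pytest.approx(
                brute_force_vwd(seq, table2), abs=1e-9
            )


class TestDailyVWD:
    def test_trough_play_trough_worked_example(self, table2):
        """The least active day in the reference barn: trough -> playing
        device -> trough, twice 5.2 m = 10.4 m."""
        readings = make_readings(["trough", "playing_device", "trough"], step_s=3600)
        day = pw.daily_vwd(readings, table2)
        assert day.vwd_m == pytest.approx(10.4)
        assert day.n_transitions == 2
        assert day.n_readings == 3

    def test_trough_drinker1_drinker2(self, table2):
        readings = make_readings(["trough", "drinker1", "drinker2"])
        assert pw.daily_vwd(readings, table2).vwd_m == pytest.approx(7.0 + 1.6)

    def test_single_reading_scores_zero(self, table2):
        day = pw.daily_vwd(make_readings(["drinker2"]), table2)
        assert day.vwd_m == 0.0
        assert day.n_transitions == 0

    def test_empty_day_is_missing_not_zero(self, table2):
        with pytest.raises(ValueError, match="missing"):
            pw.daily_vwd(make_readings([]), table2)

    def test_mixed_animal_days_rejected(self, table2):
        a = make_readings(["trough"], animal_id="p1")
        b = make_readings(["trough"], animal_id="p2")
        with pytest.raises(ValueError, match="one animal-day"):
            pw.daily_vwd(pd.concat([a, b]), table2)

    def test_unknown_location_raises(self, table2):
        readings = make_readings(["trough", "mud_bath"])
        with pytest.raises(KeyError, match="mud_bath"):
            pw.daily_vwd(readings, table2)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.sampled_from(LOCS), min_size=1, max_size=40))
    def test_reversal_invariance(self, table2, seq):
        """A symmetric matrix makes VWD direction-blind."""
        fwd = pw.daily_vwd(make_readings(seq), table2).vwd_m
        rev = pw.daily_vwd(make_readings(seq[::-1]), table2).vwd_m
        assert fwd == pytest.approx(rev, abs=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.sampled_from(LOCS), min_size=1, max_size=40))
    def test_zero_iff_single_distinct_location(self, table2, seq):
        day = pw.daily_vwd(make_readings(seq), table2)
        assert day.vwd_m >= 0
        assert (day.vwd_m == 0) == (len(set(seq)) <= 1)

    def test_subsampling_monotonicity(self, table2):
        """Dropping readings can only shorten the path (triangle
        inequality), checked on 200 random sequence/subset pairs."""
        rng = np.random.default_rng(99)
        assert pw.validate_matrix(table2).ok  # precondition
        for _ in range(200):
            seq = random_sequence(rng, int(rng.integers(2, 80)))
            keep = rng.random(len(seq)) < rng.uniform(0.2, 0.9)
            subset = [s for s, k in zip(seq, keep) if k]
            full = brute_force_vwd(seq, table2)
            sub = brute_force_vwd(subset, table2)
            assert sub <= full + 1e-9


class TestHourlyVWD:
    def test_distances_land_in_arrival_hours(self, table2):
        base = pd.Timestamp("2023-01-02")
        readings = pd.DataFrame(
            {
                "timestamp": [
                    base + pd.Timedelta("07:55:00"),
                    base + pd.Timedelta("08:10:00"),
                    base + pd.Timedelta("20:30:00"),
                ],
                "animal_id": "p1",
                "location_id": ["trough", "drinker1", "trough"],
                "pen_id": "pen1",
            }
        )
        h = pw.hourly_vwd(readings, table2)
        assert h.bins[8] == pytest.approx(7.0)
        assert h.bins[20] == pytest.approx(7.0)
        assert h.bins.sum() == pytest.approx(h.bins[8] + h.bins[20])

    def test_no_transitions_gives_24_zeros(self, table2):
        h = pw.hourly_vwd(make_readings(["trough", "trough"]), table2)
        assert np.all(h.bins == 0)

    def test_bins_conserve_daily_total(self, table2):
        rng = np.random.default_rng(5)
        for _ in range(50):
            seq = random_sequence(rng, int(rng.integers(1, 200)))
            readings = make_readings(seq, step_s=240)
            day = pw.daily_vwd(readings, table2)
            h = pw.hourly_vwd(readings, table2)
            assert h.total() == pytest.approx(day.vwd_m, abs=1e-9)


class TestComputeAll:
    def test_row_per_observed_animal_day(self, meta):
        layout = pw.bundled_layout()
        frames = [
            make_readings(["trough", "drinker1"], day=d, animal_id=a)
            for a in ("p1", "p2")
            for d in ("2023-01-02", "2023-01-03", "2023-01-04")
        ]
        readings = pd.concat(frames, ignore_index=True)
        daily, hourly = pw.compute_all(readings, layout, meta)
        assert len(daily) == 6
        assert len(hourly) == 6

    def test_reading_free_day_absent(self, meta):
        layout = pw.bundled_layout()
        readings = pd.concat(
            [
                make_readings(["trough", "drinker1"], day="2023-01-02"),
                make_readings(["trough", "drinker1"], day="2023-01-04"),
            ],
            ignore_index=True,
        )
        daily, _ = pw.compute_all(readings, layout, meta)
        assert list(daily["fattening_day"]) == [1, 3]  # day 2 missing, not zero

    def test_fattening_day_counts_from_move_in(self, meta):
        layout = pw.bundled_layout()
        readings = make_readings(["trough"], day="2023-01-31")
        daily, _ = pw.compute_all(readings, layout, meta)
        assert daily.loc[0, "fattening_day"] == 30

    def test_pen_without_start_date_errors(self):
        layout = pw.bundled_layout()
        readings = make_readings(["trough"], pen_id="pen9")
        with pytest.raises(KeyError, match="pen9"):
            pw.compute_all(readings, layout, pw.CohortMeta({}))

    def test_empty_stream_gives_empty_tables(self, meta):
        layout = pw.bundled_layout()
        daily, hourly = pw.compute_all(make_readings([]), layout, meta)
        assert daily.empty and hourly.empty

    def test_matches_per_day_computation(self, table2, meta):
        """The vectorized whole-stream driver must agree with the scalar
        per-animal-day functions on every row."""
        rng = np.random.default_rng(77)
        frames = []
        for a in ("p1", "p2", "p3"):
            for d in ("2023-01-02", "2023-01-03"):
                seq = random_sequence(rng, int(rng.integers(1, 120)))
                frames.append(make_readings(seq, day=d, animal_id=a, step_s=120))
        readings = pd.concat(frames, ignore_index=True)
        layout = pw.bundled_layout()
        daily, hourly = pw.compute_all(readings, layout, meta)
        for (a, d), grp in readings.groupby(
            ["animal_id", readings["timestamp"].dt.normalize()]
        ):
            row = daily[(daily["animal_id"] == a) & (daily["date"] == d)].iloc[0]
            ref = pw.daily_vwd(grp.reset_index(drop=True), table2)
            assert row["vwd_m"] == pytest.approx(ref.vwd_m, abs=1e-12)
            assert row["n_transitions"] == ref.n_transitions
            assert row["n_readings"] == ref.n_readings
            href = pw.hourly_vwd(grp.reset_index(drop=True), table2)
            hrow = hourly[(hourly["animal_id"] == a) & (hourly["date"] == d)]
            np.testing.assert_allclose(
                hrow[HOUR_COLUMNS].to_numpy()[0], href.bins, atol=1e-12
            )

    def test_deterministic_row_order(self, meta):
        layout = pw.bundled_layout()
        readings = pd.concat(
            [
                make_readings(["trough", "drinker1"], animal_id=a, day=d)
                for a in ("p2", "p1")
                for d in ("2023-01-03", "2023-01-02")
            ],
            ignore_index=True,
        )
        daily1, _ = pw.compute_all(readings, layout, meta)
        daily2, _ = pw.compute_all(readings.sample(frac=1, random_state=0), layout, meta)
        pd.testing.assert_frame_equal(daily1, daily2)
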