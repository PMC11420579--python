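"""Unit-day metric suite: rates, flood episodes, concurrency, pauses."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alarmkit.events import AlarmColor, ChangeKind, Device, PauseEvent, SettingsChangeEvent
from alarmkit.metrics import (
    alarms_per_bed_day,
    concurrent_alarm_duration,
    concurrent_seconds,
    detect_flood_conditions,
    flood_episode_count,
    pause_metrics,
    settings_change_rates,
)

from .conftest import (
    DAY0,
    concurrency_oracle,
    flood_oracle,
    make_alarm,
    make_occupancy,
)


# ---------------------------------------------------------------------------
# alarms per bed per day
# ---------------------------------------------------------------------------

def test_ten_alarms_two_beds_is_five_per_bed():
    events = [make_alarm(i * 100) for i in range(10)]
    tab = alarms_per_bed_day(events, [make_occupancy(2)])
    assert tab["value"].tolist() == [5.0]


def test_no_alarms_is_zero_not_missing():
    tab = alarms_per_bed_day([], [make_occupancy(5)])
    assert tab["value"].tolist() == [0.0]


def test_zero_occupancy_day_with_events_is_flagged_and_excluded():
    events = [make_alarm(50)]
    tab = alarms_per_bed_day(events, [make_occupancy(0, capacity=4)])
    assert tab.empty
    assert len(tab.attrs["flagged"]) == 1


def test_events_without_occupancy_coverage_raise():
    with pytest.raises(ValueError, match="occupancy"):
        alarms_per_bed_day([make_alarm(0, unit="u9")], [make_occupancy(2)])


def test_color_decomposition_sums_to_total(rng):
    events = [
        make_alarm(float(s), color=AlarmColor(c))
        for s, c in zip(
            rng.uniform(0, 86400, 120),
            rng.choice(["RED", "YELLOW", "TECHNICAL"], 120),
        )
    ]
    occ = [make_occupancy(4)]
    total = alarms_per_bed_day(events, occ)["value"].sum()
    parts = sum(
        alarms_per_bed_day(events, occ, colors=[c])["value"].sum()
        for c in ("RED", "YELLOW", "TECHNICAL")
    )
    assert total == pytest.approx(parts)


def test_per_bed_rate_scales_inversely_with_beds():
    events = [make_alarm(i * 10) for i in range(12)]
    v2 = alarms_per_bed_day(events, [make_occupancy(2)])["value"].iloc[0]
    v4 = alarms_per_bed_day(events, [make_occupancy(4)])["value"].iloc[0]
    assert v2 == 2 * v4


def test_lead_off_exclusion_affects_only_flagged_events():
    import dataclasses

    plain = [make_alarm(i) for i in range(4)]
    flagged = [
        dataclasses.replace(
            make_alarm(100 + i, label="ECG lead off", device=Device.ECG,
                       color=AlarmColor.YELLOW),
            lead_off=True,
        )
        for i in range(2)
    ]
    occ = [make_occupancy(2)]
    with_all = alarms_per_bed_day(plain + flagged, occ)["value"].iloc[0]
    without = alarms_per_bed_day(plain + flagged, occ, include_lead_off=False)["value"].iloc[0]
    assert with_all == 3.0 and without == 2.0


# ---------------------------------------------------------------------------
# flood episodes
# ---------------------------------------------------------------------------

def test_nine_onsets_in_window_is_no_flood():
    assert flood_episode_count(np.arange(9) * 10.0) == 0


def test_exactly_ten_onsets_within_ten_minutes_is_one_episode():
    assert flood_episode_count(np.linspace(0, 600, 10)) == 1


def test_two_separated_bursts_are_two_episodes():
    onsets = np.concatenate([np.arange(10) * 5.0, 4000 + np.arange(10) * 5.0])
    assert flood_episode_count(onsets) == 2


def test_nonpositive_parameters_rejected():
    with pytest.raises(ValueError):
        flood_episode_count([1.0], window_s=0)
    with pytest.raises(ValueError):
        flood_episode_count([1.0], threshold=-1)


def test_flood_counting_is_per_bed_and_normalized():
    # 10-onset burst on each of two beds, 2 occupied beds -> 2 episodes / 2 beds
    events = [make_alarm(i * 30, bed="b1") for i in range(10)]
    events += [make_alarm(40000 + i * 30, bed="b2") for i in range(10)]
    tab = detect_flood_conditions(events, [make_occupancy(2)])
    assert tab["value"].tolist() == [1.0]


def test_technical_alarms_do_not_enter_flood_detection():
    events = [
        make_alarm(i * 30, color=AlarmColor.TECHNICAL, label="SpO2 sensor off")
        for i in range(20)
    ]
    tab = detect_flood_conditions(events, [make_occupancy(2)])
    assert tab["value"].tolist() == [0.0]


@given(st.lists(st.floats(min_value=0, max_value=86400), min_size=0, max_size=80))
@settings(max_examples=150, deadline=None)
def test_flood_detector_matches_all_pairs_oracle(onsets):
    assert flood_episode_count(onsets) == flood_oracle(onsets)


# ---------------------------------------------------------------------------
# concurrent alarm duration
# ---------------------------------------------------------------------------

def test_three_simultaneous_alarms_one_second_counts_two():
    assert concurrent_seconds([(100, 1), (100, 1), (100, 1)]) == 2


def test_two_alarms_overlapping_five_seconds_counts_five():
    assert concurrent_seconds([(0, 10), (5, 10)]) == 5


def test_zero_duration_alarm_occupies_no_second():
    assert concurrent_seconds([(100, 0), (100, 5)]) == 0


def test_no_overlap_is_zero():
    assert concurrent_seconds([(0, 10), (20, 10), (40, 5)]) == 0


def test_duration_above_cutoff_excluded_before_accumulation():
    events = [make_alarm(0, duration=1801), make_alarm(0, duration=1801)]
    tab = concurrent_alarm_duration(events, [make_occupancy(1)])
    assert tab["value"].tolist() == [0.0]
    # at exactly the cutoff the alarm is retained
    events = [make_alarm(0, duration=1800), make_alarm(0, duration=1800)]
    tab = concurrent_alarm_duration(events, [make_occupancy(1)])
    assert tab["value"].tolist() == [1800.0]


def test_concurrency_additive_under_disjoint_time_partition(rng):
    morning = [(float(s), float(d)) for s, d in
               zip(rng.uniform(0, 30000, 40), rng.uniform(1, 300, 40))]
    evening = [(float(s), float(d)) for s, d in
               zip(rng.uniform(50000, 80000, 40), rng.uniform(1, 300, 40))]
    assert (
        concurrent_seconds(morning + evening)
        == concurrent_seconds(morning) + concurrent_seconds(evening)
    )


@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=2000),
            st.floats(min_value=0, max_value=120),
        ),
        min_size=0,
        max_size=40,
    )
)
@settings(max_examples=150, deadline=None)
def test_concurrency_matches_per_second_sweep_oracle(intervals):
    assert concurrent_seconds(intervals) == concurrency_oracle(intervals)


def test_unit_level_concurrency_spans_beds():
    events = [make_alarm(0, duration=10, bed="b1"), make_alarm(0, duration=10, bed="b2")]
    unit_level = concurrent_alarm_duration(events, [make_occupancy(2)])
    per_bed = concurrent_alarm_duration(events, [make_occupancy(2)], per_bed=True)
    assert unit_level["value"].iloc[0] == 5.0  # 10 concurrent s / 2 beds
    assert per_bed["value"].iloc[0] == 0.0


# ---------------------------------------------------------------------------
# pauses and settings changes
# ---------------------------------------------------------------------------

def make_pause(sec: float, duration: float = 120.0, bed: str = "b1") -> PauseEvent:
    return PauseEvent("u1", bed, DAY0 + dt.timedelta(seconds=sec), duration)


def test_pause_rate_per_bed_day():
    pauses = [make_pause(i * 600) for i in range(24)]
    pm = pause_metrics(pauses, [], [make_occupancy(2)])
    assert pm.pauses_per_bed_day["value"].tolist() == [12.0]


def test_proper_pause_ratio_counts_suppressing_pauses():
    # 100 pauses; alarms onset only inside the first 8 pause windows
    pauses = [make_pause(i * 600) for i in range(100)]
    alarms = [make_alarm(i * 600 + 30) for i in range(8)]
    pm = pause_metrics(pauses, alarms, [make_occupancy(2)])
    assert pm.proper_pause_ratio["u1"] == pytest.approx(0.08)


def test_no_pauses_means_ratio_undefined_not_zero():
    pm = pause_metrics([], [make_alarm(0)], [make_occupancy(2)])
    assert pm.proper_pause_ratio["u1"] is None


def test_settings_change_rates_by_kind():
    changes = [
        SettingsChangeEvent("u1", "b1", DAY0 + dt.timedelta(seconds=i),
                            ChangeKind.THRESHOLD_CHANGE)
        for i in range(4)
    ]
    tab = settings_change_rates(changes, [make_occupancy(4)])
    by_kind = tab.set_index("kind")["value"]
    assert by_kind["THRESHOLD_CHANGE"] == 1.0
    assert by_kind["PROFILE_CHANGE"] == 0.0


def test_vectorized_proper_ratio_matches_pluggable_predicate(rng):
    from alarmkit.metrics import default_proper_pause_predicate

    alarms = [make_alarm(float(s), bed=f"b{b}") for s, b in
              zip(rng.uniform(0, 86400, 200), rng.integers(0, 3, 200))]
    pauses = [make_pause(float(s), duration=float(d), bed=f"b{b}") for s, d, b in
              zip(rng.uniform(0, 86400, 60), rng.uniform(30, 300, 60),
                  rng.integers(0, 3, 60))]
    occ = [make_occupancy(3)]
    fast = pause_metrics(pauses, alarms, occ)
    slow = pause_metrics(pauses, alarms, occ, proper=default_proper_pause_predicate)
    assert fast.proper_pause_ratio == slow.proper_pause_ratio
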