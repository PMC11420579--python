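"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from alarmkit.events import AlarmColor, AlarmEvent, Device, OccupancyRecord

DAY0 = dt.datetime(2021, 1, 5)


def make_alarm(
    sec: float,
    duration: float = 10.0,
    unit: str = "u1",
    bed: str = "b1",
    color: AlarmColor = AlarmColor.YELLOW,
    device: Device = Device.SPO2,
    label: str = "SpO2 low",
    day: int = 0,
) -> AlarmEvent:
    return AlarmEvent(
        unit_id=unit,
        bed_id=bed,
        onset=DAY0 + dt.timedelta(days=day, seconds=sec),
        duration=duration,
        device=device,
        color=color,
        label=label,
    )


def make_occupancy(
    occupied: int, unit: str = "u1", day: int = 0, capacity: int | None = None
) -> OccupancyRecord:
    return OccupancyRecord(
        unit_id=unit,
        date=(DAY0 + dt.timedelta(days=day)).date(),
        occupied_beds=occupied,
        capacity=capacity if capacity is not None else max(occupied, 1),
    )


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def flood_oracle(onsets, window_s: int = 600, threshold: int = 10) -> int:
    """O(n^2) all-pairs-window flood oracle: every onset anchors a
    candidate window [t, t+window_s]; qualifying windows (>= threshold
    onsets inside, counted pairwise) are merged by interval union."""
    onsets = sorted(float(t) for t in onsets)
    qualifying = []
    for t in onsets:
        count = sum(1 for s in onsets if t <= s <= t + window_s)
        if count >= threshold:
            qualifying.append((t, t + window_s))
    episodes = 0
    end = None
    for lo, hi in qualifying:
        if end is None or lo > end:
            episodes += 1
        end = hi
    return episodes


def concurrency_oracle(intervals) -> int:
    """Per-second sweep: walk every integer second in range and count
    the alarms covering it; accumulate max(0, active - 1)."""
    if not intervals:
        return 0
    lo = int(np.floor(min(s for s, _ in intervals)))
    hi = int(np.ceil(max(s + d for s, d in intervals)))
    total = 0
    for sec in range(lo, hi + 1):
        active = sum(1 for s, d in intervals if s <= sec < s + d)
        total += max(0, active - 1)
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(20210311)
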