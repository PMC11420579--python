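"""Alarm-situation metrics per unit-day.

All per-bed rates divide a unit-day tally by the beds occupied on that
day; a unit-day with zero occupied beds but recorded events is an
inconsistency — its rate is undefined (not zero) and the row is flagged
and excluded rather than silently dropped.

Seconds are treated as half-open intervals [onset, onset + duration): a
second ``s`` counts as covered by an alarm iff ``onset <= s <
onset + duration``, so an alarm of duration 0 occupies no full second.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import (
    AlarmColor,
    AlarmEvent,
    OccupancyRecord,
    PauseEvent,
    SettingsChangeEvent,
    alarms_to_frame,
    occupancy_lookup,
    occupancy_to_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AUDITORY_COLORS",
    "FLOOD_WINDOW_S",
    "FLOOD_THRESHOLD",
    "CONCURRENCY_CUTOFF_S",
    "alarms_per_bed_day",
    "flood_episode_count",
    "detect_flood_conditions",
    "concurrent_seconds",
    "concurrent_alarm_duration",
    "pause_metrics",
    "settings_change_rates",
    "default_proper_pause_predicate",
]

# Flood and concurrency metrics consider only alarms with an auditory
# modality: the red and yellow classes.
AUDITORY_COLORS = (AlarmColor.RED.value, AlarmColor.YELLOW.value)
FLOOD_WINDOW_S = 600
FLOOD_THRESHOLD = 10
CONCURRENCY_CUTOFF_S = 1800


def _day_starts(onsets: pd.Series) -> pd.Series:
    return onsets.dt.normalize()


def _per_bed_table(
    counts: pd.DataFrame, occupancy, value_col: str = "value"
) -> pd.DataFrame:
    """Join unit-day counts against occupancy and divide by occupied beds.

    ``counts`` has columns unit_id, date, n.  Returns one row per
    occupancy unit-day (count 0 where no events); unit-days with events
    but 0 occupied beds are excluded and recorded in attrs['flagged'].
    """
    occ = occupancy_to_frame(occupancy)
    occ = occ.assign(date=pd.to_datetime(occ["date"]).dt.date)
    merged = occ.merge(counts, on=["unit_id", "date"], how="outer", indicator=True)
    orphan = merged["_merge"] == "right_only"
    if orphan.any():
        raise ValueError(
            "events on unit-days absent from the occupancy table: "
            + ", ".join(
                f"{r.unit_id}/{r.date}" for r in merged[orphan].itertuples()
            )
        )
    merged["n"] = pd.to_numeric(merged["n"], errors="coerce").fillna(0.0)
    flagged = merged[(merged["occupied_beds"] == 0) & (merged["n"] > 0)]
    for r in flagged.itertuples():
        logger.warning(
            "unit-day %s/%s has %d events but 0 occupied beds; excluded",
            r.unit_id, r.date, int(r.n),
        )
    keep = merged["occupied_beds"] > 0
    out = merged[keep].copy()
    out[value_col] = out["n"] / out["occupied_beds"]
    out = out[["unit_id", "date", value_col]].sort_values(
        ["unit_id", "date"], ignore_index=True
    )
    out.attrs["flagged"] = [
        (r.unit_id, r.date, int(r.n)) for r in flagged.itertuples()
    ]
    return out


def alarms_per_bed_day(
    events: Iterable[AlarmEvent] | pd.DataFrame,
    occupancy: Iterable[OccupancyRecord] | pd.DataFrame,
    colors: Sequence[str] | None = None,
    devices: Sequence[str] | None = None,
    include_lead_off: bool = True,
) -> pd.DataFrame:
    """Alarm load in alarms per occupied bed per day.

    ``colors``/``devices`` select a stratum (values of the respective
    enums); by default all colors except BLUE are counted.
    ``include_lead_off=False`` drops flagged ECG-lead-off alarms, which
    the yellow-load contrast requires because the units classified that
    signal inconsistently.
    """
    df = alarms_to_frame(events)
    if colors is None:
        colors = (AlarmColor.RED.value, AlarmColor.YELLOW.value,
                  AlarmColor.TECHNICAL.value)
    sel = df["color"].isin(list(colors))
    if devices is not None:
        sel &= df["device"].isin(list(devices))
    if not include_lead_off:
        sel &= ~df["lead_off"]
    sub = df[sel]
    counts = (
        sub.assign(date=sub["onset"].dt.date)
        .groupby(["unit_id", "date"], as_index=False)
        .size()
        .rename(columns={"size": "n"})
    )
    return _per_bed_table(counts, occupancy)


def flood_episode_count(
    onsets_s: np.ndarray | Sequence[float],
    window_s: int = FLOOD_WINDOW_S,
    threshold: int = FLOOD_THRESHOLD,
) -> int:
    """Count alarm-flood episodes in one onset stream.

    A window [t, t + window_s] qualifies when it contains >= threshold
    onsets; overlapping qualifying windows (anchored at onsets) merge
    into a single episode.  Runs in O(n log n) from the sort.
    """
    if window_s <= 0 or threshold <= 0:
        raise ValueError("window_s and threshold must be positive")
    t = np.sort(np.asarray(onsets_s, dtype=float))
    n = t.size
    if n < threshold:
        return 0
    # onset i anchors a qualifying window iff onset i+threshold-1 falls
    # within window_s of it
    qual = t[threshold - 1:] - t[: n - threshold + 1] <= window_s
    if not qual.any():
        return 0
    anchors = t[: n - threshold + 1][qual]
    # merge overlapping windows [a, a + window_s]
    episodes = 1
    current_end = anchors[0] + window_s
    for a in anchors[1:]:
        if a > current_end:
            episodes += 1
        current_end = a + window_s
    return episodes


def detect_flood_conditions(
    events: Iterable[AlarmEvent] | pd.DataFrame,
    occupancy: Iterable[OccupancyRecord] | pd.DataFrame | None = None,
    window_s: int = FLOOD_WINDOW_S,
    threshold: int = FLOOD_THRESHOLD,
    per_bed: bool = True,
) -> pd.DataFrame:
    """Flood episodes per unit-day, optionally normalized per occupied bed.

    Only red and yellow (auditory) alarms enter the count.  Episodes are
    detected within each bed's daily onset stream (``per_bed=True``,
    matching per-bed-per-day reporting) or within the whole unit's
    stream (``per_bed=False``).  With ``occupancy`` given, the returned
    ``value`` is episodes / occupied beds; otherwise the raw episode
    count per unit-day.
    """
    df = alarms_to_frame(events)
    df = df[df["color"].isin(AUDITORY_COLORS)].copy()
    if df.empty:
        counts = pd.DataFrame(columns=["unit_id", "date", "n"])
    else:
        df["date"] = df["onset"].dt.date
        df["sec"] = (df["onset"] - _day_starts(df["onset"])).dt.total_seconds()
        keys = ["unit_id", "bed_id", "date"] if per_bed else ["unit_id", "date"]
        rows = []
        for key, grp in df.groupby(keys, sort=True):
            n_ep = flood_episode_count(grp["sec"].to_numpy(), window_s, threshold)
            rows.append((key[0], key[-1], n_ep))
        counts = (
            pd.DataFrame(rows, columns=["unit_id", "date", "n"])
            .groupby(["unit_id", "date"], as_index=False)["n"].sum()
        )
    if occupancy is None:
        return counts.rename(columns={"n": "value"})
    return _per_bed_table(counts, occupancy)


def concurrent_seconds(intervals: Sequence[tuple[float, float]]) -> int:
    """Concurrent alarm duration of one interval set, in whole seconds.

    For every integer second ``s``, the contribution is
    ``max(0, active(s) - 1)`` where ``active(s)`` counts intervals with
    ``start <= s < start + duration``.  Two simultaneous alarms thus add
    one concurrent second per second of overlap; three add two.
    Implemented as a change-point sweep over the integer-second grid.
    """
    if not len(intervals):
        return 0
    starts = np.ceil(np.asarray([iv[0] for iv in intervals], dtype=float)).astype(np.int64)
    ends = np.ceil(np.asarray([iv[0] + iv[1] for iv in intervals], dtype=float)).astype(np.int64)
    keep = ends > starts
    starts, ends = starts[keep], ends[keep]
    if starts.size == 0:
        return 0
    pts = np.concatenate([starts, ends])
    deltas = np.concatenate([np.ones_like(starts), -np.ones_like(ends)])
    order = np.argsort(pts, kind="stable")
    pts, deltas = pts[order], deltas[order]
    uniq, idx = np.unique(pts, return_index=True)
    level = np.add.reduceat(deltas, idx).cumsum()
    seg_len = np.diff(uniq)
    excess = np.maximum(level[:-1] - 1, 0)
    return int(np.dot(excess, seg_len))


def concurrent_alarm_duration(
    events: Iterable[AlarmEvent] | pd.DataFrame,
    occupancy: Iterable[OccupancyRecord] | pd.DataFrame | None = None,
    cutoff_s: float = CONCURRENCY_CUTOFF_S,
    per_bed: bool = False,
) -> pd.DataFrame:
    """Concurrent alarm duration (seconds) per unit-day.

    Only red and yellow alarms count; durations exceeding ``cutoff_s``
    are outliers and excluded before accumulation.  By default all
    alarms of a unit share one soundscape (``per_bed=False``); an event
    is attributed to the day of its onset even if it rings past
    midnight.  With ``occupancy``, values are per occupied bed.
    """
    df = alarms_to_frame(events)
    df = df[df["color"].isin(AUDITORY_COLORS) & (df["duration"] <= cutoff_s)].copy()
    if df.empty:
        counts = pd.DataFrame(columns=["unit_id", "date", "n"])
    else:
        df["date"] = df["onset"].dt.date
        df["sec"] = (df["onset"] - _day_starts(df["onset"])).dt.total_seconds()
        keys = ["unit_id", "bed_id", "date"] if per_bed else ["unit_id", "date"]
        rows = []
        for key, grp in df.groupby(keys, sort=True):
            secs = concurrent_seconds(
                list(zip(grp["sec"].to_numpy(), grp["duration"].to_numpy()))
            )
            rows.append((key[0], key[-1], secs))
        counts = (
            pd.DataFrame(rows, columns=["unit_id", "date", "n"])
            .groupby(["unit_id", "date"], as_index=False)["n"].sum()
        )
    if occupancy is None:
        return counts.rename(columns={"n": "value"})
    return _per_bed_table(counts, occupancy)


def default_proper_pause_predicate(
    pause: PauseEvent, alarms: pd.DataFrame
) -> bool:
    """A pause counts as proper when it actually suppressed sound: at
    least one alarm onset on the same bed falls inside the pause window.

    This operationalizes "proper use before manipulation"; the original
    bedside definition is not published, so the predicate is pluggable.
    """
    start = pd.Timestamp(pause.start)
    end = start + pd.Timedelta(seconds=pause.duration)
    sel = alarms[
        (alarms["unit_id"] == pause.unit_id)
        & (alarms["bed_id"] == pause.bed_id)
        & (alarms["onset"] >= start)
        & (alarms["onset"] < end)
    ]
    return len(sel) > 0


@dataclass
class PauseMetrics:
    """Pause-use summary: per-bed-per-day rates and per-unit propriety."""

    pauses_per_bed_day: pd.DataFrame
    # unit_id -> proper pauses / all pauses, None when the unit recorded
    # no pauses (undefined, not zero)
    proper_pause_ratio: dict[str, float | None]


def pause_metrics(
    pauses: Sequence[PauseEvent],
    events: Iterable[AlarmEvent] | pd.DataFrame,
    occupancy: Iterable[OccupancyRecord] | pd.DataFrame,
    proper: Callable[[PauseEvent, pd.DataFrame], bool] | None = None,
) -> PauseMetrics:
    """Alarm-pause usage per bed per day and the proper pause-to-pause
    ratio per unit over the whole period."""
    use_fast_default = proper is None
    proper = proper or default_proper_pause_predicate
    alarms = alarms_to_frame(events)
    counts = (
        pd.DataFrame(
            [(p.unit_id, p.start.date()) for p in pauses],
            columns=["unit_id", "date"],
        )
        .groupby(["unit_id", "date"], as_index=False)
        .size()
        .rename(columns={"size": "n"})
        if pauses
        else pd.DataFrame(columns=["unit_id", "date", "n"])
    )
    rate = _per_bed_table(counts, occupancy)

    units = occupancy_to_frame(occupancy)["unit_id"].astype(str).unique()
    totals: dict[str, int] = {u: 0 for u in units}
    propers: dict[str, int] = {u: 0 for u in units}
    if use_fast_default:
        # vectorized form of default_proper_pause_predicate: binary
        # search per pause in the bed's sorted onset vector
        onsets_by_bed = {
            key: np.sort(grp["onset"].to_numpy().astype("datetime64[ns]").astype(np.int64))
            for key, grp in alarms.groupby(["unit_id", "bed_id"], sort=False)
        }
        for p in pauses:
            totals.setdefault(p.unit_id, 0)
            propers.setdefault(p.unit_id, 0)
            totals[p.unit_id] += 1
            vec = onsets_by_bed.get((p.unit_id, p.bed_id))
            if vec is None:
                continue
            lo = np.datetime64(p.start, "ns").astype(np.int64)
            hi = lo + int(p.duration * 1e9)
            if np.searchsorted(vec, hi, "left") > np.searchsorted(vec, lo, "left"):
                propers[p.unit_id] += 1
    else:
        for p in pauses:
            totals.setdefault(p.unit_id, 0)
            propers.setdefault(p.unit_id, 0)
            totals[p.unit_id] += 1
            if proper(p, alarms):
                propers[p.unit_id] += 1
    ratio = {
        u: (propers[u] / totals[u]) if totals[u] > 0 else None for u in totals
    }
    return PauseMetrics(pauses_per_bed_day=rate, proper_pause_ratio=ratio)


def settings_change_rates(
    changes: Sequence[SettingsChangeEvent],
    occupancy: Iterable[OccupancyRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Threshold-change and profile-change rates per bed per day.

    Returns columns unit_id, date, kind, value with one row per
    occupancy unit-day per change kind (0.0 where none occurred).
    """
    from .events import ChangeKind

    frames = []
    for kind in ChangeKind:
        sub = [c for c in changes if c.kind is kind]
        counts = (
            pd.DataFrame(
                [(c.unit_id, c.timestamp.date()) for c in sub],
                columns=["unit_id", "date"],
            )
            .groupby(["unit_id", "date"], as_index=False)
            .size()
            .rename(columns={"size": "n"})
            if sub
            else pd.DataFrame(columns=["unit_id", "date", "n"])
        )
        tab = _per_bed_table(counts, occupancy)
        tab.insert(2, "kind", kind.value)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
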