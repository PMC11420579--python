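"""Normalized event model for patient-monitor alarm logs.

All timestamps are timezone-naive local time at second resolution; a
calendar day runs from local midnight to local midnight, and an event
that straddles midnight is attributed to the day of its onset.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Device",
    "AlarmColor",
    "ChangeKind",
    "AlarmEvent",
    "PauseEvent",
    "SettingsChangeEvent",
    "OccupancyRecord",
    "alarms_to_frame",
    "frame_to_alarms",
    "occupancy_to_frame",
    "occupancy_lookup",
]


class Device(str, Enum):
    """Medical device that issued an alarm signal."""

    ECG = "ECG"
    IBP = "IBP"
    NIBP = "NIBP"
    SPO2 = "SPO2"
    TEMPERATURE = "TEMPERATURE"
    OTHER = "OTHER"


class AlarmColor(str, Enum):
    """Alarm severity class.

    RED flags a potentially life-threatening event, YELLOW a vital sign
    beyond its set threshold, TECHNICAL a device/sensor condition.  BLUE
    exists on some monitor configurations (advisory signals); it is kept
    in the model but excluded from load contrasts by default.
    """

    RED = "RED"
    YELLOW = "YELLOW"
    TECHNICAL = "TECHNICAL"
    BLUE = "BLUE"


class ChangeKind(str, Enum):
    THRESHOLD_CHANGE = "THRESHOLD_CHANGE"
    PROFILE_CHANGE = "PROFILE_CHANGE"


@dataclass(frozen=True)
class AlarmEvent:
    """One alarm occurrence.

    ``duration`` is in seconds and must be non-negative.  ``lead_off``
    marks ECG-lead-off signals, which some units classify inconsistently
    and which must be excludable from yellow-load contrasts while still
    counting toward technical tallies.
    """

    unit_id: str
    bed_id: str
    onset: dt.datetime
    duration: float
    device: Device = Device.OTHER
    color: AlarmColor = AlarmColor.YELLOW
    label: str = ""
    lead_off: bool = False

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError(f"alarm duration must be >= 0, got {self.duration}")

    def with_mapping(self, device: Device, color: AlarmColor) -> "AlarmEvent":
        return replace(self, device=device, color=color)


@dataclass(frozen=True)
class PauseEvent:
    """Operator activation of the monitor's alarm-pause function."""

    unit_id: str
    bed_id: str
    start: dt.datetime
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"pause duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class SettingsChangeEvent:
    """An alarm-threshold or monitoring-profile change at the bedside."""

    unit_id: str
    bed_id: str
    timestamp: dt.datetime
    kind: ChangeKind


@dataclass(frozen=True)
class OccupancyRecord:
    """Occupied beds on one unit for one calendar day."""

    unit_id: str
    date: dt.date
    occupied_beds: int
    capacity: int

    def __post_init__(self) -> None:
        if not 0 <= self.occupied_beds <= self.capacity:
            raise ValueError(
                f"need 0 <= occupied_beds <= capacity, got "
                f"{self.occupied_beds}/{self.capacity}"
            )


_ALARM_COLUMNS = [
    "unit_id",
    "bed_id",
    "onset",
    "duration",
    "device",
    "color",
    "label",
    "lead_off",
]


def alarms_to_frame(events: Iterable[AlarmEvent] | pd.DataFrame) -> pd.DataFrame:
    """Canonical tabular form of an alarm stream (one row per alarm)."""
    if isinstance(events, pd.DataFrame):
        df = events.copy()
        for col in _ALARM_COLUMNS:
            if col not in df.columns:
                if col == "lead_off":
                    df[col] = False
                elif col == "label":
                    df[col] = ""
                else:
                    raise KeyError(f"alarm frame missing column {col!r}")
        return df[_ALARM_COLUMNS]
    rows = [
        (e.unit_id, e.bed_id, e.onset, e.duration, e.device.value, e.color.value,
         e.label, e.lead_off)
        for e in events
    ]
    df = pd.DataFrame(rows, columns=_ALARM_COLUMNS)
    if not df.empty:
        df["onset"] = pd.to_datetime(df["onset"])
    else:
        df = df.astype({"onset": "datetime64[ns]", "duration": float,
                        "lead_off": bool})
    return df


def frame_to_alarms(df: pd.DataFrame) -> list[AlarmEvent]:
    return [
        AlarmEvent(
            unit_id=str(r.unit_id),
            bed_id=str(r.bed_id),
            onset=pd.Timestamp(r.onset).to_pydatetime(),
            duration=float(r.duration),
            device=Device(r.device),
            color=AlarmColor(r.color),
            label=str(r.label),
            lead_off=bool(getattr(r, "lead_off", False)),
        )
        for r in df.itertuples(index=False)
    ]


def occupancy_to_frame(
    occupancy: Iterable[OccupancyRecord] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(occupancy, pd.DataFrame):
        return occupancy[["unit_id", "date", "occupied_beds", "capacity"]].copy()
    rows = [(o.unit_id, o.date, o.occupied_beds, o.capacity) for o in occupancy]
    return pd.DataFrame(rows, columns=["unit_id", "date", "occupied_beds", "capacity"])


def occupancy_lookup(
    occupancy: Iterable[OccupancyRecord] | pd.DataFrame,
) -> dict[tuple[str, dt.date], int]:
    """Map (unit_id, date) -> occupied beds."""
    df = occupancy_to_frame(occupancy)
    out: dict[tuple[str, dt.date], int] = {}
    for r in df.itertuples(index=False):
        date = r.date
        if isinstance(date, (pd.Timestamp, dt.datetime)):
            date = pd.Timestamp(date).date()
        out[(str(r.unit_id), date)] = int(r.occupied_beds)
    return out
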