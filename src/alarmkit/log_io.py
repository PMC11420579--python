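"""Readers, writers, and harmonization for alarm-log exports.

Two dialects are supported for the same event model: delimited text
(CSV, as produced by the general-ICU monitor exports) and XML (as
produced by the isolation-unit exports).  Both carry one record per
event; the CSV column set and the XML attribute set mirror each other,
so a stream written in either dialect reads back identically.

CSV columns (header row, UTF-8, comma-delimited by default):

    event_type, unit_id, bed_id, onset, duration_s, label, color, device

``event_type`` is one of ``alarm``, ``pause``, ``threshold_change``,
``profile_change``; ``onset`` is ISO-8601 at second resolution;
``duration_s`` is empty for settings changes.  The XML dialect is a flat
``<alarmlog>`` root with one ``<event>`` element per record whose
attributes mirror the CSV columns.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from lxml import etree

from .events import (
    AlarmColor,
    AlarmEvent,
    ChangeKind,
    Device,
    OccupancyRecord,
    PauseEvent,
    SettingsChangeEvent,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CsvDialect",
    "ParseResult",
    "RowError",
    "FilterResult",
    "DEFAULT_LABEL_MAP",
    "VENTILATION_LABELS",
    "LEAD_OFF_LABEL",
    "read_alarm_log_csv",
    "read_alarm_log_xml",
    "write_alarm_log_csv",
    "write_alarm_log_xml",
    "read_occupancy_csv",
    "write_occupancy_csv",
    "harmonize_and_filter",
]

_CANONICAL_COLUMNS = (
    "event_type", "unit_id", "bed_id", "onset", "duration_s", "label",
    "color", "device",
)

_EVENT_TYPES = {"alarm", "pause", "threshold_change", "profile_change"}


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping for a delimited alarm-log export.

    ``columns`` maps canonical role names to the column names actually
    present in the file; identity by default.  ``timestamp_format`` is a
    strptime pattern, or None for ISO-8601.
    """

    delimiter: str = ","
    timestamp_format: str | None = None
    columns: Mapping[str, str] = field(default_factory=dict)

    def actual(self, canonical: str) -> str:
        return dict(self.columns).get(canonical, canonical)


@dataclass(frozen=True)
class RowError:
    """A rejected input row with its position and reason."""

    row: int
    reason: str


@dataclass
class ParseResult:
    """Outcome of parsing one log file.

    Conservation holds by construction: data rows in = alarms + pauses +
    changes + rejected.
    """

    alarms: list[AlarmEvent] = field(default_factory=list)
    pauses: list[PauseEvent] = field(default_factory=list)
    changes: list[SettingsChangeEvent] = field(default_factory=list)
    rejected: list[RowError] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.alarms) + len(self.pauses) + len(self.changes)


# Signals named in the shipped default mapping.  Real exports carry
# vendor-specific labels; users supply their own table for those.
LEAD_OFF_LABEL = "ECG lead off"

DEFAULT_LABEL_MAP: dict[str, tuple[Device, AlarmColor]] = {
    "ECG asystole": (Device.ECG, AlarmColor.RED),
    "ECG vfib/vtach": (Device.ECG, AlarmColor.RED),
    "ECG HR high": (Device.ECG, AlarmColor.YELLOW),
    "ECG HR low": (Device.ECG, AlarmColor.YELLOW),
    LEAD_OFF_LABEL: (Device.ECG, AlarmColor.TECHNICAL),
    "SpO2 desaturation": (Device.SPO2, AlarmColor.RED),
    "SpO2 low": (Device.SPO2, AlarmColor.YELLOW),
    "SpO2 high": (Device.SPO2, AlarmColor.YELLOW),
    "SpO2 sensor off": (Device.SPO2, AlarmColor.TECHNICAL),
    "IBP extreme": (Device.IBP, AlarmColor.RED),
    "IBP high": (Device.IBP, AlarmColor.YELLOW),
    "IBP low": (Device.IBP, AlarmColor.YELLOW),
    "NIBP high": (Device.NIBP, AlarmColor.YELLOW),
    "NIBP low": (Device.NIBP, AlarmColor.YELLOW),
    "Temperature high": (Device.TEMPERATURE, AlarmColor.YELLOW),
    "Temperature low": (Device.TEMPERATURE, AlarmColor.YELLOW),
}

# Ventilator alarms arrive through the same network but are unreliable
# in the log export, so they are dropped wholesale during harmonization.
VENTILATION_LABELS = frozenset({
    "Vent apnea", "Vent disconnect", "Vent high pressure", "Vent low pressure",
})


def _parse_timestamp(raw: str, fmt: str | None) -> dt.datetime:
    if fmt is not None:
        return dt.datetime.strptime(raw, fmt)
    return dt.datetime.fromisoformat(raw)


def _row_to_event(
    idx: int,
    rec: Mapping[str, object],
    dialect: CsvDialect,
    result: ParseResult,
) -> None:
    """Validate one raw record and append it to the right bucket."""

    def get(canonical: str) -> str:
        val = rec.get(dialect.actual(canonical), "")
        if val is None or (isinstance(val, float) and pd.isna(val)):
            return ""
        return str(val).strip()

    etype = get("event_type").lower()
    if etype not in _EVENT_TYPES:
        result.rejected.append(RowError(idx, f"unknown event_type {etype!r}"))
        return
    unit_id, bed_id = get("unit_id"), get("bed_id")
    if not unit_id or not bed_id:
        result.rejected.append(RowError(idx, "missing unit_id or bed_id"))
        return
    try:
        onset = _parse_timestamp(get("onset"), dialect.timestamp_format)
    except ValueError:
        result.rejected.append(RowError(idx, f"malformed timestamp {get('onset')!r}"))
        return

    if etype in ("threshold_change", "profile_change"):
        kind = (ChangeKind.THRESHOLD_CHANGE if etype == "threshold_change"
                else ChangeKind.PROFILE_CHANGE)
        result.changes.append(SettingsChangeEvent(unit_id, bed_id, onset, kind))
        return

    raw_dur = get("duration_s")
    try:
        duration = float(raw_dur)
    except ValueError:
        result.rejected.append(RowError(idx, f"malformed duration {raw_dur!r}"))
        return

    if etype == "pause":
        if duration <= 0:
            result.rejected.append(RowError(idx, f"non-positive pause duration {duration}"))
            return
        result.pauses.append(PauseEvent(unit_id, bed_id, onset, duration))
        return

    if duration < 0:
        result.rejected.append(RowError(idx, f"negative alarm duration {duration}"))
        return
    color_raw, device_raw = get("color").upper(), get("device").upper()
    try:
        color = AlarmColor(color_raw) if color_raw else AlarmColor.YELLOW
    except ValueError:
        result.rejected.append(RowError(idx, f"unknown color {color_raw!r}"))
        return
    try:
        device = Device(device_raw) if device_raw else Device.OTHER
    except ValueError:
        result.rejected.append(RowError(idx, f"unknown device {device_raw!r}"))
        return
    result.alarms.append(
        AlarmEvent(unit_id, bed_id, onset, duration, device, color, get("label"))
    )


def read_alarm_log_csv(
    path: str | Path, dialect: CsvDialect | None = None
) -> ParseResult:
    """Parse a delimited alarm-log export.

    Rows whose mandatory fields fail validation are rejected with
    row-indexed diagnostics rather than aborting the parse; event counts
    are conserved (rows in = events out + rejected rows).

    Raises FileNotFoundError for a missing file and KeyError naming the
    first missing mandatory column.
    """
    dialect = dialect or CsvDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    for canonical in _CANONICAL_COLUMNS:
        if dialect.actual(canonical) not in df.columns:
            raise KeyError(f"missing mandatory column {dialect.actual(canonical)!r}")
    result = ParseResult()
    for idx, rec in enumerate(df.to_dict(orient="records")):
        _row_to_event(idx, rec, dialect, result)
    for err in result.rejected:
        logger.warning("rejected row %d of %s: %s", err.row, path.name, err.reason)
    return result


def read_alarm_log_xml(path: str | Path) -> ParseResult:
    """Parse an XML alarm-log export; output matches the CSV reader for
    equivalent content.

    Malformed XML raises ``lxml.etree.XMLSyntaxError`` (with position);
    elements other than ``<event>`` are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tree = etree.parse(str(path))
    dialect = CsvDialect()
    result = ParseResult()
    idx = 0
    for elem in tree.getroot():
        if elem.tag != "event":
            logger.warning("skipping unknown element <%s> in %s", elem.tag, path.name)
            continue
        _row_to_event(idx, dict(elem.attrib), dialect, result)
        idx += 1
    for err in result.rejected:
        logger.warning("rejected event %d of %s: %s", err.row, path.name, err.reason)
    return result


def _event_records(
    alarms: Iterable[AlarmEvent],
    pauses: Iterable[PauseEvent] = (),
    changes: Iterable[SettingsChangeEvent] = (),
) -> list[dict[str, str]]:
    recs: list[dict[str, str]] = []
    for a in alarms:
        recs.append({
            "event_type": "alarm", "unit_id": a.unit_id, "bed_id": a.bed_id,
            "onset": a.onset.isoformat(sep=" "), "duration_s": repr(a.duration),
            "label": a.label, "color": a.color.value, "device": a.device.value,
        })
    for p in pauses:
        recs.append({
            "event_type": "pause", "unit_id": p.unit_id, "bed_id": p.bed_id,
            "onset": p.start.isoformat(sep=" "), "duration_s": repr(p.duration),
            "label": "", "color": "", "device": "",
        })
    for c in changes:
        recs.append({
            "event_type": c.kind.value.lower(),
            "unit_id": c.unit_id, "bed_id": c.bed_id,
            "onset": c.timestamp.isoformat(sep=" "), "duration_s": "",
            "label": "", "color": "", "device": "",
        })
    return recs


def write_alarm_log_csv(
    path: str | Path,
    alarms: Iterable[AlarmEvent],
    pauses: Iterable[PauseEvent] = (),
    changes: Iterable[SettingsChangeEvent] = (),
) -> None:
    recs = _event_records(alarms, pauses, changes)
    df = pd.DataFrame(recs, columns=list(_CANONICAL_COLUMNS))
    df["event_type"] = df["event_type"].str.lower()
    df.to_csv(path, index=False)


def write_alarm_log_xml(
    path: str | Path,
    alarms: Iterable[AlarmEvent],
    pauses: Iterable[PauseEvent] = (),
    changes: Iterable[SettingsChangeEvent] = (),
) -> None:
    root = etree.Element("alarmlog")
    for rec in _event_records(alarms, pauses, changes):
        rec = {k: v for k, v in rec.items()}
        rec["event_type"] = rec["event_type"].lower()
        etree.SubElement(root, "event", attrib=rec)
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def read_occupancy_csv(path: str | Path) -> list[OccupancyRecord]:
    """Read a bed-occupancy table: unit_id, date, occupied_beds, capacity."""
    df = pd.read_csv(path)
    return [
        OccupancyRecord(
            unit_id=str(r.unit_id),
            date=dt.date.fromisoformat(str(r.date)),
            occupied_beds=int(r.occupied_beds),
            capacity=int(r.capacity),
        )
        for r in df.itertuples(index=False)
    ]


def write_occupancy_csv(path: str | Path, occupancy: Iterable[OccupancyRecord]) -> None:
    df = pd.DataFrame(
        [(o.unit_id, o.date.isoformat(), o.occupied_beds, o.capacity)
         for o in occupancy],
        columns=["unit_id", "date", "occupied_beds", "capacity"],
    )
    df.to_csv(path, index=False)


@dataclass
class FilterResult:
    """Harmonized alarms plus a per-rule removal tally.

    Conservation: len(input) == len(retained) + sum(removed.values()).
    """

    retained: list[AlarmEvent]
    removed: dict[str, int]


def harmonize_and_filter(
    events: Sequence[AlarmEvent],
    mapping: Mapping[str, tuple[Device, AlarmColor]] | None = None,
    window: tuple[dt.date, dt.date] | None = None,
    ventilation_labels: frozenset[str] | set[str] = VENTILATION_LABELS,
    lead_off_label: str = LEAD_OFF_LABEL,
) -> FilterResult:
    """Harmonize device/color from the label table and apply exclusions.

    Ventilation-device alarms are removed (unreliable in the export);
    events outside ``window`` (inclusive date range) are removed;
    ECG-lead-off events are flagged ``lead_off=True`` but retained, so
    yellow-load contrasts can drop them while technical tallies keep
    them.  Labels absent from the mapping keep their parsed device/color
    if set, else fall back to OTHER with a logged warning.

    The operation is idempotent: applying it twice equals applying once.
    """
    if mapping is None:
        mapping = DEFAULT_LABEL_MAP
    if not mapping:
        raise ValueError("label mapping must not be empty")
    retained: list[AlarmEvent] = []
    removed = {"ventilation": 0, "window": 0}
    for e in events:
        if e.label in ventilation_labels:
            removed["ventilation"] += 1
            continue
        if window is not None and not (window[0] <= e.onset.date() <= window[1]):
            removed["window"] += 1
            continue
        if e.label in mapping:
            device, color = mapping[e.label]
            e = e.with_mapping(device, color)
        elif e.label and e.device is Device.OTHER:
            logger.warning("unmapped alarm label %r -> OTHER", e.label)
        if e.label == lead_off_label and not e.lead_off:
            e = replace(e, lead_off=True)
        retained.append(e)
    return FilterResult(retained=retained, removed=removed)
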