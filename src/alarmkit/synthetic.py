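"""Seeded generator for alarm logs, occupancy, and questionnaire tables.

The generator emulates the statistical structure the analysis assumes:

* daily per-bed alarm loads are gamma distributed per color (right
  skewed), converted to integer event counts via the beds occupied;
* alarm durations are exponential (right skewed), truncated at a
  configurable maximum so the outlier cutoff is exercised;
* onsets are uniform within the day, except for a clustering knob that
  reallocates part of the yellow-alarm pool into short bursts so that
  alarm-flood episodes occur at a configurable rate;
* bed occupancy follows a bounded random walk around a unit-specific
  mean fraction;
* questionnaire respondents draw a latent fatigue percentage from a
  normal per role group, which is decomposed into 9 Likert items
  (binomial thinning) whose sum recovers the latent score in
  expectation.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import (
    AlarmColor,
    ChangeKind,
    Device,
    OccupancyRecord,
    PauseEvent,
    SettingsChangeEvent,
)
from .log_io import LEAD_OFF_LABEL
from .questionnaire import (
    DEFAULT_REVERSE_ITEMS,
    N_ITEMS,
    QuestionnaireResponse,
    Role,
    UnitType,
)

__all__ = [
    "GammaLoad",
    "UnitConfig",
    "RespondentGroup",
    "ScenarioConfig",
    "ScenarioData",
    "sample_daily_loads",
    "generate_scenario",
    "study_presets",
    "write_scenario",
]

SECONDS_PER_DAY = 86_400
STUDY_DAYS = 113
STUDY_START = dt.date(2020, 11, 19)

_LABELS = {
    (Device.ECG, AlarmColor.RED): "ECG vfib/vtach",
    (Device.ECG, AlarmColor.YELLOW): "ECG HR high",
    (Device.ECG, AlarmColor.TECHNICAL): LEAD_OFF_LABEL,
    (Device.SPO2, AlarmColor.RED): "SpO2 desaturation",
    (Device.SPO2, AlarmColor.YELLOW): "SpO2 low",
    (Device.SPO2, AlarmColor.TECHNICAL): "SpO2 sensor off",
    (Device.IBP, AlarmColor.RED): "IBP extreme",
    (Device.IBP, AlarmColor.YELLOW): "IBP high",
    (Device.NIBP, AlarmColor.YELLOW): "NIBP high",
    (Device.TEMPERATURE, AlarmColor.YELLOW): "Temperature high",
}


@dataclass(frozen=True)
class GammaLoad:
    """Gamma-distributed daily per-bed load, parameterized by moments."""

    mean: float
    sd: float

    @property
    def shape(self) -> float:
        return (self.mean / self.sd) ** 2

    @property
    def scale(self) -> float:
        return self.sd**2 / self.mean


@dataclass
class UnitConfig:
    unit_id: str
    unit_type: UnitType
    capacity: int
    occupancy_frac: float
    loads: dict[AlarmColor, GammaLoad]
    device_mix: dict[AlarmColor, dict[Device, float]]
    duration_mean_s: dict[AlarmColor, float]
    duration_max_s: float = 7200.0
    occupancy_jitter: float = 0.03
    pause_rate: float = 8.0  # pauses per occupied bed per day
    proper_pause_prob: float = 0.05
    threshold_change_rate: float = 1.0
    profile_change_rate: float = 0.2
    # clustering knob: bursts per occupied bed per day, each burst packs
    # burst_size yellow onsets into burst_window_s on one bed (events
    # reallocated from the daily pool, not added, so configured loads
    # are preserved)
    burst_rate: float = 0.0
    burst_size: int = 12
    burst_window_s: float = 300.0

    def validate(self) -> list[str]:
        problems = []
        if self.capacity <= 0:
            problems.append(f"{self.unit_id}: capacity must be > 0")
        if not 0 < self.occupancy_frac <= 1:
            problems.append(f"{self.unit_id}: occupancy_frac must be in (0, 1]")
        for color, mix in self.device_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                problems.append(
                    f"{self.unit_id}: device mix for {color.value} sums to {total}"
                )
        for name in ("pause_rate", "threshold_change_rate",
                     "profile_change_rate", "burst_rate"):
            if getattr(self, name) < 0:
                problems.append(f"{self.unit_id}: {name} must be >= 0")
        return problems


@dataclass(frozen=True)
class RespondentGroup:
    """One homogeneous block of questionnaire respondents."""

    unit_id: str
    unit_type: UnitType
    role: Role
    n: int
    mean_pct: float  # target mean fatigue percentage
    sd_pct: float


@dataclass
class ScenarioConfig:
    units: list[UnitConfig]
    days: int = STUDY_DAYS
    start: dt.date = STUDY_START
    respondents: list[RespondentGroup] = field(default_factory=list)
    missing_rate: float = 0.05
    reverse_items: frozenset[int] = DEFAULT_REVERSE_ITEMS

    def validate(self) -> None:
        problems = []
        if self.days <= 0:
            problems.append("days must be > 0")
        if not self.units:
            problems.append("at least one unit is required")
        for u in self.units:
            problems.extend(u.validate())
        if not 0 <= self.missing_rate < 1:
            problems.append("missing_rate must be in [0, 1)")
        if problems:
            raise ValueError("invalid scenario config: " + "; ".join(problems))


@dataclass
class ScenarioData:
    """In-memory result of one generated scenario."""

    alarms: pd.DataFrame  # canonical alarm columns (see events module)
    pauses: list[PauseEvent]
    changes: list[SettingsChangeEvent]
    occupancy: list[OccupancyRecord]
    responses: list[QuestionnaireResponse]


def sample_daily_loads(
    load: GammaLoad, days: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-bed daily loads from the configured gamma distribution."""
    return rng.gamma(load.shape, load.scale, size=days)


def _occupancy_walk(cfg: UnitConfig, days: int, rng: np.random.Generator) -> np.ndarray:
    frac = np.empty(days)
    f = cfg.occupancy_frac
    for d in range(days):
        f = float(np.clip(f + rng.normal(0.0, cfg.occupancy_jitter), 0.3, 1.0))
        frac[d] = f
    occ = np.clip(np.round(frac * cfg.capacity), 1, cfg.capacity).astype(int)
    return occ


def _generate_unit(
    cfg: UnitConfig, days: int, start: dt.date, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[PauseEvent], list[SettingsChangeEvent], list[OccupancyRecord]]:
    occ = _occupancy_walk(cfg, days, rng)
    occupancy = [
        OccupancyRecord(cfg.unit_id, start + dt.timedelta(days=d), int(occ[d]),
                        cfg.capacity)
        for d in range(days)
    ]

    cols: dict[str, list] = {k: [] for k in
                             ("bed_id", "onset_s", "day", "duration", "device",
                              "color", "label", "lead_off")}
    pauses: list[PauseEvent] = []
    changes: list[SettingsChangeEvent] = []

    for d in range(days):
        beds = occ[d]
        day_onsets: list[float] = []  # for proper-pause placement
        day_beds: list[int] = []
        for color, load in cfg.loads.items():
            per_bed = rng.gamma(load.shape, load.scale)
            n = int(round(per_bed * beds))
            if n == 0:
                continue
            onsets = rng.uniform(0, SECONDS_PER_DAY, size=n)
            bed_idx = rng.integers(0, beds, size=n)
            if color is AlarmColor.YELLOW and cfg.burst_rate > 0:
                n_bursts = rng.poisson(cfg.burst_rate * beds)
                pos = 0
                for _ in range(n_bursts):
                    if pos + cfg.burst_size > n:
                        break
                    t0 = rng.uniform(0, SECONDS_PER_DAY - cfg.burst_window_s)
                    bed = rng.integers(0, beds)
                    sl = slice(pos, pos + cfg.burst_size)
                    onsets[sl] = t0 + rng.uniform(0, cfg.burst_window_s,
                                                  size=cfg.burst_size)
                    bed_idx[sl] = bed
                    pos += cfg.burst_size
            mix = cfg.device_mix[color]
            devices = rng.choice(
                [dv.value for dv in mix], size=n, p=list(mix.values())
            )
            durations = np.minimum(
                rng.exponential(cfg.duration_mean_s[color], size=n),
                cfg.duration_max_s,
            )
            cols["bed_id"].extend(f"{cfg.unit_id}-b{i:02d}" for i in bed_idx)
            cols["onset_s"].extend(np.floor(onsets))
            cols["day"].extend([d] * n)
            cols["duration"].extend(np.round(durations, 1))
            cols["device"].extend(devices)
            cols["color"].extend([color.value] * n)
            labels = [
                _LABELS.get((Device(dv), color), f"{dv} {color.value.lower()}")
                for dv in devices
            ]
            cols["label"].extend(labels)
            cols["lead_off"].extend(lb == LEAD_OFF_LABEL for lb in labels)
            if color in (AlarmColor.RED, AlarmColor.YELLOW):
                day_onsets.extend(np.floor(onsets))
                day_beds.extend(bed_idx)

        day0 = dt.datetime.combine(start + dt.timedelta(days=d), dt.time())
        onsets_by_bed: dict[int, np.ndarray] = {}
        if day_onsets:
            ob = np.asarray(day_beds)
            ot = np.asarray(day_onsets)
            onsets_by_bed = {b: np.sort(ot[ob == b]) for b in np.unique(ob)}
        n_pauses = rng.poisson(cfg.pause_rate * beds)
        for _ in range(n_pauses):
            dur = float(rng.uniform(60, 180))
            if day_onsets and rng.random() < cfg.proper_pause_prob:
                # proper use: the pause brackets an alarm it silences
                j = int(rng.integers(0, len(day_onsets)))
                t = max(0.0, day_onsets[j] - rng.uniform(0, 30))
                bed = day_beds[j]
            else:
                # improper use: paused although no alarm would have
                # sounded; rejection-sample an alarm-free stretch
                bed = int(rng.integers(0, beds))
                vec = onsets_by_bed.get(bed, np.empty(0))
                for _try in range(20):
                    t = float(rng.uniform(0, SECONDS_PER_DAY))
                    lo = np.searchsorted(vec, t, "left")
                    hi = np.searchsorted(vec, t + dur, "left")
                    if hi == lo:
                        break
            pauses.append(
                PauseEvent(cfg.unit_id, f"{cfg.unit_id}-b{bed:02d}",
                           day0 + dt.timedelta(seconds=round(t)), dur)
            )
        for kind, rate in (
            (ChangeKind.THRESHOLD_CHANGE, cfg.threshold_change_rate),
            (ChangeKind.PROFILE_CHANGE, cfg.profile_change_rate),
        ):
            for _ in range(rng.poisson(rate * beds)):
                changes.append(
                    SettingsChangeEvent(
                        cfg.unit_id,
                        f"{cfg.unit_id}-b{int(rng.integers(0, beds)):02d}",
                        day0 + dt.timedelta(
                            seconds=float(rng.integers(0, SECONDS_PER_DAY))),
                        kind,
                    )
                )

    onset = (
        pd.to_datetime(dt.datetime.combine(start, dt.time()))
        + pd.to_timedelta(np.asarray(cols["day"]) * SECONDS_PER_DAY
                          + np.asarray(cols["onset_s"]), unit="s")
    ) if cols["day"] else pd.Series([], dtype="datetime64[ns]")
    alarms = pd.DataFrame({
        "unit_id": cfg.unit_id,
        "bed_id": cols["bed_id"],
        "onset": onset,
        "duration": np.asarray(cols["duration"], dtype=float),
        "device": cols["device"],
        "color": cols["color"],
        "label": cols["label"],
        "lead_off": np.asarray(cols["lead_off"], dtype=bool),
    })
    alarms = alarms.sort_values("onset", kind="stable", ignore_index=True)
    return alarms, pauses, changes, occupancy


def _generate_questionnaire(
    groups: Sequence[RespondentGroup],
    missing_rate: float,
    reverse_items: frozenset[int],
    rng: np.random.Generator,
) -> list[QuestionnaireResponse]:
    responses = []
    rid = 0
    for g in groups:
        latent = np.clip(rng.normal(g.mean_pct, g.sd_pct, size=g.n), 0.0, 100.0)
        for pct in latent:
            p = pct / 100.0
            contrib = rng.binomial(4, p, size=N_ITEMS) - 2
            items = [
                int(-contrib[i]) if (i + 1) in reverse_items else int(contrib[i])
                for i in range(N_ITEMS)
            ]
            if rng.random() < missing_rate:
                k = 2 if rng.random() < 0.2 else 1
                for j in rng.choice(N_ITEMS, size=k, replace=False):
                    items[j] = None
            responses.append(
                QuestionnaireResponse(
                    respondent_id=f"r{rid:04d}",
                    unit_id=g.unit_id,
                    unit_type=g.unit_type,
                    role=g.role,
                    items=tuple(items),
                )
            )
            rid += 1
    return responses


def generate_scenario(config: ScenarioConfig, seed: int) -> ScenarioData:
    """Generate the full data bundle for one scenario, reproducibly."""
    config.validate()
    rng = np.random.default_rng(seed)
    frames, pauses, changes, occupancy = [], [], [], []
    for cfg in config.units:
        a, p, c, o = _generate_unit(cfg, config.days, config.start, rng)
        frames.append(a)
        pauses.extend(p)
        changes.extend(c)
        occupancy.extend(o)
    alarms = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    responses = _generate_questionnaire(
        config.respondents, config.missing_rate, config.reverse_items, rng
    )
    return ScenarioData(alarms, pauses, changes, occupancy, responses)


def _mix(**kw: float) -> dict[Device, float]:
    return {Device[k.upper()]: v for k, v in kw.items()}


def study_presets(
    days: int = STUDY_DAYS,
) -> tuple[ScenarioConfig, ScenarioConfig]:
    """Preset pair (covid-like, noncovid-like) matching the study's
    printed per-unit load means/SDs, occupancy fractions, pause rates,
    flood rates, and questionnaire group means."""
    yellow_mix_nc = _mix(ecg=0.36, ibp=0.50, nibp=0.003, spo2=0.12, temperature=0.017)
    yellow_mix_cv = _mix(ecg=0.29, ibp=0.49, nibp=0.004, spo2=0.19, temperature=0.026)
    red_mix_nc = _mix(ecg=0.229, ibp=0.470, spo2=0.301)
    red_mix_cv = _mix(ecg=0.297, ibp=0.337, spo2=0.366)
    tech_mix_nc = _mix(ecg=0.72, spo2=0.28)
    tech_mix_cv = _mix(ecg=0.70, spo2=0.30)
    dur_nc = {AlarmColor.RED: 33.0, AlarmColor.YELLOW: 14.4, AlarmColor.TECHNICAL: 7.2}
    dur_cv = {AlarmColor.RED: 26.0, AlarmColor.YELLOW: 14.4, AlarmColor.TECHNICAL: 20.2}

    def unit(uid, utype, cap, occ, red, yellow, tech, pause, proper, burst):
        covid = utype is UnitType.COVID
        return UnitConfig(
            unit_id=uid,
            unit_type=utype,
            capacity=cap,
            occupancy_frac=occ,
            loads={
                AlarmColor.RED: GammaLoad(*red),
                AlarmColor.YELLOW: GammaLoad(*yellow),
                AlarmColor.TECHNICAL: GammaLoad(*tech),
            },
            device_mix={
                AlarmColor.RED: red_mix_cv if covid else red_mix_nc,
                AlarmColor.YELLOW: yellow_mix_cv if covid else yellow_mix_nc,
                AlarmColor.TECHNICAL: tech_mix_cv if covid else tech_mix_nc,
            },
            duration_mean_s=dur_cv if covid else dur_nc,
            pause_rate=pause,
            proper_pause_prob=proper,
            threshold_change_rate=0.8 if covid else 1.5,
            profile_change_rate=0.15 if covid else 0.3,
            burst_rate=burst,
        )

    noncovid = ScenarioConfig(
        units=[
            unit("surgical", UnitType.NON_COVID, 16, 0.9726,
                 (10.94, 2.43), (108.48, 37.86), (5.10, 2.17), 12.21, 0.04, 1.71),
            unit("medical", UnitType.NON_COVID, 14, 0.9227,
                 (10.99, 2.82), (107.71, 26.68), (5.03, 2.97), 12.21, 0.08, 1.95),
        ],
        days=days,
        respondents=[
            RespondentGroup("surgical", UnitType.NON_COVID, Role.NURSE, 40, 59.00, 13.05),
            RespondentGroup("medical", UnitType.NON_COVID, Role.NURSE, 27, 59.00, 13.05),
            RespondentGroup("surgical", UnitType.NON_COVID, Role.PHYSICIAN, 9, 59.00, 13.05),
            RespondentGroup("surgical", UnitType.NON_COVID, Role.SUPPORT, 12, 31.65, 13.0),
        ],
    )
    covid = ScenarioConfig(
        units=[
            unit("covid_a", UnitType.COVID, 16, 0.8879,
                 (14.99, 5.89), (126.23, 37.93), (10.30, 2.30), 5.08, 0.04, 2.60),
            unit("covid_b", UnitType.COVID, 12, 0.8275,
                 (15.81, 4.01), (140.56, 41.08), (10.84, 2.51), 5.08, 0.03, 2.73),
        ],
        days=days,
        respondents=[
            RespondentGroup("covid_a", UnitType.COVID, Role.NURSE, 21, 64.28, 14.20),
            RespondentGroup("covid_b", UnitType.COVID, Role.NURSE, 4, 64.28, 14.20),
            RespondentGroup("covid_a", UnitType.COVID, Role.PHYSICIAN, 7, 64.28, 14.20),
            RespondentGroup("covid_a", UnitType.COVID, Role.SUPPORT, 24, 44.96, 13.0),
        ],
    )
    return covid, noncovid


def write_scenario(
    data: ScenarioData, out_dir: str | Path, xml: bool = False
) -> dict[str, Path]:
    """Persist a scenario in the package's file dialects."""
    from .events import frame_to_alarms
    from .log_io import (
        write_alarm_log_csv,
        write_alarm_log_xml,
        write_occupancy_csv,
    )
    from .questionnaire import write_questionnaire_csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alarms = frame_to_alarms(data.alarms)
    paths = {}
    if xml:
        paths["alarms"] = out_dir / "alarms.xml"
        write_alarm_log_xml(paths["alarms"], alarms, data.pauses, data.changes)
    else:
        paths["alarms"] = out_dir / "alarms.csv"
        write_alarm_log_csv(paths["alarms"], alarms, data.pauses, data.changes)
    paths["occupancy"] = out_dir / "occupancy.csv"
    write_occupancy_csv(paths["occupancy"], data.occupancy)
    paths["questionnaire"] = out_dir / "questionnaire.csv"
    write_questionnaire_csv(paths["questionnaire"], data.responses)
    return paths
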