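"""End-to-end orchestration: generate or load data, compute the metric
suite, run the hypothesis battery, and emit result tables.

The emitted tables mirror the analysis layout: per-unit load summaries,
group load contrasts (gamma GLM + Cohen's d, Bonferroni within the
family), duration contrasts (bootstrap margin test on medians +
median-based d-type effect size), fatigue-score comparisons, and an
exploratory block (floods, concurrency, pauses, settings changes).
Percentage contrasts are (covid − noncovid)/noncovid × 100, stored
unrounded and rounded half away from zero to an integer.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics as M
from . import stats as S
from .events import AlarmColor, OccupancyRecord
from .questionnaire import compare_fatigue, impute_missing
from .synthetic import ScenarioConfig, ScenarioData, generate_scenario, study_presets

__all__ = ["AnalysisReport", "percentage_contrast", "run_pipeline"]

_COLOR_STRATA = {
    "total": (AlarmColor.RED.value, AlarmColor.YELLOW.value, AlarmColor.TECHNICAL.value),
    "red": (AlarmColor.RED.value,),
    "yellow": (AlarmColor.YELLOW.value,),
    "technical": (AlarmColor.TECHNICAL.value,),
}


def percentage_contrast(covid_mean: float, noncovid_mean: float) -> tuple[float, int]:
    """Relative excess of the covid group over the non-covid group, in
    percent: unrounded value and integer rounded half away from zero."""
    if noncovid_mean == 0:
        raise ZeroDivisionError("non-covid mean is zero")
    value = (covid_mean - noncovid_mean) / noncovid_mean * 100.0
    rounded = int(math.floor(abs(value) + 0.5) * (1 if value >= 0 else -1))
    return value, rounded


@dataclass
class AnalysisReport:
    per_unit_loads: pd.DataFrame
    load_contrasts: pd.DataFrame
    duration_contrasts: pd.DataFrame
    fatigue: pd.DataFrame
    exploratory: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "per_unit_loads": self.per_unit_loads,
            "load_contrasts": self.load_contrasts,
            "duration_contrasts": self.duration_contrasts,
            "fatigue": self.fatigue,
            "exploratory": self.exploratory,
        }

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
        with open(out_dir / "summary.txt", "w") as fh:
            for name, df in self.tables().items():
                fh.write(f"== {name} ==\n{df.to_string(index=False)}\n\n")


def _group_of(unit_id: str, group_map: Mapping[str, str]) -> str:
    return group_map[unit_id]


def _load_series(
    alarms: pd.DataFrame,
    occupancy: Sequence[OccupancyRecord],
    colors: Sequence[str],
    include_lead_off: bool = True,
) -> pd.DataFrame:
    return M.alarms_per_bed_day(
        alarms, occupancy, colors=colors, include_lead_off=include_lead_off
    )


def run_pipeline(
    config: tuple[ScenarioConfig, ScenarioConfig] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_boot: int = S.DEFAULT_N_BOOT,
) -> AnalysisReport:
    """Run the full analysis on a scenario pair (covid-like,
    noncovid-like); defaults to the study presets.  Deterministic
    for a fixed seed."""
    covid_cfg, noncovid_cfg = config if config is not None else study_presets()
    ss = np.random.SeedSequence(seed)
    seed_cv, seed_nc, seed_imp, seed_boot = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    cv = generate_scenario(covid_cfg, seed_cv)
    nc = generate_scenario(noncovid_cfg, seed_nc)

    group_map = {u.unit_id: "COVID" for u in covid_cfg.units}
    group_map.update({u.unit_id: "NON_COVID" for u in noncovid_cfg.units})
    alarms = pd.concat([cv.alarms, nc.alarms], ignore_index=True)
    occupancy = cv.occupancy + nc.occupancy
    pauses = cv.pauses + nc.pauses
    changes = cv.changes + nc.changes

    # --- per-unit load summary (one row per unit x stratum) ---
    unit_rows = []
    for stratum, colors in _COLOR_STRATA.items():
        tab = _load_series(alarms, occupancy, colors)
        for unit_id, grp in tab.groupby("unit_id"):
            unit_rows.append({
                "unit_id": unit_id,
                "group": _group_of(unit_id, group_map),
                "stratum": stratum,
                "mean": grp["value"].mean(),
                "sd": grp["value"].std(ddof=1),
                "n_days": len(grp),
            })
    per_unit = pd.DataFrame(unit_rows)

    # --- group load contrasts: gamma GLM + Cohen's d, Bonferroni m=4 ---
    contrast_rows = []
    for stratum, colors in _COLOR_STRATA.items():
        tab = _load_series(alarms, occupancy, colors,
                           include_lead_off=(stratum != "yellow"))
        groups = {
            g: grp["value"].to_numpy()
            for g, grp in tab.assign(
                group=tab["unit_id"].map(group_map)
            ).groupby("group")
        }
        glm = S.gamma_glm_contrast(groups, contrast=("COVID", "NON_COVID"),
                                   drop_zeros=True)
        d = S.cohens_d(groups["COVID"], groups["NON_COVID"])
        pct, pct_round = percentage_contrast(
            glm.fitted_means["COVID"], glm.fitted_means["NON_COVID"]
        )
        contrast_rows.append({
            "stratum": stratum,
            "noncovid_mean": glm.fitted_means["NON_COVID"],
            "covid_mean": glm.fitted_means["COVID"],
            "ratio": glm.ratio,
            "statistic": glm.test.statistic,
            "p_raw": glm.test.p_raw,
            "cohen_d": d.value,
            "pct_contrast": pct,
            "pct_contrast_rounded": pct_round,
        })
    load_contrasts = pd.DataFrame(contrast_rows)
    load_contrasts["p_adjusted"] = S.bonferroni_adjust(
        load_contrasts["p_raw"].tolist(), m=len(load_contrasts)
    )

    # --- duration contrasts per color (bootstrap margin on medians) ---
    rng_boot = np.random.default_rng(seed_boot)
    aud = alarms[alarms["duration"] <= M.CONCURRENCY_CUTOFF_S]
    dur_rows = []
    for stratum in ("red", "yellow", "technical"):
        colors = _COLOR_STRATA[stratum]
        sub = aud[aud["color"].isin(colors)]
        grp = sub.assign(group=sub["unit_id"].map(group_map))
        a = grp.loc[grp["group"] == "COVID", "duration"].to_numpy()
        b = grp.loc[grp["group"] == "NON_COVID", "duration"].to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        test = S.bootstrap_median_margin_test(a, b, n_boot=n_boot, seed=rng_boot)
        k_cv = len({u.unit_id for u in covid_cfg.units})
        k_nc = len({u.unit_id for u in noncovid_cfg.units})
        eff = S.median_effect_size(a, b, k_a=k_cv, k_b=k_nc)
        qa, qb = np.percentile(a, [25, 50, 75]), np.percentile(b, [25, 50, 75])
        dur_rows.append({
            "stratum": stratum,
            "noncovid_median": qb[1], "noncovid_iqr": f"{qb[0]:.0f}-{qb[2]:.0f}",
            "covid_median": qa[1], "covid_iqr": f"{qa[0]:.0f}-{qa[2]:.0f}",
            "statistic": test.statistic,
            "p_raw": test.p_raw,
            "d_type": eff.value,
            "n_covid": a.size, "n_noncovid": b.size,
        })
    duration_contrasts = pd.DataFrame(dur_rows)
    if not duration_contrasts.empty:
        duration_contrasts["p_adjusted"] = S.bonferroni_adjust(
            duration_contrasts["p_raw"].tolist(), m=len(duration_contrasts)
        )

    # --- fatigue questionnaire ---
    responses = impute_missing(cv.responses + nc.responses, seed=seed_imp).responses
    fat_rows = []
    for subgroup in ("all", "clinicians"):
        cmp = compare_fatigue(responses, subgroup=subgroup)
        fat_rows.append({
            "subgroup": subgroup,
            "noncovid_mean_pct": cmp.mean_non_covid,
            "covid_mean_pct": cmp.mean_covid,
            "t": cmp.test.statistic,
            "df": cmp.test.df,
            "p_raw": cmp.test.p_raw,
            "cohen_d": cmp.effect.value,
            "n_covid": cmp.n_covid,
            "n_noncovid": cmp.n_non_covid,
        })
    fatigue = pd.DataFrame(fat_rows)
    fatigue["p_adjusted"] = S.bonferroni_adjust(
        fatigue["p_raw"].tolist(), m=len(fatigue)
    )

    # --- exploratory block ---
    floods = M.detect_flood_conditions(alarms, occupancy)
    conc = M.concurrent_alarm_duration(alarms, occupancy)
    pm = M.pause_metrics(pauses, alarms, occupancy)
    changes_tab = M.settings_change_rates(changes, occupancy)
    exp_rows = []
    for name, tab in (("floods_per_bed_day", floods),
                      ("concurrent_s_per_bed_day", conc),
                      ("pauses_per_bed_day", pm.pauses_per_bed_day)):
        g = tab.assign(group=tab["unit_id"].map(group_map)).groupby("group")["value"]
        means = g.mean()
        pct, pct_round = percentage_contrast(means["COVID"], means["NON_COVID"])
        exp_rows.append({
            "metric": name,
            "noncovid_mean": means["NON_COVID"],
            "covid_mean": means["COVID"],
            "pct_contrast": pct,
            "pct_contrast_rounded": pct_round,
        })
    for kind, tab in changes_tab.groupby("kind"):
        g = tab.assign(group=tab["unit_id"].map(group_map)).groupby("group")["value"]
        means = g.mean()
        pct, pct_round = percentage_contrast(means["COVID"], means["NON_COVID"])
        exp_rows.append({
            "metric": f"{kind.lower()}s_per_bed_day",
            "noncovid_mean": means["NON_COVID"],
            "covid_mean": means["COVID"],
            "pct_contrast": pct,
            "pct_contrast_rounded": pct_round,
        })
    for unit_id, ratio in sorted(pm.proper_pause_ratio.items()):
        exp_rows.append({
            "metric": f"proper_pause_ratio[{unit_id}]",
            "noncovid_mean": ratio if group_map[unit_id] == "NON_COVID" else np.nan,
            "covid_mean": ratio if group_map[unit_id] == "COVID" else np.nan,
            "pct_contrast": np.nan,
            "pct_contrast_rounded": np.nan,
        })
    exploratory = pd.DataFrame(exp_rows)

    report = AnalysisReport(
        per_unit_loads=per_unit,
        load_contrasts=load_contrasts,
        duration_contrasts=duration_contrasts,
        fatigue=fatigue,
        exploratory=exploratory,
    )
    if out_dir is not None:
        report.save(out_dir)
    return report
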