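"""Scoring and comparison of the 9-item alarm-fatigue instrument.

Each item is a 5-point Likert response coded −2 ("strongly disagree")
to +2 ("strongly agree"), 0 for "partly agree".  Four items are worded
in the opposite direction and are negated before summation; the sum is
the fatigue score in [−18, 18] (−18 = no fatigue, +18 = extreme
fatigue, midpoint 0), reported as a percentage via the linear map
(score + 18)/36 × 100.

Responses missing one or two items are completed by single-draw
predictive mean matching (PMM) against the complete responses;
responses missing three or more items are excluded, not imputed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import (
    EffectSizeResult,
    TestResult,
    cohens_d,
    one_tailed_t_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "UnitType",
    "Role",
    "QuestionnaireResponse",
    "FatigueScore",
    "DEFAULT_REVERSE_ITEMS",
    "N_ITEMS",
    "SCORE_MIN",
    "SCORE_MAX",
    "read_questionnaire_csv",
    "write_questionnaire_csv",
    "impute_missing",
    "score_response",
    "score_to_percentage",
    "compare_fatigue",
]

N_ITEMS = 9
SCORE_MIN, SCORE_MAX = -18, 18

# 1-based positions of the reverse-worded items.  The instrument's
# published short form does not identify them, so the set is
# configurable; every scoring property holds for any 4-element set.
DEFAULT_REVERSE_ITEMS: frozenset[int] = frozenset({2, 4, 6, 8})

_VALID_CODES = {-2, -1, 0, 1, 2}


class UnitType(str, Enum):
    COVID = "COVID"
    NON_COVID = "NON_COVID"


class Role(str, Enum):
    NURSE = "NURSE"
    PHYSICIAN = "PHYSICIAN"
    SUPPORT = "SUPPORT"


CLINICIAN_ROLES = frozenset({Role.NURSE, Role.PHYSICIAN})


@dataclass(frozen=True)
class QuestionnaireResponse:
    respondent_id: str
    unit_id: str
    unit_type: UnitType
    role: Role
    items: tuple[int | None, ...]  # length 9, None = missing

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} items, got {len(self.items)}")
        for v in self.items:
            if v is not None and v not in _VALID_CODES:
                raise ValueError(f"item value {v!r} outside coded range -2..2")

    @property
    def n_missing(self) -> int:
        return sum(v is None for v in self.items)


@dataclass(frozen=True)
class FatigueScore:
    score: int  # in [-18, 18]
    percentage: float  # in [0, 100]


def read_questionnaire_csv(path: str | Path) -> list[QuestionnaireResponse]:
    """Read responses: respondent_id, unit_id, unit_type, role,
    item1..item9 (coded −2..2, blank = missing).  Rows with out-of-range
    codes are rejected with a logged diagnostic."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for idx, r in enumerate(df.to_dict(orient="records")):
        try:
            items = tuple(
                None if r[f"item{i}"].strip() == "" else int(r[f"item{i}"])
                for i in range(1, N_ITEMS + 1)
            )
            out.append(
                QuestionnaireResponse(
                    respondent_id=r["respondent_id"],
                    unit_id=r["unit_id"],
                    unit_type=UnitType(r["unit_type"]),
                    role=Role(r["role"]),
                    items=items,
                )
            )
        except (ValueError, KeyError) as exc:
            logger.warning("rejected questionnaire row %d: %s", idx, exc)
    return out


def write_questionnaire_csv(
    path: str | Path, responses: Iterable[QuestionnaireResponse]
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["respondent_id", "unit_id", "unit_type", "role"]
            + [f"item{i}" for i in range(1, N_ITEMS + 1)]
        )
        for r in responses:
            w.writerow(
                [r.respondent_id, r.unit_id, r.unit_type.value, r.role.value]
                + ["" if v is None else v for v in r.items]
            )


@dataclass
class ImputationResult:
    responses: list[QuestionnaireResponse]
    excluded: list[tuple[str, str]]  # (respondent_id, reason)


def impute_missing(
    responses: Sequence[QuestionnaireResponse],
    seed: int | np.random.Generator | None = None,
    n_donors: int = 5,
) -> ImputationResult:
    """Single-imputation predictive mean matching for sparse missingness.

    For each response missing one or two items, each missing item is
    regressed (OLS) on the items the recipient did answer, using the
    complete responses as donors; the recipient's predicted mean is
    matched against donor predictions and the imputed value is drawn at
    random from the ``n_donors`` nearest donors' observed values.  Thus
    an imputed value is always a value some donor actually gave.
    Responses with three or more missing items are excluded with a
    reason code; complete responses pass through untouched.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    donors = [r for r in responses if r.n_missing == 0]
    need = [r for r in responses if 1 <= r.n_missing <= 2]
    if need and len(donors) < n_donors:
        raise ValueError(
            f"PMM needs at least {n_donors} complete donor responses, "
            f"have {len(donors)}"
        )
    donor_mat = np.array([r.items for r in donors], dtype=float) if donors else None

    out: list[QuestionnaireResponse] = []
    excluded: list[tuple[str, str]] = []
    for r in responses:
        if r.n_missing == 0:
            out.append(r)
            continue
        if r.n_missing > 2:
            excluded.append((r.respondent_id, f"{r.n_missing} items missing (> 2)"))
            continue
        observed_idx = [i for i, v in enumerate(r.items) if v is not None]
        items = list(r.items)
        for j in (i for i, v in enumerate(r.items) if v is None):
            X = donor_mat[:, observed_idx]
            X1 = np.column_stack([np.ones(len(X)), X])
            y = donor_mat[:, j]
            beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
            donor_pred = X1 @ beta
            rec_pred = float(
                beta[0] + np.dot(beta[1:], [items[i] for i in observed_idx])
            )
            nearest = np.argsort(np.abs(donor_pred - rec_pred), kind="stable")[:n_donors]
            pick = int(rng.choice(nearest))
            items[j] = int(donor_mat[pick, j])
        out.append(replace(r, items=tuple(items)))
    return ImputationResult(responses=out, excluded=excluded)


def score_response(
    response: QuestionnaireResponse | Sequence[int],
    reverse_items: frozenset[int] | set[int] = DEFAULT_REVERSE_ITEMS,
) -> FatigueScore:
    """Sum the 9 coded items into the fatigue score, negating the
    reverse-worded items first.  Items must be complete."""
    items = response.items if isinstance(response, QuestionnaireResponse) else tuple(response)
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} items")
    if any(v is None for v in items):
        raise ValueError("cannot score a response with missing items; impute first")
    if len(reverse_items) != 4:
        raise ValueError("exactly 4 items are reverse-scored")
    score = sum(
        -v if (i + 1) in reverse_items else v for i, v in enumerate(items)
    )
    return FatigueScore(score=score, percentage=score_to_percentage(score))


def score_to_percentage(score: float) -> float:
    """Linear map of the fatigue score onto [0, 100]:
    −18 → 0, 0 → 50, +18 → 100."""
    if not SCORE_MIN <= score <= SCORE_MAX:
        raise ValueError(f"score {score} outside [{SCORE_MIN}, {SCORE_MAX}]")
    return (score - SCORE_MIN) / (SCORE_MAX - SCORE_MIN) * 100.0


@dataclass
class FatigueComparison:
    test: TestResult
    effect: EffectSizeResult
    n_covid: int
    n_non_covid: int
    mean_covid: float
    mean_non_covid: float


def compare_fatigue(
    responses: Sequence[QuestionnaireResponse],
    subgroup: str = "all",
    reverse_items: frozenset[int] | set[int] = DEFAULT_REVERSE_ITEMS,
) -> FatigueComparison:
    """One-tailed comparison of percentage fatigue scores between unit
    types (alternative: COVID above non-COVID), on all staff or on
    clinicians (nurses and physicians) only."""
    if subgroup not in ("all", "clinicians"):
        raise ValueError("subgroup must be 'all' or 'clinicians'")
    pool = [
        r for r in responses
        if subgroup == "all" or r.role in CLINICIAN_ROLES
    ]
    covid = [
        score_response(r, reverse_items).percentage
        for r in pool if r.unit_type is UnitType.COVID
    ]
    non_covid = [
        score_response(r, reverse_items).percentage
        for r in pool if r.unit_type is UnitType.NON_COVID
    ]
    if not covid or not non_covid:
        raise ValueError(f"subgroup {subgroup!r} lacks one of the unit types")
    test = one_tailed_t_test(covid, non_covid, alternative="greater")
    effect = cohens_d(covid, non_covid)
    return FatigueComparison(
        test=test,
        effect=effect,
        n_covid=len(covid),
        n_non_covid=len(non_covid),
        mean_covid=float(np.mean(covid)),
        mean_non_covid=float(np.mean(non_covid)),
    )
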