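"""Fatigue-instrument scoring, percentage map, PMM imputation, and group
comparison."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alarmkit.questionnaire import (
    DEFAULT_REVERSE_ITEMS,
    N_ITEMS,
    QuestionnaireResponse,
    Role,
    UnitType,
    compare_fatigue,
    impute_missing,
    read_questionnaire_csv,
    score_response,
    score_to_percentage,
    write_questionnaire_csv,
)


def resp(items, rid="r1", unit="u1", utype=UnitType.NON_COVID, role=Role.NURSE):
    return QuestionnaireResponse(rid, unit, utype, role, tuple(items))


def max_fatigue_items(reverse=DEFAULT_REVERSE_ITEMS):
    """Raw pattern scoring +2 on every item after reverse coding."""
    return [-2 if (i + 1) in reverse else 2 for i in range(N_ITEMS)]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def test_all_partly_agree_scores_zero_and_fifty_percent():
    fs = score_response(resp([0] * 9))
    assert fs.score == 0 and fs.percentage == 50.0


def test_extreme_patterns_hit_score_bounds():
    hi = score_response(resp(max_fatigue_items()))
    lo = score_response(resp([-v for v in max_fatigue_items()]))
    assert (hi.score, hi.percentage) == (18, 100.0)
    assert (lo.score, lo.percentage) == (-18, 0.0)


@given(
    st.lists(st.sampled_from([-2, -1, 0, 1, 2]), min_size=9, max_size=9),
    st.sets(st.integers(min_value=1, max_value=9), min_size=4, max_size=4),
)
@settings(max_examples=200, deadline=None)
def test_score_bounds_integrality_and_flip_antisymmetry(items, reverse):
    """For any items and any 4-element reverse set: the score is an
    integer in [-18, 18], and negating every raw response negates it."""
    fs = score_response(resp(items), frozenset(reverse))
    assert isinstance(fs.score, int) and -18 <= fs.score <= 18
    flipped = score_response(resp([-v for v in items]), frozenset(reverse))
    assert flipped.score == -fs.score


def test_scoring_requires_complete_items():
    with pytest.raises(ValueError, match="missing"):
        score_response(resp([0] * 8 + [None]))


def test_reverse_set_must_have_four_items():
    with pytest.raises(ValueError, match="4"):
        score_response(resp([0] * 9), reverse_items=frozenset({1, 2}))


def test_out_of_range_item_rejected_at_construction():
    with pytest.raises(ValueError, match="coded range"):
        resp([3] + [0] * 8)


def test_percentage_map_endpoints_and_monotonicity():
    assert score_to_percentage(-18) == 0.0
    assert score_to_percentage(0) == 50.0
    assert score_to_percentage(18) == 100.0
    pcts = [score_to_percentage(s) for s in range(-18, 19)]
    assert all(a < b for a, b in zip(pcts, pcts[1:]))
    with pytest.raises(ValueError):
        score_to_percentage(19)


def test_group_mean_shift_translates_through_map_slope():
    """A 0.73-point score-scale difference maps to ~2.0 percentage
    points under the 100/36 slope."""
    assert score_to_percentage(0.73) - score_to_percentage(0.0) == pytest.approx(
        0.73 * 100 / 36
    )
    assert score_to_percentage(0.73) - score_to_percentage(0.0) == pytest.approx(
        2.0, abs=0.03
    )


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def donors(n=20, seed=0):
    rng = np.random.default_rng(seed)
    return [
        resp(rng.integers(-2, 3, size=9).tolist(), rid=f"d{i}")
        for i in range(n)
    ]


def test_three_missing_items_excluded_with_reason():
    r = resp([None, None, None] + [0] * 6, rid="bad")
    out = impute_missing(donors() + [r], seed=1)
    assert ("bad", "3 items missing (> 2)") in out.excluded
    assert all(x.respondent_id != "bad" for x in out.responses)


def test_degenerate_donor_pool_imputes_the_only_observed_value():
    pool = [resp([1] * 9, rid=f"d{i}") for i in range(6)]
    r = resp([None] + [1] * 8, rid="m")
    out = impute_missing(pool + [r], seed=0)
    imputed = next(x for x in out.responses if x.respondent_id == "m")
    assert imputed.items[0] == 1


def test_pmm_draws_only_observed_donor_values_and_keeps_complete_rows():
    rng = np.random.default_rng(7)
    pool = donors(200, seed=7)
    missing = []
    for i in range(20):
        items = rng.integers(-2, 3, size=9).tolist()
        items[int(rng.integers(0, 9))] = None
        missing.append(resp(items, rid=f"m{i}"))
    out = impute_missing(pool + missing, seed=3)
    assert not out.excluded
    by_id = {r.respondent_id: r for r in out.responses}
    for d in pool:  # complete responses pass through untouched
        assert by_id[d.respondent_id].items == d.items
    donor_mat = np.array([d.items for d in pool])
    for i, orig in enumerate(missing):
        fixed = by_id[f"m{i}"]
        for j, v in enumerate(orig.items):
            if v is None:
                assert fixed.items[j] in set(donor_mat[:, j].tolist())
                assert -2 <= fixed.items[j] <= 2
            else:
                assert fixed.items[j] == v


def test_imputation_reproducible_under_seed():
    pool = donors(50, seed=2)
    r = resp([None] + [0] * 8, rid="m")
    a = impute_missing(pool + [r], seed=9).responses
    b = impute_missing(pool + [r], seed=9).responses
    assert a == b


def test_donor_shortfall_is_error():
    pool = [resp([0] * 9, rid=f"d{i}") for i in range(3)]
    with pytest.raises(ValueError, match="donor"):
        impute_missing(pool + [resp([None] + [0] * 8)], seed=0)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def scored_population(rng, n, mean_pct, utype, role=Role.NURSE, tag=""):
    out = []
    for i in range(n):
        p = np.clip(rng.normal(mean_pct, 13) / 100, 0, 1)
        contrib = rng.binomial(4, p, size=9) - 2
        items = [
            int(-contrib[j]) if (j + 1) in DEFAULT_REVERSE_ITEMS else int(contrib[j])
            for j in range(9)
        ]
        out.append(resp(items, rid=f"{tag}{i}", utype=utype, role=role))
    return out


def test_identical_relabeled_tables_give_midpoint_p_and_zero_d(rng):
    base = scored_population(rng, 30, 55, UnitType.COVID, tag="c")
    mirrored = [
        dataclasses.replace(r, unit_type=UnitType.NON_COVID, respondent_id=f"n{i}")
        for i, r in enumerate(base)
    ]
    cmp = compare_fatigue(base + mirrored)
    assert cmp.test.p_raw == pytest.approx(0.5)
    assert cmp.effect.value == pytest.approx(0.0, abs=1e-12)


def test_clinician_subgroup_excludes_support_staff(rng):
    pop = (
        scored_population(rng, 10, 60, UnitType.COVID, Role.NURSE, "a")
        + scored_population(rng, 5, 60, UnitType.COVID, Role.SUPPORT, "b")
        + scored_population(rng, 8, 55, UnitType.NON_COVID, Role.PHYSICIAN, "c")
        + scored_population(rng, 4, 55, UnitType.NON_COVID, Role.SUPPORT, "d")
    )
    cmp = compare_fatigue(pop, subgroup="clinicians")
    assert (cmp.n_covid, cmp.n_non_covid) == (10, 8)
    all_cmp = compare_fatigue(pop, subgroup="all")
    assert (all_cmp.n_covid, all_cmp.n_non_covid) == (15, 12)


def test_empty_subgroup_is_error(rng):
    pop = scored_population(rng, 5, 60, UnitType.COVID, Role.SUPPORT)
    with pytest.raises(ValueError):
        compare_fatigue(pop, subgroup="clinicians")


def test_cohens_d_recovery_at_study_group_sizes():
    """Latent shift of 0.363 pooled SDs at n = (76, 32) is recovered in
    expectation by the questionnaire pipeline's Cohen's d."""
    rng = np.random.default_rng(42)
    sd_pct = 13.5
    shift = 0.363 * sd_pct
    ds = []
    for _ in range(400):
        covid = scored_population(rng, 32, 57 + shift, UnitType.COVID, tag="c")
        nonc = scored_population(rng, 76, 57, UnitType.NON_COVID, tag="n")
        ds.append(compare_fatigue(covid + nonc).effect.value)
    mean_d = float(np.mean(ds))
    se = float(np.std(ds, ddof=1) / np.sqrt(len(ds)))
    # item-level binomial noise attenuates the latent shift slightly, so
    # allow the recovery band around the target to absorb it
    assert abs(mean_d - 0.363) < max(3 * se, 0.06)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def test_questionnaire_csv_roundtrip(tmp_path):
    rows = donors(5) + [resp([None] + [1] * 8, rid="m")]
    p = tmp_path / "q.csv"
    write_questionnaire_csv(p, rows)
    assert read_questionnaire_csv(p) == rows


def test_out_of_range_csv_row_rejected(tmp_path):
    p = tmp_path / "q.csv"
    header = "respondent_id,unit_id,unit_type,role," + ",".join(
        f"item{i}" for i in range(1, 10)
    )
    p.write_text(
        header + "\n"
        "r1,u1,COVID,NURSE,0,0,0,0,0,0,0,0,0\n"
        "r2,u1,COVID,NURSE,5,0,0,0,0,0,0,0,0\n"
    )
    rows = read_questionnaire_csv(p)
    assert [r.respondent_id for r in rows] == ["r1"]
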