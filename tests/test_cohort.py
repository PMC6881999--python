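"""Visit alignment, exclusion rules, quartiles and design matrices."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_scored_visits
from dyadinform.cohort import (PREDICTORS, StratumSpec, align_visits,
                               apply_exclusions, assign_quartiles,
                               build_design)
from dyadinform.errors import EmptyStratumError, MalformedInputError


# --- alignment ---------------------------------------------------------------


def _visit(pid, year=None, months=None, disc=False, **kw):
    d = dict(participant_id=pid, visit_year=year,
             months_from_baseline=months, is_discontinuation_visit=disc)
    d.update(kw)
    return d


def test_discontinuation_visits_map_to_nearest_year():
    df = make_scored_visits([
        _visit("A", year=0),
        _visit("A", year=1),
        _visit("A", months=25.0, disc=True),   # nearest year 2
        _visit("B", year=0),
        _visit("B", months=30.0, disc=True),   # exact tie rounds down -> 2
    ])
    out = align_visits(df)
    assert out.loc[(out.participant_id == "A") & out.is_discontinuation_visit,
                   "visit_year"].item() == 2
    assert out.loc[(out.participant_id == "B") & out.is_discontinuation_visit,
                   "visit_year"].item() == 2


def test_discontinuation_visit_dropped_when_year_already_occupied():
    df = make_scored_visits([
        _visit("A", year=0),
        _visit("A", year=3),
        _visit("A", months=34.0, disc=True),  # maps to occupied year 3
    ])
    out = align_visits(df)
    assert len(out) == 2
    assert not out.is_discontinuation_visit.any()


def test_duplicate_regular_visits_are_malformed():
    df = make_scored_visits([_visit("A", year=1), _visit("A", year=1)])
    with pytest.raises(MalformedInputError):
        align_visits(df)


# --- exclusions --------------------------------------------------------------


def _cohort_with_planted_missingness():
    rows = []
    # P1: clean completer
    rows += [_visit("P1", year=t) for t in range(5)]
    # P2: baseline partner CFI missing
    rows += [_visit("P2", year=0, s_cfi=np.nan), _visit("P2", year=1)]
    # P3: baseline CDR-Global 0.5 (fails entry criterion)
    rows += [_visit("P3", year=t, cdr_global_baseline=0.5) for t in (0, 1)]
    # P4: year-2 participant CFI missing, otherwise fine
    rows += [_visit("P4", year=0), _visit("P4", year=1),
             _visit("P4", year=2, p_cfi=np.nan)]
    # P5: baseline composite missing
    rows += [_visit("P5", year=0, composite=np.nan), _visit("P5", year=1)]
    return make_scored_visits(rows)


def test_prospective_exclusions_match_hand_counts():
    df = _cohort_with_planted_missingness()
    retained, log = apply_exclusions(df, "prospective")
    kept = set(retained.participant_id)
    assert kept == {"P1", "P4", "P5"}  # P2 missing baseline CFI, P3 CDR>0
    rules = log.groupby("rule").size().to_dict()
    assert rules == {"baseline_cdr_not_zero": 1, "baseline_cfi_missing": 1}
    # all P2/P3 rows gone, nothing else dropped
    assert len(retained) == len(df) - 2 - 2


def test_cross_sectional_exclusions_match_hand_counts():
    df = _cohort_with_planted_missingness()
    retained, log = apply_exclusions(df, "cross_sectional")
    kept = set(retained.participant_id)
    # P3 fails entry; P5 has no baseline composite; P2's baseline CFI gap is
    # irrelevant cross-sectionally
    assert kept == {"P1", "P2", "P4"}
    rules = log.groupby("rule").size().to_dict()
    assert rules == {"baseline_cdr_not_zero": 1,
                     "baseline_composite_missing": 1,
                     "cross_sectional_cfi_missing": 1}
    # P4 keeps every visit except year 2
    assert sorted(retained.loc[retained.participant_id == "P4",
                               "visit_year"]) == [0, 1]


@pytest.mark.parametrize("mode", ["prospective", "cross_sectional"])
def test_exclusions_are_idempotent(mode):
    df = _cohort_with_planted_missingness()
    once, _ = apply_exclusions(df, mode)
    twice, log2 = apply_exclusions(once, mode)
    pd.testing.assert_frame_equal(once, twice)
    assert log2.empty


def test_retained_plus_excluded_accounts_for_every_participant():
    df = _cohort_with_planted_missingness()
    retained, log = apply_exclusions(df, "prospective")
    assert (set(retained.participant_id) | set(log.participant_id)
            == set(df.participant_id))


# --- quartiles ---------------------------------------------------------------


def test_quartiles_of_one_to_eight():
    vals = pd.Series(np.arange(1.0, 9.0), index=list("abcdefgh"))
    labels = assign_quartiles(vals)
    assert list(labels) == [1, 1, 2, 2, 3, 3, 4, 4]


def test_identical_values_all_lowest_quartile():
    labels = assign_quartiles(pd.Series([2.0] * 6))
    assert (labels == 1).all()


def test_quartile_labels_shift_invariant():
    rng = np.random.default_rng(0)
    vals = pd.Series(rng.normal(size=40))
    pd.testing.assert_series_equal(assign_quartiles(vals),
                                   assign_quartiles(vals + 17.3))


def test_quartile_group_sizes_balanced():
    rng = np.random.default_rng(1)
    vals = pd.Series(rng.uniform(size=1000))
    counts = assign_quartiles(vals).value_counts()
    assert all(abs(counts[q] - 250) <= 1 for q in (1, 2, 3, 4))


def test_too_few_participants_raise():
    with pytest.raises(MalformedInputError):
        assign_quartiles(pd.Series([1.0, 2.0, 3.0]))


# --- design matrices ----------------------------------------------------------


def _design_cohort():
    rows = []
    for i, (dyad, comp0) in enumerate([
            ("spousal", -1.2), ("spousal", -0.4), ("non_spousal", 0.3),
            ("non_spousal", 1.1)]):
        pid = f"D{i}"
        for t in range(4):
            rows.append(_visit(
                pid, year=t, dyad_type=dyad, composite=comp0 + 0.1 * t,
                p_cfi=float(i + t), s_cfi=float(10 + i - t),
                cdr_sb=0.5 * t, age=76.0 + i, education=12.0 + i,
                sex="female" if i % 2 else "male", race_caucasian=i % 2,
                cvd_history=1))
    return make_scored_visits(rows)


def test_prospective_design_uses_baseline_predictors():
    df = _design_cohort()
    q = assign_quartiles(df[df.visit_year == 0]
                         .set_index("participant_id")["composite"])
    X, y, names = build_design(df, StratumSpec("prospective", 2), q)
    assert names == list(PREDICTORS)
    assert list(X.columns) == list(PREDICTORS)
    # baseline p_cfi for D0 is 0.0 even though year-2 value is 2.0
    assert X.loc["D0", "p_cfi"] == 0.0 and X.loc["D0", "cdr_sb"] == 0.0
    assert y[list(X.index).index("D0")] == pytest.approx(-1.0)


def test_cross_sectional_design_uses_outcome_year_predictors():
    df = _design_cohort()
    X, y, _ = build_design(df, StratumSpec("cross_sectional", 3))
    assert X.loc["D0", "p_cfi"] == 3.0       # year-3 value
    assert X.loc["D0", "s_cfi"] == 7.0
    assert X.loc["D0", "cdr_sb"] == 1.5
    assert X.loc["D0", "age"] == 76.0        # covariates stay baseline


def test_dyad_and_quartile_filters():
    df = _design_cohort()
    q = assign_quartiles(df[df.visit_year == 0]
                         .set_index("participant_id")["composite"])
    X, _, _ = build_design(df, StratumSpec("prospective", 1, "spousal"), q)
    assert set(X.index) == {"D0", "D1"}
    X1, _, _ = build_design(
        df, StratumSpec("prospective", 1, "all", 1), q)
    assert set(X1.index) == {"D0"}  # poorest baseline composite
    with pytest.raises(EmptyStratumError):
        build_design(df, StratumSpec("prospective", 1, "spousal", 4), q)


def test_rows_with_missing_predictor_or_outcome_dropped():
    df = _design_cohort()
    df.loc[(df.participant_id == "D1") & (df.visit_year == 0), "cdr_sb"] = np.nan
    df.loc[(df.participant_id == "D2") & (df.visit_year == 2), "composite"] = np.nan
    X, y, _ = build_design(df, StratumSpec("prospective", 2))
    assert set(X.index) == {"D0", "D3"}
    assert len(y) == 2


def test_invalid_stratum_spec_rejected():
    with pytest.raises(MalformedInputError):
        StratumSpec("prospective", 5)
    with pytest.raises(MalformedInputError):
        StratumSpec("prospective", 1, "friends")
    with pytest.raises(MalformedInputError):
        StratumSpec("retrospective", 1)
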