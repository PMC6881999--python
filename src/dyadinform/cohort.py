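"""Visit alignment, exclusion filters, stratification and design matrices.

The analysis cohort is a long-format visit table: one row per participant
per annual visit (year 0 = baseline, years 1-4 follow-up), carrying the
scored instruments, the cognitive composite, and baseline covariates.
Participants who discontinue may return for a single early final visit;
such visits are mapped to the closest annual visit, and dropped when a
regular visit for that year already exists.

Two analysis modes share the machinery:

* prospective — baseline participant and partner CFI (plus baseline CDR-SB)
  predicting the composite at a later year;
* cross-sectional — the outcome year's own CFI and CDR-SB predicting the
  same year's composite.

Both adjust for baseline age, education, sex, race and cardiovascular
history, and can be stratified by dyad type (spousal vs non-spousal) and by
quartile of the baseline composite (quartile 1 = poorest cognition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from . import scores
from .errors import EmptyStratumError, MalformedInputError

__all__ = ["StratumSpec", "score_visit_table", "align_visits",
           "apply_exclusions", "assign_quartiles", "build_design",
           "PREDICTORS"]

#: predictor names of the design matrix, in column order
PREDICTORS = ("p_cfi", "s_cfi", "cdr_sb", "age", "education", "sex", "race",
              "cvd")

#: CSV component columns -> canonical component names
COMPONENT_COLUMNS = {
    "fcsrt": "fcsrt_total_recall",
    "pr": "paragraph_recall",
    "dsst": "digit_symbol",
    "mmmse": "mmmse",
    "fluency": "animal_fluency",
}

P_ITEM_COLUMNS = tuple(f"p_cfi_{i:02d}" for i in range(1, 15))
S_ITEM_COLUMNS = tuple(f"s_cfi_{i:02d}" for i in range(1, 15))


@dataclass(frozen=True)
class StratumSpec:
    """One analysis cell: mode x outcome year x dyad x baseline quartile."""

    mode: Literal["prospective", "cross_sectional"]
    outcome_year: int
    dyad_filter: Literal["all", "spousal", "non_spousal"] = "all"
    quartile_filter: int | Literal["all"] = "all"

    def __post_init__(self):
        if self.mode not in ("prospective", "cross_sectional"):
            raise MalformedInputError(f"unknown mode {self.mode!r}")
        if self.outcome_year not in (1, 2, 3, 4):
            raise MalformedInputError("outcome_year must be 1..4")
        if self.dyad_filter not in ("all", "spousal", "non_spousal"):
            raise MalformedInputError(f"unknown dyad filter {self.dyad_filter!r}")
        if self.quartile_filter not in ("all", 1, 2, 3, 4):
            raise MalformedInputError(
                f"unknown quartile filter {self.quartile_filter!r}")

    def label(self) -> str:
        q = self.quartile_filter
        return (f"{self.mode}|year={self.outcome_year}|dyad={self.dyad_filter}"
                f"|quartile={q}")


def _score_items(raw: pd.DataFrame, columns: tuple[str, ...]) -> pd.Series:
    def one(row) -> float:
        sc = scores.score_cfi(list(row))
        return np.nan if sc.is_missing else sc.total
    return raw[list(columns)].apply(one, axis=1)


def score_visit_table(raw: pd.DataFrame,
                      reference: scores.CompositeReference | None = None,
                      ) -> tuple[pd.DataFrame, scores.CompositeReference]:
    """Score CFI items, fit the composite reference, compute composites.

    ``raw`` is the long-format visit table (see the column dictionary in the
    package docs).  The reference group is the baseline rows of participants
    with CDR-Global 0; pass ``reference`` to reuse a previously fitted one.
    Returns the visit table with ``p_cfi``, ``s_cfi`` and ``composite``
    columns added, plus the reference.
    """
    df = raw.copy()
    comp = pd.DataFrame(index=df.index)
    for col, name in COMPONENT_COLUMNS.items():
        comp[name] = pd.to_numeric(df[col], errors="coerce")

    if reference is None:
        at_baseline = (df["visit_year"] == 0) & (~df["is_discontinuation_visit"].astype(bool))
        in_ref = at_baseline & (df["cdr_global_baseline"] == 0)
        reference = scores.fit_reference(comp.loc[at_baseline],
                                         in_ref.loc[at_baseline])

    df["p_cfi"] = _score_items(df.fillna(""), P_ITEM_COLUMNS)
    df["s_cfi"] = _score_items(df.fillna(""), S_ITEM_COLUMNS)
    df["composite"] = scores.composite_column(comp, reference)
    return df, reference


def align_visits(records: pd.DataFrame) -> pd.DataFrame:
    """Map discontinuation visits to the closest annual visit.

    A discontinuation visit at m months is assigned
    ``visit_year = round(m / 12)``, with exact half-year ties rounding down;
    if the participant already has a regular visit for that year, the
    discontinuation visit is dropped.  Two regular visits in the same year
    are malformed input.
    """
    df = records.copy()
    disc = df["is_discontinuation_visit"].astype(bool)

    regular = df.loc[~disc]
    dup = regular.duplicated(subset=["participant_id", "visit_year"])
    if dup.any():
        pid = regular.loc[dup, "participant_id"].iloc[0]
        raise MalformedInputError(
            f"participant {pid!r} has two regular visits in the same year")

    # round-half-down: ceil(x - 0.5)
    months = df.loc[disc, "months_from_baseline"].astype(float)
    df.loc[disc, "visit_year"] = np.ceil(months / 12.0 - 0.5).astype(int)

    occupied = set(zip(regular["participant_id"], regular["visit_year"]))
    keep = ~disc.copy()
    for i in df.index[disc]:
        key = (df.at[i, "participant_id"], df.at[i, "visit_year"])
        keep.at[i] = key not in occupied
    df = df.loc[keep].copy()
    df["visit_year"] = df["visit_year"].astype(int)
    return df.sort_values(["participant_id", "visit_year"]).reset_index(drop=True)


def apply_exclusions(records: pd.DataFrame, mode: str,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort entry and mode-specific missing-instrument rules.

    Rules, in order:

    * ``baseline_cdr_not_zero`` — cohort entry requires CDR-Global 0 at
      baseline (participant-level).
    * ``no_baseline_visit`` — a retained participant must have a baseline
      row (participant-level).
    * prospective mode, ``baseline_cfi_missing`` — baseline participant or
      partner CFI missing (participant-level).
    * cross-sectional mode, ``cross_sectional_cfi_missing`` — a follow-up
      row whose same-year participant or partner CFI is missing (row-level);
      and ``baseline_composite_missing`` — the baseline composite anchors
      the quartile strata, so participants without it are excluded
      (participant-level).

    Returns (retained rows, exclusion log with columns participant_id,
    visit_year, rule).  Idempotent.
    """
    if mode not in ("prospective", "cross_sectional"):
        raise MalformedInputError(f"unknown mode {mode!r}")
    df = records.copy()
    log_rows: list[dict] = []

    def drop_participants(pids, rule):
        nonlocal df
        pids = set(pids)
        if not pids:
            return
        for pid in sorted(pids):
            log_rows.append({"participant_id": pid, "visit_year": 0,
                             "rule": rule})
        df = df.loc[~df["participant_id"].isin(pids)]

    baseline = df.loc[df["visit_year"] == 0].set_index("participant_id")
    drop_participants(
        baseline.index[baseline["cdr_global_baseline"] != 0],
        "baseline_cdr_not_zero")
    drop_participants(
        set(df["participant_id"]) - set(baseline.index),
        "no_baseline_visit")

    baseline = df.loc[df["visit_year"] == 0].set_index("participant_id")
    if mode == "prospective":
        bad = baseline.index[baseline["p_cfi"].isna() | baseline["s_cfi"].isna()]
        drop_participants(bad, "baseline_cfi_missing")
    else:
        rows = df.loc[(df["visit_year"] >= 1)
                      & (df["p_cfi"].isna() | df["s_cfi"].isna())]
        for _, r in rows.iterrows():
            log_rows.append({"participant_id": r["participant_id"],
                             "visit_year": int(r["visit_year"]),
                             "rule": "cross_sectional_cfi_missing"})
        df = df.drop(index=rows.index)
        baseline = df.loc[df["visit_year"] == 0].set_index("participant_id")
        drop_participants(baseline.index[baseline["composite"].isna()],
                          "baseline_composite_missing")

    log = pd.DataFrame(log_rows, columns=["participant_id", "visit_year", "rule"])
    if df.empty:
        import warnings
        warnings.warn("all records excluded", stacklevel=2)
    return df.reset_index(drop=True), log


def assign_quartiles(baseline_composites: pd.Series) -> pd.Series:
    """Quartile labels 1..4 from baseline composites; 1 = poorest cognition.

    Cut points are the empirical 25/50/75th percentiles (linear
    interpolation); values <= Q1 get label 1, (Q1, Q2] label 2, (Q2, Q3]
    label 3, above Q3 label 4.
    """
    vals = baseline_composites.dropna()
    if len(vals) < 4:
        raise MalformedInputError("need at least 4 participants for quartiles")
    q1, q2, q3 = np.quantile(vals.to_numpy(dtype=float), [0.25, 0.5, 0.75])
    labels = pd.Series(4, index=vals.index, dtype=int)
    labels[vals <= q3] = 3
    labels[vals <= q2] = 2
    labels[vals <= q1] = 1
    return labels


def build_design(records: pd.DataFrame, spec: StratumSpec,
                 quartiles: pd.Series | None = None,
                 ) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Assemble (X, y, predictor names) for one stratum.

    y is the composite at ``spec.outcome_year``.  In prospective mode the
    CFI and CDR-SB predictors come from baseline; in cross-sectional mode
    from the outcome year itself.  Covariates (age, education, female
    indicator, Caucasian indicator, cardiovascular history) always come
    from baseline.  Rows with any missing predictor or missing outcome are
    dropped (complete case).
    """
    baseline = records.loc[records["visit_year"] == 0].set_index("participant_id")
    outcome = records.loc[records["visit_year"] == spec.outcome_year]
    outcome = outcome.set_index("participant_id")
    pids = outcome.index.intersection(baseline.index)

    src = baseline if spec.mode == "prospective" else outcome
    X = pd.DataFrame({
        "p_cfi": src.loc[pids, "p_cfi"],
        "s_cfi": src.loc[pids, "s_cfi"],
        "cdr_sb": src.loc[pids, "cdr_sb"].astype(float),
        "age": baseline.loc[pids, "age"].astype(float),
        "education": baseline.loc[pids, "education"].astype(float),
        "sex": (baseline.loc[pids, "sex"] == "female").astype(float),
        "race": baseline.loc[pids, "race_caucasian"].astype(float),
        "cvd": baseline.loc[pids, "cvd_history"].astype(float),
    }, index=pids)
    y = outcome.loc[pids, "composite"].astype(float)

    if spec.dyad_filter != "all":
        keep = baseline.loc[pids, "dyad_type"] == spec.dyad_filter
        X, y = X.loc[keep], y.loc[keep]
    if spec.quartile_filter != "all":
        if quartiles is None:
            raise MalformedInputError(
                "quartile_filter requires assigned quartiles")
        labels = quartiles.reindex(X.index)
        keep = labels == spec.quartile_filter
        X, y = X.loc[keep.fillna(False)], y.loc[keep.fillna(False)]

    ok = X.notna().all(axis=1) & y.notna()
    X, y = X.loc[ok], y.loc[ok]
    if X.empty:
        raise EmptyStratumError(spec)
    return X, y.to_numpy(dtype=float), list(PREDICTORS)
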