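"""Instrument scoring: the 14-item CFI total and the mADCS-PACC-style composite.

The Cognitive Function Instrument (CFI) asks 14 yes/no/maybe questions about
functional and cognitive decline over the past year; "yes" scores 1, "maybe"
0.5, "no" 0, giving a total in [0, 14].  Items answered "not applicable"
(driving, finances, work) receive the mean of the answered items.  A truly
blank item marks the whole instrument as missing, which downstream exclusion
rules act on.

The cognitive composite averages per-component z-scores (FCSRT total recall,
paragraph recall, digit symbol substitution, modified MMSE, animal fluency),
each standardised against the baseline mean/SD of the cognitively normal
reference group; lower values indicate poorer cognition.  Participants
missing some components receive the mean of the available z-scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateReferenceError, MalformedInputError

N_CFI_ITEMS = 14

#: legal item responses; "na" = not applicable, "blank" = truly missing
RESPONSES = ("yes", "no", "maybe", "na", "blank")

_ITEM_POINTS = {"yes": 1.0, "no": 0.0, "maybe": 0.5}

#: composite components, in canonical order
COMPONENTS = (
    "fcsrt_total_recall",
    "paragraph_recall",
    "digit_symbol",
    "mmmse",
    "animal_fluency",
)


@dataclass(frozen=True)
class CfiScore:
    """Scored CFI for one respondent at one visit."""

    total: float | None
    n_na: int
    is_missing: bool

    def __post_init__(self):
        if not self.is_missing and self.total is not None:
            assert 0.0 <= self.total <= N_CFI_ITEMS


@dataclass(frozen=True)
class CompositeReference:
    """Baseline mean/SD per component for the reference group."""

    means: Mapping[str, float]
    sds: Mapping[str, float]
    reference_n: int

    def __post_init__(self):
        for c in COMPONENTS:
            if c not in self.means or c not in self.sds:
                raise MalformedInputError(f"reference missing component {c!r}")
            if not self.sds[c] > 0:
                raise DegenerateReferenceError(
                    f"component {c!r} has non-positive SD")


def score_cfi(responses: Sequence[str]) -> CfiScore:
    """Score one 14-item CFI response set.

    Parameters
    ----------
    responses
        Exactly 14 strings, each one of ``yes``, ``no``, ``maybe``, ``na``
        (not applicable) or ``blank`` (truly missing; the empty string is
        accepted as an alias).

    Returns
    -------
    CfiScore
        ``total`` is the sum over the 14 items with "not applicable" items
        contributing the mean of the answered items.  The score is missing
        if any item is blank, or if every item is "not applicable".
    """
    responses = ["blank" if r in ("", None) or (isinstance(r, float) and math.isnan(r))
                 else str(r) for r in responses]
    if len(responses) != N_CFI_ITEMS:
        raise MalformedInputError(
            f"CFI requires exactly {N_CFI_ITEMS} items, got {len(responses)}")
    for r in responses:
        if r not in RESPONSES:
            raise MalformedInputError(f"unknown CFI response {r!r}")

    n_na = responses.count("na")
    if "blank" in responses:
        return CfiScore(total=None, n_na=n_na, is_missing=True)

    answered = [_ITEM_POINTS[r] for r in responses if r != "na"]
    if not answered:  # all items "not applicable": no information present
        return CfiScore(total=None, n_na=n_na, is_missing=True)

    mean_available = sum(answered) / len(answered)
    total = sum(answered) + n_na * mean_available
    return CfiScore(total=float(total), n_na=n_na, is_missing=False)


def fit_reference(
    baseline_components: pd.DataFrame,
    in_reference_group: Iterable[bool],
) -> CompositeReference:
    """Fit the composite reference from baseline rows.

    ``baseline_components`` holds one row per participant's baseline visit
    with the five component columns (missing values as NaN);
    ``in_reference_group`` flags rows belonging to the reference group
    (participants with a global CDR of 0 at baseline).  Mean and SD are
    computed per component over non-missing reference values; SD uses the
    n-1 denominator.
    """
    flags = np.asarray(list(in_reference_group), dtype=bool)
    if len(flags) != len(baseline_components):
        raise MalformedInputError("flags and component rows differ in length")
    ref = baseline_components.loc[flags]

    means, sds = {}, {}
    for c in COMPONENTS:
        if c not in ref.columns:
            raise MalformedInputError(f"missing component column {c!r}")
        vals = ref[c].dropna().to_numpy(dtype=float)
        if vals.size < 2:
            raise DegenerateReferenceError(
                f"component {c!r} has {vals.size} non-missing reference "
                "values; need at least 2")
        sd = float(np.std(vals, ddof=1))
        if sd == 0.0:
            raise DegenerateReferenceError(
                f"component {c!r} is constant in the reference group")
        means[c] = float(np.mean(vals))
        sds[c] = sd
    return CompositeReference(means=means, sds=sds, reference_n=int(flags.sum()))


def compute_composite(
    components: Mapping[str, float],
    ref: CompositeReference,
) -> float:
    """Average of available per-component z-scores; NaN if all are missing."""
    zs = []
    for c in COMPONENTS:
        x = components.get(c, np.nan)
        x = np.nan if x is None else float(x)
        if not math.isnan(x):
            zs.append((x - ref.means[c]) / ref.sds[c])
    return float(np.mean(zs)) if zs else float("nan")


def composite_column(components: pd.DataFrame, ref: CompositeReference) -> pd.Series:
    """Vectorised :func:`compute_composite` over a component DataFrame."""
    z = pd.DataFrame(index=components.index)
    for c in COMPONENTS:
        z[c] = (components[c] - ref.means[c]) / ref.sds[c]
    return z.mean(axis=1, skipna=True)
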