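"""Synthetic dyadic cohort generator.

Emulates a 4-year observational cohort of cognitively normal older adults,
each enrolled with a study partner (spousal or non-spousal), in which both
dyad members independently complete a 14-item report of the participant's
cognitive/functional decline at every annual visit while an objective
cognitive battery is administered.

Generative structure
--------------------
Each participant i carries a latent cognition trajectory

    c_i(t) = b_i + s_i * t + eps_it,

with random baseline level b_i, random slope s_i (mean slightly negative:
gradual decline) and visit noise eps_it.  The five battery components are
noisy linear reads of c_i(t) on component-specific scales; the composite
z-scores them against the baseline reference group and averages.

Reports are generated from *propensities to endorse decline*:

* participant propensity reads the trajectory ENDPOINT b_i + s_i * T — the
  participant senses where they are heading;
* partner propensity reads the CURRENT value c_i(t), with dyad-specific
  weight and noise (spousal partners are less noisy observers).

Propensities map to the 14 items through an ordered-logistic link (per-item
logistic noise with fixed no/maybe/yes thresholds), so higher propensity
monotonically shifts items toward "yes".  Designated items (driving,
finances, work) may instead be answered "not applicable"; whole instruments
go missing at a small rate; participants drop out with a constant annual
hazard and may return once for an off-schedule final visit.

Because informativeness is encoded structurally (endpoint vs current value)
rather than through correlation targets, which dyad member is informative
about which quantity is a recoverable ground truth for the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import P_ITEM_COLUMNS, S_ITEM_COLUMNS
from .errors import MalformedInputError

__all__ = ["LatentModel", "ReportModel", "CovariateModel", "MissingnessModel",
           "CohortParams", "generate_cohort", "scenario_presets"]

# ordered-logit thresholds carving no / maybe / yes on the propensity scale
_TAU_MAYBE = 1.0
_TAU_YES = 2.2
# items offering a "not applicable" answer (driving, finances, work)
NA_ITEM_INDICES = (7, 8, 9)

# component scales: (mean, loading on latent, residual SD)
_COMPONENT_SCALES = {
    "fcsrt": (75.0, 5.0, 4.0),
    "pr": (8.5, 1.8, 1.5),
    "dsst": (42.0, 6.0, 5.0),
    "mmmse": (95.8, 2.2, 1.6),
    "fluency": (18.0, 3.0, 3.5),
}
_P_COMPONENT_MISSING = 0.007


@dataclass(frozen=True)
class LatentModel:
    baseline_mean: float = 0.0
    baseline_sd: float = 1.0
    slope_mean: float = -0.10
    slope_sd: float = 0.15
    visit_noise_sd: float = 0.30


@dataclass(frozen=True)
class ReportModel:
    """Weights/noise linking latent cognition to report propensities.

    ``beta_p_future`` scales the participant's read of the (standardised,
    sign-flipped) trajectory endpoint; the ``beta_s_current_*`` scale the
    partner's read of current cognition.  ``beta_p_current`` and
    ``beta_s_future`` default to zero and exist to swap the roles (the
    role-reversed scenario gives the partner the endpoint read and the
    participant a noisy current read).  ``alpha_*`` set marginal endorsement
    levels (participants endorse slightly more decline than partners report,
    as observed in such cohorts).
    """

    beta_p_future: float = 1.2
    beta_s_current_spousal: float = 1.0
    beta_s_current_nonspousal: float = 0.5
    beta_p_current: float = 0.0
    beta_s_future: float = 0.0
    report_noise_sd_p: float = 0.6
    report_noise_sd_s_spousal: float = 0.5
    report_noise_sd_s_nonspousal: float = 1.4
    alpha_p: float = -0.65
    alpha_s: float = -1.35


@dataclass(frozen=True)
class CovariateModel:
    age_mean: float = 79.4
    age_sd: float = 3.6
    edu_mean: float = 15.1
    edu_sd: float = 2.9
    p_female_by_dyad: tuple[float, float] = (0.365, 0.759)  # (spousal, non-spousal)
    p_caucasian_by_dyad: tuple[float, float] = (0.915, 0.697)
    p_cvd: float = 0.66
    p_baseline_cdr_nonzero: float = 0.0  # raise to plant entry-criterion violations


@dataclass(frozen=True)
class MissingnessModel:
    p_item_na: float = 0.08
    p_instrument_missing: float = 0.01
    annual_dropout_hazard: float = 0.07
    p_return_visit: float = 0.5  # dropouts returning for one final visit


@dataclass(frozen=True)
class CohortParams:
    n_dyads: int = 450
    prop_spousal: float = 0.42
    years: int = 4
    latent: LatentModel = field(default_factory=LatentModel)
    report: ReportModel = field(default_factory=ReportModel)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    missingness: MissingnessModel = field(default_factory=MissingnessModel)
    seed: int = 0

    def validate(self) -> None:
        m, c = self.missingness, self.covariates
        probs = [self.prop_spousal, m.p_item_na, m.p_instrument_missing,
                 m.annual_dropout_hazard, m.p_return_visit, c.p_cvd,
                 c.p_baseline_cdr_nonzero, *c.p_female_by_dyad,
                 *c.p_caucasian_by_dyad]
        if any(not (0.0 <= q <= 1.0) for q in probs):
            raise MalformedInputError("probabilities must lie in [0, 1]")
        sds = [self.latent.baseline_sd, self.latent.slope_sd,
               self.latent.visit_noise_sd, self.report.report_noise_sd_p,
               self.report.report_noise_sd_s_spousal,
               self.report.report_noise_sd_s_nonspousal,
               c.age_sd, c.edu_sd]
        if any(s < 0 for s in sds):
            raise MalformedInputError("SDs must be non-negative")
        if self.n_dyads < 1 or self.years < 1:
            raise MalformedInputError("n_dyads and years must be positive")


def _items_from_propensity(prop: np.ndarray, rng: np.random.Generator,
                           ) -> np.ndarray:
    """Ordered-logit item draws: (n, 14) array of 'yes'/'maybe'/'no'."""
    n = prop.shape[0]
    u = rng.logistic(size=(n, 14)) + prop[:, None]
    out = np.full((n, 14), "no", dtype=object)
    out[u > _TAU_MAYBE] = "maybe"
    out[u > _TAU_YES] = "yes"
    return out


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Generate the long-format visit table; deterministic given the seed."""
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n, T = params.n_dyads, params.years
    lat, rep, cov, mis = (params.latent, params.report, params.covariates,
                          params.missingness)

    spousal = rng.random(n) < params.prop_spousal
    dyad_type = np.where(spousal, "spousal", "non_spousal")

    age = np.clip(rng.normal(cov.age_mean, cov.age_sd, n), 75.0, 97.0)
    education = np.clip(np.round(rng.normal(cov.edu_mean, cov.edu_sd, n)),
                        6, 20)
    p_female = np.where(spousal, *cov.p_female_by_dyad)
    female = rng.random(n) < p_female
    p_cauc = np.where(spousal, *cov.p_caucasian_by_dyad)
    caucasian = rng.random(n) < p_cauc
    cvd = rng.random(n) < cov.p_cvd
    cdr_global = np.where(rng.random(n) < cov.p_baseline_cdr_nonzero, 0.5, 0.0)

    b = rng.normal(lat.baseline_mean, lat.baseline_sd, n)
    s = rng.normal(lat.slope_mean, lat.slope_sd, n)

    # analytic standardisation of the quantities each dyad member reads
    end_mean = lat.baseline_mean + lat.slope_mean * T
    end_sd = float(np.hypot(lat.baseline_sd, lat.slope_sd * T)) or 1.0
    endpoint_z = (b + s * T - end_mean) / end_sd

    # dropout: first year (1..T) whose hazard draw fires; T+1 = completer
    haz = rng.random((n, T)) < mis.annual_dropout_hazard
    dropped_year = np.where(haz.any(axis=1), haz.argmax(axis=1) + 1, T + 1)
    returns = rng.random(n) < mis.p_return_visit
    return_month = 12.0 * (dropped_year - 1) + rng.uniform(2.0, 11.0, n)

    beta_s = np.where(spousal, rep.beta_s_current_spousal,
                      rep.beta_s_current_nonspousal)
    noise_s = np.where(spousal, rep.report_noise_sd_s_spousal,
                       rep.report_noise_sd_s_nonspousal)

    frames = []

    def visit_rows(mask: np.ndarray, t_cont: np.ndarray, visit_year: np.ndarray,
                   is_disc: bool) -> None:
        """Draw one visit for every participant; keep rows where mask holds.

        Draws are made for the full cohort so the random stream does not
        depend on who is still enrolled, keeping the table reproducible
        under parameter changes that only affect masking.
        """
        c = b + s * t_cont + rng.normal(0.0, lat.visit_noise_sd, n)
        cur_sd = np.sqrt(lat.baseline_sd ** 2 + (lat.slope_sd * t_cont) ** 2
                         + lat.visit_noise_sd ** 2)
        cur_mean = lat.baseline_mean + lat.slope_mean * t_cont
        current_z = (c - cur_mean) / np.where(cur_sd > 0, cur_sd, 1.0)

        comp_cols = {}
        for name, (mu, load, sd_e) in _COMPONENT_SCALES.items():
            vals = mu + load * c + rng.normal(0.0, sd_e, n)
            if name == "mmmse":
                vals = np.minimum(vals, 100.0)
            vals[rng.random(n) < _P_COMPONENT_MISSING] = np.nan
            comp_cols[name] = vals

        cdr_sb = np.maximum(
            0.0, np.round(0.05 - 0.12 * c + rng.normal(0.0, 0.18, n), 1))

        prop_p = (rep.alpha_p - rep.beta_p_future * endpoint_z
                  - rep.beta_p_current * current_z
                  + rng.normal(0.0, rep.report_noise_sd_p, n))
        prop_s = (rep.alpha_s - beta_s * current_z
                  - rep.beta_s_future * endpoint_z
                  + rng.normal(0.0, noise_s, n))
        p_items = _items_from_propensity(prop_p, rng)
        s_items = _items_from_propensity(prop_s, rng)
        for items in (p_items, s_items):
            for j in NA_ITEM_INDICES:
                na = rng.random(n) < mis.p_item_na
                items[na, j] = "na"
            blank = rng.random(n) < mis.p_instrument_missing
            items[blank, :] = ""

        row = {
            "participant_id": np.array([f"P{i:04d}" for i in range(n)]),
            "visit_year": visit_year,
            "months_from_baseline": 12.0 * t_cont,
            "is_discontinuation_visit": np.full(n, is_disc),
            "dyad_type": dyad_type,
            "cdr_global_baseline": cdr_global,
            "cdr_sb": cdr_sb,
            "age": np.round(age, 1),
            "education": education,
            "sex": np.where(female, "female", "male"),
            "race_caucasian": caucasian.astype(int),
            "cvd_history": cvd.astype(int),
        }
        for k, (colp, cols) in enumerate(zip(P_ITEM_COLUMNS, S_ITEM_COLUMNS)):
            row[colp] = p_items[:, k]
            row[cols] = s_items[:, k]
        for name, vals in comp_cols.items():
            row[name] = vals
        frames.append(pd.DataFrame(row).loc[mask])

    for t in range(T + 1):
        active = t < dropped_year
        visit_rows(active, np.full(n, float(t)), np.full(n, t), is_disc=False)

    disc_mask = (dropped_year <= T) & returns
    visit_rows(disc_mask, return_month / 12.0,
               np.full(n, -1), is_disc=True)

    out = pd.concat(frames, ignore_index=True)
    out.loc[out["is_discontinuation_visit"], "months_from_baseline"] = (
        np.round(return_month[disc_mask], 1))
    out.loc[out["is_discontinuation_visit"], "visit_year"] = np.nan
    return out.sort_values(
        ["participant_id", "months_from_baseline"]).reset_index(drop=True)


def scenario_presets() -> dict[str, CohortParams]:
    """Named generative scenarios used by tests and documentation.

    * ``paper_like`` — participants informative about future cognition;
      spousal partners are accurate observers of current cognition while
      non-spousal partners are weak/noisy.
    * ``null`` — no report carries any signal.
    * ``partner_dominant`` — roles reversed: partners read cognition
      accurately, participants barely at all.
    """
    base = CohortParams()
    null_report = ReportModel(beta_p_future=0.0, beta_s_current_spousal=0.0,
                              beta_s_current_nonspousal=0.0)
    # structural role swap: partner reads the trajectory endpoint, the
    # participant becomes a weak, noisy observer of current cognition
    reversed_report = ReportModel(
        beta_p_future=0.0, beta_p_current=0.5, report_noise_sd_p=1.4,
        beta_s_current_spousal=0.0, beta_s_current_nonspousal=0.0,
        beta_s_future=1.2,
        report_noise_sd_s_spousal=0.5, report_noise_sd_s_nonspousal=0.6)
    return {
        "paper_like": base,
        "null": replace(base, report=null_report),
        "partner_dominant": replace(base, report=reversed_report),
    }


def get_preset(name: str, **overrides) -> CohortParams:
    presets = scenario_presets()
    if name not in presets:
        raise MalformedInputError(
            f"unknown preset {name!r}; available: {sorted(presets)}")
    return replace(presets[name], **overrides) if overrides else presets[name]
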