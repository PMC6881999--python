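# dyadinform

Who provides more information about a clinical-trial participant's
cognition — the participant themself, or the study partner who enrols with
them?

Preclinical Alzheimer's disease trials enrol cognitively normal older
adults together with a study partner (a spouse or another knowledgeable
informant) who reports on the participant's everyday cognition. Whether the
partner's report adds information beyond the participant's own is an open
design question for such trials. `dyadinform` implements a reusable
pipeline for answering it in dyadic cohorts:

* **Instrument scoring** — the 14-item Cognitive Function Instrument
  (CFI; yes = 1, maybe = 0.5, no = 0, total 0–14, with "not applicable"
  items imputed at the mean of the answered items), completed independently
  by participant and partner at each annual visit.
* **Cognitive composite** — a PACC-style composite: per-component z-scores
  (FCSRT total recall, paragraph recall, digit-symbol substitution,
  modified MMSE, animal fluency) against the baseline mean/SD of the
  cognitively normal reference group, averaged over available components;
  lower = poorer cognition.
* **eMVI** — the headline statistic. A regression random forest predicts
  the composite from both CFI scores plus covariates (CDR-SB, age,
  education, sex, race, cardiovascular history); variable importance is a
  depth-weighted split frequency,

  ```
  imp_j = Σ_d w_d · f_{j,d},   f_{j,d} = share of depth-d splits on predictor j,
  w_d ∝ d^(-γ)  over occupied depths d ≤ D   (defaults D = 4, γ = 2),
  ```

  so splits nearer the root weigh more and the vector sums to 1. Because a
  single forest's importance depends on its seed, the forest is refit R
  times (default R = 100) with seeds `base + 1 … base + R`; the **estimated
  mean variable importance (eMVI)** is the replicate mean and its 95%
  uncertainty bounds are the 2.5th/97.5th replicate percentiles.
* **Designs and strata** — prospective (baseline CFI predicting the
  composite 1–4 years later) and cross-sectional (same-year CFI and CDR-SB)
  analyses, stratified by dyad type (spousal / non-spousal) and by
  quartile of the baseline composite (quartile 1 = poorest cognition),
  with the cohort's exclusion rules (baseline CDR-Global 0 entry, missing
  instrument handling, mapping of early discontinuation visits to the
  closest annual visit) applied and logged.
* **Adjusted linear models** — OLS with the same adjustment set, reported
  per stratum for magnitude and direction.
* **Synthetic cohorts** — a generator of dyadic visit tables with a latent
  cognition trajectory per participant, participant reports reading the
  trajectory's *future endpoint* and partner reports reading its *current
  value* (spousal partners less noisily), item-level responses, "not
  applicable" items, instrument missingness and dropout — so the whole
  pipeline is testable with known ground truth.

## Worked example

```bash
dyadinform simulate --preset paper_like --n 450 --seed 7 --out cohort.csv
dyadinform run --input cohort.csv --mode prospective --years 1 \
    --dyads all --quartiles all --n-forests 20 --n-trees 200 \
    --seed 11 --out results/
```

which prints `completed 1/1 strata; outputs in results/` and writes
`emvi.csv` with one row per predictor (values from this exact command,
rounded):

```
mode,year,dyad,quartile,predictor,emvi,ub_lower,ub_upper,R
prospective,1,all,all,p_cfi,0.3633,0.3335,0.3995,20
prospective,1,all,all,s_cfi,0.1963,0.1682,0.2265,20
prospective,1,all,all,cdr_sb,0.2226,0.2012,0.2566,20
...
```

Read: in this synthetic cohort the participant's own baseline report
(`p_cfi`, eMVI 0.36) carries clearly more of the forest's early splitting
decisions about the year-1 composite than the partner's report (`s_cfi`,
0.20), and their 95% uncertainty bounds do not overlap — the pipeline
recovers the generator's ground truth, in which participants are the
informative dyad member about future cognition. `coefficients.csv` adds the
signed OLS view (more endorsed decline at baseline → lower later
composite), `exclusions.csv` logs every excluded row with its rule, and
`forest_plot.csv` is the plot-ready participant-vs-partner table per
stratum-year cell.

The same analysis runs on real data: provide a long-format visit CSV (one
row per participant-visit; see `docs/methods.md` for the column
dictionary) instead of a preset.

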