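# Methods

## The question and the estimand

In a dyadic cohort where a participant and their study partner each
complete the 14-item Cognitive Function Instrument (CFI) about the
participant's cognitive/functional decline, we ask which report carries
more information about an objective cognitive composite — prospectively
(baseline reports, later outcome) and cross-sectionally (same-visit reports
and outcome). "Information" is operationalised as the share of early
splitting decisions a regression random forest devotes to each report when
both are offered simultaneously alongside the adjustment covariates. This
is a relative, model-based notion of informativeness, not a causal effect;
the adjusted OLS coefficients reported alongside supply magnitude and
direction.

## Instrument scoring

CFI items score yes = 1, maybe = 0.5, no = 0, summed over 14 items
(range 0–14). Items answered "not applicable" (available on the driving /
finances / work questions) contribute the mean of the answered items, so a
response set with k answered items summing to S totals S·14/k. A truly
blank item marks the instrument as missing: the source of truth for
missingness is the record-level exclusion step, so no partial total is ever
propagated. An all-not-applicable instrument is likewise missing (no
information present). The imputation mean is not rounded.

## The cognitive composite

The composite averages per-component z-scores of five battery components
(FCSRT total recall, paragraph recall, digit-symbol substitution, modified
MMSE, animal fluency). The reference for each z-score is the baseline mean
and SD (n−1 denominator, the standard choice when standardising against a
sample) over the cognitively normal reference group (baseline CDR-Global
0), computed per component over the rows non-missing *for that component*.
Participants missing some components receive the mean of the available
z-scores; all-missing gives a missing composite. Lower values mean poorer
cognition. A component that is constant or has fewer than two values in
the reference group is a hard error rather than a silent NaN.

## Forest and importance statistic

Each forest is an ensemble of greedy CART regression trees: at every node,
`mtry` candidate predictors are drawn without replacement and the split
maximising the between-child variance reduction n_L·n_R/n·(ȳ_L − ȳ_R)² is
taken, with thresholds at midpoints between adjacent distinct sorted values
and both children required to keep at least `min_node_size` rows. Ties
break toward the lowest predictor index, then the lowest threshold, making
fits deterministic given the seed. Trees are grown on without-replacement
subsamples; per-tree random streams are spawned from the forest seed.

Variable importance is a depth-weighted split frequency. With f_{j,d} the
share of depth-d internal nodes (root depth 1, pooled over trees) splitting
on predictor j, the importance of j is

    imp_j = Σ_{d∈S} d^(−γ) f_{j,d} / Σ_{d∈S} d^(−γ),

where S is the set of depths ≤ D containing at least one split. The vector
is non-negative and sums to 1 whenever any split exists; a splitless forest
yields the zero vector with a warning. Defaults D = 4 and γ = 2 follow the
convention of split-frequency importance in generalized-random-forest
software: the root split weighs 16× a depth-4 split, so the statistic reads
as "who gets the early, high-leverage splits". Categorical covariates enter
as indicator columns (all covariates here are binary or numeric, so no
summing over indicator groups is needed). Honest splitting (sample
splitting between partition and leaf estimation) is not implemented:
importance depends only on split structure, which honesty does not change
qualitatively.

Forest defaults: 500 trees, mtry = ⌈p/3⌉, min_node_size 5, subsample
fraction 0.5 — standard regression-forest conventions.

## eMVI and uncertainty bounds

Because importance varies with the forest seed, the forest is refit R times
(default R = 100) on the *same* data with seeds base+1 … base+R. The eMVI
is the per-predictor mean over replicates; the 95% uncertainty bounds are
the empirical 2.5th/97.5th percentiles of the replicate values
(linear-interpolation quantiles, the common scientific-computing default).
These bounds quantify Monte-Carlo seed variability only — the data are not
resampled — so they are not confidence intervals, and comparisons between
predictors report ordering plus a bound-overlap flag rather than a p-value.

## Cohort construction

* **Visit alignment.** Early discontinuation visits map to the closest
  annual visit, `round(months/12)` with exact half-year ties rounding
  *down* (conservative toward the earlier assessment); a discontinuation
  visit whose year is already occupied by a regular visit is dropped. Two
  regular visits in one year is malformed input.
* **Exclusions.** Cohort entry requires baseline CDR-Global 0. The
  prospective analysis drops participants whose baseline participant or
  partner CFI is missing. The cross-sectional analysis drops individual
  follow-up rows whose same-year CFI is missing (the baseline row is kept
  as the source of covariates and quartile anchoring, since baseline CFI
  does not enter cross-sectional designs), and drops participants missing
  the baseline composite, which anchors the quartile strata. Every
  exclusion is logged with its rule, and the operation is idempotent.
* **Quartiles.** Baseline-composite quartiles use linear-interpolation
  percentiles with left-closed boundaries (≤ Q1 → quartile 1, the poorest
  performers); ties therefore fall into the lower stratum.
* **Designs.** The outcome is always the composite at the outcome year
  (1–4). Prospective designs take CFI and CDR-SB from baseline,
  cross-sectional designs from the outcome year; age, education, female
  indicator, Caucasian indicator and cardiovascular history always come
  from baseline, matching the adjustment set and the dichotomous coding of
  the cohort's descriptive table. Rows with any missing predictor or
  outcome are dropped (complete case — covariate missingness is rare and
  never modelled), and the drop is visible in the logged counts.

## Linear models

Per stratum, OLS of the outcome on the same predictors with an intercept;
conventional (non-robust) standard errors from (XᵀX)⁻¹σ̂²,
σ̂² = RSS/(n−p−1). Rank deficiency raises an error naming the first
offending column. No multiplicity adjustment is applied across strata or
years; estimates are reported raw per cell.

## Synthetic cohorts: what they emulate and what they do not

Each participant carries a latent trajectory c_i(t) = b_i + s_i·t + ε_it
(defaults: b ~ N(0,1), s ~ N(−0.10, 0.15²) — slow heterogeneous decline —
visit noise SD 0.30). Battery components are linear reads of c_i(t) on
realistic scales plus noise; 0.7% of components go missing. CDR-SB is a
left-censored noisy read of −c (mostly zero, mean ≈ 0.08, as in a
cognitively normal cohort).

Reports are generated from propensities to endorse decline pushed through
an ordered-logistic link (per-item logistic noise, thresholds 1.0 / 2.2
carving no / maybe / yes), so the scoring path — including "not applicable"
on the three designated items (rate 0.08) and whole-instrument missingness
(rate 0.01) — is exercised end to end. The structural assumption that makes
the headline contrast a recoverable ground truth: the participant
propensity reads the standardised trajectory *endpoint* b + s·T (weight 1.2,
noise SD 0.6), the partner propensity reads the standardised *current*
value c_i(t) with dyad-specific quality (spousal weight 1.0 / noise 0.5;
non-spousal weight 0.5 / noise 1.4). Intercepts (−0.65 participant, −1.35
partner) put baseline CFI means near the cohort descriptives (participants
≈ 2, partners ≈ 1, participants endorsing more decline than partners).
Covariates follow the descriptive table's coarse structure: 42% spousal
dyads; age ≈ N(79.4, 3.6) truncated at 75; education ≈ N(15.1, 2.9);
female proportion 36.5% (spousal) vs 75.9% (non-spousal); Caucasian 91.5%
vs 69.7%; cardiovascular history 66%. Dropout is a constant annual hazard
(0.07); half of dropouts return once for an off-schedule final visit,
exercising the alignment rules.

Presets: `paper_like` (as above), `null` (all report weights zero) and
`partner_dominant` (roles swapped structurally: the partner reads the
endpoint, the participant a weak noisy current read — the mirror image of
`paper_like`). The strength-only alternative (partner keeps the current
read, merely with more weight) was rejected for the reversal scenario
because conditioning on the lowest baseline quartile range-restricts
exactly the quantity such a partner reads, attenuating the planted signal;
a genuine role swap keeps the two scenarios symmetric.

What the generator does **not** emulate: learning effects and practice
gains in the battery, partner replacement, non-linear or non-Gaussian
trajectories, informative (cognition-dependent) dropout, item-level
heterogeneity of the CFI, and any biomarker structure. Passing tests
therefore show that the pipeline recovers the planted informativeness
ordering under its own assumptions — not that those assumptions hold in any
real cohort.

## Numerical and size choices

Unit and end-to-end tests run the generator at 80–2,000 dyads and forests
of 10–200 trees; the headline-recovery check uses 450-dyad cohorts, R = 20
replicates and 200-tree forests over 10 independent seeds per scenario,
with the prospective non-spousal lowest-quartile stratum evaluated at
year 2 (mid-study: late enough for slopes to separate endpoint from
baseline, early enough that dropout leaves the stratum well populated).
These sizes keep the full suite and the acceptance script to a few minutes
on one core while leaving the Monte-Carlo margins comfortable. All
tolerances are stated at the point of use: exact identities at 1e−10/1e−12,
oracle agreement at 1e−8 (OLS) and 1e−13 (importance traversal).

## Input column dictionary

One row per participant-visit: `participant_id`; `visit_year` (0–4, empty
for discontinuation visits); `months_from_baseline`;
`is_discontinuation_visit`; `dyad_type` (`spousal`/`non_spousal`);
`cdr_global_baseline`; `cdr_sb`; `age`; `education`; `sex`
(`female`/`male`); `race_caucasian` (0/1); `cvd_history` (0/1); CFI items
`p_cfi_01..p_cfi_14`, `s_cfi_01..s_cfi_14` with values
`yes`/`no`/`maybe`/`na` or empty for blank; raw components `fcsrt`, `pr`,
`dsst`, `mmmse`, `fluency` as reals or empty.

## Known limitations

The importance statistic inherits the usual biases of split-frequency
measures (preference for high-cardinality predictors); within one panel all
continuous predictors here have comparable cardinality, and conclusions are
drawn from the participant-vs-partner *contrast*, which both reports share.
Uncertainty bounds do not reflect sampling variability of the cohort. The
forest is not honest, and hyperparameters (trees per forest, mtry, depth
cap, decay) are conventions, not estimates; sensitivity to the decay
exponent is the main untested degree of freedom.
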