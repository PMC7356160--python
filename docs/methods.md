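# Methods

This note records the modelling choices behind `cdintake`: what is computed,
under which assumptions, and what the synthetic cohorts do and do not show.

## Intake model

Cd intake is assessed by individual food analysis: each questionnaire item's
intake (g/day) is multiplied by an effective Cd concentration (mg/kg ≡ µg/g)
and an optional mass-change factor, and summed. Units make g/day × mg/kg
come out in µg/day with no conversion constant. Weekly intake per body
weight is `7 × daily total / body weight` and is compared with the tolerable
weekly intake (TWI) of 7 µg/kg BW/week; the threshold is configurable, and a
value exactly at the threshold counts as exceeding (the exceedance bins are
labelled `<7` / `≥7`).

Reconciliation between the questionnaire and the measured foods is
declarative (`mapping.py` + `data/default_mapping.yaml`): weighted
component splits (boiled barley-rice = 70% rice + 30% wheat flour; the joint
noodle item split half udon, half soba), proxy assignments (wheat-flour
noodles priced at the udon concentration; pastries at white bread; sweets at
the sweet-bun concentration), averages over member foods (tofu, leafy
greens, tubers, shrimp, fish eggs, non-oyster shellfish, liver), and
explicit exclusions for foods in which Cd was never detected (meat, eggs,
milk, brewed tea, fruit). Component weights must sum to one; every
referenced food must exist in the concentration table; coverage validation
reports unmapped questionnaire items, never-referenced concentration items
(e.g. foods measured but not assessed by the questionnaire, such as kelp and
hijiki — a recognised source of underestimation), and explicit exclusions.

Rice is special throughout: each subject's own measured rice Cd is used; a
brown-rice eater's concentration is multiplied by 0.9 (polished-rice
equivalent — polishing removes about 10% of the Cd); a missing measurement
is backfilled with the area-specific geometric mean. The questionnaire
reports *cooked* rice while Cd is measured on raw rice, so intake runs on
the synthetic cohorts pass a rice mass-change factor (see below); the
mapping default is a neutral 1.0 because the published mass-change table is
external to the data modelled here.

Subject exclusion rules: energy intake ≤ 1000 or ≥ 3500 kcal/day, or zero
rice consumption. Boundaries are implemented exactly as stated (≤ / ≥), and
the filter is idempotent.

## Concentration data

Concentrations are carried per replicate with left-censoring: a value below
the detection limit (0.01 mg/kg for cereal-group foods, 0.005 mg/kg
otherwise, 0.001 mg/L for drinking water) is a censored record holding only
its LOD. Censored values enter computation only through an explicit
substitution rule: `zero` (default for intake contributions — foods in which
Cd was never detected contribute nothing), `half_lod` (default for
summaries) or `lod`. Item summaries use the arithmetic mean except rice,
whose clearly lognormal distribution is summarised by the geometric mean;
requesting a GM with a zero-substituted censored value is an error that
points to a nonzero substitution rule.

The packaged table transcribes a published market survey (~100 food items,
two areas) as printed summaries (n, mean, range). Raw replicates were never
published; `expand_summary` reconstructs per item `n` replicate values with
the printed range endpoints fixed and a constant interior solved so the
recomputed mean (log-scale for the rice GM) reproduces the printed one.
Where the printed rounded mean is not exactly attainable inside the printed
range, the interior is clipped and the recomputed mean agrees with the
printed one to the print precision (10⁻³). Two printed summaries are
internally inconsistent (a mean below the minimum achievable given the
printed range); the fixtures keep the printed ranges and the tests document
the exception. Range endpoints printed as "<LOD" are stored at the LOD,
matching the printed range.

## Statistical procedures

All test statistics are hand-implemented; scipy supplies only distribution
functions (χ², Student t, normal, studentized range).

* **Median test** (Brown–Mood): pooled grand median; counts above vs
  at-or-below per group; Pearson χ² with 1 df, ties in the ≤ cell, no
  continuity correction by default (Yates available by flag). A fully tied
  sample returns a degenerate table with p = 1.
* **χ² 2×2**: Pearson form Σ(O−E)²/E, upper-tail p on 1 df; zero marginals
  are an error.
* **Smirnov–Grubbs**, two-sided, iterative: G = max|xᵢ−x̄|/s against the
  critical value ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) t-quantile
  on n−2 df; the extreme point is removed while G exceeds the critical value
  (α = 0.05 default, removals unbounded unless capped). In the pipeline the
  screen is applied to **log** weekly intakes: under the lognormal model the
  log scale is where the normal-theory test is valid, and on the raw scale an
  iterative Grubbs screen would cascade through the natural right tail of a
  skewed cohort rather than isolate genuinely aberrant subjects.
* **Steel–Dwass**: for each pair of groups, mid-ranks on the two groups
  alone; rank sum standardised with mean nᵢ(nᵢ+nⱼ+1)/2 and tie-corrected
  variance nᵢnⱼ(nᵢ+nⱼ+1)/12 × (1 − Σ(t³−t)/(N³−N)); √2·|z| referred to the
  studentized range for k groups, ∞ df. This is the standard large-sample
  form; exact small-sample tables are out of scope. At k = 2 the decision
  coincides with the two-sided rank-sum normal approximation.
* **t-test**: pooled-variance two-sided form; sample SDs use n−1 throughout.

## Lognormal Monte Carlo

The weekly-intake distribution is fitted either by MLE (mean/SD of logs,
n−1) on a screened cohort, or by quantile matching from a printed summary:
µ = ln(median), σ = ln(q75/q25)/(2·z₀.₇₅) with z₀.₇₅ ≈ 0.67449. Quantile
matching reproduces the median exactly and the quartile ratio exactly; both
quartiles individually only when they are symmetric on the log scale. The
simulation draws 10,000 values (numpy `default_rng`, seed mandatory in the
CLI and recorded in the report) and reports median, 5–95th percentiles and
range; the range is reported but treated as unstable (extreme order
statistics). The model-based exceedance is the closed-form upper tail at the
TWI.

Quantile convention everywhere (cohort summaries and simulation summaries):
linear interpolation of order statistics (the common "type 7" default);
alternative conventions would be a one-line switch where percentiles are
computed.

## Synthetic cohorts

`synthetic.py` generates cohorts in which every published summary acts as a
distributional constraint:

* age from the published decade-strata counts (uniform within band);
  height, weight, energy and cooked-rice intake from normal distributions
  with the published means/SDs, truncated at the published ranges;
* individual rice Cd lognormal around the published area GM (0.158 / 0.109
  mg/kg), with log-sd 0.667 (A) and 0.827 (B) chosen so the modelled
  fraction of rice above the 0.4 mg/kg safety standard matches the published
  8.2% / 5.8%;
* a single lognormal **non-rice** daily Cd intake, spread over a fixed
  six-item basket (one representative item per reporting subgroup, shares
  derived from the published subgroup medians renormalised) by inverting the
  resolved concentrations — so the full mapping/intake machinery reproduces
  the drawn total exactly;
* a rice mass-change factor of 0.48 (raw-equivalent per gram cooked rice):
  the published rice-Cd GM × mean cooked-rice intake is about twice the
  published median rice-Cd intake, consistent with cooked-to-raw mass
  conversion of roughly this size;
* 5% brown-rice eaters (value not published; a small minority consistent
  with polished rice being the staple), and one missing rice measurement in
  area A.

The non-rice (µ, σ) are calibrated by a damped fixed-point search under
common random numbers so the cohort's weekly-intake quartiles match the
published ones (tolerance 3%, with a final location polish that pins the
median); calibration evaluates quantiles on an enlarged 50,000-subject
cohort so it does not absorb single-draw noise, using a closed-form weekly
intake that is provably identical (and tested to machine precision) to the
intake engine's output. The calibrated values are frozen in the packaged
presets.

What the synthetic cohorts do **not** emulate: correlation between food
items (beyond rice × rice-Cd), seasonal variation, measurement error in the
questionnaire, and any dependence of diet on age or body size. Passing tests
therefore demonstrate the pipeline arithmetic and the distributional
calibration, not the behaviour of real dietary data.

## Problem sizes and numerical choices

Tests run the study-sized cohorts (712 and 432 subjects), 10,000-draw
simulations, and 10,000-replicate null simulations for the type-I-error
checks of the median test and t-test; the whole suite completes in a few
seconds on one CPU. Weight-sum validation uses a 10⁻⁹ tolerance; fixture
mean reproduction is asserted at the 10⁻³ print precision; subgroup
additivity at machine precision. Degenerate inputs (constant cohorts,
zero-variance samples, empty strata, zero marginals) return explicit
degenerate results or raise typed errors rather than NaNs.

## Known limitations

* The reconstructed concentration replicates match printed n/mean/range but
  not the unpublished within-item spread; per-item variance-sensitive
  analyses should not rely on them.
* The questionnaire catalog is limited to the items named in the published
  reconciliation; real DHQ exports with other item names pass through as
  unmapped (logged, zero contribution).
* Monthly tolerable-intake accounting is not implemented; the weekly
  threshold is configurable but fixed in form.
* The Steel–Dwass implementation is the asymptotic version; with very small
  strata (n < ~5) its family-wise control is approximate.
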