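# Methods

`sgaskit` validates a four-item postnatal maturity score against imperfect
gestational-age (GA) references. This note records the models, the default
parameters and why they were chosen, the numerical decisions, and what the
synthetic-cohort results do and do not demonstrate.

## Scoring

The four items — posture (0..+4), skin (−1..+5), breast (−1..+4), genitals
(−1..+4) — are validated against their closed ranges and summed; the total
lies exactly in [−3, 17] (verified by enumeration of all 1,512 item
combinations). Classification is strict: `preterm` iff total < cutoff. Two
cut-off conventions circulate for this instrument — the original app rule
(<14) and the data-driven rule (<13). The package default is 13, because the
tree-based cut-off discovery and all downstream accuracy analyses in the
validation literature use it; 14 remains one flag away (`APP_CUTOFF`).
Averaged two-assessor totals may be half-integers; the same strict
inequality applies.

## Synthetic cohort

The generator emulates a facility-based cohort of singleton live births in
which true GA is never observed downstream. Structure and defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| `n_births` | 10,000 | — | a realistic large validation cohort; analyses are O(n) |
| `preterm_target` | 0.08 | — | latent (true) preterm prevalence; reference-standard prevalences then land in the 6–10% band typical of facility cohorts |
| `ga_sd` | 1.8 | weeks | spread of the truncated normal on [24, 43]; the location is *solved* (Brent) so P(GA < 37) equals the target |
| `lmp_error_sd` | 1.0 | weeks | menstrual-recall error; combined with USG error it retains ~60% of records in the 1-week dating-agreement window and ~90% in the 2-week window |
| `usg_error_sd_base`, `usg_error_slope` | 0.2, 0.015 | weeks, weeks/week | ultrasound dating error grows linearly with GA at scan (late scans date pregnancies poorly); at a 32-week scan the SD is ~0.7 weeks |
| `usg_scan_ga_mean/sd` | 32, 6 | weeks | most scans in such settings happen in the third trimester; clipped to [6, GA at birth] |
| `bw_intercept`, `bw_slope`, `bw_sd` | −3.2, 0.155, 0.35 | kg, kg/week, kg | mean 3.0 kg at 40 weeks, 2.5 kg a little below 37 weeks; floor 0.3 kg; gives a ~19% low-birthweight fraction |
| `maturity_sd` | 2.5 | weeks | per-newborn biological deviation of maturity from GA, shared by both assessors and all items |
| `rater_noise_sd` | 2.0 | weeks | independent per-assessor, per-item perception noise |
| item thresholds | spread over 25–38.5 weeks | weeks | the expected total crosses the <13 cut-off a little below 37 weeks of perceived maturity, yielding the characteristic low-Se (~0.4), high-Sp (~0.9) screening profile |

Item scores are produced by discretizing a perceived maturity age
(true GA + shared biological deviation + independent rater noise) against
strictly increasing per-item thresholds, so expected scores are monotone in
GA and `rater_noise_sd = 0` makes the two assessments identical. Identical
seeds give bit-identical cohorts (single `numpy` Generator, fixed draw
order).

Eligibility follows the dating-agreement design: a record is analysable when
|GA_LMP − GA_USG| ≤ tolerance, with the boundary inclusive (a tie at exactly
the tolerance is eligible; configurable in principle by passing a slightly
smaller tolerance). GA is stored in decimal weeks and the preterm threshold
is strict, so a birth at 36.9 weeks is preterm.

What the generator does **not** emulate: digit preference and outright recall
failure in LMP (errors are Gaussian, so the 2-week window retains more than
field studies report), growth restriction (birthweight depends on GA only),
multiple gestation, facility-level case-mix differences (facility labels are
exchangeable by construction, which is exactly what the stratified
Mantel–Haenszel null checks assume), and any dependence of assessor noise on
maturity itself. Passing tests therefore demonstrate *internal correctness
of the estimators and pipeline*, not field performance of the instrument.

## Agreement

Lin's CCC uses population (1/n) moments,
ρc = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²), with the Fisher-z interval using
Lin's large-sample variance; inputs where both sequences are constant with
equal means raise a degenerate-input error (0/0), and |ρc| → 1 collapses the
CI to the point estimate rather than dividing by zero on the z scale.
Fleiss' kappa uses pooled category marginals — the correct chance correction
when each newborn is rated by two assessors drawn from a rotating pool — with
the Fleiss–Nee–Landis variance for the interval. The agreement panel reports
kappa twice: on the two assessors' raw totals as categorical ratings
(complementing the CCC), and on the dichotomous preterm/term calls. An
alternative construction sometimes described — kappa "on the score
difference" — does not define an n×m rating matrix (the |difference| is one
number per newborn), so the panel reports the |difference| distribution
(bins 0/1/2/3/4+) as its own table instead.

## Accuracy

Proportions use Wilson score intervals by default (exact Clopper–Pearson via
`ci_method`); likelihood ratios use Simel's log-method intervals; Sp = 1
yields LR⁺ = ∞ with a flag rather than an exception. The AUC is the
Mann–Whitney concordance probability with half credit for ties; for a
monotone univariate logistic model the predicted-probability AUC equals the
raw-marker AUC, which is the identity implemented (markers where *low* means
positive are negated first). The DeLong structural-component variance gives
the CI, with a seeded bootstrap fallback when that variance degenerates
(e.g. constant markers). Mantel–Haenszel pooling, the
Robins–Breslow–Greenland variance and the Breslow–Day test are delegated to
`statsmodels.stats.contingency_tables.StratifiedTable`; strata containing a
zero cell receive a 0.5 continuity correction (that stratum only) and are
flagged. When a family of stratified comparisons is emitted, a Bonferroni
per-comparison α = 0.05/k is available via `bonferroni_alpha`, with k the
number of comparisons in the emitted table.

## Classification tree

Greedy binary recursive partitioning with deviance impurity by default (the
convention of the classic R tree grower; Gini optional). Candidate
thresholds are midpoints between consecutive distinct values; a split is
accepted only if both children have ≥ `min_leaf` (default 7) records, the
node has ≥ `min_split` (default 20), depth < `max_depth` (default 4) and the
impurity decrease is positive. These defaults produce the small readable
trees (a handful of risk groups ordered by preterm probability) that the
clinical use case calls for; no pruning or cross-validation is applied, so
the tree is a deterministic function of the data. Ties between equal-gain
splits resolve to the first predictor in insertion order and the smallest
threshold. Reported score cut-offs snap the half-integer midpoint up to the
smallest integer ≥ threshold, so that "score < c" reproduces the split;
continuous predictors (birthweight) keep the raw midpoint.

## Hui–Walter latent class model

J ≥ 3 binary tests, one population, conditional independence given the
latent class; 2^J − 1 ≥ 2J + 1 degrees of freedom make the single-population
J = 3 case exactly identified (perfect-fit residuals are expected there, so
goodness-of-fit is only meaningful for J > 3 and is not reported for J = 3).
EM maximizes the multinomial pattern likelihood: E-step computes each
pattern's posterior probability of the diseased class, M-step re-estimates
(π, Se, Sp) as count-weighted proportions. Defaults: 20 starts (one
moment-flavoured, 19 uniform-random from a fixed master seed), stop when the
log-likelihood gain falls below 1e−8, cap 5,000 iterations. Monotonicity of
the likelihood is asserted on every iteration. The mirrored solution
(π → 1−π, Se ↔ 1−Sp) is resolved by requiring Se_j + Sp_j ≥ 1 for a majority
of tests. Confidence intervals are nonparametric bootstrap percentiles
(multinomial resamples of the pattern counts, default 500, refitted from the
point estimate); boundary solutions (any parameter within 1e−6 of 0 or 1)
are flagged. Per-test LR⁺ = Se_j/(1 − Sp_j) is derived on the fit.

**Known limitation.** On cohorts from the synthetic generator the
conditional-independence assumption is mildly violated: LMP and USG errors
both ride on the continuous GA, and the eligibility filter conditions on
their agreement. Averaged over seeds the parameter estimates track the
generator-implied values closely in the mean, but individual parameters —
most visibly the LMP sensitivity — carry an upward bias of a few points.
This is a property of the model under dependence, not an estimation defect:
on data simulated from the latent-class model itself, recovery is within a
fraction of a percentage point (see `scripts/acceptance.py`). Real cohorts
share this dependence structure, so latent-class Se/Sp from such designs
should be read as approximations.

## Incremental value

Old model: logistic on birthweight; new model: birthweight + total score
(maximum likelihood via statsmodels' Newton/IRLS, convergence declared when
the score equations hold to < 1e−4 in the gradient; complete separation
raises an explicit error rather than silently diverging). IDI is the
difference of discrimination slopes, verified internally by the two-path
identity; NRI is continuous by default — no clinical risk categories are
standard for this outcome — with category-based NRI available for
user-supplied strictly increasing thresholds. CIs are asymptotic
paired-difference normal intervals.

## Decision threshold

The testing threshold solves odds(p) · LR⁺ · (B/R) = 1, i.e.
p = 1/(1 + LR⁺·B/R); the (Se, Sp) parameterization
(1−Sp)/[(1−Sp) + Se·B/R] is algebraically identical and exposed for users
who start from an accuracy table. With LR⁺ = 5 and B/R = 5 the threshold is
1/26 ≈ 0.0385. The function is strictly decreasing in both arguments and
depends on them only through their product.

## Pipeline

`run_validation` applies the eligibility filter at 1- and/or 2-week
tolerances and emits, per subset: the agreement panel, the accuracy table
per reference standard per assessor plus the average-score AUC, the
classification tree and its cut-offs per standard, the three-test
latent-class fit (average-score call, LMP, USG), IDI/NRI per assessor per
standard, and the decision threshold implied by the latent-class LR⁺ of the
score with B/R = 5. Input CSVs are validated row by row against the
documented header; rows with missing required fields or out-of-range items
are rejected (error names the row and field), with a configurable tolerated
fraction below which bad rows are dropped and logged. All floats in the
bundle are rounded to 10 decimals before serialization so that seeded reruns
are byte-identical; the run seed, package version and configuration echo are
written alongside every report.

## Problem sizes

Defaults throughout were chosen so the whole surface runs comfortably on one
CPU: cohorts of 10,000, 20-seed recovery studies, 500-resample bootstraps
(200 inside the pipeline), 1,000-instance brute-force comparison batches,
and a 7-parameter grid-search likelihood oracle at step 0.05 on an n = 200
instance (the exact label-swap symmetry halves the prevalence grid). The
test suite and the acceptance script each complete in about a minute.
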