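# Methods

This note records the statistical model behind `shuntpred`, the design
choices made where the published description leaves freedom, and what the
synthetic data do and do not establish.

## Clinical rules

**Tap test.** Positivity requires at least one of: ≥ 20 % relative
improvement in 10 m walk *time or steps* (improvement = decrease,
(pre − post)/pre, either measure sufficing), ≥ 10 % relative improvement in
MMSE ((post − pre)/pre), or a decrease of ≥ 1 point on the 0–10 urinary
incontinence self-rating. All boundaries are inclusive. A zero MMSE
baseline makes the relative change undefined; the cognition criterion is
then treated as not met and the record flagged — the degenerate case has
no published convention, so the conservative reading was chosen. The
urinary criterion is read as a *decrease* (improvement) of at least one
point, not any one-point change.

**Krauss responder rule.** The outcome grade is the relative improvement
index (pre − post)/pre of an ordinal symptom-severity score; responder iff
index ≥ 0.5, boundary inclusive. The underlying severity scale is not
specified in the source description, so the index is exposed as a
pluggable scoring hook (`KraussRule.scoring`) with the relative-improvement
form as default.

**CA dichotomization.** Positive iff CA ≤ cutoff, *inclusive*, so the
selected cutoff itself falls with the group it was chosen to capture;
strict comparison is available as a config switch. The reference cutoff is
68.7°; pipelines can either pin it (fixtures do) or re-estimate it on the
analyzed cohort by the Youden index.

**Combination rules.** The OR rule upgrades a negative tap on a positive
imaging sign (believe-the-positive). The three-way rule starts from the
tap result and overrides it only when both imaging signs disagree; it is
identical to a 2-of-3 majority vote, an identity the tests verify
exhaustively.

## Diagnostic accuracy

A dichotomous test has the three-point ROC (0,0)–(1−spec, sens)–(1,1),
whose trapezoidal area is exactly (sens + spec)/2; every reported AUC of a
binary rule uses this identity (all six published rows are consistent with
it). For continuous markers, candidate thresholds are midpoints between
adjacent distinct values plus ∓∞ sentinels, computed by an O(n log n)
cumulative-count sweep; tied values move together, which makes the
trapezoidal AUC equal the Mann–Whitney U statistic over n₁n₂ with half
credit for ties (a tested identity). Youden's J = sens + spec − 1 is
maximized over thresholds; among tied maxima the higher-specificity
threshold wins, then the smaller threshold, so cutoff selection is
deterministic. Report tables round at 2 decimals, half away from zero
(0.595 → 0.60); raw values are always retained alongside.

## Group comparisons and the multivariable model

Continuous variables dispatch through a gate: Shapiro–Wilk in each group
and the two-sample variance-ratio F test (two-sided, same α = 0.05); only
when all pass is the pooled-variance t-test used, otherwise Mann–Whitney U.
"F test" is read as the variance-ratio test rather than a Levene-type
test. Mann–Whitney uses exact enumeration below n = 8 without ties and the
tie-corrected normal approximation otherwise, without continuity
correction — so identical groups give p = 1 exactly. Categorical variables
use Pearson χ² without continuity correction (df = 1).

The multivariable model is maximum-likelihood logistic regression
(statsmodels' Newton fitter) with forward stepwise selection by
likelihood-ratio tests over the candidates {EI, DESH, CA}: the candidate
with the smallest LR p below `entry_alpha` = 0.05 enters; any included
variable whose LR drop-test p exceeds `removal_alpha` = 0.10 is removed
(conventional defaults; both config-exposed). Per-variable Wald
χ² = (β/se)², OR = exp(β), 95 % CI = exp(β ± 1.96·se). Because flipping
the outcome coding maps every OR to its reciprocal — and the published OR
of 0.09 for DESH alongside "more favorable response" implies a coding the
source never states — the result object records the coding and reports
both directions. Separation is detected by diverging coefficients
(|β| > 25) or exploding standard errors (> 10³), or statsmodels' own
perfect-separation error, and raised as `SeparationError`; convergence is
relative log-likelihood change below 1e−10 within 50 Newton iterations.
The score vector at the reported MLE is verified ≈ 0 in the tests, the
observable counterpart of monotone-likelihood fitting.

## Synthetic cohorts

`simulate_cohort` emulates the study conditions: 96 responders and 70
non-responders with the published per-group means/SDs and event rates for
demographics, imaging and comorbidities. Sampling goes through a latent
Gaussian copula: each variable gets a standard-normal latent; continuous
variables are mapped through truncated-normal quantile transforms whose
supports encode the type invariants (CSF pressure 80–200 mmH₂O, EI above
the 0.3 enlargement criterion, angles inside (0, 180), non-negative
widths); binary variables threshold the latent at the rate quantile.
Truncation shifts means slightly where the support clips appreciable mass
(EI by ≈ +0.01; CA's shift is negligible, < 0.01°). Default dependence is
independence; a named preset calibrated from the reconstructed joint
tables (group-weighted tetrachoric correlations for tap–DESH–CA) ships as
`calibrated_dependence()`. CA positivity is never sampled separately — it
is implied by the sampled angle and the cutoff, so angle and
dichotomization cannot disagree.

Tap assessments are back-filled so the classification rule reproduces each
subject's sampled tap status exactly: positives meet the gait criterion
with an improvement fraction in [0.25, 0.45]; negatives keep every
criterion strictly below threshold. Severity scores are back-filled the
same way for the Krauss rule (preop 6–12; postop ≤ ⌊pre/2⌋ for responders,
> ⌊pre/2⌋ otherwise). Center assignment is multinomial over three centers
with default weights (0.5, 0.3, 0.2) — the real centers' sizes are not
published.

What the generator does **not** emulate: center-specific measurement
effects, correlations beyond the optional tap–DESH–CA block,
measurement error in the imaging reads, and any relation between tap
improvement magnitudes and eventual shunt response beyond the binary
status. Tests passing on these cohorts therefore establish correctness of
the *pipeline mechanics* under the published marginals, not clinical
validity on real data.

## Joint-table reconstruction

The published counts fix the per-group tap (61/35, 28/42) and DESH (53/43,
8/62) margins exactly; the 2-decimal performance rows constrain the CA
margin, both OR-combinations and the majority rule to ±0.005 (agnostic to
the unknown rounding convention). The solver enumerates every integer
2×2×2 table over (tap, DESH, CA-positive) honoring the exact margins
(vectorized over CA splits) and classifies tables as exact when all rule
metrics fall within the band. Findings, confirmed by an independently
coded pure-Python brute-force oracle in the tests:

* responder group — exactly **2** exact tables exist;
* non-responder group — **no** exact table exists; the published values
  are mutually inconsistent at integer level. The two minimal-deviation
  tables (max deviation 0.0186) are used instead, and the report says so.

Solutions are ordered lexicographically by cell counts (cell order: tap ×
DESH × CA, positives first), making the canonical fixture deterministic.
The narrative count of "additionally identified responders" in the source
conflicts with its own tabulated sensitivities; the reconstruction trusts
the table and surfaces the discrepancy as a report note. Fixture cohorts
materialize one record per cell occupant, with CA drawn from the group's
truncated normal below/above the cutoff per the cell, so rerunning the
pipeline on a fixture reproduces the solver's derived metrics exactly
(a tested cross-module identity).

## Pipeline

`run_full_analysis` executes, in order: Krauss outcome labeling (severity
scores authoritative, text labels as fallback; unlabeled records are
tallied and skipped), the demographic and imaging comparison tables, the
forward-LR logistic model, Youden cutoff selection for CA, dichotomization
(pinned or re-estimated cutoff), and the six-row performance table. Every
stage failure (zero marginals, separation after center exclusion,
degenerate markers) is captured in the report rather than raised, except a
single-class cohort which is a hard error. Significance marks (0.05 /
0.01 / 0.001) are annotations only. Reports serialize to byte-identical
JSON for identical inputs. `leave_one_center_out` reruns everything on
each 2-of-3-center subset and attaches per-subset summaries (group sizes,
tap and DESH counts, mean EI/CA).

## Numerical and test-design choices

* Problem sizes: the type-I calibration of forward selection uses 1000
  null replicates at n = 200 with one candidate; coefficient recovery uses
  n = 5000; sign recovery under reference-direction effects uses 40 seeds
  at n = 1660. The copula rate-convergence check uses 50 000 per group.
* The Youden-cutoff simulation compares the mean estimated cutoff over 5
  replicates of 200 000 per group against a 0.01°-grid search on the two
  Gaussian CDFs. The empirical Youden cutoff converges at the cube-root
  rate, so small simulations carry degree-scale noise; the chosen sizes
  bring the sampling SD of the mean to ≈ 0.33°.
* Stochastic unit tests fix seeds and, where a dispatch decision depends
  on a sampled gate (e.g. Shapiro–Wilk), verify the gate independently
  inside the test rather than trusting the seed.

## Known limitations

* The published multivariable table cannot be reproduced numerically
  without the patient-level data; only direction/recovery properties are
  checked.
* DESH, CA, sCCA, horn widths and third-ventricle width are manual/visual
  measurements: the package validates ranges but cannot compute them from
  images (and does not try).
* BVR is computed per supplied measurement pair; whether a published
  value refers to the anterior-commissure level, posterior-commissure
  level, or their average is left to the caller.
* Disease duration is stored in months — the only unit consistent with
  the published magnitudes, though the source labels the row in years.
* Follow-up timing is recorded but not enforced (the source states both
  "at least 3 months" and "6–12 months").
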