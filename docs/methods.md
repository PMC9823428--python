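# Methods

This note documents the models, defaults and numerical choices behind
`heinvs`, and what its synthetic data can and cannot show.

## Diary scoring

A diary is a set of logged food items already assigned to one of the ten
index components (or `other`); mapping food names to components is out of
scope, since it requires a food-composition database.  Mean daily intake
divides the 7-day component total by the number of *distinct observed
days*; diaries under 7 days are rejected unless explicitly allowed.

Scoring is piecewise-linear and continuous.  Adequacy components
(vegetables, fruits, grains, dairy, fish, beverages) score
`max * min(1, intake/reference)`; moderation components (meat, eggs,
spreadable fats, alcohol) hold the maximum up to the reference and decline
linearly to zero at `zero_point_multiple * reference` (default 2.0).  This
is the functional form of the HEI-1995 lineage the index descends from.
The published component standards are not reproduced in full anywhere
convenient, so the bundled reference table carries the two documented DGE
amounts (vegetables 400 g/d, fruits 250 g/d) and DGE-plausible
placeholders elsewhere, all editable in YAML without code changes.  Open
points we resolved by configuration rather than assumption: possible
sex-specific references (not modelled; a second YAML table can express
them per analysis) and whether beverages are scored by volume or energy
(volume, grams at density 1 g/mL).

Energy density is total kcal over total grams of *food*, beverages
excluded (the standard convention in energy-density research; a flag
includes them).  Energy intake is total kcal divided by diary days.

## Synthetic trial

The generator emulates a two-arm web-based weight-loss RCT in adults with
overweight/obesity: n = 153, 1:1 permuted-block allocation (blocks of 4
and 6), four occasions (baseline, 3 months, +6, +12), and 22.9%
cumulative dropout.  Per subject and component, scores follow
`mean(arm, time) + b_i + e_it` with the subject share of variance set by
an ICC (0.45 for components), then clamp to `[0, max]`; the clamping rate
is logged because components such as spreadable fats sit close to their
ceiling (mean 9.8, SD 0.8) and truncation is unavoidable.  The total is
the *sum* of the simulated components, which keeps additivity exact but
means its marginal SD (~8.6 under independence) is an emergent property,
not a dial.

Change scores, not raw repeated measures, carry the cross-variable
correlation structure, because the association analysis operates on
t1−t0 and t3−t0 differences.  Since the total score is a sum of
components, its change cannot be a free multivariate-normal coordinate;
instead the non-component variables' standardized changes are drawn from
the conditional of a user-supplied correlation matrix given the realized
(empirically standardized) total-score change.  The matrix is validated
symmetric/unit-diagonal/PSD; the default couples the total's change to
energy density at −0.30 and, weakly, to fasting glucose (+0.15) and
fat-free mass (−0.15).  Component trajectories follow the published
per-arm descriptive statistics of the trial being emulated; trajectories
the trial did not publish (lipids, blood pressure, body composition,
energy intake/density) are realistic values for such a cohort, chosen
once and fixed.

Dropout is monotone and missing-at-random: a per-stage logistic hazard in
arm (+0.2 logits for control) and standardized baseline BMI (+0.25 per
SD), with the intercept calibrated by Gauss–Hermite quadrature so the
marginal cumulative rate hits the configured 22.9% exactly in
expectation.  An MCAR switch zeroes the covariate effects for null
testing.  Which variables actually predicted dropout in the real study is
unknown; this mechanism is a modelling choice.

Diaries are generated by inverting the scoring rules (adequacy:
`reference * score/max`; moderation: `reference * (k − (k−1)·score/max)`,
so a full moderation score maps to intake exactly at the reference).  The
gap between the scored food mass and the mass required by
`energy_intake / energy_density` is filled with unscored `other` food;
when a draw would make that gap negative, energy intake is raised to the
feasibility floor and the panel cell updated (logged).  Daily amounts are
Dirichlet splits (concentration 20) of the weekly total, so 7-day means —
and therefore scores, energy density and energy intake — are preserved to
machine precision; re-scoring the emitted diaries reproduces the panel.

What passing tests on these data do *not* show: robustness to real-diary
pathologies (underreporting, skipped days, mixed dishes), non-normal
outcome margins beyond boundary truncation, seasonal or pandemic-era
drift, and informative (MNAR) dropout.

## Multiple imputation

Imputation runs on the wide panel (one column per variable x timepoint);
baseline columns must be complete, which the trial design guarantees.
Each incomplete column is regressed on arm, the baseline value of the
same variable, and the concurrent values of the other variables.  Draws
are predictive-mean matching: OLS on the observed rows, a Gaussian
perturbation of the coefficients from their sampling covariance (computed
via pseudo-inverse and an eigenvalue square root, since concurrent
predictors include a total alongside its components and are exactly
collinear), then a donor drawn uniformly from the 5 nearest predicted
means.  Each of the m imputations is an independent chain (default
5 burn-in + 3 spacing cycles).  PMM is the default because component
scores are bounded and non-normal; a Bayesian-normal alternative
(iterative regression imputation with posterior sampling) is available by
flag.  Imputed — never observed — score cells are clamped to their valid
range.  This is deliberately a single-level imputation; the longitudinal
structure enters through baseline conditioning rather than random
effects, and imputed totals are not constrained to equal the sum of
imputed components.

Pooling follows Rubin's rules, `T = W + (1 + 1/m)B`, with the classic
large-sample degrees of freedom, switching to Barnard–Rubin when a
complete-data df is supplied.

## Robust linear mixed model

The outcome model is `y ~ time * group + (1 | subject)` with treatment
coding against baseline and the intervention arm — exactly eight fixed
effects.  The maximum-likelihood fit profiles the residual variance and
GLS coefficients over the variance ratio λ = σ²ᵤ/σ²ₑ (per-subject
Woodbury identities; 1-D bounded search on log λ, with an explicit λ = 0
boundary check that also serves as the fixed-effects fallback when the
between-subject variance degenerates).

Robustification is iteratively reweighted GLS: conditional residuals
(observed minus fixed part minus BLUP), a MAD scale, Huber weights
`min(1, 1.345·s/|e|)`, and moment-based robust variance components (MAD
of per-subject mean residuals, floored at zero).  Scale and variance
updates freeze after 20 iterations so the coefficient iteration can
contract; convergence requires the max coefficient change to fall below
`1e-8 * (1 + ||β||∞)` — relative to the coefficient scale, because an
absolute 1e-8 on an intercept near 80 would demand machine precision from
a limit-cycle-prone weight update.  Non-convergence raises an error
carrying the step trace.  With the tuning constant at infinity all
weights are one and the fit *is* the ML solution (verified against an
independent ML mixed-model implementation to ~1e-6); with Huber weights
active the robust and ML estimators differ by a term of the order of the
coefficient standard errors, so exact agreement is claimed — and tested —
only in the low-noise clean-data limit.  This estimator is not the
design-adaptive scale estimator of the R `robustlmm` package; on clean
data the two targets coincide, under contamination they differ in detail.

Wald p-values use the normal approximation: robust mixed models have no
exact finite-sample df, and per-imputation fits are pooled with Rubin's
rules (t reference with pooled df).

Cohen's d standardizes the within-group change by the SD of the change
scores (the alternative — baseline-SD standardization — is a documented
flag-worthy variant, not the default), with the usual
`d ± 1.96·√(1/n + d²/2n)` interval, pooled across imputations like any
other estimate.

## Bootstrapped correlations

Change scores pool both arms.  For each variable and interval the pairs
bootstrap (B = 5000 by default, vectorized) yields the BC interval:
`z0 = Φ⁻¹(#{r* < r̂}/B)` (proportion clipped to (1/(B+1), 1−1/(B+1))),
endpoints at bootstrap quantiles `Φ(z0 + (z0 ± 1.96)/(1 − a(z0 ± 1.96)))`
with a = 0; "bias-corrected" is read as BC, with BCa (jackknife
acceleration, computed in closed form from leave-one-out sums) behind a
flag.  Degenerate cases: |r̂| = 1 collapses the interval with a warning; a
constant bootstrap distribution raises.

How to combine bootstrap intervals across 50 imputations has no canonical
answer, so the package defines one and labels it: every imputation is
bootstrapped with the *same* replicate seed; r and both bounds are
Fisher-z transformed; the point estimate is Rubin-pooled; each bound's
per-imputation half-width acts as a within-imputation 1.96·SE and the
(1+1/m)-inflated between-imputation variance is added before
back-transforming.  This preserves the BC asymmetry and collapses exactly
to the single-dataset interval when the imputations are identical.  A
"stacked" mode (each replicate resamples a randomly chosen imputation) is
provided as a sensitivity analysis.  No multiplicity correction is
applied across the 26 table cells by default; Benjamini–Hochberg is left
to the user.

## Problem sizes used in the test suite

The calibration tests run at the sizes a desk machine handles in minutes:
robust-vs-ML contamination superiority at 200 replicates of n = 150
(5% gross +50-point outliers, win rate ≥ 90%); interaction recovery at
200 replicates of n = 153 with 30% MAR dropout and m = 10 (scaled down
from the analysis default of 50), requiring mean bias below 0.5 on a true
interaction of −5; bootstrap coverage/type-I at 500 replicates with
B = 1000 (92–98% coverage at ρ = −0.3, 3–8% false positives at ρ = 0);
and the end-to-end pipeline at m = 10, B = 1000.  The oracle-equivalence
check runs at σᵤ = 0.02, σₑ = 0.005 — the clean-data limit in which the
0.1%-per-coefficient agreement criterion is meaningful (at realistic
noise the two estimators legitimately differ by a few percent of a
standard error).

## Known limitations

* Reference amounts other than vegetables/fruits are placeholders; scores
  are only as faithful as the table supplied.
* The simulator draws components independently (given arm and time), so
  between-component correlations of real diets are absent, and the total
  score's variance is understated relative to positively correlated
  components.
* Single-level imputation ignores random-effects structure beyond
  baseline conditioning.
* The robust estimator's variance components are moment-based
  approximations; its standard errors come from the weighted GLS
  information and do not account for the weighting's extra variability.
* Bootstrap-across-imputations combination is a reasoned convention, not
  an established result.
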