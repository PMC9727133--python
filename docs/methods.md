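# Methods

## Scope and model

`msynscreen` evaluates simple anthropometric indices as screening
tests for metabolic syndrome (MSyn). The analysis chain is: raw
anthropometry and fasting biochemistry → seven indices → rule-based
MSyn diagnosis (ATP III) → per-index, per-sex ROC analysis with an
optimal screening cutoff. Nothing is model-fitted to data; the only
estimated quantities are empirical ROC functionals and their
confidence intervals.

## Index formulas and units

Inputs are stored in the cohort CSV's units (cm, kg, mg/dL); each
formula converts internally. ABSI and CI take WC and height in
metres; WHtR and BRI are ratios of like units and therefore
unit-invariant; VAI takes TG and HDL in mmol/L (conversion divisors
18.016 for glucose, 88.57 for TG, 38.67 for cholesterol, from molar
masses).

Two deliberate numerical choices:

* **VAI linear term.** VAI is implemented as
  WC/(39.68 + 1.88·BMI) (men) and WC/(36.58 + 1.89·BMI) (women), the
  original definition. A subtracted variant sometimes seen in print
  (`WC/39.68 − 1.88·BMI`) is negative for typical adults and is not
  offered.
* **Domain errors, not NaN.** Non-positive measurements and the
  geometric impossibility WC > π·height (which would make the BRI
  square root negative) raise `DomainError` naming the offending field
  and record, so bad rows surface in the exclusion log instead of
  propagating silently.

BRI is bounded in [−1.3, 364.2) and strictly increasing in WC at fixed
height; VAI equals exactly 1 for a subject at the reference WC, TG and
HDL. Both facts are enforced as property tests.

Reported tables round indices to 2 decimals except WHtR (3) and ABSI
(4), matching their typical printed granularity; full precision is kept
internally.

## ATP III classification

Five components; diagnosis at ≥ 3. All thresholds are **inclusive** at
the printed value, including HDL ("≤ 40/50 mg/dL") — some ATP III
statements print "<" for HDL, but the inclusive reading is applied
uniformly. Drug treatment for a component marks it abnormal regardless
of the measured value; antihypertensive treatment alone suffices for
the blood-pressure component (no separate hypertension-history field is
required). Blood pressure uses the mean of two seated readings; a
missing second reading falls back to the single reading with a warning.
Records missing any required field are excluded listwise and logged.
Thresholds are parameters of `Atp3Classifier`, so alternative waist
cutoffs (e.g. IDF's 94/80 cm) can be emulated.

## ROC analysis

The empirical ROC uses the positivity rule "index > cutoff" with one
operating point per distinct observed value plus the all-positive
extreme. The trapezoidal AUC is computed along the threshold-ordered
path, which makes it exactly the normalised Mann–Whitney count
(#{case > control} + ½·#{ties})/(n₁n₀) — verified exactly against
brute-force enumeration on tied data.

Confidence intervals: DeLong's structural-components variance is the
default (nonparametric, matches standard software); Hanley–McNeil is
provided for parity with older outputs; a stratified percentile
bootstrap is available and seeded. Wald intervals are clipped to
[0, 1]. The DeLong implementation is checked against an independent
reference value frozen from R's pROC on a fixed dataset.
Sensitivity/specificity at the chosen cutoff get Wilson score
intervals.

The Youden-optimal cutoff maximises J = sens + spec − 1 over
**observed** score values (no midpoint interpolation, so a reported
cutoff is always an attainable operating point). Ties in J are broken
by higher sensitivity, then smaller cutoff: in a screening context a
false negative is costlier than a false positive. Discrimination
bands: AUC ≥ 0.9 excellent, [0.8, 0.9) good, [0.7, 0.8) fair,
[0.6, 0.7) poor, [0.5, 0.6) failed (left-closed); below 0.5 is
reported as failed with a below-chance warning.

## Descriptive statistics

Pearson chi-square without continuity correction for all r×c contrasts
(zero expected counts are an error advising category merge);
independent-samples t-test with pooled variance by default (Welch via
`equal_var=False`); percentages to 1 decimal. BMI classes use WHO
cut-points (18.5/25/30, left-closed on the heavier side).

## Synthetic cohort generator

The generator exists so every pipeline stage has a testable
known-truth input; it emulates a sex-stratified outpatient cohort with
42.5% MSyn prevalence and 54.2% men, the conditions of the motivating
cross-sectional study.

Structure per subject: sex ~ Bernoulli(0.542); a latent
"syndrome-prone" class ~ Bernoulli(target prevalence); (height, BMI,
WC) trivariate normal with class- and sex-conditional WC/BMI moments
taken from the study's case/non-case summary table, truncated to
physiological bounds (height 140–200 cm, weight 35–160 kg, WC
50–160 cm, WC < π·height) by resampling; weight derived as
BMI·height². Heights (171 ± 6.5 cm men, 158 ± 6 cm women) were chosen
so the implied WHtR matches the same table; the correlations
corr(BMI, WC) = 0.85, corr(height, WC) = 0.15,
corr(height, BMI) = −0.05 are typical adult values — none of these are
identified by the published moments. Biomarkers are drawn per class:
normal FPG and HDL, log-normal TG (sex-specific medians), bivariate
normal BP (corr 0.7), with the prone class shifted toward abnormality
and slightly overdispersed; treatment flags are Bernoulli with higher
probability in the prone class.

The between-class biomarker shift is scaled by a single multiplier
calibrated by bisection (≤ 25 iterations) until ATP III classification
of the generated cohort reproduces the target prevalence within 0.005.
All underlying variates are drawn once and the shift rescaled, so
prevalence is monotone in the multiplier and the bisection is exact;
an unattainable target raises `CalibrationError`.

What the generator does **not** emulate: the real joint dependence
between anthropometry and biomarkers beyond the one latent class (the
published summaries only identify marginal class-conditional moments),
recruitment design, and covariate structure of smoking/education
beyond marginal frequencies. Consequently, passing tests demonstrate
that the *machinery* recovers known truth and reproduces the
qualitative index ordering (BRI/WHtR strong, ABSI weakest) — not that
real-data AUCs would equal the simulated ones.

## Problem sizes and determinism

Everything is seeded through `numpy.random.default_rng`; identical
seeds give bit-identical cohorts and reports. The validation suites
use: 500 random small instances (n ≤ 30, heavy ties) for exact oracle
equivalence; binormal samples of 2 × 10,000 per AUC grid point
{0.5, …, 0.9} for AUC recovery (3 Hanley–McNeil SEs); 2 × 50,000 for
Youden-cutoff recovery (within 0.05·σ of the theoretical midpoint —
the empirical argmax of J converges at a cube-root rate, so this is
the slowest-converging check and the acceptance script averages three
replicates); and a 5,000-subject synthetic cohort for the end-to-end
prevalence and index-ordering checks.

## Known limitations

* DeLong/Hanley–McNeil intervals are Wald-type and degenerate near
  AUC = 1 (clipped); use the bootstrap near the boundary.
* Cutoffs are observed values; with coarse score grids the reported
  cutoff can sit a full grid step from the population optimum.
* The chi-square implementation requires strictly positive expected
  counts and offers no exact (Fisher) fallback.
* `component_distribution` and the report tables assume the five-flag
  ATP III rule; other syndrome definitions (IDF, JIS) are only
  reachable by re-parameterising thresholds, not as named presets.
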