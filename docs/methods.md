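# Methods

`labcascade` implements a national diabetes care-cascade analysis over
longitudinal laboratory records: cohort assembly from per-specimen
extracts, probabilistic record linkage, classification of three
sequential outcomes, direct age-standardization, and modified Poisson
risk-ratio regression. Because the real national laboratory extract it
is designed for is not redistributable, the package ships a synthetic
generator that reproduces the statistical structure the analysis
assumes, with ground truth, so every stage is testable end to end.

## The cascade model

A patient enters the cohort at their first diabetes-type laboratory
test (HbA1c, fasting plasma glucose FPG, or random plasma glucose RPG)
if that test falls in the enrollment window (2012-01-01 through
2015-03-31, both inclusive) and the patient is at least 30 completed
years old on that date (the age floor screens out most type 1
diabetes). Three sequential binary outcomes follow:

- **Lab-diagnosed diabetes**: any diabetes-type lab at or above its
  diagnostic cut-off — HbA1c ≥ 6.5 %, FPG ≥ 7.0 mmol/l, RPG ≥ 11.1
  mmol/l — from the first test through `horizon_days` after it. By
  default the diagnosing lab may be any lab in that horizon
  (`diagnosis_mode="window"`); a strict mode confines assessment to the
  first test. Both readings of "patients whose labs indicated diabetes"
  are defensible on a specimen-level database; the permissive reading
  is the default and the choice is a config key.
- **Retained-in-care**: ≥ 1 diabetes-type lab in the half-open window
  `(diagnosis + 30 d, diagnosis + 730 d]`. A lab exactly 30 days after
  diagnosis does not qualify; day 31 does; day 730 does; day 731 does
  not. The expanded definition `retained_any` accepts a laboratory test
  of any type in the same window (capturing patients who stayed in the
  health system without diabetes-specific monitoring).
- **Glycaemic control**: ≥ 1 diabetes-type lab in the retention window
  strictly below its control cut-off — HbA1c < 7.0 %, FPG < 8.0
  mmol/l, RPG < 10.0 mmol/l. A control-qualifying lab is necessarily a
  retention-qualifying lab, so `controlled ⇒ retained_dm ⇒ diagnosed`
  holds by construction and is asserted on every cascade table.

Calendar words are realized day-exactly and configurably: one month =
30 days, 24 months = 730 days, six months = 183 days. Same-day test-type
ties break by HbA1c > FPG > RPG, HbA1c being the guideline-preferred
diagnostic. Age is completed years at the first test.

**Co-morbidity ascertainment.** HIV status (PLWH/PLWOH) is positive
when any CD4 or HIV viral-load record exists at any time up to 24
months after the first diabetes test (lookback unbounded), or a rapid
HIV test with a positive result in that range. TB status (TB+/TB−) is
positive when a TB assay exists within ±183 days of the first test;
presence of the assay suffices by default (the ascertainment is
test-based, mirroring how such cohorts define "acute TB infection"),
with a `require_positive` mode available.

**Pre-diabetes** is classified only when a per-test interval is
configured; there is no accepted default cut-off, so none is shipped.

## Record linkage

Laboratory databases accumulate identity errors (typos, date-of-birth
slips, relocations), so records are clustered into patients before the
cascade. The pair score is a weighted sum of per-field similarities
with weights given_name 0.3, family_name 0.3, dob 0.2, sex 0.1,
province 0.05, facility 0.05: names use normalized Levenshtein
similarity (1 − distance / max length, case-insensitive, via edlib);
date of birth scores 1 on exact match and 0.5 when exactly one of
day/month/year differs (tolerating single-component errors); sex,
province and facility are exact-match. Candidate pairs are generated by
blocking on (sex, birth year) ∪ (sex, surname initial) — under the
corruption model a record rarely loses both its birth year and its
surname initial at once, so candidate generation stays near-complete
while tractable.

Pairs scoring ≥ 0.85 become edges; connected components are the
asserted patients. Because transitive chains of borderline matches can
over-merge, an optional refinement (on by default) splits any component
in which more than half of the internal candidate pairs score below the
threshold, removing the weakest match edge per pass until every
component complies. The threshold and weights were set so that, on the
bundled mildly corrupted fixture, positive predictive value stays above
0.95 — precision is prioritised over recall, since a false merge
contaminates a patient's longitudinal history while a false split only
loses follow-up.

Evaluation is pairwise: sensitivity = recovered true co-referent record
pairs / all true co-referent pairs; PPV = correct asserted pairs / all
asserted pairs. With zero asserted pairs PPV is reported as 1 and
flagged degenerate. Lowering the threshold (refinement off) can never
decrease the number of true-positive pairs, a property the test suite
checks.

## Direct age-standardization

Proportions are standardized over 5-year age bands 30–34 … 70–74 plus
an open-ended 75+ band: `p_std = Σ_b w_b p_b` with delta-method
standard error `sqrt(Σ_b w_b² p_b (1−p_b) / n_b)` and a
normal-approximation 95% CI. Bands with positive weight but no
observations have their weight renormalized over observed bands, and
the estimate flags the condition. The bundled weight file
(`data/age_weights_synthetic.csv`) is a plausible adult age pyramid for
a middle-income country and is explicitly synthetic — it is **not** an
official mid-year population estimate, so standardized values computed
with it are demonstrations of the machinery, not reproductions of any
published standardized estimate.

## Modified Poisson regression

Risk ratios for the binary outcomes come from a log-link Poisson GLM
with a robust sandwich variance (the standard modified-Poisson
approach). Variance is cluster-robust at the facility level with
facility labels made unique within district, respecting the
facility-in-district nesting; a random-intercept formulation is not
used because the sandwich form is fully specifiable and testable
against closed forms. Without clusters the HC0 sandwich is used, which
in the two-group case equals `se(log RR) = sqrt((1−p₁)/(n₁p₁) +
(1−p₀)/(n₀p₀))` exactly — a closed form the tests verify to 1e-8.

The three models are nested: diagnosis on everyone tested, retention on
the diagnosed, control on the retained. Covariates: sex, age band
(30–39.9 / 40–49.9 / 50–59.9 / ≥60), HIV status, TB status, facility
type, year of first lab, plus province as fixed-effect indicators, and
the diagnostic type for the diagnosis and control models only.
Reference levels are male, 30–39.9, PLWOH, TB−, hospital, 2012, HbA1c.
For the diagnosis model the diagnostic-type covariate is the type of
the patient's *first* test, since it must be defined for the whole
tested population; `diagnostic_used` proper (the type of the
diagnosing lab) exists only after a diagnosis and enters the control
model. Crude mode fits one covariate at a time. IRLS runs with
tolerance 1e-8 and at most 100 iterations; non-convergence and
separated levels (all-0 or all-1 outcomes) are flagged in the output
rather than dropped.

## The synthetic generator

The generator emulates a public-sector laboratory information system:
a facility-in-district-in-province hierarchy (nine provinces, by
default two districts each with three facilities, ~62% hospitals);
per-patient longitudinal streams of HbA1c/FPG/RPG, CD4, HIV viral
loads, rapid HIV tests, TB assays and routine chemistry over an era
from April 2004 to March 2017; and identity corruption with withheld
ground truth.

Outcomes are drawn from a log-link Bernoulli model, `P(outcome) =
p_base · Π_c rr_c^{x_c}` over binary covariates (HIV, TB, female,
clinic), which makes the configured risk ratios exactly the estimand of
the modified Poisson fit — parameter recovery is therefore a
well-defined test. Configurations whose implied probability exceeds 1
in any covariate stratum are rejected with the offending combination
named.

Default parameters are the study conditions the package emulates:
female 0.635, HIV prevalence 0.152, TB 0.015, hospital share 0.62, age
distribution peaking in the early 50s, first-test mix 60% HbA1c / 20%
FPG / 20% RPG, enrollment window 2012-01-01 to 2015-03-31, horizon 730
days. Base-stratum probabilities (diabetes 0.45, retention 0.27,
control-given-retention 0.35, any-other-lab 0.25) were chosen so that,
after the default risk ratios act, the marginal cascade proportions
land near the national cohort's reported crude margins (diagnosed
~45%, retained-in-care ~33% of diagnosed, controlled ~27% of
retained, any-lab retention ~54% of diagnosed). Default risk ratios
mirror the reported adjusted associations (e.g. HIV: 0.73 on
diagnosis, 1.12 on retention, 1.42 on control). Result values are drawn
uniformly within threshold-respecting ranges (e.g. a diagnosed
patient's first HbA1c in [6.5, 14.0] %); follow-up dates are uniform
over the qualifying window — the simplest models consistent with the
windowed definitions.

Identity corruption perturbs only identity fields (names, date of
birth, facility context), never the ground-truth identifier or
specimen data: per-field single character edits, ±1 errors in one
date-of-birth component, facility moves on later records, and record
fragmentation (a patient's later records carrying a consistent surname
variant). Names are drawn from bundled synthetic pools of ~100 given
and ~100 family names so that cross-patient collisions occur at rates
that genuinely exercise the linkage stage.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: seasonality and secular trends in
testing, mortality and migration, pregnancy, point-of-care testing,
assay measurement error beyond threshold-respecting draws, visit-driven
correlated test panels, and realistic per-patient test-frequency
distributions (test frequency is a free parameter, as no authoritative
distribution is available). Linkage performance on the synthetic names
and corruption model does not guarantee performance on real identity
data.

## Numerical and design choices

- Binomial CIs on crude proportions: Wald by default, Wilson optional;
  standardized CIs use the normal approximation (a gamma-interval
  alternative is out of scope).
- Empty strata report absent (NaN) proportions, never 0.
- Degenerate linkage PPV (no asserted pairs) reports 1 with a flag.
- Extract files are comma-delimited text with ISO-8601 dates and a
  fixed column order; parse errors name the offending line.
- Everything is seeded: identical configuration and seed reproduce
  extracts byte-for-byte, and the pipeline manifest records config
  hashes and output checksums to make reruns verifiable.

## Problem sizes

The bundled tests and the acceptance script run the generator at up to
50,000 patients for calibration and parameter-recovery checks, ~5,000
records for linkage fidelity, and 100 small random configurations for
cascade-invariant checks; these sizes put Monte-Carlo error well inside
the stated tolerances (4 binomial SEs; 10% relative error on recovered
risk ratios) while keeping a full run to a few minutes on one CPU.

## Known limitations

- The real national cohort's published age-standardized estimates are
  not reproducible here: the raw data are confidential and the official
  standardization weights are not published; the bundled weights are
  synthetic stand-ins.
- "Mixed effects" in the regression is realized as cluster-robust
  variance, not a random-intercept GLMM; point estimates can differ
  from a true GLMM under strong cluster heterogeneity.
- Whether sensitivity/PPV of the original linkage were pairwise or
  cluster-level is not documented; pairwise is implemented.
- The cascade cannot see care delivered without laboratory testing
  (e.g. point-of-care glucometers), so "retained" and "controlled" are
  lab-visible lower bounds.
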