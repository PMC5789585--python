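# Methods

## Problem and scope

`opmort` implements the external validation and recalibration of five
published risk models for operative mortality (death in hospital or within
30 days of surgery) in colorectal cancer surgery: POSSUM, P-POSSUM,
CR-POSSUM, the AFC score, and the IRCS score. Patient-level data from
prospective surgical registries of this kind are not publicly available, so
the package also ships a synthetic cohort generator that reproduces the
statistical structure of such a cohort — an elective-dominated population of
~2,700 patients with in-hospital mortality near 1.5% and 30-day mortality
near 1.7% — which makes every stage of the pipeline executable and testable
end to end.

## Risk models

Two model families are implemented behind one registry format.

**Score-link models (POSSUM, P-POSSUM, CR-POSSUM).** Each clinical variable
is assigned an integer weight by the category it falls in; the weights sum
into a physiological score (PS) and an operative severity score (OS), and
the probability of death is

    logit(R) = b0 + b1 * PS + b2 * OS

with the published coefficients (POSSUM: −9.065 + 0.1692·PS + 0.1550·OS;
P-POSSUM: −9.37 + 0.19·PS + 0.15·OS; CR-POSSUM: −9.167 + 0.338·PS +
0.308·OS). POSSUM and P-POSSUM share a single 18-variable binning
(12 physiological, 6 operative) and differ only in coefficients — this is
enforced structurally: the P-POSSUM registry file references the POSSUM bins
rather than copying them. CR-POSSUM uses 10 variables (6 physiological,
4 operative), so its minimum scores are PS = 6 and OS = 4.

**Category models (AFC, IRCS).** Each variable contributes one coefficient
per non-reference category directly to the linear predictor; the reference
is the lowest-risk category. AFC uses four binary factors (age > 70,
neurological comorbidity, weight loss > 10% in six months, non-elective
surgery). The registry deliberately ships **no** original AFC coefficient
set: validation of AFC with original coefficients is reported as `NA`
while its recalibration is fully functional, reproducing the asymmetry such
a model shows when its source equation is not usable. The IRCS entry uses
the score's five preoperative variables (age band, heart failure,
respiratory status, urgency, stage); its shipped coefficient set is a
clearly labelled *synthetic representative* stand-in (provenance
`synthetic_representative`, file `ircs_synthetic.json`) because the source
publication's fit is not reproduced here — it exists so the
original-coefficient validation path can be exercised, and it must not be
cited as the published IRCS equation.

### Bin topology and unit conventions

Printed weight tables give category labels, not interval topology. The
registry expands every label into explicit half-open partitions so that any
in-range value falls in exactly one bin (e.g. SBP `[90, 100)` carries the
"90–99" weight, `[100, 170]` is closed on both ends). Property tests fuzz
records across the full domain to confirm no gaps or overlaps. Units are
fixed (urea mmol/L, haemoglobin g/dL); no automatic conversion is ever
applied, but the CSV reader warns when magnitudes suggest a unit mix-up
(urea above 60 looks like mg/dL, haemoglobin above 30 like g/L).

The CR-POSSUM weights are frozen from the tabulated category weights used
in external validation (leading weight digit per category: urgency 1/3/8,
operative severity 1/3/4/8, contamination 1/2/3, heart failure 1/2/3, age
1/3/4/8, staging 1/2/3). The POSSUM tables are the original 1991 weights
adapted to this package's categorical levels: heart failure
none_or_mild/moderate/severe maps to 1/4/8, the pooled "none or serous"
contamination level takes the lower original weight, and malignancy is
keyed on Dukes stage (A–B = 2, C = 4, D = 8 — every patient in scope has a
primary cancer, so the "no malignancy" weight is unreachable).

## Validation engine

* **Discrimination.** AUC is computed as the Mann–Whitney concordance
  (ties count one half), implemented through midranks; tests verify exact
  agreement with the exhaustive all-pairs oracle. The 95% CI uses DeLong's
  structural-components variance by default; a seeded stratified bootstrap
  (2,000 resamples) is available for very small event counts. CIs are
  clipped to [0, 1].
* **Calibration.** The Hosmer–Lemeshow statistic sums (O−E)²/E over both
  outcome classes in ten near-equal groups of predicted risk (stable sort,
  ties kept adjacent); groups with zero expected deaths are merged into a
  neighbour and counted. Degrees of freedom are `groups − 2` for both
  validation and recalibration reports (the common fitted-model convention;
  the df used is printed in every report). Simulation tests confirm the
  test's null rejection rate stays near 5% when the fitted model is the
  generating model. Calibration tables report per-band n, observed and
  expected deaths plus the overall O/E ratio; O/E < 1 means overestimation.
* **Event rates.** Crude mortality with a normal-approximation CI truncated
  at zero (the convention that reproduces printed registry CIs at one
  decimal); Clopper–Pearson exact is available behind a flag.
* **Bivariate screening.** Per-factor chi-square tests, switching to
  Fisher's exact for sparse 2×2 tables (expected cell < 5); larger sparse
  tables keep the chi-square and are flagged.

Complete-case analysis is applied per model: a patient missing any variable
the model requires is excluded, and the exclusion log attributes every
exclusion to the missing variable(s). Because the five models need
different variable sets, their analyzable Ns differ — with the default
missingness the ordering is N(IRCS) > N(CR-POSSUM) > N(POSSUM/P-POSSUM) >
N(AFC), the structural signature of fewer-variable models being usable in
more patients.

## Recalibration engine

Recalibration keeps each model's structure and refits its coefficients by
maximum likelihood: outcome on (PS, OS) for the score-link family, outcome
on category indicators for AFC/IRCS. Fitting is Newton–Raphson (IRLS) via
statsmodels with score tolerance 1e−8 and a 50-iteration cap, both
configurable and logged in the fit metadata. Because POSSUM and P-POSSUM
share (PS, OS), their recalibrated equations are identical to machine
precision — an asserted invariant. Logistic MLE guarantees
calibration-in-the-large on the fitting cohort (O/E = 1), also asserted.

Separation is a realistic hazard at ~40 deaths: a fitted coefficient beyond
15 logit units, a singular Hessian, or statsmodels' perfect-separation
signal raises a `SeparationError` naming the culprit term, identified with
a lightly ridge-penalized refit that stays solvable under separation. The
IRCS registry keeps its category contrasts coarse (binary heart failure,
dyspnoea, urgency) precisely so a refit remains identifiable at realistic
event counts. No shrinkage is applied by default (a ridge path exists only
as the separation diagnostic, never in reported fits).

## Synthetic cohort generator

The generator's defaults are the study conditions, not tuning knobs:

* **Marginals.** The CR-POSSUM factor distributions reproduce the published
  cohort (age bands 23.3/30.2/32.9/13.6%; heart failure 92.9/5.4/1.7%;
  urgency 96.4/3.4/0.3%; contamination 98.0/0.3/1.7%; staging
  57.9/32.7/9.4%; operative severity 0/2.2/55.4/42.4%; SBP, heart rate,
  urea, haemoglobin bands likewise), plus sex 63.6% male and colon share
  72%. Variables only the 18-parameter models use (GCS, leucocytes, sodium,
  potassium, ECG, blood loss, procedures, respiratory status) have no
  published marginals and use realistic registry values chosen once:
  overwhelmingly normal physiology (e.g. GCS 15 in 99%, normal ECG 90%)
  with small abnormal tails.
* **Continuous values** are drawn uniformly within the sampled category's
  interval (unbounded edges truncated at physiologic limits, e.g. SBP
  60–210 mmHg, age 24–97 y). Only bin membership affects any score, so the
  within-bin law is irrelevant to the pipeline by construction.
* **Outcomes.** In-hospital death is Bernoulli from a configurable true
  logistic model (default: the CR-POSSUM score structure with slopes
  0.338/0.308). The intercept is tuned by root-finding so the cohort's mean
  true risk equals the target rate (default 1.5%); the tuned intercept is
  recorded in the cohort metadata and serves as the known truth in
  parameter-recovery tests. 30-day death contains every simulated
  in-hospital death plus post-discharge deaths with probability
  proportional to the same true risk, scaled to the 30-day target (1.7%).
* **Missingness** is injected missing-completely-at-random per variable.
  The five CR-POSSUM factors use the published gaps (urea 10.3%, heart
  rate 5.2%, SBP 4.2%, heart failure 2.7%, haemoglobin 2.0%); the
  POSSUM-only variables get small plausible gaps (1–3%) and weight loss — an
  anamnestic item that is hardest to collect — 45%, so per-model
  complete-case Ns differentiate the way they do in real registries.
  Outcomes are never blanked.
* **Dependence.** Variables are independent by default (only marginals are
  matched); an optional one-factor Gaussian copula couples chosen variables
  through loadings on a shared latent normal.
* **Seeding.** One master seed spawns deterministic per-stage child streams
  (categories, continuous fills, outcomes, 30-day layer, missingness); the
  spawn keys are logged in the cohort metadata and identical configs are
  byte-identical.

**What passing tests do and do not show.** The generator matches marginals,
event rates and missingness patterns, but real registry data have
correlated risk factors, informative (non-MCAR) missingness concentrated in
urgent cases, hospital-level clustering, and an outcome process that no
single logistic score generates. Discrimination measured on synthetic
cohorts therefore reflects the generator's assumptions, not any real
cohort's AUC; what the tests certify is the correctness and calibration of
the machinery (scores, statistics, refits), not clinical performance.

## Numerical choices

* Inverse logit is evaluated in its numerically stable branch form.
* The intercept tuner brackets the root in ±30 logit units and solves to
  1e−12; the mean-risk-vs-shift map is strictly monotone, so the root is
  unique.
* H-L groups are formed with `argsort(kind="stable")` + `array_split`, so
  row order is irrelevant for distinct predictions and tied predictions are
  kept adjacent deterministically.
* Exact CSV round-trips: floats are written as shortest round-trip `repr`
  and parsed with Python's correctly rounded `float()` (pandas' fast parser
  can be off by one ulp).
* Statistical suite sizes were chosen to keep the default test run around a
  minute on one core: 100k-patient cohorts for marginal checks, 50k for
  recovery (50 seeds in the acceptance suite), 20k × 500 replicates for the
  H-L null, 1,000 random instances for the AUC oracle.

## Known limitations

* The AFC and IRCS original equations are not reproduced; AFC validates as
  `NA` and IRCS's shipped set is an explicitly synthetic stand-in.
* MCAR missingness understates the complete-case bias that informative
  missingness would produce; the urgency-dependent mechanism is available
  via per-variable maps but is not the default.
* The generator emulates one pooled cohort; inter-hospital heterogeneity is
  out of scope.
* A 3-SE recovery criterion has ~99.7% coverage per estimate, so across 150
  estimates an isolated excursion is expected behaviour; the acceptance
  suite therefore requires near-complete (≥47/50 seeds) coverage plus an
  unbiased pooled mean rather than literal 150/150.
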