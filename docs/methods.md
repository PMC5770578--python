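# Methods

`actitraj` analyses consumer-tracker step data in cohorts of people with
rheumatoid arthritis (RA) or axial spondyloarthritis (axSpA): minute-level
step counts are filtered for valid wear, reduced to daily activity
patterns, scored against activity recommendations, partitioned into
longitudinal trajectory clusters, and compared between disease groups.
Because such study datasets are rarely shareable, the package ships a
synthetic-cohort generator with known ground truth; every downstream
stage is validated against it.

## Observation window and validity rules

Each participant contributes 90 consecutive calendar days starting on the
first Monday *strictly* after device activation (an activation on a
Monday starts the following Monday; "following" most plainly reads as
strictly subsequent, and the choice shifts the window by at most seven
days). Days are civil calendar days, midnight to midnight, in local time;
daylight-saving transitions do not move records between days.

A day is **full** when at least 8 hours (480 min) elapse between the
first and the last minute with recorded steps. Because the tracker only
reports steps, a minute with zero steps is indistinguishable from a
non-worn minute; the first-to-last-step span is the only wear proxy
available, and no within-day non-wear imputation is attempted. Only full
days are analysed. A participant is **analyzable** with at least 60 full
days of the 90 (inclusive threshold). For adherence reporting, a day
counts as *worn* if it has any record at all — excluded participants'
partial wear would otherwise be invisible.

## Daily activity patterns

Cadence (steps/min) classifies each minute's intensity: >= 20 steps/min
is activity, >= 100 is moderate-to-vigorous (MVPA), >= 130 vigorous; all
thresholds are inclusive and configurable. Per full day we derive: total
steps; total activity duration; MVPA duration; vigorous duration; MVPA
steps; and the morning-step proportion (steps before 12:00 over total
steps, a proxy for morning stiffness). The morning proportion of a
zero-step day would be 0/0 and is stored as missing (such a day cannot be
full anyway).

Participant summaries are means over full days. Weekly MVPA defaults to
the daily mean times seven; a calendar-week aggregation (per-week sums
rescaled for partially observed weeks) is also available. The two
coincide on fully observed data but can differ under weekly-structured
missingness, and published weekly figures do not always equal 7x the
published daily figure — both conventions are therefore exposed.
Recommendation scoring uses >= 150 min/week MVPA or >= 75 min/week
vigorous (WHO), and >= 10,000 or >= 7,000 steps/day; all inclusive.

## Missing-day imputation

For sensitivity analyses, each missing day of a participant's trajectory
is imputed by that participant's mean over observed days of the same
weekday (windows all start on Mondays, so weekday is day-index mod 7).
Observed cells are never altered, and observed weekday means are
preserved exactly. A participant with no observed instance of some
weekday falls back to their overall mean (logged); a participant with no
observed days at all cannot be imputed and is rejected.

## Trajectory clustering

Participant trajectories (one daily feature over the 90 days, MVPA
minutes by default) are partitioned by K-means in the style used for
longitudinal data: Lloyd iterations with plain Euclidean distance on the
whole 90-vector, no standardization or time warping, multi-start
(20 random starts by default, seed centroids drawn from the data), best
start by total within-cluster sum of squares, empty clusters reseeded
from the farthest trajectory. Ties in assignment go to the lowest
cluster index. Matrices with missing days are handled by available-case
distances (mean squared deviation over observed entries) with per-day
centroid means, so observed-data and imputed matrices go through the same
code path. Labels are canonicalised by ascending centroid grand mean:
cluster 0 is always the low-activity cluster.

Partition quality is scored by between-cluster dispersion B, within-
cluster dispersion W, and the Calinski-Harabasz ratio
(B/(k-1))/(W/(n-k)); `select_k` fits a range of k and keeps the
maximiser. The within-cluster SS is non-increasing over Lloyd iterations
and, on small instances, multi-start Lloyd attains the exhaustive-
enumeration optimum (both are tested).

Two caveats are worth stating plainly. First, the criterion compares
*ratios* of dispersions: when one class is very small (the default cohort
has a high-activity class of ~3%, five participants), the between-cluster
gain from isolating it cannot offset the (k-1) penalty, and the criterion
legitimately prefers k=2. An exact sum-of-squares decomposition shows
that for the default cohort structure no realistic within-cluster
dispersion makes k=3 the criterion's maximum — the within-class
participant variance alone already exceeds the bound. k is therefore
fixed at 3 in the replication pipeline (three clusters is the
substantive description of the cohort), while `select_k` implements the
criterion faithfully and is validated on cohorts with three well-
populated, well-separated classes. Second, K-means centroids are dragged
by boundary members: the fitted high-activity cluster absorbs the upper
tail of the moderate class, so fitted cluster proportions sit a few
points away from the generating class proportions even when recovery is
good (adjusted Rand index ~0.9 on the default cohort).

The main clustering runs on the imputed matrix; an available-case run is
always fitted alongside it and the assignment agreement between the two
(>= 90% expected) is reported as the imputation-sensitivity diagnostic.

## Cohort-level inference

**Longitudinal group comparison.** A daily feature over day 1..90 is
modelled by a linear mixed model: fixed effects for disease group, a
linear day trend (day centred and scaled to [-0.5, 0.5]), and baseline
covariates (sex, age, BMI, disease duration, biologic therapy,
employment, patient global assessment); random intercept and day slope
per participant; REML estimation delegated to statsmodels' MixedLM with
the response rescaled to unit variance for optimizer stability.
Residual heteroscedasticity is handled by a power-of-the-mean variance
function Var(e) = sigma^2 |mu|^(2 theta): for fixed theta the model is
*exactly* a row-rescaled mixed model (response, fixed and random design
rows divided by |mu|^theta, with mu the conditional fitted values), and
theta is estimated by iterating the slope of log|residual| on
log|fitted| to zero (Harvey-type estimator, convergence tolerance 0.01,
max 4 iterations). The variance function engages only when a residual
slope test is significant at alpha = 0.05 ("when observed"); it can be
forced, fixed, or disabled. Non-convergence is flagged on the result,
never silently ignored.

**Logistic models.** Guideline fulfilment and low-cluster membership are
modelled by maximum-likelihood logistic regression with Wald 95% CIs,
adjusted for arthritis type and the covariates above. Age enters the
logistic models dichotomised at 60 years while remaining continuous in
the mixed model — an asymmetry kept deliberately, since the two analyses
conventionally report age differently. The BMI odds ratio is reported
per 5-unit increase (exp(5 beta), CI transformed identically). Rank-
deficient designs raise a collinearity error; quasi-separation is
flagged. No multiplicity adjustment is applied anywhere, and reports say
so.

**Design sample size.** Participants per group to detect a difference
delta between two means with common SD sigma:
n = ceil(2 (z_{1-alpha/2} + z_{1-beta})^2 (sigma/delta)^2), floored at 1.
The normal approximation is the default because it reproduces the
classical design numbers exactly (delta = 1500 steps/day, sigma = 3300,
80% power, alpha = 5% gives 76); a noncentral-t variant is available and
is never smaller.

## The synthetic cohort

The generator emulates a 178-participant RA/axSpA cohort followed for 90
days. Its defaults *are* the study conditions every simulation in the
test suite runs under:

- **Classes.** Three latent MVPA classes, constant in mean over time:
  7.2 / 23.8 / 49.4 min/day at proportions 54.1 / 42.7 / 3.2%. Class
  daily-step means (5950 / 8750 / 11400) are set so the realised cohort
  mean, Sunday dip included, lands near 7100 steps/day with SD ~2300.
- **Participant heterogeneity.** A shared lognormal participant factor
  (log-SD 0.2 for both steps and MVPA) perturbs class means. The spread
  is calibrated so that the three classes remain recoverable by the
  clustering stage (adjusted Rand ~0.9); wider spreads blur the
  class boundaries until the fitted partition no longer reflects the
  generating classes.
- **Covariates.** Age ~ N(45.8, 12.5), BMI ~ N(25.1, 4.5), disease
  duration, PtGA, sex, employment and biologic use drawn to match a
  typical established-arthritis outpatient cohort. BMI acts on activity
  twice: it shifts the latent class propensity (probit index with
  cutpoints chosen to keep marginal class proportions exact for any
  effect size; default 0.4 per BMI SD, roughly doubling the odds of
  low-class membership per 5 kg/m^2) and multiplicatively depresses
  within-class activity by 2% per kg/m^2. A purely within-class effect
  would leave cluster membership almost independent of BMI, because
  membership is dominated by the latent class; the propensity route is
  what makes a BMI-cluster association exist to be recovered.
- **Time structure.** Sundays scale all activity by 0.8 (weekly
  periodicity with quieter Sundays). Day-to-day noise is lognormal for
  steps (log-SD 0.25) and Poisson-lognormal for MVPA minutes (log-SD
  0.35), giving realistic within-person CVs of ~25% and ~45%.
- **Missingness.** Each participant's daily missing-day probability is
  Beta-distributed (mean 8%, concentration 37.5 — adherence differs
  across people; a shared constant rate makes wear patterns far too
  homogeneous); worn days are partial (wear window < 8 h) with
  probability 5%; 15% of participants abandon the tracker at a uniform
  day in [30, 90). Together these yield ~88% of days worn, ~70% of
  participants wearing >= 80 days, and ~11% failing the 60-full-days
  rule.
- **Within-day structure.** Minutes are placed by an hour-of-day weight
  profile (quiet nights, ~32% of steps before noon, afternoon/evening
  plateau) with MVPA cadences ~N(112, 8) clipped to [100, 180], light
  activity ~N(48, 14) clipped to [20, 99], and incidental sub-rest
  minutes at cadence 1-19. Full days carry two low-cadence sentinel
  minutes near 07:30 and 21:00 so the generated wear span always
  satisfies the full-day rule. No within-day model is validated against
  real data — the diurnal shape is a plausible free choice, and
  conclusions about sub-day structure should not be drawn from it.

Day-level simulation studies (mixed-model error rates, logistic
recovery) sample from the generator's day layer directly
(`simulate_daily_features`); rendering and re-aggregating 1440 minutes
per day would add cost but no information at that level.

What passing tests on this cohort do **not** show: robustness to device
artifacts (false steps, sync loss), to non-lognormal activity
distributions, to informative missingness (missingness here is
independent of activity level given the participant), or to trajectory
shapes that change over time (class means are constant, as the study
design assumes).

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through numpy
Generators; a fixed seed gives bit-identical cohorts, cluster models and
reports. Problem sizes in the test suite are chosen to keep the full run
within a few minutes of CPU: 200 replicates for the mixed-model type-I
check at 60 participants per group, 60 replicates for power at the
design size (76 per group), 100 replicates per logistic simulation at
n=157, 20 seeds for cluster recovery. Exhaustive partition enumeration
is used as the clustering oracle up to 10 trajectories. Lloyd iterations
cap at 200 (never reached in practice); assignment ties break to the
lower label; the quality criterion is reported as missing at k=1 and
infinite for a zero-W partition.

## Known limitations

- K-means with Euclidean distance cannot represent shape differences or
  time shifts; it is the method replicated here, not a recommendation.
- The power variance function uses a two-stage slope estimator rather
  than joint REML over theta; for the mild heteroscedasticity of step
  data the difference is well below the fixed-effect standard errors.
- Wald CIs for odds ratios are first-order; with 5-member clusters or
  near-separation they can be optimistic (flagged, not corrected).
- The generator's class structure is stylised: real cohorts do not have
  sharply defined latent activity classes.
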