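# Methods

`iohdef` implements a two-stage, data-driven procedure for deciding which
definition of intraoperative hypotension (IOH) is most strongly associated
with three perioperative outcomes — 30-day mortality, hospital length of
stay (hLOS) and post-anesthesia-care-unit length of stay (PACU-LOS) — and
for estimating the adjusted association of the winning definition on an
independent half of the data.  Because no public dataset couples raw
intraoperative blood-pressure series with these outcomes, the package also
ships a synthetic cohort generator with fully known ground truth; every
claim the test-suite makes about the pipeline is a claim about its behavior
on that generator.

## Signal processing

Raw records are timestamped SBP/DBP/MAP triples per patient.  Six cut-off
rules remove artifacts: SBP ≥ 300, SBP ≤ 20, DBP ≤ 5, DBP ≥ 225,
SBP ≤ DBP + 5 (all per sample, on raw values), and any pressure channel
outside the patient's mean ± 3 SD.  Rule 6's statistics are computed once
on the survivors of rules 1–5 and are **not** iterated: iteration is
non-idempotent and has no principled stopping point.  A sample violating
several rules is attributed to the lowest-numbered one.  Which channel(s)
the 3-SD rule screens is genuinely ambiguous ("a patient's mean blood
pressure"); the default screens all three channels, a MAP-only variant is
selectable (`rule6_channels=("map",)`), and neither is asserted as the
historically correct reading.  Samples missing MAP get it derived as
(SBP + 2·DBP)/3 when SBP > DBP; samples with no usable pressure are dropped
with their own reason code.

Cleaned series are linearly interpolated to a homogeneous 15-second MAP
grid from the first to the last retained measurement, never extrapolating.
Anesthesia duration is operationalized as last-minus-first retained
timestamp (no other definition is available from chart data alone), and a
grid tick represents 0.25 min of exposure.  Internal gaps are interpolated
across with no cap by default; a `max_gap_s` option exists for sensitivity
use.

## The definition registry

Four families, 24 members by default (`tables_24`; the `methods_22`
registry drops the 15-minute entries):

| family | parameter | value returned |
|---|---|---|
| lowest sustained MAP | 1, 3, 5, 10, 15 min | smallest threshold held ≤ continuously for the window (sliding-window max, then min) |
| lowest cumulative MAP | 1, 3, 5, 10, 15 min | k-th smallest grid value, k = 4·minutes (total, interruptible time) |
| absolute time below | 50…80 mmHg by 5 | 0.25 min × ticks strictly below |
| relative time below | 50…80 mmHg by 5 | the above / anesthesia duration, clipped to [0, 1] |

Conventions worth stating: "N minutes" is 4·N ticks (a tick is an
interval, not an instant); the episode families use *at-or-below* so the
returned limit is an attained MAP value, while the time-below families use
strictly-below, matching "time under" phrasing; records shorter than a
window yield a missing value and the patient drops out of that
definition's models only.  These choices are pinned by brute-force
threshold-scan oracles in the tests: on random grids the sliding-window
and order-statistic implementations agree exactly with direct enumeration.

## Model design

For one definition and one outcome the design contains: the winsorized
(99th-percentile-capped) definition value expanded in a natural cubic
spline basis (3 df), plus a binary zero-exposure indicator for the
time-below families (their distributions have a point mass at zero — the
patients with no hypotensive time at all); sex, surgical specialty (6
levels) and ASA class (1–4) as dummies with reference male /
"Urology, gynecology, general surgery" / ASA 2; age and winsorized BMI as
2-df splines; winsorized surgery duration, time from admission to surgery
and the Charlson-type comorbidity score as 3-df splines.

The spline basis is the truncated-power natural cubic basis (linear term
plus differences of scaled truncated cubics), boundary knots at the data
extremes and interior knots at equally spaced quantiles.  Heavily tied
variables (the comorbidity score, the rarely-positive time-below
definitions) can collapse quantile knots; duplicate knots are merged, and
a variable with fewer than three distinct knots falls back to a single
linear column with a warning.  Quantiles use the linear-interpolation
estimator throughout.  Winsorization caps and knots are computed once on
the dataset half being modeled, before cross-validation; the mild
information leakage is accepted as part of the emulated procedure and the
parameterization is recorded in the matrix metadata so estimation-stage
predictions reuse it.

Mortality models use the 30-day death flag.  For hLOS, patients who died
before discharge are assigned an infinite stay, the largest
⌈trim·n⌉ values are removed (infinities first, exact ties broken by
patient id for determinism) and the natural log of the remainder is the
outcome — the analysis then describes the (1−trim) "best" patients.
PACU-LOS is trimmed the same way but without the infinity rule (the
set-to-infinity convention is tied to in-hospital death and hospital
stay); patients admitted directly to ICU are excluded from the PACU
analysis entirely.  If deaths-before-discharge exceed the trim fraction
the trim cannot produce a finite outcome and the matrix builder raises,
rather than silently dropping extra rows.

## Fitting and scoring

Logistic models are fit by iteratively reweighted least squares
(tolerance 1e-8 on the coefficient sup-norm, ≤ 100 iterations), linear
models by least squares; both report log-likelihood, AIC and the
asymptotic covariance, and the tests cross-check coefficients, likelihoods
and covariances against statsmodels.  For linear models the AIC counts the
residual variance as an estimated parameter (k = p + 1), keeping the
identity AIC = 2k − 2·loglik exact; the constant offset against other
conventions cancels in Akaike weights.  Quasi-complete separation is
flagged when the fitted log-odds exceed 30 in absolute value (fitted
probabilities numerically pinned at 0 or 1) or when IRLS fails to
converge; flagged fits are excluded from ranking with a reason.  A
standardized-coefficient cutoff was tried first and rejected: natural
spline blocks are collinear enough that large opposite-signed
coefficients routinely describe a perfectly modest fitted function.
Rank-deficient designs drop aliased columns (pivoted QR) with a warning.
Goodness of fit for mortality models uses the Hosmer–Lemeshow Ĉ statistic
on deciles of predicted risk (ties share a group, df = groups − 2).

## Selection stage

Patients are randomly halved (sizes differ by ≤ 1, deterministic by seed).
On the shaping half, every registry definition's multivariable model is
scored by k-fold cross-validation with R repetitions (defaults k = 10,
R = 40): per repetition a fresh partition (stratified by outcome for
mortality; folds whose training part has no outcome variation are skipped
and counted), per fold a refit on the remaining folds, held-out
predictions pooled, Brier score (mortality) or log-scale MSE (stay
outcomes) computed per repetition and averaged.  Definitions are ranked
ascending; exact ties break toward fewer parameters, then registry order.

Selection uncertainty is summarized by Akaike weights from single fits on
the full shaping half (AIC is a full-data quantity; CV refits would
conflate two resampling schemes): w_i ∝ exp(−Δ_i/2), sorted descending and
accumulated until the cumulative weight first exceeds 0.95, including the
model that crosses the boundary — so the set always contains the
top-weight model.

## Estimation stage

The selected definition's model is refit on the held-out half with the
same settings (dfs, winsorization rule, trim fraction), re-parameterized
on that half.  Adjusted effect curves are drawn for a fixed reference
patient (male, 53 y, BMI 26, 1.7 h surgery, 1 day to surgery, reference
specialty, ASA 2, comorbidity 0) over the winsorized exposure range, on
the probability scale for mortality and back-transformed (exp) to
days/hours for the stay outcomes, with delta-method 95% CIs on the linear
predictor transformed monotonically — the point estimate is therefore
always inside its own band.  Effect sizes are contrasts at clinically
salient exposures (MAP 50/65/75 mmHg; 5 and 10 min; 5% and 10% of
anesthesia time) against a reference exposure: MAP 75 mmHg for the episode
families and zero time below threshold (indicator on) for the time-below
families — the highest listed "clinically relevant" MAP and the natural
null exposure respectively; both are configurable.  Contrasts reduce to
linear functionals of the exposure block (adjustment covariates cancel),
with delta-method CIs; odds ratios for mortality, stay ratios otherwise.

Variable contributions repeat the cross-validation once per variable
group removed (IOH block including its indicator counts as one group),
sharing fold partitions across refits so the deltas are not confounded by
partition noise.  Sensitivity variants rerun the shaping stage with trim
fractions 1.5%/2% and a 4-df exposure spline.

## The synthetic generator

Per patient, drawn from an independent counter-keyed substream of one
master seed (so enlarging a cohort never reshuffles earlier patients):

* covariates loosely matched to a general surgical population: age
  ~N(52, 19) truncated at 18, BMI log-normal around 25.7, surgery duration
  log-normal around 100 min, time-to-surgery log-normal around 1 day,
  56.6% female, ASA probabilities (0.30, 0.45, 0.23, 0.02), six specialty
  categories, zero-inflated comorbidity score.  These are defaults, not
  fitted targets.
* a MAP process: constant baseline ~N(85, 8) mmHg, AR(1) noise
  (lag-15 s autocorrelation 0.9, marginal SD 4 mmHg, clipped at 2.6 SD),
  rectangular hypotensive episodes arriving at `episode_rate`/h with
  uniform depth (10–35 mmHg) and duration (1–15 min).  SBP/DBP are
  reconstructed from a per-patient pulse pressure with small bounded
  measurement noise.  Records are emitted in the two historical recording
  dialects (every 2 min vs. every 15 s).
* artifacts: per-sample corruptions at `artifact_rate`, uniformly targeting
  each of the six cleaning rules, with a hidden truth channel recording the
  targeted rule, so cleaning sensitivity is measurable.
* outcomes: the "true" exposure is one chosen registry definition computed
  on the artifact-free grid and standardized across the cohort;
  mortality is Bernoulli with logit = intercept + β_mort·z + covariate
  effects, the stays log-normal with analogous linear predictors.  PACU-LOS
  is missing for the `icu_admission_prob` fraction admitted directly to
  ICU; a configurable fraction of 30-day deaths occur before discharge.

Two guarantees are engineered in.  First, artifact-free series pass all
six cleaning rules by construction: noise is bounded, channel margins keep
rules 1–5 unreachable, and episode depth is rescaled (then residual
noise-wander outliers clamped) until the 3-SD rule is satisfied with
margin.  Without this, a single short deep episode — or plain AR(1)
wander, whose sample SD can sit well below the marginal SD — would
legitimately trip rule 6, and the generator could not promise that truth
exposures equal the pipeline's recomputation.  The cost is that episode
depth is a cap rather than an exact realization for sparse-episode
records.  Second, outcome randomness is drawn per patient before
cohort-level standardization, so outcome draws are reproducible per
patient even though the exposure z-scores are cohort-level quantities.

What the generator does **not** emulate: vasopressor/fluid management and
its feedback on blood pressure, non-stationary baselines, measurement
gaps, informative artifact timing, correlated covariates (age and ASA are
drawn independently), or competing risks between death and discharge.
Passing tests therefore demonstrate the pipeline's internal correctness
and statistical calibration under a known model, not fidelity to any
hospital's data-generating process.

## Problem sizes and event rates at desk scale

The emulated study had ~65,000 patients with a 0.9% 30-day mortality
(~580 events).  Scaling the cohort down while keeping the event *rate*
would leave a handful of events against ~27 parameters and every logistic
fit quasi-separated, so desk-scale runs keep the event *count* comparable
instead: demo and recovery cohorts raise the mortality intercept to ≈5%
prevalence (≈500 events at n = 10,000) and lower the
death-before-discharge share so deaths stay below the 1% hLOS trim.
Prevalence calibration at the realistic 0.9% is still verified directly on
the generator at n = 20,000–50,000, where it is estimable.

Monte-Carlo suite sizes used by the tests: oracle equivalence on 10,000
random grids; parameter recovery over 10 replicates at n = 10,000
(contrast within 3 SE in ≥ 9/10); definition recovery over 20 replicates
at n = 4,000 with a strong planted effect (top-3 rank in ≥ 80%); null rank
uniformity over 16 replicates at n = 1,200 (χ² on rank quartiles,
α = 0.01); end-to-end determinism on a full demo run at n = 2,000 with 5
CV repetitions.

## Numerical and degenerate-input choices

IRLS probabilities are clipped at 1e-10 for the working weights; CV fold
seeds derive from a SeedSequence of the scheme seed; all JSON artifacts are
written with sorted keys so reruns are byte-identical.  Degenerate inputs
are first-class: empty cleaned records raise a "no valid blood pressure"
exclusion, single-sample records cannot be gridded, grids shorter than an
episode window yield missing definition values, all-ICU cohorts make the
PACU analysis set empty (error), and constant predictors reduce the
Hosmer–Lemeshow grouping with a warning.

## Known limitations

* The zero-spike indicator gives time-below models one more parameter than
  episode models, so under the null the CV ranking is not exactly
  exchangeable across families; the uniformity check is run at a
  significance level (0.01) and replicate count where this bias is
  negligible.
* Akaike weights compare models fit to slightly different rows when
  definitions differ in missingness (short records); with the default
  generator durations this affects no patients, but real short records
  would make AICs not strictly comparable across definitions.
* Delta-method CIs are first-order; profile-likelihood intervals may
  differ for small event counts.
* The 3-SD cleaning rule genuinely removes extreme true hypotension in
  sparse-episode records; the generator sidesteps this by construction,
  real data cannot.
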