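# Methods

## The decision problem

Critically ill patients with severe acute kidney injury (AKI) may start
kidney replacement therapy (KRT, acute dialysis) as soon as they become
eligible ("accelerated" initiation) or only once a conventional indication
develops ("standard" initiation). The two strategies differ in 90-day
survival, in dialysis dependence among survivors, and in health-care costs,
and those differences propagate over the rest of the patients' lives.
`krtcua` estimates the lifetime trade-off as a cost-utility analysis:
expected discounted cost and quality-adjusted life-years (QALYs) per
randomized patient in each arm, their increments, the incremental
cost-effectiveness ratio (ICER), the incremental net monetary benefit
(INMB), and a cost-effectiveness acceptability curve (CEAC).

## Model structure

A cohort-level Markov model with four health states defined at and after
day 90 post-randomization:

| state | definition | utility (beta α, β) |
|---|---|---|
| `NO_CKD` | alive, no dialysis, eGFR ≥ 60 mL/min/1.73 m² | 0.85 (80.00, 14.40) |
| `CKD_NO_KRT` | alive, no dialysis, eGFR < 60 | 0.74 (49.90, 18.00) |
| `KRT_DEPENDENT` | alive, receiving dialysis | 0.60 (44.80, 30.00) |
| `DEAD` | absorbing | 0 |

Cycles are monthly (1/12 year); the horizon is 480 cycles (40 years), long
enough for essentially complete absorption (the base-case trace reaches
dead-state occupancy > 0.999 by cycle 480, which the tests assert). The
cohort enters the model at day 90; the entry distribution includes the
90-day decedent fraction, so all outputs are means per randomized patient,
not per survivor. This convention is an inference: the per-survivor QALY
totals implied by dividing arm QALY means by 90-day survival are nearly
equal across arms, which is what one expects if decedents are carried in
the denominator. It is configurable
(`ModelConfig.include_decedents_in_start`).

Entry mixture per arm: 90-day survival 68.5% (accelerated) / 78.1%
(standard); KRT dependence among survivors 2.1% / 9.8%. The split of the
remaining survivors between `NO_CKD` and `CKD_NO_KRT` is not published; it
is a parameter (`StartParams.nockd_share_nonkrt`) defaulting to 0.5, and
base-case state occupancy (hence costs and QALYs) depends on it.

### Transition probabilities

Static monthly probabilities (beta-distributed in the PSA, with the
published shape parameters):

* `NO_CKD → KRT_DEPENDENT` 0.001; `CKD_NO_KRT → KRT_DEPENDENT` 0.016;
  `KRT_DEPENDENT → NO_CKD` 0.073; `KRT_DEPENDENT → CKD_NO_KRT` 0.063
  (shared between arms);
* `CKD_NO_KRT → NO_CKD` is arm-specific: 0.139 (standard) vs 0.063
  (accelerated) — the only arm-split transition in the evidence.

Some published beta shapes are not perfectly consistent with their
published means (e.g. 0.396/2.875 = 0.1377 against a printed 0.139, and
49.90/67.90 = 0.7349 against a printed 0.74). The package treats the means
as authoritative for deterministic runs and the shape parameters as
authoritative for PSA sampling, and does not attempt to reconcile them.

Time-dependent monthly probabilities are summarized in the evidence only as
a mean and range over the horizon:

* deaths: `NO_CKD` 0.022 (0.001–0.990), `CKD_NO_KRT` 0.030 (0.003–0.990),
  `KRT_DEPENDENT` 0.033 (0.005–0.990), arm-independent;
* progression `NO_CKD → CKD_NO_KRT` 0.001 (0.000–0.017).

### Schedule construction and calibration

The per-cycle shape of those vectors is not published, so the package uses
the simplest shape consistent with the summary and with mortality rising
over a lifetime: log-linear (Gompertz-like) growth from the range minimum
toward the maximum,

    p_t = min · (max/min)^(c · t/(n−1)),  capped at max,

with a single exponent `c` per schedule solved (Brent's method) so the
vector mean matches the published mean to 1e-3. The calibrated `c` values
are reported in the run manifest. When the published minimum is 0 the
log-linear start is replaced by a small positive floor (max/1000) before
calibration. Consequences to keep in mind: the minimum of the schedule
equals the published minimum exactly, the maximum is generally *below* the
published maximum (the mean constraint binds first: the base-case death
schedules top out near 0.10–0.11), and any other shape with the same mean
and range would give different lifetime totals. This is the main reason the
published lifetime table is not exactly reproducible from published inputs;
the package's lifetime QALYs run higher than the published ones, while all
signs, orderings and dominance results agree (and are what the tests
assert).

Each cycle's matrix is assembled from the off-diagonals with the diagonal
as residual; the dead row is (0, 0, 0, 1). A deterministic matrix whose
off-diagonals exceed 1 raises an error naming the row.

## Costs

Period costs in 2024 Canadian dollars, following the observation that
health-care costs stabilize about four months after KRT initiation:

* a one-time cost from index admission to day 90, booked undiscounted at
  model entry for every randomized patient (decedents' acute-care costs
  included): mean (SD) 182,626 (175,710) accelerated / 161,601 (104,048)
  standard;
* a month-4 (days 91–120) cost applied only to the first model cycle;
* a steady monthly cost (> 120 days) applied to every later cycle and
  extrapolated over the remaining lifetime (the evidence covers costs only
  to one year; uniform extrapolation is the natural reading of applying the
  average monthly cost to the remaining months).

Monthly totals are decomposed across the alive states with the published
shares — KRT-dependent 71%, CKD 17%, no-CKD 12% of total monthly cost —
applied to both the mean and SD of each period total (e.g. accelerated
month 4: 28,486 × 0.71 ≈ 20,299). The dead state accrues nothing. Cycle
contributions are weighted by end-of-cycle occupancy; an optional half-cycle
correction (off by default — with monthly cycles it changes QALYs by well
under 2%) averages adjacent occupancy rows instead.

Costs and QALYs are discounted at 1.5%/year as (1.015)^(−t/12) for cycle t;
cycle 0 is undiscounted.

## Probabilistic sensitivity analysis

5000 Monte Carlo draws by default. Per draw: utilities and static
transitions from their betas, costs from method-of-moments gamma fits
(k = mean²/SD², θ = SD²/mean; SD = 0 yields the constant), and each cycle's
time-dependent probability from a per-cycle beta with mean equal to the
calibrated schedule value. The per-cycle sampling SD is not identified by
the published summaries; the package sets SD_t = CV·p_t with the CV taken
from the calibrated schedule itself (std/mean across cycles, ≈ 0.8–1.2 for
the death schedules), scalable via `timedep_cv_scale` (0 freezes the
schedules). When beta moments are infeasible for a cycle the sampler falls
back to a [0, 1]-truncated normal; occurrences are logged and counted in
the result diagnostics.

Sampled rows can be infeasible (the `KRT_DEPENDENT → CKD_NO_KRT`
Beta(0.036, 0.521) is extremely skewed and occasionally draws near 1): such
rows are renormalized to off-diagonal sum 1 with diagonal 0, counted and
logged (≈ 0.5% of draw-cycle rows in the base case). The deterministic
engine never renormalizes — it raises.

Parameters without an arm split (utilities, shared transitions, the death
and progression schedules) use the same draw in both arms, so incremental
results are not diluted by common noise. Arm-specific quantities (costs,
`CKD_NO_KRT → NO_CKD`, starting mixtures) are drawn/set per arm. Starting
mixtures are not sampled.

Reported per analysis: per-arm mean (SD) cost and QALYs over draws; ΔC and
ΔQ (standard − accelerated); the ICER as the ratio of mean increments (not
the mean of ratios), with southwest/northeast dominance flags; the INMB
λ·ΔQ − ΔC at λ = $50,000/QALY; and the CEAC P(λ·ΔQ − ΔC > 0) on a λ grid of
$0–$100,000 in $1,000 steps, with the linearly interpolated λ at which it
crosses 0.5. Two intervals accompany the INMB: `inmb_cri`, the 2.5th–97.5th
percentile of the draws (parameter uncertainty in the incremental net
benefit), and `inmb_mean_ci`, mean ± 1.96·SD/√n (uncertainty in the
*expected* INMB — the much narrower interval that published mean-INMB
intervals correspond to numerically).

## One-way scenarios

* **start-states**: KRT dependence among 90-day survivors replaced by the
  trial-wide 10.4% (accelerated) / 6.0% (standard); survival and everything
  else unchanged.
* **equal-costs**: every month-4 and steady monthly cost parameter replaced
  by the unweighted two-arm average (e.g. pooled steady total
  (3,293 + 5,558)/2 = 4,425.5); one-time 0–90 day costs keep their
  arm-specific values. "Equal monthly costs" could also mean adopting one
  arm's values; pooling is the default reading, and the parameter
  transformation (`ModelParameters.with_pooled_monthly_costs`) is separate
  from the engine so alternatives are easy to construct.

## Synthetic cohort generator

Patient-level inputs for this analysis are confidential linked
administrative records, so the generator produces cohorts with the same
statistical structure for testing and demonstration: per-arm Bernoulli
90-day survival and KRT dependence, a configurable no-CKD share of the
remaining survivors, eGFR from truncated normals on either side of 60
(N(75, 12) on [60, ∞) and N(45, 12) on [5, 60) — only the ≥60/<60
classification matters downstream), gamma period costs and beta utilities
by method of moments, and day-90 → day-365 evolution by nine monthly
multinomial steps under the configured monthly matrix, which is what makes
estimator parameter recovery a meaningful test. An optional
`state_cost_shares` tilts post-90-day costs by day-90 state (mean scaled by
share/occupancy) so the aggregate 71/17/12 decomposition is recoverable
while the overall mean is preserved.

What the generator does not emulate — and hence what passing tests do not
establish about real data: within-patient cost–outcome correlation
(costs, utilities and transitions are drawn independently given the
state), calendar effects, site heterogeneity, informative missingness of
EQ-5D-5L responses, and any deviation of true cost distributions from the
gamma family. Recovery tests show the estimators invert the generator, not
that the generator matches Alberta.

## Estimation from patient-level data

State classification: dead dominates; dialysis dominates eGFR; eGFR = 60
classifies as `NO_CKD` (boundary belongs to "≥ 60"). The day-90 → day-365
transition matrix is the row-normalized 4×4 count matrix (dead row forced
to (0,0,0,1)); rows with no day-90 occupants are flagged inestimable rather
than zero-filled, and the caller must supply fallback values. The monthly
adjustment applies the constant-hazard map 1 − (1−p)^(1/9) to each
off-diagonal and p^(1/9) to the diagonal, then renormalizes the row — the
standard competing-risk compromise; it does not exactly invert a 9-step
matrix power, so parameter-recovery tests compare the *period* matrix
against the true 9-step product, which is the actual binomial quantity.

`CostUtilityModel.from_cohort` assembles a full parameter set from a
cohort: estimated statics get beta shapes from their binomial standard
errors; estimated monthly death probabilities become the schedule means
(ranges kept from the published base, but capped so that no row's
off-diagonals can exceed 1 once the estimated statics are in place);
utilities use observed EQ-5D-5L scores when a state has ≥ 10 observations
and literature values otherwise — mirroring how the original analysis
handled sparse day-365 quality-of-life data.

## Numerical choices and problem sizes

* Schedule calibration: Brent root-finding, xtol 1e-12; mean tolerance 1e-3
  enforced at construction.
* Trace checks: row sums within 1e-9; dead occupancy nondecreasing.
* Beta/gamma moment fits raise on infeasible moments
  (sd² ≥ mean(1−mean), nonpositive gamma moments) rather than clipping.
* CSV round trips write floats at full `repr` precision and read with
  pandas' round-trip parser, so read(write(x)) == x exactly.
* The PSA engine is vectorized across draws (one seeded
  `numpy.random.Generator`, fixed sampling order), making a 5000-draw,
  480-cycle, two-arm run a few seconds; `sample_draw` exposes the identical
  single-draw distribution for inspection and testing.
* Test problem sizes: parameter recovery uses 10⁵ patients per arm with
  3-standard-error bands; structural property checks use 1000 random
  configurations; directional end-to-end checks use the full 5000-draw PSA.

## Known limitations

* The per-cycle death schedules are under-identified by a mean and range;
  lifetime magnitudes therefore depend on the chosen shape, and only
  directions/orderings should be compared against published lifetime
  results (they agree; QALY levels here are higher).
* The no-CKD/CKD split at entry (0.5 by default) is unpublished and shifts
  both arms' levels.
* Steady monthly costs are extrapolated from the first post-admission year
  over the entire lifetime.
* Cohort expectation only — no individual-level microsimulation, no age/sex
  life tables, no value-of-information analysis.
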