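# Methods

This note records the modeling assumptions, estimator conventions,
numerical choices and known limitations behind `screenq`.  It states
no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## Model

An open network of `J` infinite-server queues tracks the number of
patients in each disease state.  The assumptions that buy exactness
are:

- **Poisson exogenous arrivals.** New disease instances arise as
  independent homogeneous Poisson processes.  This is the one
  assumption that is empirically testable from registry data, and the
  `gof` module tests it (yearly arrival increments vs a Poisson law).
  Networks with non-Poisson exogenous arrivals fall outside the theory
  and would require simulation only.
- **Arbitrary service times with finite means.** Waiting times between
  state transitions are iid per queue but need no parametric form — no
  memorylessness, no constant hazards.  At equilibrium the joint
  occupancy law is a product of independent Poisson(ρ_j) marginals
  with ρ_j = λ_j/μ_j, where λ solves the traffic equations
  λ = η + λR.  The law depends on service distributions only through
  their means (insensitivity); the simulator-based tests exercise this
  with exponential, lognormal, deterministic and uniform services.
- **Infinite servers.** Patients never compete for capacity, so their
  paths are independent.  Finite-server phenomena (appointment queues,
  bed capacity) are deliberately out of scope.

Mean residual lifetime is the mean network sojourn by Little's law,
`E(W*) = Σ_j ρ_j / η`.  Exit from the network means death, so the
difference in `E(W*)` between a screening network and its no-screening
counterpart is the expected residual-lifetime gain of the program.

### Screening and counterfactual topology

The per-subgroup screening network has three queues: undetected
early-stage disease (mean sojourn `1/μ1`), early treatment, late-stage
disease (mean survival `1/μ3`).  Routing out of the early state sends
`r10` to death, `r12·d` to early treatment (`d` = detection
probability) and the rest to progression.  Early-treated survival
averages `e·L` where `e` is the screen's effectiveness and `L` the
subgroup's conditional residual life expectancy; anchoring survival to
the *conditional* life expectancy at the current age is what keeps the
estimates free of lead-time bias.

The no-screening counterfactual is not printed anywhere as a topology;
this package's choice is to reassign the screened mass `r12·d` to
progression (`r13`) rather than to death: screening catches patients
who would otherwise have presented symptomatically, while
death-before-diagnosis is already carried by `r10`.  At `d = 0` the
two networks coincide exactly (tested).

Treatment-associated morbidity multiplies the affected part of a
sojourn by a QALY factor in [0, 1]; treatment-associated mortality
mixes a point mass (default one month) into the early-treatment
service distribution with probability `p`.  Imperfect specificity
extends the network with a false-positive treatment queue fed by
healthy screenees who fail both the screen and a confirmatory test;
the net benefit (true-positive gains minus false-positive losses) can
be negative, which is the quantitative signature of overtreatment.

## Parameter estimation

There is no likelihood: with arbitrary waiting-time distributions only
means and proportions are identified, so the estimators are
deliberately simple and transparent.

- Diagnosis rate `η1`: mean yearly diagnosis count over the study
  window (default 2000–2016), including zero years.
- Treated fraction `f`: unweighted mean of per-year treated fractions.
- Treated survival: mean of (death − treatment start) after censoring
  imputation.  Untreated survival: mean diagnosis-anchored survival of
  untreated records.
- Late-stage mean `1/μ3` is composed as
  `f·(w + mean treated survival) + (1−f)·mean untreated survival`,
  with `w` the diagnosis-to-treatment wait.  `w` varies by institution
  and is not estimable from registry extracts; it is a tunable with a
  1-month default.
- The preclinical mean `1/μ1` cannot be estimated from
  diagnosis-anchored registries at all; the default of 180 months
  reflects the long genetic-progression window of pancreatic-like
  disease and should be set per cancer type.
- `L` comes from a life table stratified by ancestry × sex × coarse
  age band (≤64, 65–74, 75+), looked up at the 5-year band midpoint.
  The piecewise-constant bands produce a known artificial upward bump
  in modeled survival at age 65.

**Censoring imputation.** A record censored at `t` is replaced by the
mean of observed deaths exceeding `t` (equivalently
`t + E(s − t | s > t)`), the conditional-mean version of the
conditional-empirical-survival rule; imputing a random draw from the
conditional distribution is the unbiased-in-distribution alternative
and would only add variance to mean estimates.  When no observed death
exceeds `t` the rule is undefined; such records pass through unchanged
with a logged warning, which is conservative (imputation never
decreases a time).  Two small downward biases remain: the conditioning
deaths are themselves censoring-truncated, and the pass-through
records retain lower bounds.  Under the reference synthetic conditions
(17-year window, lognormal treated survival with 13.5-month mean and
log-sd 1.0, ~4% censoring) the validation experiments measure the
effect within the tolerances asserted in the acceptance suite.

**Exclusions.** Subgroups under 100 records are excluded rather than
estimated.  Incidence underestimation from deaths before diagnosis is
not corrected (it is small outside the oldest bands); a warning is
logged for 75+ subgroups.  Subgroups are keyed by age at disease
development, so there is no flux between age-band models.

**Registry-derived routing fractions.** A diagnosis-anchored registry
observes neither `r10` (death before any diagnosis) nor the
screen-detectable fraction directly.  Defaults: `r10 = 0`,
`r12 = 1 − r10` (every diagnosed case could in principle have been
caught during its preclinical window), both overridable in
`EstimationConfig`.

## Allocation

Per-screen benefit is constant within a subgroup, so total benefit is
linear in screens assigned and the greedy rule — rank by score,
saturate in order, skip scores at or below the threshold `T` — is
exactly optimal under the budget and size constraints (verified
against exhaustive search on random instances).  Scores strictly
greater than `T` qualify; ties break by larger subgroup then
lexicographic key for deterministic reports.  The threshold's units
(per screen vs per patient) are an explicit mode flag since both
framings are legitimate.  An equity-style constraint (per-group
minimums) is intentionally not built in; it would change the objective
rather than the algorithm and is better expressed by pre-partitioning
the budget.

## Simulator

Infinite servers make agents independent, so the simulator propagates
whole waves of agents with vectorized draws (arrivals → services →
routing) instead of a global event heap; this is exact for this model
class, not an approximation.  All variates come from one PCG64 stream
in a fixed processing order, so a seed fully determines the event log
(bit-identical reruns); a per-agent counter-substream scheme was
considered and rejected because it forfeits vectorization without
adding reproducibility.  Arrivals are drawn on `[0, horizon]` and each
agent's path is followed past the horizon, so occupancy sampling
anywhere in the window is free of boundary truncation.  Defaults:
burn-in of 5× and sample spacing of 1× the largest mean service time.
Occupancy samples at that spacing retain mild autocorrelation (an
agent's total path can outlast one spacing), which inflates naive iid
standard errors; the validation experiments therefore size sample
counts generously rather than assume independence.

## Goodness of fit

The KS statistic is computed against discrete references (Poisson
counts/occupancies), where the classical asymptotic p-value is
conservative.  Default p-values therefore come from a simulated null
(the asymptotic version remains available behind a flag).  For the
arrival test the rate is re-estimated inside each null replicate,
because the observed rate is itself estimated from the counts under
test; for the queue-length test the predicted load is an external
model quantity and is held fixed.  Decisions across subgroups use
Bonferroni-adjusted p-values at 5%.

## Validation experiment sizes

Chosen so Monte-Carlo noise sits well inside each tolerance on one
CPU, and stated here as the package's own design points:

- Product-form marginals: 3×10^4 decorrelated occupancy samples per
  service family (spacing 15 months) on the two-queue reference model
  (loads 60 and 48).  The total-variation noise floor for a
  Poisson(60) marginal is ≈ 2.5/√m, so resolving a 0.02 TV band needs
  m ≳ 2×10^4 even for a perfect model.
- Little's law: 3×10^5 agents on the three-state screening network
  (exact mean sojourn 8.6 years), putting the ~0.3% standard error of
  the mean about three sigma inside the 1% band.
- Parameter recovery: 20 independent synthetic registries at the
  reference conditions (η1 = 200/yr, f = 0.4, 17 years).
- GOF calibration: 500 null replicates with 500 simulated-null
  replicates each.

## What the synthetic registry does and does not emulate

It reproduces the *structure* that the estimators consume: Poisson
yearly arrivals per subgroup, Bernoulli treatment, arbitrary
(default lognormal, deliberately non-exponential) survival,
administrative right-censoring at a cutoff, 5-year age bands, and
coarse life tables.  It does not emulate secular trends in incidence
or survival, competing risks, migration between registries, treatment
selection on prognosis (treatment is assigned at random, so estimated
"benefits" are not confounded the way observational registry contrasts
are), staging detail, or reporting delay.  Passing tests therefore
show the estimators and pipeline are correct under the model's
assumptions — not that those assumptions hold in any particular
registry; the `gof` module is the tool for interrogating the latter.

## Numerical choices

- Traffic equations: direct LU solve of `(I − R)ᵀ λᵀ = ηᵀ` with a
  fixed-point fallback; residual tolerance 1e-9 relative.  "Every
  agent eventually exits" is checked via invertibility of `(I − R)`
  with a non-negative inverse (tolerance 1e-10), which is necessary
  and sufficient for a unique non-negative traffic solution.
- Joint pmf in log space; tails via the exact Poisson survival
  function (regularized incomplete gamma), valid for any load.
- Zero-load queues carry degenerate Poisson(0) marginals rather than
  erroring — the no-screening network always has an empty
  early-treatment queue.
- Times are months internally (registry survival is recorded in
  months); gains are reported in years, per-screen benefits in days
  (365 days/year).
- Declared service means must match analytic means to 1e-9 relative;
  queue indices are 0-based internally, 1-based in network files and
  display labels.

## Known limitations

- Stationary analysis only: no transient (time-dependent) occupancy
  distributions, no time-varying arrival rates.
- Single screening opportunity per preclinical episode (`d` multiplies
  the detectable fraction); repeated-screening schedules with
  correlated test outcomes are not modeled.
- No clinical-stage substructure and no period/cohort trend
  adjustment; aggregating 2000–2016 may mask improvements over time.
- The coarse life-table bands create the age-65 artifact noted above;
  finer life tables remove it without code changes.
- Observational registry survival reflects treatment selection and
  access-to-care effects; modeled gains inherit those biases unless
  the inputs come from randomized data.
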