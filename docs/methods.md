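# Methods

## Model

Patient flow through the ED is modelled as a continuous-time Markov chain on
five states: 1 triage, 2 physician management, 3 observation / waiting for
admission, 4 discharge, 5 admission. States 4 and 5 are absorbing. Seven
movements are allowed: 1→2, 1→4 (departure from triage without physician
contact), 2→3, 2→4, 2→5, 3→4, 3→5. The graph is acyclic, which the
closed-form absorption solver exploits (back-substitution over states in
label order).

Each movement carries an intensity `q_ij` in events per person-hour; time is
in hours everywhere and this is not configurable. Conditional on the
covariates, the waiting time in a transient state is exponential with rate
equal to the state's total exit intensity `r_i = Σ_j q_ij`, and the
destination follows the embedded jump chain `P(j) = q_ij / r_i`. One point
deserves care: the *reciprocal-rate* reading of an intensity (`1/q_ij` as a
mean waiting time) describes the hypothetical time to a particular movement
in isolation; under competing risks the realized mean sojourn in state *i*
is `1/r_i`. `sojourn_stats` reports the competing-risks quantities (mean
`1/r_i`, median `ln 2 / r_i`) and its docstring flags the distinction so
reports cannot conflate the two.

Covariates enter log-linearly, `q_ij(z) = q_ij0 · exp(β_ij · z)`, with
`exp(β)` the relative rate (RR) per unit increment. Covariates are numeric,
uncentered scores: triage level 1–5 (1 most acute), age group 1–5 (<20,
20–40, 40–60, 60–80, >80 years). Treating these ordinal scores as
continuous keeps the parameter count small at the cost of assuming a
constant RR per step; per-category coding would be the refinement.

Within-day variation is handled by a shift model: the 24-hour day is
partitioned into [0,6) night, [6,12) morning, [12,18) afternoon, [18,24)
evening, and each shift carries its own full set of baseline intensities
(piecewise-constant in clock time).

## Synthetic data

The generator produces exactly the data-generating process the estimators
assume, at reference parameter values describing a high-volume tertiary ED
(~150k visits/year): baseline intensities per movement, per-movement RRs for
triage level and age group, four-shift values for the observation→admission
intensity, and empirical covariate marginals (triage level
.0558/.1520/.5987/.1767/.0167; age group .2929/.2143/.2290/.1927/.0712;
category trauma/adult/pediatric .1763/.5916/.2322). The published age-group
tallies these marginals derive from total 147,907 against a cohort of
147,897, so each marginal vector is normalized by its own sum.

Choices a user should know:

- **Shift handling is freeze-at-entry.** A sojourn is drawn entirely from
  the rates of the shift in force when the state is entered, even if it
  crosses a boundary. This matches the estimator's attribution rule (below),
  making simulate→fit recovery internally consistent. A true
  piecewise-hazard sojourn (re-drawing the residual at each boundary) is the
  natural alternative; with six-hour shifts and sojourns mostly well under
  six hours the two differ mainly for the slow observation state.
- **Arrivals**: patients arrive over a configurable number of days (default
  7), with shift weights (night, morning, afternoon, evening) =
  (0.15, 0.30, 0.30, 0.25) and uniform placement within a shift. The weights
  are a package default — arrival patterns vary by site — and exist so that
  every shift is exercised; no day-of-week or finer seasonality is modelled.
- **No interaction between patients.** The chain has no capacity
  constraints, so the generator cannot reproduce congestion feedback
  (queueing delays that depend on census). Tests passing on these cohorts
  demonstrate correctness of the estimators under the model's own
  assumptions, not robustness to real-world model violations.
- The rare triage→departure movement (intensity 0.0005/h, under 0.1% of
  patients) is retained so that pathway is exercised.
- One seeded NumPy generator per cohort; the seed is recorded in a CSV
  header comment. Simulation is vectorized stage-by-stage (triage cohort →
  physician cohort → observation cohort), so 200k-patient cohorts take
  about two seconds.

## Inference

Timestamps are exact (administrative event logs), so the likelihood is the
exact-observation one: a spell of length `t` in state `i` ending in a move
to `j` contributes `q_ij(z) · exp(-r_i(z) t)`. Aggregated, the log-likelihood
is `Σ_ij [N_ij log q_ij − q_ij T_i]` with `N_ij` event counts and `T_i`
person-time — no omitted constants, so likelihoods are comparable across
nested fits and against brute-force per-patient computation (tested to
1e-9). Panel (interval-censored) likelihoods are out of scope.

- **MLE.** Closed form `q̂_ij = N_ij / T_i`; 95% Wald intervals on the log
  scale, `exp(log q̂ ± 1.96/√N_ij)`. The interval construction is a package
  choice; zero-event transitions yield a 0 estimate with undefined interval
  and are flagged rather than raised.
- **Covariate model.** Per transition, the likelihood is exactly that of a
  Poisson regression of the spell-level event indicator on the covariates
  with a log-sojourn offset. It is maximized by damped Newton/IRLS to
  gradient max-norm < 1e-8 (statsmodels' GLM is used as an independent
  cross-check in the test suite, not as the implementation). Singular
  information (e.g. a constant-zero covariate) falls back to least-squares
  steps and pseudo-inverse covariance; non-convergence and |β| > 30
  (separation) are flagged in the result, not raised.
- **Shift attribution.** A spell belongs wholly to the shift of its
  state-entry clock time; exposures are not split at boundaries. This
  mirrors the generator and keeps the per-shift likelihoods independent.
  Boundary-splitting would be the alternative convention for data whose
  sojourns often span shifts.
- **MCMC.** Because the likelihood factorizes, the random-walk Metropolis
  sampler runs an independent chain on each `log q_ij`. Default prior
  Normal(0, 10) on the log scale (vague); a Gamma(a, b) prior on the rate
  scale is supported, for which the posterior is Gamma(a+N, b+T) exactly and
  serves as a conjugate correctness check. Proposal scale adapts toward
  ~35% acceptance during burn-in only (preserving detailed balance
  afterwards); defaults 6000 iterations, 1000 burn-in; posterior medians and
  central 95% intervals are reported, and acceptance rates outside
  [0.1, 0.6] are flagged. With ~150k-patient data the posterior medians
  agree with the MLE to well under 1%.
- **Degenerate inputs.** Tied timestamps (zero sojourns) are nudged forward
  by one second (1/3600 h) with a logged count; records with non-monotone
  timestamps are rejected with their ids, either aborting (default) or
  skip-and-log.

## Prediction

State occupancy after entry at triage is the first row of
`P(t) = expm(Q t)`, computed by SciPy's scaling-and-squaring matrix
exponential on the full 5×5 generator (the acyclic closed form and a stiff
ODE integration serve as independent oracles in tests, never as the
implementation). For shift models the distribution is propagated through
successive shift windows, multiplying by each window's matrix exponential;
the curve is therefore continuous across boundaries and invariant to the
reporting grid (tested to 1e-9). Default grid: 0.1 h steps over a 6-hour
horizon. Curves condition on reference (all-zero) covariates unless a
covariate vector is supplied; averaging over a cohort distribution can be
done by mixing curves externally. In-system probability is
`1 − P(discharge) − P(admission)`.

Steady-flow counts multiply each intensity by the supplied census of its
origin state and round half-away-from-zero to integers; transitions out of
states without a supplied census are reported as "—" (the triage census is
typically not a tracked bed count).

## Problem sizes and tolerances in the test suite

Simulation-recovery tests use cohorts of 2,000 (shared fixture), 100,000
(covariate/shift recovery) and 200,000 (rate recovery, medians,
Monte-Carlo cross-checks) patients — sizes at which Monte-Carlo error is
comfortably below the asserted tolerances (e.g. relative SE of a rate with
N events is 1/√N). Tolerances follow that scaling: 2% for well-populated
transitions, widened to three Poisson standard errors for sparse strata
(the rare triage-departure movement; the night-shift observation→admission
stratum, whose intensity 0.0012/h yields only a few hundred events per
100k patients). Wald-interval calibration is checked over 200 replicates of
2,000 patients against the binomial band [90%, 99%] for nominal 95%.

## Known limitations

- Markov (memoryless) sojourns: no duration dependence within a state.
- No capacity/queueing feedback; rates are per-patient and independent.
- Covariate effects are constant within a visit (no time-varying
  covariates) and log-linear in ordinal scores.
- The shift model freezes rates at state entry rather than integrating the
  piecewise hazard across boundaries.
- Frequentist intervals are Wald-type; they can undercover for very sparse
  transitions (where the result is flagged anyway).
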