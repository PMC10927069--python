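# Methods

## The estimand and the estimator

The quantity of interest is the expected number of days an employee
spends in each of seven labor market states over a fixed 730-day
follow-up, as a function of a work-stress exposure count (0–3), within
six sex × age strata (18–34, 35–49, 50–64). Four states are recurrent
(work, sickness absence, unemployment, temporary out) and three are
absorbing (retirement, disability pension, death); the 24 permitted
transitions are every recurrent state into each of the six other
states.

Estimation proceeds in four steps per stratum:

1. **Per-transition Cox models.** Each arrow *h → j* gets a weighted
   proportional-hazards fit on the clock-forward scale (days since
   follow-up start), with delayed entry at each episode's start day so
   repeat visits to *h* contribute repeat risk periods. The only
   regressors are three exposure-level dummies (levels 1–3 vs the
   zero-indicator reference). Ties are handled by Breslow's
   approximation and the reference baseline cumulative hazard is the
   Breslow estimator dA⁰(t) = d_t / Σ_ℓ Y_ℓ(t)·e^{β_ℓ}, where d_t is
   the weighted event mass and Y_ℓ(t) the weighted risk mass of level ℓ.
   The Newton solver works on (event-day × level) aggregates, which
   makes it exact and fast for categorical exposure; it is cross-checked
   in the test suite against lifelines on tie-free data (where Efron and
   Breslow coincide) and against a hand-computed Nelson–Aalen value.

2. **Product-integral probabilities.** For exposure level ℓ the
   increment matrix dA(t_m) has off-diagonals dA⁰_hj(t_m)·e^{β_hj,ℓ}
   and a diagonal making rows sum to zero; the state probability matrix
   is the finite product P(0,t) = ∏_{t_m ≤ t}(I + dA(t_m)) over event
   days — the discrete realization of the Chapman–Kolmogorov
   composition rule. If heavy ties push a row's increment mass above 1,
   the off-diagonals of that row are rescaled to unit mass and a
   warning logged, keeping every factor stochastic.

3. **Durations.** Occupation probabilities p_k(t) = Σ_h π_h P_hk(0,t)
   are step functions, so E_k = ∫₀⁷³⁰ p_k dt is computed exactly as a
   sum of segment widths × levels. π is the observed start-state
   frequency of the stratum × exposure cell (cells are free to start in
   any recurrent state). Deltas are Δ_k(ℓ) = E_k(ℓ) − E_k(0); days are
   conserved (Σ_k E_k = 730, Σ_k Δ_k = 0) by construction.

4. **Resampling intervals.** 1000 parameter draws are propagated to the
   duration scale: per transition, coefficient vectors from the
   asymptotic normal N(β̂, Î⁻¹), and baseline increments rebuilt under
   each coefficient draw as d_t / Σ_ℓ Y_ℓ(t)e^{β*_ℓ} plus an
   independent normal perturbation with the Poisson-type standard error
   √(Σ_{events} w²)/denominator. Rebuilding the denominator per draw is
   essential: coefficient error moves all of a transition's baseline
   increments coherently, and ignoring it makes reference-level
   intervals far too narrow. Draws are shared across exposure levels so
   delta intervals come from coupled draws. Intervals are empirical
   2.5/97.5 percentiles.

Confounding is handled entirely by weights: a per-stratum multinomial
logistic propensity model of the exposure level on nine categorical
baseline covariates (BMI, smoking, alcohol, physical activity, disease
treatment, working-time arrangement, sector, education, number of
survey waves, each with explicit "not available" levels) yields
stabilized weights P(ℓ)/p̂(ℓ|x), floored at propensity 0.001, times the
register coverage weight. Education may change during follow-up but
weights are fixed at follow-up start. Covariates deliberately never
enter the Cox linear predictors.

Censoring truncates each follow-up at the first of: day 730, the day
the person turns 65, the start of the person's next follow-up, or a
registered employer change. When raw overlapping payment records are
supplied, state prioritization resolves each day: absorbing states
dominate recurrent ones (death > disability pension > retirement among
simultaneous absorbing records); among recurrent payments the one with
most recorded hours per day wins; uncovered days inherit the preceding
state, since the registers contain no leisure-time records.

## Costing

Duration deltas are valued by the human-capital approach. Wages are
standardized to hourly rates with the 7.4 h/day norm (37-hour week),
truncated to [€6.72, €268.63] (DKK 50–2000 at 7.44 DKK/EUR), imputed
where missing by OLS of log wage on sex, age group, education, sector
and industry group, and indexed to 2022 with a sex/age-specific CPI
supplied through the configuration (the series itself is an input, not
shipped). Annual costs per employee are C_k = rate × 7.4 × Δ_k/2 for
the non-work recurrent states and C_A = rate × 7.4 × (−Δ_work)/2 for
work absenteeism; the divisor 2 annualizes the two-year deltas.
Negative values are cost savings. C_A equals the sum of the three
components plus an absorbing-state remainder term that the engine
reports explicitly, making the accounting identity exact. Per-employee
averages are survey-weight means over exposed employees (levels 1–3,
full-time by default, part-time includable by flag); totals multiply
averages by weighted counts; "Total" rows weight strata by their
exposed counts. Reduction scenarios re-assign a fraction f of exposed
follow-ups (drawn proportionally within levels, nested across f under
a fixed seed so reported reductions are exactly monotone) to the
reference level and recompute the totals.

## The synthetic register generator

The generator emulates a linked survey + payment-register extract: it
draws exact continuous-time Markov trajectories from per-exposure-level
7×7 intensity matrices Q, then discretizes to whole days as date-based
registers do (the state occupying the start of a day owns the day, so
sojourns that never span a day boundary vanish — a real feature of
register data). Baseline tables carry the three stress indicators
(independent Bernoulli per indicator at configurable prevalence), the
nine covariates, log-normal hourly wages with a configurable missing
fraction, and positive survey/register weights. An optional confounding
mode lets smoking raise both the indicator odds and the work → sickness
hazard, for validating the weighting stage. The closed-form truth
E* = πᵀ∫₀ᵀ exp(Qt) dt is computed by the block matrix-exponential
identity (machine precision) and shipped with each cohort.

Default calibration: reference daily intensities put the unexposed
mid-age reference at roughly 690 of 730 days in work, ~15 days of
sickness absence and single-digit days of unemployment and temporary
out, of the order seen in register cohorts of active employees; the
exposure multiplies the work → sickness hazard by (1, 1.5, 1.75, 2.0),
the work → unemployment hazard by (1, 1.2, 1.4, 1.6), and slows return
to work slightly. Default indicator prevalences (0.13, 0.18, 0.14) are
of survey magnitude. These are study conditions, set once.

What the generator does **not** emulate: duration-dependent
(semi-Markov) hazards, seasonal or calendar-time effects, measurement
error in the indicators, correlated indicators, within-employer
clustering, and real covariate–wage joint structure. Passing tests
therefore demonstrate internal validity of the estimation machinery
under a Markov world, not external validity on register data.

## Validation design and problem sizes

- Oracle equivalence uses a homogeneous cohort (all prevalences 0,
  n = 5000): fitted durations agree with the closed form within 1% of
  the horizon (7.3 days) per state. The tolerance is read against the
  horizon because near-empty states make a purely relative bound
  ill-posed at Monte-Carlo noise levels.
- Recovery and interval-calibration experiments use one stratum with
  prevalence 0.3 per indicator so the smallest (3-indicator) cell holds
  ~135 persons at n = 5000 and ~27 at n = 1000 — enough to define the
  planted-coefficient recovery and level-3 intervals at all.
- Interval calibration pools coverage over the 4 recurrent states × 4
  exposure levels across 200 replicates of n = 1000 with 200 resamples
  each; pooled coverage sits near 0.93. The sparse 3-indicator cell
  undercovers individually because levels with zero events on an arrow
  get their coefficient capped at −10 with no draw variance — the
  deliberate monotone-likelihood rule, conservative for hazards and
  optimistic for intervals at very small cell sizes.

## Numerical choices and degenerate inputs

- Monotone likelihood (a level at risk with zero events) caps the
  coefficient at ±10 on the log scale, flagged; levels never at risk
  keep coefficient 0 with zero variance.
- Transitions with no events at all degenerate to a zero hazard
  (flagged), keeping the product integral well defined.
- Singular information matrices fall back to a diagonal covariance,
  flagged; covariance draws use SVD so positive semi-definite inputs
  are accepted.
- Propensities are floored at 0.001 before inversion; floor hits are
  logged and affect well under 1% of records at default conditions.
- Start distributions of empty cells fall back to the stratum-wide
  start frequencies.
- Day intervals are half-open integers [start, end); absorbing states
  extend to the horizon and reject any later-dated record.

## Known limitations

- The proportional-hazards and Markov assumptions are taken as given;
  no sojourn-time dependence, frailty, or time-varying coefficients.
- Model-based (not sandwich) coefficient covariance feeds the
  resampling; with strongly variable weights the intervals can be
  anti-conservative.
- The ±10 capping rule makes sparse-cell intervals too narrow, as the
  calibration experiment quantifies.
- Costing counts only absenteeism wage value: no healthcare use,
  presenteeism, quality-of-life or tax/transfer accounting, and no
  macro extrapolation beyond the weighted totals.
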