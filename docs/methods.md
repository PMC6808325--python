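# Methods

This note documents the model, the estimation conventions, the sensitivity
machinery, what the synthetic data does and does not emulate, and the
design choices made where the published description left the design open.

## Markov cohort model

**States and dynamics.** Three states — HD, CAPD, Death — with Death
absorbing.  The cohort occupancy row vector evolves as
`pi[k] = pi[k-1] @ P` over `n_cycles = 5` annual cycles
(`cycle_length = 1` year).  Only one movement per cycle is possible, which
is exactly what a single-step transition matrix encodes.  The matrix is
built from annual event rates (events per patient-year) via
`p = 1 - exp(-r * t)` applied independently to each exit (HD→CAPD,
HD→Death, CAPD→HD, CAPD→Death), with the stay probability defined as one
minus the exits.  The independent conversion of competing rates slightly
overstates each exit relative to an exact multinomial decomposition of a
generator matrix; it is retained deliberately because it is the standard
convention for decision models parameterized from published annual rates,
and at the default magnitudes (0.007–0.134/year) the discrepancy is far
below every tolerance used here.  Construction fails loudly if the exits
out of any state sum to ≥ 1.

**Assumptions.** Memorylessness (transition probabilities do not depend on
history), a homogeneous cohort (no age/sex strata), constant rates over
the horizon, no transplant state (deceased-donor transplantation is rare
in the modelled setting and enters only as a censoring cause in the data
stage), and no one-off transition costs (none are defined in the inputs).

**Half-cycle correction.** Transitions are assumed to occur on average
halfway through a cycle.  This is realized as trapezoidal weighting:
cycle k's contribution for each alive state is
`cycle_length * (pi[k-1] + pi[k]) / 2` times the state's per-year payoff
(1 for life years, the state utility for QALYs, the state's annual
treatment cost for costs).  Over the whole horizon this is equivalent to
boundary weights (1/2, 1, ..., 1, 1/2) on occupancy.  Death accrues
nothing.

**Discounting.** Cycle k (k = 1..N) is discounted by `(1+d)^-k`
(end-of-cycle timing) at `d = 0.03/year` by default.  Because the
half-cycle correction already centres accrual mid-cycle, some analysts
prefer `(1+d)^-(k-1/2)`; this is available as `discount_timing="half"`.
The choice moves 5-year discounted totals by ~1.5% and does not change any
qualitative conclusion.

**Linearity.** Scenario results are exactly linear in the initial mix:
`result(w_HD, w_CAPD) = w_HD * result(1,0) + w_CAPD * result(0,1)`
(`weighted_strategy_result` exploits and tests this).  A corollary worth
knowing: the incremental cost and QALYs between any two initial-mix
strategies are proportional to the mix difference, so every pairwise ICER
between such strategies is identical.

## Estimation from registry records

**Life years (intention-to-treat).** Kaplan-Meier product-limit curves are
computed per *first* modality: a patient who switches keeps their original
modality and a death after switching still counts against it.  Censoring
causes: transplant, recovered renal function, loss to follow-up, and
administrative end of follow-up.  Ties are resolved events-first (the
standard convention).  The implementation takes its risk table from
`lifelines.utils.survival_table_from_events` and applies the product-limit
and Greenwood formulas explicitly; tests cross-check against both a
brute-force enumeration of the formula and `lifelines.KaplanMeierFitter`.
Time is carried in months (mean month = 365.25/12 days) and life years are
the area under the step function to the horizon, held at the last observed
value (with a warning) if follow-up ends earlier.

**Annual rates.** The annual rate of an event is events in a calendar year
divided by the estimated mid-year population, averaged with equal weight
over the observation years.  "Mid-year population" is the average of the
on-dialysis counts on 1 January and 31 December — the boundary-average
convention, documented here because "estimated mid-year population" does
not pin down a formula.  Patients administratively censored on a snapshot
date still count as on dialysis that day (their follow-up, not their
treatment, ended); without this the final year's denominator collapses and
its rate roughly doubles.  Death rates can be attributed to the modality
current at death (default, matching per-modality mortality bookkeeping) or
to the first modality (ITT); both conventions are exposed because either
could underlie published per-modality rates.  Switch rates are always
attributed to the modality being left.

**Reporting rounding.** Life years to 2 decimals, QALYs to 3, ringgit to
whole units, ratios to 2 decimals, rounding half away from zero — except
the QALY product LY × utility, which is formed in exact decimal arithmetic
with ties to even: 3.70 × 0.905 = 3.3485 exactly, and the published table
value (3.348) implies the ties-to-even convention.  Cost per QALY is
computed from the rounded figures (as a published table would), and cost
per life year is reported as the mean annual treatment cost — the cost of
sustaining one year of life on dialysis — with the ratio-of-cohort-totals
alternative available separately.

## One-way sensitivity (tornado)

Each of the 22 uncertain inputs (8 cost components × 2 modalities, 2
utilities, 4 rates) is pinned in turn at its published low and high bound
with everything else at the mean; the model is rerun for both compared
strategies and the incremental NMB at the threshold recorded.  Defaults:
intervention = scenario 2 (50:50), comparator = base case (60:40) — the
policy question is whether expanding CAPD beats current practice — at the
RM120,000/QALY threshold, on discounted outcomes (undiscounted available).
Entries are sorted by bar width; the analysis is deterministic and
order-invariant.

At the means the intervention dominates (NMB ≈ +RM1,977 at RM120k,
discounted): expanding CAPD saves money and gains QALYs.  Four inputs can
flip the sign within their published ranges — the two utilities (the
incremental QALYs change sign when HD's utility approaches 1 or CAPD's
falls toward its lower bound) and the CAPD hospitalization and outpatient
cost bounds (which can make the CAPD-heavy mix the costlier one at an
ICER far above the threshold).  A published qualitative claim that every
one-way endpoint remains cost-effective at RM120,000 is therefore *not*
reproduced by this per-patient model; it traces to the same undocumented
tool-specific aggregation as the non-reconstructible 5-year totals (whose
printed incremental QALYs per 10-point mix shift are several times larger
than any per-patient 3-state model with these inputs can produce).  The
corresponding acceptance test records this discrepancy as a failure by
design, and a companion test pins the model's actual behaviour, including
the input ranking (utilities, then hospitalization and outpatient costs)
that *does* match the published tornado.

## Probabilistic sensitivity analysis

Every cost component is drawn from a gamma distribution and every utility
and transition rate from a beta distribution, fitted by method of moments
with the published (low, high) range read as a central 95% interval:
`SD = (high - low) / 3.92` (a `z=4` variant is available).  Gamma:
`shape = mean^2/var`, `rate = mean/var`; beta: `alpha = mean*nu`,
`beta = (1-mean)*nu`, `nu = mean(1-mean)/var - 1`.  Fitted means equal the
input means exactly; zero-width ranges degenerate to point masses.  The
hospitalization components (lower bound 0, strongly right-skewed) yield
valid gammas with shape < 1.  Utility ranges touching 1.0 are clipped to
the unit interval before fitting.

Each of the 1,000 iterations draws one parameter vector, rebuilds the
transition matrix (draws implying exits ≥ 1 are rejected and redrawn,
counted — at the default ranges this effectively never happens), and runs
all scenarios on the same draw (common random numbers), so that between-
strategy differences are not masked by sampling noise.  Draws are
independent across parameters; no correlation structure is imposed because
none is published.  The CEAC reports, on a RM0–200,000 grid in RM5,000
steps, the fraction of iterations in which each strategy attains the
maximal NMB, with exact ties split equally; probabilities sum to 1 at
every threshold by construction.  Discounted and undiscounted curves are
both available.

## Synthetic registry

The generator emulates the study design behind the survival inputs:
uniform enrolment over 2011-01-01 to 2015-12-31, follow-up to 2016-12-31,
and per-patient competing exponential clocks for death, modality switch,
transplant, recovery and loss to follow-up, with death and switch hazards
depending on the current modality and all clocks restarting on a switch
(memorylessness).  Defaults are the published annual rates (death 0.125/y
HD, 0.134/y CAPD; switch 0.007/y HD→CAPD, 0.067/y CAPD→HD) and a 60:40
initial mix.  The censoring hazards are not published; they were chosen
once as 0.012 (transplant), 0.004 (recovery) and 0.010 (loss to
follow-up) per patient-year — small, reflecting a setting where
deceased-donor transplantation is rare — and are not tuned.

Records carry the first modality, the first switch date and the final
modality; a patient who switches twice (probability of order 1e-3 at the
default hazards) has only the first switch recorded, so the reconstructed
modality timeline is wrong after a second switch.  This is negligible for
every statistic tested.  What the generator does *not* emulate: covariate
heterogeneity (age, sex, comorbidity), time-varying or non-exponential
hazards (a constant hazard is the minimal model consistent with a single
published annual rate), centre effects, and informative censoring.
Passing recovery tests therefore show that the estimators are correct
under the model's own assumptions, not that real registry data satisfy
those assumptions.

**Problem sizes.** Rate-recovery tests use n = 5,000 patients (the scale
at which 3 Monte-Carlo standard errors correspond to roughly ±8% of the
death rates) across 20 seeds; the restricted-mean check uses n = 5,000
with a 0.25/y hazard against the closed form (1 − e^{−1.25})/0.25; the
oracle-equivalence test uses 100 random instances; the PSA uses the
published 1,000 iterations.  These sizes make every statistical tolerance
comfortable while keeping the full suite around a few seconds.

## Numerical choices and degenerate inputs

- Row-stochasticity is enforced to 1e-9 on input matrices; occupancy
  conservation holds to 1e-12 in tests.
- `p = 1 - exp(-rt)` is computed with `expm1` for accuracy at small rates
  (p ≈ rt to < 0.1% below rt = 1e-3, tested).
- All-censored record sets yield a flat survivor curve with a warning
  rather than an error; empty record sets are an error.
- A cost-and-effect tie between strategies is flagged `equivalent` on the
  ICER ladder and excluded from the frontier; extended dominance is
  applied by default (strict-only mode available) and frontier ICERs are
  strictly increasing by construction.
- Parameter bundles are validated on load: component sums must match the
  printed totals within RM0.50 (printed values are rounded to the sen),
  utilities within [0, 1], scenario mixes summing to 1, rates positive.

## Known limitations

- The absolute 5-year aggregates of the published scenario table are not
  reproducible from the printed inputs (see the tornado section above and
  the README); per-patient results are reported instead and bounded by the
  horizon.
- No covariate adjustment or propensity matching in the survival stage;
  the modelled mortality difference between modalities is the unadjusted
  one, and part of it may reflect patient selection rather than modality
  effects.
- Costs enter as annual per-patient parameters; there is no patient-level
  cost microsimulation and no transition (one-off) costs.
- The WTP thresholds are GDP-per-capita heuristics; local
  willingness-to-pay may be substantially lower.
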