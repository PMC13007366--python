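# Methods

## The model

`carespan` implements an incidence-based discrete-time multistate life
table over four states: no care (0), home care (1), care home (2), and
death (3, absorbing). All transitions among the transient states are
allowed, including recovery to lower care levels.

Time is age. Transition probabilities are estimated on a 3-month grid from
age 70 to a terminal age Ω = 105: for every grid interval `[a, a + Δ)`
(Δ = 0.25 years) and origin state `i`, the probability `P_a[i][j]` of being
in state `j` at `a + Δ` given `i` at `a`. Occupancy follows
`π(a + Δ) = π(a) P_a` from an index age (default 75) to Ω, where all
remaining mass is moved to death (closure). Expected time in transient
state `s` from index age `x` is

    E_s(x) = Δ · Σ_{a = x, x+Δ, …, Ω−Δ} Pr(in s at a),

so state expectancies sum to total remaining life expectancy by
construction. The default occupancy convention credits a full interval to
anyone present at the interval start; a trapezoid variant (half weight at
the index age and Ω) is available via `half_interval=True`. The two differ
by at most Δ/2 and the choice is declared so results reproduce exactly.

Population-level results default to the observed state distribution at the
index age as the initial distribution (pooled over one year of grid ages
for stability); any explicit distribution, e.g. conditional on starting
without care, can be passed instead. Both modes are first-class because
register publications rarely state which one a figure uses.

## Estimation

**Counting.** Each person contributes one origin/destination pair to every
3-month age interval they begin under observation: origin is the state in
the calendar month containing the interval-start age, destination the
state at the interval end, or death if it occurred within the interval.
People censored mid-interval contribute to neither numerator nor
denominator of that interval. Panel months are mapped to ages treating a
month as exactly 1/12 year; the ≤1.5-day discrepancy with calendar months
is negligible against sampling noise.

When the administrative end of follow-up is known (it always is for a
fixed study window), persons are additionally excluded from any interval
their window cannot cover — otherwise a person whose window closes
mid-interval is dropped if they survive but counted if they die, which
inflates per-interval death probabilities by roughly q/24 under a shared
3-year window and biases life expectancy down by ~0.1 years. The
parameter-recovery oracle exposed this asymmetry, and the `window_end`
argument of `count_transitions` removes it. Random (emigration) censoring
retains the asymmetry in principle, but at ~1%/year its effect is
O(1e-5) per interval.

**Smoothing.** Raw occurrence/exposure probabilities are noisy at old
ages, so each off-diagonal transition is smoothed with a binomial P-spline
(penalized generalized additive model) on the logit scale: cubic B-splines
on an equally spaced extended knot grid (15 basis functions over
[70, 105]), second-order difference penalty, weights equal to at-risk
counts. The smoothing parameter is chosen by generalized cross-validation
over a 9-point log-spaced grid; GCV was chosen over an REML-type criterion
because the fitter must be cheap enough to re-run (and re-select) inside
every bootstrap replicate, and a hand-written penalized-IRLS fit with a
small GCV grid is orders of magnitude faster than general GAM machinery
while agreeing with it to ~1e-5 in the unpenalized limit (see the test
suite's statsmodels cross-check). With the second-order penalty the
heavy-penalty limit is exactly a straight line in age on the logit scale.

The stay probability is defined residually (1 − fitted exits), which keeps
every row stochastic; if fitted exits ever sum above 1 they are rescaled
proportionally and a warning is emitted. The death row is fixed at
(0, 0, 0, 1). Ages 70–75 enter the smoother for stability but reported
quantities start at 75. Rows with no data are predicted from the fit.
Smoothing is per-transition binomial rather than a joint multinomial
smoother: it is the simplest faithful choice and is testable
transition-by-transition.

## Rates, standardization, decomposition

Baseline care state is the state occupied in the calendar month before the
baseline month (default baseline 2017-04-01); within a month the highest
care level occupied wins — an explicit convention for mid-month changes.
Proportions use Bernoulli Wald 95% CIs, `p ± 1.96 √(p(1−p)/n)`, clipped to
[0, 1].

Death rates per 1000 person-years are deaths over exposure from baseline
to death, censoring, or baseline + follow-up (default 3 years, 5 for
sensitivity), stratified by sex, 5-year age group ([75, 80), …, [100, ∞))
and *baseline* care state — deaths after a later care change still count
in the baseline state's cell. CIs use Poisson variance on the natural
scale, `rate ± 1.96·1000·√D/PY`; rate-ratio CIs are Wald on the log scale.
Age standardization weights age-group-specific values by the combined
two-population baseline count shares (per sex, and additionally per care
state for state-specific rates), with variance `Σ w² var`.

The total-population rate in an age group is `M = Σ_s π_s m_s` with
baseline-state shares `π_s` and state rates `m_s`. The difference between
populations A and B is decomposed Kitagawa-style:

    rate component (s) = ((π_sA + π_sB)/2) (m_sA − m_sB)
    composition        = Σ_s ((m_sA + m_sB)/2) (π_sA − π_sB)

Additivity is exact, components negate under population swap, and the
averaged form equals the mean of the two pure stepwise-replacement orders
(both available via `method=`). Standardized decompositions are weighted
sums of age-specific ones; when an age group lacks a complete set of state
cells in either population (possible at 100+ in desk-scale cohorts) the
reference weights are restricted to decomposable groups and renormalized.

## Inference

Percentile bootstrap (default 1000 replicates; pipeline reports use 100),
resampling whole individuals with replacement within population × sex
strata, preserving per-stratum sizes exactly and within-person serial
dependence. Smoothing parameters are re-selected in every replicate.
Replicate seeds derive from the master seed through a counter stream.
Replicates on which the statistic fails are dropped with a warning below a
1% failure fraction and raise a hard error above it.

## The synthetic-cohort generator

Registry data of this kind are not public, so the generator produces
cohorts with the statistical structure the analysis assumes: two
populations × two sexes, baseline ages 75+ drawn from a 5-year-group
mixture, baseline care states from an age-group-specific distribution,
monthly trajectories from baseline − 1 month (so the baseline state is
always observed) to death, emigration, or baseline + follow-up.

Hazards are parameterized per 3-month interval: state-specific death
probabilities at age 75 with log-linear age slopes, care-entry
probabilities (no→home, no→care home, home→care home) with slopes, and
age-constant recovery probabilities. The simulator runs on a monthly clock
using `1 − (1 − p)^{1/3}` split proportionally across competing exits, so
the generator's time step is genuinely finer than the estimation grid and
interval handling is actually exercised. Exact per-interval matrices (the
product of the three monthly matrices) and the life expectancies they
imply are exposed as oracles for recovery tests.

The default scenario contrasts population A (lower mortality inside the
care states, more home care, fewer care homes — Japan-like) with
population B (higher in-care mortality, more care-home use — Sweden-like);
women have lower mortality and higher care use than men. Baseline
composition defaults are loosely matched to published register-based
composition of the Japanese and Swedish 75+ populations; transition
parameters are plausible-by-construction, *not* calibrated to any
published rates (none are printed), chosen once so that remaining life
expectancy at 75 lands in the empirically observed 11–14-year range.
Emigration censoring is exponential in time and state-independent
(default 1%/year). Per-stratum random streams are keyed by a stable hash
of the (population, sex) labels, which makes cohorts reproducible under a
master seed and invariant to relabeling; simulation is vectorized across
persons within a stratum.

What the generator does **not** emulate: household structure, informal
care, calendar-period effects (no COVID shock), duration dependence within
a state, or heterogeneous frailty. Passing recovery tests therefore shows
the estimator chain is correct for a monthly Markov data-generating
process with smooth hazards — not that real registry data satisfy those
assumptions.

## Problem sizes and numerical choices

Recovery and coverage tests use 10,000 individuals per stratum with 200
bootstrap replicates, and the Monte-Carlo life-table oracle uses 200,000
trajectories; these sizes give 3-SE checks that are tight relative to the
effects of interest while keeping the default test run quick. Pointwise
3-SE comparisons over hundreds of cells allow a 1% violation fraction
(≈0.3% is expected by chance at 3 SE). Exact identities (row sums,
additivity, antisymmetry) are asserted at 1e-9 or tighter. IRLS uses a
1e-9 ridge for conditioning, clips the linear predictor at ±30, and starts
every smoothing-parameter candidate from the constant-logit fit (warm
starts can propagate a diverged nearly-unpenalized fit). Degenerate
inputs: all-zero event series fit to probability zero; empty at-risk rows
are flagged missing, excluded from smoothing input, and predicted from the
fit; zero-death rate cells get a degenerate (0, 0) interval flagged
`low_information`.

## Known limitations

- The discrete-time full-interval-credit convention biases LE up by up to
  Δ/2 ≈ 0.125 years relative to a continuous-time reading; the trapezoid
  flag quantifies this.
- Smoothed surfaces extrapolate on the logit scale outside the observed
  age range (notably 70–75 and 103+); extrapolated rows are only as good
  as the penalty's linearity assumption.
- The generator's baseline-state distributions and hazards are stylized;
  no calibration routine to external life tables is provided.
- Proportion CIs are plain Wald and degenerate at p ∈ {0, 1}.
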