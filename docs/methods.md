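# Methods

## Setting and model

The package studies comparative safety analyses of two initiator cohorts
(test drug TD, comparator drug CD) in the presence of a single treatment
switch, framed as an illness-death multistate model without recovery:
state 0 is the initial exposure, state 1 a switch to the other drug, and
state 2 the (absorbing) adverse event. Cause-specific hazards
`α_lj(t) dt = P(X_{(t+dt)-} = j | X_{t-} = l)` govern the transitions;
cumulative hazards are estimated nonparametrically by the Nelson–Aalen
estimator, whose increment at an event time is the number of observed
l→j transitions divided by the number in state l just prior and under
observation. With delayed entry a row contributes to risk sets only on
its interval `(entry, exit]`.

The arm comparison is a Cox proportional-hazards model for the binary
attribution TD vs CD on counting-process data, `β` the log hazard ratio.
Under proportional hazards, `exp(β̂)` approximately equals the ratio of
the arm-wise Nelson–Aalen estimates at the horizon; this identity is used
throughout as a consistency check between the semiparametric fit and the
nonparametric decomposition.

## Dataset constructions under study

Both approaches are implemented as deterministic row-rewriting rules from
the subject table to a start/stop table (`augmentation`):

* **Experimental hierarchical** (asymmetric): TD starters keep their whole
  follow-up under TD regardless of switching; CD starters are censored on
  CD at a switch to TD and cloned onto TD for the post-switch period.
* **Overlapping** (symmetric): every subject keeps a full-follow-up row on
  the initiated arm; each observed switcher adds a post-switch clone on
  the destination arm, so a switcher's event is counted once per arm.

Each has two clock conventions for the clone: **restarted**
(`(0, T − s]`, the estimator in common use) and **original / no restart**
(`(s, T]`, a left-truncated observation — the modification under
evaluation). Intervals are half-open `(entry, exit]` with events at exit,
the standard counting-process convention. Zero-length rows are impossible
under the simulator's strict-inequality switch rule but are dropped
defensively (and logged) for imported data. Clone flags and subject ids
are preserved so variance estimation can group rows by patient; the
default fit deliberately ignores the grouping, replicating the naive
analyses under study, and an optional subject-clustered sandwich standard
error implements the recommended correction.

## Hazard-ratio decomposition

`msm_decomposition` rebuilds each estimator from stratified transition
curves: TD-starter failure, CD failure (censored at switch for the
hierarchical denominator, full follow-up for the overlapping one),
post-switch failure of switchers on the chosen clock, and the 0→1
switching hazards. The composite numerator mixes the initiator and
switched-stratum hazard increments with the at-risk fraction
`P̂_TD(t)` of initiators among all rows attributed to TD at `t` —
evaluated on the analysis timescale of the chosen variant — which makes
the composite identically equal to the pooled Nelson–Aalen estimate of
the corresponding augmented stratum; the hazard *ratio* is reported on
cumulative hazards over a default grid of 200 points up to the horizon,
because raw increments are noisy atoms. Grid points with an empty
denominator risk set are flagged NaN rather than extrapolated.

With individually varying switch times the observable post-switch hazard
is an empirical mixture of individually shifted hazards; since individual
hazards are not estimable nonparametrically, the mixture is realised as
the pooled Nelson–Aalen estimate over the individually shifted switcher
records. Under a common switch time — the simulated design — it reduces
exactly to the single shifted switched-stratum curve.

## Synthetic cohorts

The generator (`cohort_sim`) emulates the study conditions: two arms of
3000 treatment-naive initiators each, latent event times i.i.d. Weibull
with `S(t) = exp(−(t/scale)^shape)` (the `rweibull` parameterization),
identical in both arms and unaffected by switching — an exact null.
Switching is assigned at baseline as an independent Bernoulli draw with a
common switch time; an assigned switcher becomes an *observed* switcher
only if follow-up exceeds the switch time (events at exactly the switch
time count as pre-switch — measure-zero, fixed for determinism).
Administrative censoring at 8 years is the only censoring. The packaged
grid holds the two high-event illustration scenarios (shape 1/scale 4 ≈
5188 expected events; shape 0.3/scale 2 ≈ 4682) and twenty rare-event
scenarios, five shape/scale pairs from 1/142.85 to 1.5/54.66 all
calibrated to ≈ 327 expected events, crossed with switch times {1, 5}
years and assigned proportions {25%, 50%}.

What the generator does *not* emulate: confounding, individually varying
or informative switch times, loss to follow-up, covariates, multiple
switches, or state-dependent post-switch hazards. Passing tests therefore
demonstrate properties of the estimators under an idealized null, not the
behaviour of the methods on real registry data, where these estimators
have additional bias sources.

Reproducibility: replicate `r` of scenario `k` draws from the independent
substream `SeedSequence(seed, spawn_key=(k, r))`, so cohorts are
bit-identical given `(seed, k, r)`, replicates are independent, and all
four analysis variants of a cell analyse the same cohorts (paired
comparisons).

## Estimation and testing

The Cox fit is a Newton–Raphson maximization of the Breslow partial
likelihood in the single binary covariate (gradient tolerance 1e-8, max
50 iterations, step-halving on likelihood decrease); simulated continuous
times make ties probability-zero, so Breslow vs Efron is immaterial here
and Breslow is used for imported data too. Risk sets honour delayed
entry. Degenerate inputs are distinguished: no events, events in a single
arm, or no event time with both arms at risk raise a monotone-likelihood
error (as does `|β̂| > 15`, an effectively infinite hazard ratio), while
Newton failures raise a convergence error; the study driver logs and
excludes failed replicates and aborts a scenario when more than 1% fail.
P-values are two-sided from the normal approximation to the Wald
statistic `z = β̂/se(β̂)`, and the study rejects at `p < α` with
`α = 0.05` (configurable). The optional robust variance is the
subject-clustered sandwich built from score residuals restricted to each
row's `(entry, exit]` interval; it matches `survival::coxph` with a
`cluster` term.

## Study driver and problem sizes

`run_scenario` executes simulate → augment → fit → test per replicate and
aggregates the rejection proportion with its binomial Monte-Carlo
standard error `sqrt(p(1−p)/n)`, plus mean event and clone counts and
per-replicate estimates. Full-size runs use 1000 replicates per cell (the
CLI default). The test suite and acceptance script use smaller,
a-priori-fixed sizes chosen so the binomial bands remain informative:
calibration checks use 20 replicates at full cohort size; type-1-error
checks use 400–500 replicates per cell (99% binomial band half-width
≈ 0.028 at 400), with a Bonferroni-adjusted band when all 20 null
scenarios are scanned at once.

## Design choices and limitations

* The scenario-1 hazard is constant at `1/scale = 0.25`/year under the
  rweibull convention; the expected clone count ≈ 701 with SD ≈ 23
  follows, consistent with observed single-run counts in the low 700s/high
  600s.
* The at-risk table uses the left-continuous count `entry ≤ t < exit` so
  its `t = 0` row shows the full starting risk set — the simulated
  subjects plus, under clock restart, all clones injected at time 0.
* Pooling rows tagged with different timescales in one Nelson–Aalen
  estimate is refused by default and must be requested explicitly
  (`pool_timescales=True`); the clock-restarting analyses are exactly such
  a pooling, and the flag keeps that step auditable.
* Only a single switch per patient, no switch-back, and the null
  hypothesis are simulated; power under alternatives, transition
  probabilities (Aalen–Johansen), bootstrap variances and non-Markov
  estimation are out of scope.
* The overlapping approach's conservativeness here depends on the
  symmetry of the simulated design (equal arms, common switch time);
  it is not a general property.
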