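# Methods

This note records the modelling assumptions, defaults and numerical
choices behind `ewasoc`, and what the synthetic-data experiments do and
do not establish.

## The experimental environment

A session holds `2 x 4` participants in two regions playing a
four-armed bandit for 100 rounds (four 25-round phases).  Per phase and
region exactly one option is optimal; its mean payoff is the phase tier
mean (a random permutation of 13, 15, 17, 19 points across phases) and
every other option pays `payoff_gap = 3` points less.  Payoffs are
Gaussian with s.d. 3.0 in the two "hard" phases and 1.5 in the two
"easy" ones; which phases are hard is drawn uniformly.  Within each
phase the two regions' optima are drawn uniformly among ordered pairs
of distinct options — the only constraint the design imposes — so
whether an optimum changes at a phase boundary is itself random.

Every `migration_interval = 5` rounds one fixed cross-region pair swaps
regions, pairs cycling in founder order.  Events take effect at the
start of the following round; a migrant's first round in a region has
residence lag `l = 1` and displayed experience 1 ("rounds spent in the
current region, including this one").  Under the default schedule each
group consists entirely of the other group's founders after the round-20
event and is restored after the round-40 event, and the maximum
attainable lag is `group_size x migration_interval = 20`.  The realized
order of optima in the original study is not public; only its
constraints are enforced, and the schedule is configurable.

Payoffs are kept real-valued, untruncated and unrounded: whether the
original display rounded points is unknown, and using the same
continuous values in the generator and the likelihood keeps the two
exactly consistent.

## Learning model

Attractions start at zero for all options (uniform first-round choice
for any `lambda`), persist across migrations and phase boundaries (the
model has no reset mechanism), and only the chosen option's attraction
moves each round — the minimal reading of the update rule; decay of
unchosen attractions is deliberately not modelled.  Payoffs enter the
update in raw points; `lambda` absorbs the units.

Social cues come from the up-to-three group mates.  Two conventions
operationalize partial information:

* a neighbour's previous choice enters the conformity counts `n_i`
  only if its choice box was viewed that round (and the neighbour did
  not just arrive — new arrivals' choices are hidden by design);
* a neighbour's experience enters the experience weights at its
  displayed value only if the experience box was viewed, otherwise at
  `E = 0` (a unit weight).  With no experience boxes viewed the
  experience-directed probability degrades to plain counts and `beta`
  drops out of that round's likelihood.

When no social information is visible at all (round 1, individual
control, nothing viewed), the round contributes only the asocial
branch; `sigma` is unidentified for that round and deliberately not
penalized.  The mouse-tracking data only enter as these per-round box
indicators; search trajectories and dwell times are out of scope.

## Hierarchical models and priors

Individuals' parameters live on logit (`sigma`, `kappa`, `phi`), log
(`f`, `lambda`) and linear (`beta`) scales and receive correlated
varying effects: `theta_i = mu + tau * (L z_i)` with `z_i ~ N(0, I)`
(non-centred), `mu ~ N(0, 1)` per component, `tau ~ Exponential(1)`,
and `L` the Cholesky factor of an LKJ(2) correlation matrix.  The
prior scales are documented configuration, not empirical facts; they
are weakly informative on the transformed scales.

*Monotonic effects* replace a time-varying parameter's single entry by
an endpoint pair `(theta_tmin, theta_tmax)` inside the varying-effects
block (so endpoint correlations with other parameters are estimated)
joined by a step simplex `delta` over lags 1..20 with a Dirichlet(2)
prior.  The step vector is shared across individuals: the wording of
the construction ("each individual is characterized by two parameters")
implies individual endpoints over a common schedule of increments, and
a shared simplex keeps the model identifiable at eight participants per
session.  By default all six parameters are time-varying; a
`time_varying` switch restricts the machinery to a subset (e.g. the
social parameters only) for robustness runs.

*Gaussian-process effects* add population-level per-lag offsets
`d_1..d_20` with covariance
`K[x,y] = eta^2 exp(-rho^2 D^2) + sigma^2 [x=y]` and
`Exponential(1)` priors on `eta^2`, `rho^2`, `sigma^2`.  The
participant-specific GP (one covariance matrix per individual) is out
of scope — with a handful of replicates per individual-lag cell it is
not estimable.

*Contrast models* add population offsets on the transformed scales
gated by window dummies: "first five rounds" means residence lag <= 5
after an actual migration (founders' opening rounds do not count) and
phase-round <= 5 after an actual phase boundary (phase 1 does not
count); both dummies may be active at once.  Offsets apply to the four
social parameters (`sigma`, `kappa`, `f`, `beta`) by default.

## Sampling and diagnostics

The posterior is sampled by the package's own multinomial No-U-Turn
sampler (dual-averaging step size targeting 0.8 acceptance, expanding
diagonal mass-matrix windows during warmup, max tree depth 10).
Gradients are analytic end to end: a numba kernel returns per-
observation derivatives for all six natural-scale parameters — the
updating-rate gradient via a reverse sweep over the attraction
recursion — and the hierarchy chain rule is closed-form except for the
two small constrained bijections (simplex stick-breaking, correlation
Cholesky), whose Jacobians are obtained by complex-step
differentiation, exact to machine precision.  Kernel probabilities are
max-subtracted and floored at 1e-300, and log-scale parameters clipped
at +-60 before exponentiation, so warmup excursions cannot overflow;
such points are rejected through the energy check rather than crashing.

Convergence is assessed with rank-normalized split R-hat and ESS
(arviz) against the conventional thresholds R-hat <= 1.01 and
ESS > 1000 for population-level quantities; fits that miss them carry
explicit warnings, and divergent transitions are counted and reported.
HPDIs use the narrowest-window definition over sorted draws (ties
towards the lowest lower bound).  Payoff correlations are computed per
posterior draw across individuals and then summarized (mean, 89% HPDI);
a pre-aggregated payoff statistic (e.g. geometric mean per round) can
be supplied instead of totals.

## Synthetic data: what it does and does not show

The generator emulates the full experiment — design, migration,
payoffs, information display, Bernoulli viewing masks with default
rates 0.85 (choice boxes) and 0.55 (experience boxes), inside the
ranges observed in the original study — with agents driven by exactly
the learning rules the models assume.  Recovery of generating
parameters therefore validates the inference machinery (likelihood,
gradients, sampler, summaries), not the behavioural adequacy of the
EWA model for humans: real participants are told an optimum exists,
show steeper learning than softmax reinforcement agents, and their
viewing behaviour is state-dependent rather than Bernoulli.

The two-subgroup recovery scenario follows half of the agents with a
monotonically declining social-learning weight (0.8 on arrival to
~0.02, with ~60% of the decline inside the first five lags — mirroring
the halving-within-five-rounds pattern the monotonic model estimates
on real data) and half with a constant intermediate weight (0.3).
Other parameters sit at plausible microsociety values (`kappa` 0.2,
`f` 3.0, `beta` 0.5, `lambda` 0.15, `phi` 0.7) with 0.3 s.d.
heterogeneity on the transformed scales.  The exact magnitudes of the
original validation scenario were not published; these are this
package's documented choices.

## Problem sizes

Shipped example fits and acceptance tests run at reduced scale, chosen
as the smallest sizes at which the recoveries are clearly resolved:
baseline recovery on 10 simulated sessions (80 individuals, 8000
observations) at 4 chains x 500 draws; monotonic recovery on 8
scenario sessions with `sigma` time-varying at 2 chains x 300 draws;
contrast recovery on 8 sessions at 2 chains x 300 draws.  The
diagnostics demonstration fit uses 2 sessions at 4 chains x 1800
draws — a long chain on a small dataset, so every population-level
quantity clears the 1000-effective-sample bar.  The full 25-session
design and all-parameter time-varying models run through the same
interfaces, linearly slower.

## Known limitations

* No payoff-biased social learning term: participants never saw
  others' payoffs, so the cue does not exist in this design.
* The sampler is single-threaded; chains run sequentially.
* `beta` is weakly identified late after migration when few experience
  boxes are viewed; expect wide intervals there.
* The GP model reports population-level trends only.
* Real-data idiosyncrasies (dropout, attention lapses, display-order
  effects) are not simulated.
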