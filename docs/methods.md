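# Methods

## The scientific problem

When people can sample evidence for as long as they like before committing
to a judgment, the desirability of the possible conclusions can bias both
*where accumulation starts* and *how fast evidence accrues*. `valenceddm`
implements this motivated-accumulation analysis end to end for a paced
binary-categorization task (the "Factory Game"): an observer watches a
conveyor-belt stream of two item types (one item every 0.550 s: 400 ms
traverse + 150 ms lag), where the majority item type matches the trial's
true factory state with probability 0.6, and responds whenever they have
seen enough. One factory type wins the participant money (desirable), the
other loses it, and the payoff is independent of the judgment itself — so a
rational, purely accuracy-driven observer should behave identically in both
states.

## Diffusion model

The decision variable is a Wiener process with unit diffusion coefficient
between absorbing bounds at 0 and `a`; the upper bound is "judge
desirable". Time is in seconds; `a`, drift `v`, starting point `z`
(fraction of `a` measured toward the desirable bound) and the uniform
trial-to-trial starting-point range `sz` (also a fraction of `a`) are all
in this scale, as is the non-decision time `t0`. Six specifications cross a
fixed (`z = 0.5`) vs free starting point with three drift structures:

    v = b0 + b1 * evidence                         (evidence only)
    v = b0 + b1 * evidence + b2 * desirability     (additive valence bias)
    v = b0 + b1 * evidence + b3 * desirability * evidence   (interaction)

`evidence` is the centred proportion of seen items consistent with the
*true* state (−0.5 … +0.5); `desirability` is 1 when the true state is the
participant's desirable factory. The regression gives the drift *toward the
correct bound*; the effective signed drift toward the desirable (upper)
bound is `+v` on desirable trials and `−v` on undesirable trials, with the
valence terms entering before the sign flip. A positive `b2` therefore
speeds accumulation toward the desirable conclusion on desirable trials,
and a starting point `z > 0.5` biases every trial toward it.

### First-passage density

The two-boundary first-passage density is evaluated with the classical pair
of series expansions (image-term small-time series; eigenfunction
large-time series), switching per point to whichever needs fewer terms for
a truncation error of 1e-7. The upper-bound density is obtained by the
exact reflection `(v, z) → (−v, 1−z)`. The `sz` jitter is integrated by
11-point Gauss–Legendre quadrature over the uniform start interval; at
`sz = 0` the point density is used directly. A compiled (numba) kernel
implements the same formulas for the MCMC inner loop; the numpy
implementation is the reference and the two are cross-checked in the test
suite. Known limitation: in the extreme early-RT tail (density below
~1e-4 of its peak) the sz quadrature has visible relative error; the
density-vs-simulation oracle checks therefore run at `sz = 0`, and the
jittered density is validated by its exact normalization instead.

### Simulation

First-passage times are simulated by Euler–Maruyama (default `dt` = 1 ms,
60 s cap with censored trials flagged, never dropped) with a
Brownian-bridge correction: after each step the exact probability
`exp(−2 d_pre d_post / dt)` of an unobserved within-step boundary crossing
is applied. Because per-step increments of a constant-drift Wiener process
are exactly Gaussian, the only residual discretization effect is the
attribution of the crossing to the end of its step, an O(dt) timing shift;
the bin-integrated RT distribution at `dt = 0.5 ms` is statistically
indistinguishable from the analytic density at 10^6 draws.

## Task emulation vs model-recovery generation

Two synthetic-data generators serve different purposes:

* **Task emulator** (`valenceddm.task`). The agent's drift follows the
  *running* evidence of the items actually on screen, updated at every item
  boundary, so judgments covary with the realized stream — necessary for
  the psychometric function, the sampling statistics and every behavioral
  analysis to be meaningful. The recorded `evidence` covariate is
  recomputed post hoc from the items elapsed by the response
  (`n_samples = ceil(rt / 0.550)`, i.e. the item on screen at response
  counts as seen), exactly as the fitting stage uses it. Because the fitted
  model assumes one constant drift per trial, fitting task-emulated data is
  deliberately a (mild) misspecification — as it is for real data.
* **Model-recovery generator** (`valenceddm.validation.simulate_ddm_cohort`).
  Draws evidence covariates exogenously (centred binomial proportions at
  the 0.6 composition over 3–10 items) and simulates the constant-drift
  process itself, so generating and fitted models coincide and truth is
  known by construction. All parameter- and model-recovery guarantees are
  stated for this generator.

The default task agent was calibrated once to a realistic operating
point for this task — ≈71% accuracy at the 0.6/0.4 composition, with
several items sampled per decision — giving `a = 6`, `b1 = 6`, `t0 = 0.35 s`,
`sz = 0.1` in the unit-diffusion, seconds timescale convention (absolute
parameter values are convention-dependent; recovery is always assessed
within this convention). Bias parameters are per-scenario inputs; the
biased-agent condition used across the examples is `z = 0.55, b2 = 0.2`,
and between-subject heterogeneity defaults (SD 0.04 on `z`, 0.085 on `b2`,
plus spreads on `a`, `t0`, `b0`, `b1`) reproduce the qualitative spread of
subject-level estimate histograms for this kind of task (≈60–90% of
subjects on the biased side of neutral). Point rewards are opaque metadata
and never enter any computation.

One consequence of evidence-driven drift worth knowing: with
trial-to-trial drift heterogeneity, *fast* trials are the high-coherence
ones and are more accurate, while the classic "fast errors" pattern (slow
responses more accurate) requires homogeneous drift plus starting-point
jitter. The task emulator therefore does not guarantee a particular sign
for the speed–accuracy split; the canonical sign is asserted on the
homogeneous-drift regime.

## Hierarchical Bayesian estimation

Subject parameters are sampled on unconstrained scales — `log a`, `t0`
natural in (0, 2), `logit z`, the `sz` fraction (of 90% of its feasible
range, so `z ± sz/2` stays inside (0, 1)) on a logit scale, drift
coefficients natural in (−10, 10) — as draws from group-level normal
distributions. Group means carry flat priors over bounded supports
(`a ∈ (0.3, 12)`, `z ∈ (0.01, 0.99)`, `t0 ∈ (0, 2)`, betas `(−10, 10)`);
group SDs are half-uniform on (0.01, 3). The sampler is
Metropolis-within-Gibbs: per-subject per-parameter random walks with
proposal scales adapted toward 44% acceptance during burn-in only, exact
truncated-normal Gibbs updates for group means, and log-scale random walks
for group SDs. Parameters a specification fixes (e.g. `z = 0.5`) are
excluded from sampling. Initialization is data-informed (`t0` from each
subject's minimum RT, `a` from a zero-drift moment match), with retries on
a non-finite posterior.

Default chain settings are 20 000 posterior samples with the first
5 000 discarded as burn-in, convergence
diagnosed by the classic Gelman–Rubin statistic (between/within-chain
variance ratio; < 1.1 accepted) over repeated independent runs. The test
suite and acceptance script use scaled-down chains (documented below).

Model comparison: `DIC = D̄ + pD`, `pD = D̄ − D(θ̄)` with the plug-in
deviance evaluated at posterior-mean subject parameters on the natural
scale, and `BPIC = D̄ + 2 pD` (stronger complexity penalty); lower is
better, negative `pD` is flagged but still returned. Reported group
estimates and 95% intervals are central posterior quantiles of the group
mean transformed to the natural scale. All reported 95% intervals are central credible intervals; all free
parameters are hierarchical.

## Behavioral pipeline

Exclusions (one primary reason per unit, priority order): trials answered
before the second item are dropped; participants doing so on more than
half their trials are removed entirely; participants whose accuracy falls
below the sample mean minus two (sample, ddof = 1) standard deviations are
removed; participants tripping ≥ 2 bot indicators — identical-millisecond
RTs in > 10% of trials (derivable from trial data), chance-level
comprehension, implausible session metadata (optional per-participant
metadata) — are removed. The accuracy threshold is computed after the
early-response exclusions. Idempotence
holds on clean data; on pathological inputs a second application can in
principle remove further low-accuracy tails (inherent to mean−2SD rules).

Descriptive statistics are computed per participant and compared with
paired two-sided t-tests: proportion of desirable judgments vs the
proportion of desirable states encountered; mean natural-log sample counts
before desirable vs undesirable judgments (the log transform addresses the
heavy right skew); false-positive-belief vs false-negative-belief rates.
The speed–accuracy analysis rank-splits each participant's RTs at the
median (fast/slow counts differ by ≤ 1, ties broken by trial order) and
runs a 2×2 repeated-measures ANOVA of cell-mean accuracy on speed ×
judged desirability, dropping (and counting) participants with an empty
cell; exactly-zero effect contrasts are reported as F = 0 rather than the
0/0 artifact of the generic ANOVA computation.

### Psychometric function

P(judge TV) is modelled as a logistic in the centred TV-item proportion X:

    P(TV) = 1 / (1 + exp(-(b1 * X + b0)))

fitted as a hierarchical Bayesian logistic regression (subject-level
intercepts and slopes drawn from group normals, Metropolis-within-Gibbs,
same machinery as the main sampler), separately for participants whose
desirable factory is the TV vs the phone factory. **Sign convention**: with
`+b0` in the linear predictor, a larger `b0` raises P(TV) at every X and
shifts the curve *left* — fewer TV items are needed to conclude "TV". A
desirability bias toward TV therefore appears as
`b0(TV desirable) > b0(TV undesirable)`. (The form with `−b0` would invert
this relation; we use `+b0` so that the stated ordering and the leftward
shift are mathematically consistent.) Complete separation is contained by
the bounded hierarchical priors and flagged when the slope posterior
concentrates at its bound.

## Collapsing-boundary accumulator

A discrete per-item accumulator `X_t = X_{t−1} + d_t + ε_t` with
`ε ~ N(0, σ²)` and `d_t = ±1` (item supports the desirable vs the other
state), decision at the first item step with `|X_t| ≥ u_t`, where the
symmetric threshold follows the Weibull collapse
`u_t = a − [1 − exp(−(t/λ)^k)](a − a′)` with shape `k = 3` ("late
collapse") and `λ` in item steps (multiply by 0.550 for seconds). The
starting bias `X_1 = x1` is checked against `u_1` before any item
contributes (a bias on the boundary produces an immediate step-1
decision); items contribute from the first step onward.

Likelihood is simulation-based: `p_i` is the fraction of simulations whose
decision step matches trial *i*'s observed sample count within one item
step (the natural resolution of this paced task), floored at
`1/(2 n_sim)`; `log L = Σ log max(p_i, floor)`. One set of accumulator
noise and one stream extension are drawn up front and shared across all
trials and all proposals (common random numbers): the accumulator is
linear in its noise, so `X` is an exact deterministic function of the
parameters given that noise, making the objective smooth, trial-order
invariant, and optimizable. Optimization is a 2-pass adaptive grid
(span halved around the incumbent; 8 points/dimension by default) followed
by Nelder–Mead restarts from the 5 best points (500-iteration cap). The
*reported* log likelihood and AIC are re-evaluated at the optimum with a
fresh, 5× larger simulation set, removing the optimism that maximizing a
noisy surface induces (which would otherwise systematically favor the more
flexible model). The fixed-threshold comparator is the same discrete
accumulator with `a′ ≡ a` (`λ`, `a′` not counted as free parameters), so
the comparison is like-for-like; `σ²` is estimated by default (grid range
0.1–4) with options to fix `σ²` and/or `x1`. `AIC = 2k − 2 log L`. Fits
are run per participant, separately for desirable and undesirable
responses.

## Cross-validation

Trials are partitioned by parity of the trial index. Models are fitted to
even trials; each odd trial is predicted by 1000 simulations from the
subject's posterior-mean parameters with `N(0, noise_sd)` drift noise per
repetition (`noise_sd = 0.1` by default and reported in all outputs;
subject-level rather than group-level parameters are used, documented
here as the package's choice). Predictions are repetition means of log RT
(mean of log-transformed simulated RTs, matching the log-RT error metric),
the desirable-judgment indicator, and the accuracy indicator; censored
repetitions are excluded with their count logged. Mean absolute error is
computed per measure and compared between models with paired t-tests at
the trial level, pooled across participants. Note that with predictions
and observations transformed consistently, per-trial judgment and accuracy
absolute errors are mathematically identical; both are reported for
completeness.

## Scaled-down study sizes

Full-scale defaults are 20 000/5 000 chains, 1000 simulations per trial
and 8-point grids. The test suite and the
acceptance script use smaller problem sizes chosen as this package's
desk-scale standard: parameter recovery runs 20 replicate cohorts of
20 subjects × 80 trials with 2 000/500 chains (generating values
`z = 0.55`, `b2 = 0.2`, `a = 1.5`, `t0 = 0.3`, `b1 = 3`); model-selection
recovery runs 10 replicates of 7 subjects with 1 000/250 chains and strong
biases (`z = 0.60`, `b2 = 0.6` — at small cohort sizes a mild `b2` is not
reliably detectable by DIC, a power limitation worth knowing in itself); collapsing-boundary recovery uses 40 trials per
synthetic participant, 250 grid simulations per trial and an 8× final
evaluation. At these scales single-cohort group estimates are noisy
(posterior means of `b2` scatter by ≈ ±0.1 across replicate cohorts);
unbiasedness and coverage are therefore always assessed across replicates,
never from one cohort.

## Known limitations

* The evidence covariate depends on items seen, which depends on RT; it
  is treated as an exogenous per-trial covariate at fitting time.
* No inter-trial drift variability (sv) or non-decision-time variability
  (st); only `sz` is modelled.
* The sz-jittered density's extreme early tail (see above).
* Mean−2SD exclusion rules are not strictly idempotent in adversarial
  cases.
* Gelman–Rubin values at scaled-down chain lengths can exceed 1.1 for the
  weakly identified parameters (`sz` fraction, drift intercept) on some
  cohorts; full-length chains are the documented remedy.
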