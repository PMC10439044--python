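# Methods

## The model

Behaviour is modelled per participant as a hidden Markov chain over S
latent strategies. Trial t carries a joint observation (rt_t, c_t): a
response time in ms and a correctness indicator. Given the state, the two
components are conditionally independent; accuracy is Bernoulli(θ_s) in
every family, and the RT component is one of

* **non-parametric**: the participant's RTs are cut into K equal-width bins
  over their own [min, max] range and each state carries an unconstrained
  multinomial over the K categories. Both the distribution's shape and the
  order of the bins are discarded.
* **semi-parametric**: the same bins with an intercept-only cumulative-logit
  emission, P(bin ≤ k | s) = logistic(c_{s,k}) with strictly increasing
  cutpoints. With all K−1 cutpoints free this is a smooth bijection of the
  multinomial simplex — cutpoints are the logits of the cumulative
  probabilities — so the two families have identical maximized likelihoods
  and the ordinal information adds nothing at the optimum. The package
  exploits the bijection for the M-step (closed-form cutpoint transform of
  the posterior-weighted bin frequencies) and a test asserts the likelihood
  equality on identically seeded fits.
* **parametric**: state-specific Gaussian over raw RT — deliberately
  misspecified for skewed RT data, included as the conventional baseline.

## Estimation

Baum–Welch EM with scaled forward–backward recursions. Emission rows are
max-shifted before exponentiation so even far-tail Gaussian densities
cannot underflow a whole time step; the backward pass reuses the forward
scaling constants and the expected transition counts (xi) accumulate in the
same backward sweep. The recursions and the Viterbi decoder are
numba-compiled; both are property-tested against exhaustive path
enumeration for T ≤ 8, S ≤ 3 and against hmmlearn's categorical HMM on
longer sequences.

Numerical choices:

* convergence: absolute log-likelihood change < 1e-6, at most 1000
  iterations (well below the precision of any reported group statistic);
* probability floors: emission category probabilities and θ_s are clamped
  to [1e-10, 1−1e-10] and renormalized after each M-step, so empty bins
  keep categories without producing −∞;
* Gaussian SDs are floored at 0.01 ms; a fit whose state retains less than
  one trial-equivalent of posterior mass, or whose Gaussian SD falls below
  1 ms (a component collapsing onto a point, where the likelihood is
  unbounded), is flagged degenerate rather than raised;
* restarts: 20 random initializations per fit — flat-Dirichlet emission
  rows, transition rows from a Dirichlet with diagonal concentration 5,
  uniform initial law, Gaussians initialized from random quantile splits of
  the sorted RTs — keeping the lowest-BIC non-degenerate solution (at fixed
  S and family this is also the highest likelihood);
* Viterbi ties break toward the lower state index; smoothed-posterior
  argmax decoding is available alongside (`FitResult.posterior_path`), and
  on well-separated fixtures the two agree;
* BIC uses n = T, the trial count, the conventional observation count for
  HMM likelihoods;
* parameter counts: (S−1) initial + S(S−1) transition + S·df RT + S
  accuracy, with df = K−1 for both bin families (the cutpoints are a
  reparameterization, not a restriction — the count is deliberately equal)
  and 2 for the Gaussian.

## Evaluation

Fitted labels are arbitrary, so decoded states are aligned to generative
states by ascending mean RT (the natural ordering for strategies defined by
speed); if two fitted states' mean RTs fall within 1 ms the ordering falls
back to accuracy. Classification accuracy is the fraction of trials whose
aligned decoded state equals the generative state, always computed at the
generative S; how often selection criteria find that S is analyzed
separately. Pairwise family comparisons are per-participant paired
differences (mean, SD, range, sign proportions) on identical datasets.

## Simulators

The shifted Wald is parameterized by its moments, M = μ+τ, SD = √(μ³/λ),
SK = 3√(μ/λ), inverted in closed form (μ = 3·SD/SK, λ = μ·(3/SK)²,
τ = M−μ) so states can be written directly as (mean, SD, skewness).
Sampling uses the Michael–Schucany–Haas inverse-Gaussian transform plus the
shift — exact, no rejection — and is KS-tested against the scipy
inverse-Gaussian CDF.

The DDM walker is Euler–Maruyama with a 0.1 ms step on the accumulator,
absorbing boundaries at 0 and a, and a 20 s cap with resampling (the cap is
never reached at the shipped parameter values). A discrete-time walk
systematically overshoots first-passage times by O(√dt) because it misses
within-step crossings; the standard Broadie–Glasserman–Kou boundary
correction (boundaries pulled inward by 0.5826·s·√dt) cancels this, and
the sampler is validated against the closed-form unbiased-start mean
first-passage time and choice probability to within 4 standard errors at
n = 1e5.

## Study configurations

The generator defaults are the study conditions: a two-state baseline
(state 1: M 600 ms, SD 100, SK 1.5, 70% correct; state 2: M 900 ms, SD 150,
SK 1.75, 90% correct; stay-probability 0.8; 500 trials; 20 bins), a
one-factor-at-a-time grid over that baseline (RT difference 150/600 ms,
accuracy difference 10/40 points, SK and SD scaled by 2/3 and 4/3, stay
probability 0.65/0.95, 126/2000 trials, 5/35 bins, unequal mixture), a
three-state scenario adding a fast guessing state (M 300 ms, SD 70,
SK 1.25, 50% correct; 750 trials; stay 0.8, switch 0.1+0.1), and a
DDM-generated two-state scenario (speed regime: v=.081, a=.081, t0=.596 s;
accuracy regime: v=.081, a=.203, t0=.203 s; z=a/2, s=.1).

Design choices where the construction was genuinely open:

* the initial state law is uniform — for the symmetric chains it coincides
  with the stationary law;
* the unequal-mixture cell uses an asymmetric chain (switch rates 0.1 and
  0.2), whose stationary occupancy (2/3, 1/3) gives the majority state more
  than 65% of trials while preserving the dynamic-mixture construction;
* per-participant generators are spawned from the master seed via
  `numpy.random.SeedSequence`, making datasets reproducible and independent
  of how many joblib workers fit them.

At the shipped accuracy-regime DDM parameters the analytic mean RT is
≈1050 ms, so the two DDM states are separated by ≈296 ms — comparable to
the shifted-Wald baseline separation. Recovery results for the DDM
scenario should be read with that separation in mind.

## What the synthetic data do and do not show

The generators realize exactly the assumed data-generating process:
first-order Markov switching, within-state i.i.d. emissions, no item or
stimulus covariates, no RT censoring or fast-guess contamination beyond
what the states themselves encode. Passing recovery tests therefore shows
the estimator works when the model class contains the truth; it says
nothing about misspecified real data (serial dependence within a strategy,
item effects, outliers stretching the bin range — the binning module warns
when more than 40% of bins are empty, a symptom of the latter).

## Problem sizes

Group-level checks run at reduced participant counts chosen as the
package's own desk scale: 40 participants per study in
`scripts/acceptance.py` and 12–25 in the test suite, against 100 in the
full design; trial counts, state parameters and the 20-restart protocol
are never reduced. All group comparisons use two-run Monte-Carlo
tolerances 2·√(sd_ref²/100 + sd_obs²/n), so the reduced scale widens the
acceptance band rather than biasing it.

## Known limitations

* Transition and emission parameters admit no covariates; hierarchical
  (multi-participant) pooling is out of scope — participants are fitted
  independently.
* The DDM closed forms (and hence the sampler validation) cover only the
  unbiased-start, nonzero-drift case; across-trial variability parameters
  (sv, sz, st0) of the full Ratcliff model are not implemented.
* Equal-width binning is the only discretization; quantile binning would
  change the method's character (the bin widths are part of what the
  multinomial learns).
* EM finds local optima; 20 restarts make the reported group statistics
  stable, but single fits at S ≥ 3 occasionally converge to merged-state
  solutions, which is precisely what the restart protocol and the
  degeneracy flag are for.
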