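# stratmix

Identifying latent cognitive strategies from trial-level response times and
accuracy.

In many tasks people switch between qualitatively different strategies from
trial to trial — fast guessing versus careful deliberation, memory retrieval
versus computation. `stratmix` treats the strategy on each trial as the
hidden state of a first-order Markov chain and the observed behaviour
(response time and correctness) as state-dependent emissions, then recovers
the states, their number, and the per-trial strategy labels by maximum
likelihood.

Its distinguishing feature is a **non-parametric RT emission**: each
participant's RTs are discretized into K equal-width bins and modelled per
state as an unconstrained multinomial over bin categories. No RT
distribution shape is assumed, so the method cannot be misled by a wrong
parametric choice. Two comparison families are built in:

* **semi-parametric** — an intercept-only cumulative-logit (ordinal)
  emission over the same bins, which keeps bin order; with a full set of
  free cutpoints it is a bijective reparameterization of the multinomial
  and attains the same maximized likelihood;
* **parametric** — the conventional Gaussian over raw RT.

Accuracy is a per-state Bernoulli in all families. The joint per-trial
emission is `P(rt | state) * P(correct | state)`.

## Model

For states `s = 1..S` with initial law `π`, transition matrix `A`, RT
emission `f_s` and accuracy `θ_s`, the likelihood of a trial sequence
`(rt_t, c_t)` is

```
L = Σ_paths π(s_1) f_{s_1}(rt_1) θ_{s_1}^{c_1}(1-θ_{s_1})^{1-c_1} ∏_t A(s_{t-1}, s_t) f_{s_t}(rt_t) …
```

maximized by Baum–Welch EM (scaled forward–backward recursions, closed-form
M-steps, 20 random restarts keeping the lowest-BIC non-degenerate solution).
State paths are decoded with Viterbi; the number of states is selected per
participant by BIC/AIC over S = 1..4 with

```
BIC = -2 logL + k ln T,   AIC = -2 logL + 2k,
k = (S-1) + S(S-1) + S·df_RT + S,   df_RT = K-1 (binned) or 2 (Gaussian).
```

The package also ships the simulators needed to study recovery: shifted-Wald
RT mixtures specified by mean/SD/skewness (`M = μ+τ`, `SD = √(μ³/λ)`,
`SK = 3√(μ/λ)`), and a diffusion-decision-model (DDM) generator whose
Euler–Maruyama walker is validated against the closed-form mean
first-passage time `(a/2v)·tanh(av/2s²) + t0` and choice probability
`1/(1+exp(-av/s²))` for an unbiased start.

## Worked example

```python
import numpy as np
from stratmix import (baseline_config, generate_participant, bin_rts,
                      fit_with_restarts, align_states, classification_accuracy)

cfg = baseline_config(master_seed=0)     # two states: 600 ms/70% and 900 ms/90%
ds = generate_participant(cfg, np.random.default_rng(1))
binned = bin_rts(ds.rt_ms, 20)
fit = fit_with_restarts(ds, S=2, family="nonparametric", binned=binned,
                        n_restarts=20, rng=np.random.default_rng(7))
amap = align_states(fit, ds, list(cfg.states))
print(f"loglik {fit.loglik:.2f}  BIC {fit.bic:.1f}  "
      f"accuracy {classification_accuracy(fit, ds, amap):.4f}")
```

prints

```
loglik -1401.44  BIC 3070.1  accuracy 0.9120
```

i.e. the fitted two-state multinomial model explains this participant's 500
trials with a log-likelihood of −1401.44, and after mapping the faster
fitted state to the faster generative state, 91.2% of trials are assigned
to the strategy that actually generated them.

A command-line interface wraps the same machinery:

```sh
stratmix simulate --scenario baseline --participants 10 --seed 0 --out data.csv
stratmix fit data.csv --family nonparametric --states 2 --bins 20 --restarts 20 --seed 0
stratmix select data.csv --max-states 4 --seed 0
stratmix reproduce sim2 --participants 25 --seed 0 --out results/
```

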