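"""Hidden Markov machinery for RT/accuracy strategy mixtures.

Each trial emits a joint observation: an RT component and a correct/error
outcome, conditionally independent given the latent state.  Three RT
emission families are supported:

* ``nonparametric`` — an unconstrained multinomial over K equal-width RT
  bins per state.  Discards both distributional shape and bin order; this
  is the method of interest.
* ``semiparametric`` — an intercept-only cumulative-logit (ordinal) model
  over the same K bins: state s has K-1 strictly increasing cutpoints
  c_1 < ... < c_{K-1} with P(bin <= k) = logistic(c_k).  With a full set of
  free cutpoints this is a bijective reparameterization of the multinomial,
  so its maximized likelihood coincides with the non-parametric family's;
  its M-step is the closed-form cutpoint transform of the weighted bin
  frequencies.
* ``parametric`` — a Gaussian over raw RT (ms) per state, the conventional
  default.

Accuracy is Bernoulli per state in every family.  Estimation is Baum-Welch
EM with scaled forward-backward recursions (numba-compiled), random
restarts keeping the lowest-BIC non-degenerate solution, and Viterbi
decoding of the state path.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from numba import njit

from .binning import BinnedRT
from .simulate import ParticipantDataset

__all__ = [
    "Family",
    "HMMModel",
    "FitResult",
    "log_emission_matrix",
    "forward_backward",
    "viterbi",
    "em_fit",
    "fit_with_restarts",
    "count_params",
    "information_criteria",
    "probs_from_cutpoints",
    "cutpoints_from_probs",
]

logger = logging.getLogger(__name__)

# EM stopping rule and numerical guards.
EM_TOL = 1e-6
EM_MAX_ITER = 1000
PROB_FLOOR = 1e-10
GAUSS_SD_FLOOR = 1e-2  # ms
# A state supported by less than one trial-equivalent of posterior mass
# (or a collapsed Gaussian) is flagged degenerate rather than raised.
DEGENERATE_MASS = 1.0
DEGENERATE_SD = 1.0  # ms
# Transition-row Dirichlet concentration favouring self-transitions at init.
INIT_DIAG_CONCENTRATION = 5.0


class Family(str, Enum):
    NONPARAMETRIC = "nonparametric"
    SEMIPARAMETRIC = "semiparametric"
    PARAMETRIC = "parametric"


def probs_from_cutpoints(cutpoints: np.ndarray) -> np.ndarray:
    """Category probabilities implied by cumulative-logit cutpoints (rows)."""
    cdf = 1.0 / (1.0 + np.exp(-cutpoints))
    full = np.concatenate(
        [np.zeros((cdf.shape[0], 1)), cdf, np.ones((cdf.shape[0], 1))], axis=1
    )
    return np.diff(full, axis=1)


def cutpoints_from_probs(probs: np.ndarray) -> np.ndarray:
    """Inverse transform: cutpoints c_k = logit(P(bin <= k)), k = 1..K-1."""
    cum = np.cumsum(probs, axis=1)[:, :-1]
    cum = np.clip(cum, PROB_FLOOR, 1.0 - PROB_FLOOR)
    return np.log(cum / (1.0 - cum))


@dataclass
class HMMModel:
    """State-space parameters plus the family-specific RT emission.

    ``bin_probs`` (S, K) holds the multinomial rows for the bin families
    (for the ordinal family they are derived from ``cutpoints``);
    ``mean``/``sd`` (S,) hold the Gaussian parameters for the parametric
    family.  ``p_correct`` (S,) is the Bernoulli accuracy per state.
    """

    family: Family
    initial: np.ndarray
    transition: np.ndarray
    p_correct: np.ndarray
    bin_probs: np.ndarray | None = None
    cutpoints: np.ndarray | None = None
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.p_correct = np.asarray(self.p_correct, dtype=float)
        S = self.initial.shape[0]
        if self.transition.shape != (S, S):
            raise ValueError("transition shape must match the number of states")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-8):
            raise ValueError("initial distribution must sum to 1")
        if self.family is Family.SEMIPARAMETRIC and self.cutpoints is not None:
            self.bin_probs = probs_from_cutpoints(np.asarray(self.cutpoints, dtype=float))

    @property
    def n_states(self) -> int:
        return self.initial.shape[0]

    @property
    def n_bins(self) -> int | None:
        return None if self.bin_probs is None else self.bin_probs.shape[1]


@dataclass
class FitResult:
    """One fitted model with its likelihood, criteria and decoded path."""

    model: HMMModel
    loglik: float
    n_params: int
    bic: float
    aic: float
    n_obs: int
    converged: bool
    n_iter: int
    decoded: np.ndarray
    state_posteriors: np.ndarray
    degenerate: bool = False
    restart_index: int = 0
    bin_edges: np.ndarray | None = None
    loglik_trace: np.ndarray | None = None

    def posterior_path(self) -> np.ndarray:
        """Smoothed-posterior argmax decoding (1-based), the Viterbi alternative."""
        return np.argmax(self.state_posteriors, axis=1) + 1

    def to_json(self) -> str:
        m = self.model
        payload = {
            "family": m.family.value,
            "n_states": m.n_states,
            "n_bins": m.n_bins,
            "initial": m.initial.tolist(),
            "transition": m.transition.tolist(),
            "p_correct": m.p_correct.tolist(),
            "bin_probs": None if m.bin_probs is None else m.bin_probs.tolist(),
            "cutpoints": None if m.cutpoints is None else np.asarray(m.cutpoints).tolist(),
            "mean": None if m.mean is None else m.mean.tolist(),
            "sd": None if m.sd is None else m.sd.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "degenerate": self.degenerate,
            "restart_index": self.restart_index,
            "decoded": self.decoded.tolist(),
            "bin_edges": None if self.bin_edges is None else self.bin_edges.tolist(),
        }
        return json.dumps(payload)


def count_params(S: int, family: Family, K: int | None = None) -> int:
    """Free-parameter count: initial (S-1) + transitions S(S-1) + RT + accuracy.

    The RT emission contributes K-1 parameters per state for both bin
    families (the ordinal cutpoints are a reparameterization, not a
    restriction) and 2 per state for the Gaussian; accuracy adds one
    Bernoulli parameter per state.
    """
    family = Family(family)
    if family is Family.PARAMETRIC:
        rt_df = 2
    else:
        if K is None:
            raise ValueError("bin families need the bin count K")
        rt_df = K - 1
    return (S - 1) + S * (S - 1) + S * rt_df + S


def information_criteria(loglik: float, k: int, n_obs: int) -> tuple[float, float]:
    """(BIC, AIC) = (-2*loglik + k*ln(n), -2*loglik + 2k)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -2.0 * loglik + k * math.log(n_obs), -2.0 * loglik + 2.0 * k


def log_emission_matrix(
    model: HMMModel, data: ParticipantDataset, binned: BinnedRT | None = None
) -> np.ndarray:
    """T x S matrix of log P(rt_t | s) + log P(correct_t | s)."""
    correct = data.correct
    pc = np.clip(model.p_correct, PROB_FLOOR, 1.0 - PROB_FLOOR)
    log_acc = np.where(
        correct[:, None] == 1, np.log(pc)[None, :], np.log1p(-pc)[None, :]
    )
    if model.family is Family.PARAMETRIC:
        sd = np.maximum(model.sd, GAUSS_SD_FLOOR)
        z = (data.rt_ms[:, None] - model.mean[None, :]) / sd[None, :]
        log_rt = -0.5 * z**2 - np.log(sd)[None, :] - 0.5 * math.log(2.0 * math.pi)
    else:
        if binned is None:
            raise ValueError("bin families require binned RTs")
        idx = binned.bin_index
        if np.any(idx < 1) or np.any(idx > binned.K):
            raise ValueError("bin indices must lie in 1..K")
        probs = np.clip(model.bin_probs, PROB_FLOOR, 1.0)
        log_rt = np.log(probs)[:, idx - 1].T
    return log_rt + log_acc


@njit(cache=True)
def _fb_core(B, log_shift, init, trans):  # pragma: no cover - numba
    T, S = B.shape
    alpha = np.empty((T, S))
    gamma = np.empty((T, S))
    xi = np.zeros((S, S))
    c = np.empty(T)
    a = init * B[0]
    c[0] = a.sum()
    if c[0] <= 0.0:
        return -np.inf, gamma, xi
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * B[t]
        c[t] = a.sum()
        if c[t] <= 0.0:
            return -np.inf, gamma, xi
        alpha[t] = a / c[t]
    beta = np.ones(S)
    gamma[T - 1] = alpha[T - 1]
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta / c[t + 1]
        for i in range(S):
            acc = 0.0
            for j in range(S):
                term = trans[i, j] * bb[j]
                xi[i, j] += alpha[t, i] * term
                acc += term
            beta[i] = acc  # overwritten after use: beta_t from beta_{t+1}
        # careful: beta[i] must use the old beta vector; bb froze it above
        g = alpha[t] * beta
        gamma[t] = g / g.sum()
    loglik = np.log(c).sum() + log_shift
    return loglik, gamma, xi


@njit(cache=True)
def _viterbi_core(logB, log_init, log_trans):  # pragma: no cover - numba
    T, S = logB.shape
    delta = log_init + logB[0]
    back = np.zeros((T, S), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(S)
        for j in range(S):
            best = -np.inf
            arg = 0
            for i in range(S):
                v = delta[i] + log_trans[i, j]
                if v > best:  # strict: ties resolve to the lowest index
                    best = v
                    arg = i
            new[j] = best + logB[t, j]
            back[t, j] = arg
        delta = new
    path = np.empty(T, dtype=np.int64)
    best = -np.inf
    arg = 0
    for j in range(S):
        if delta[j] > best:
            best = delta[j]
            arg = j
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, best


def _scaled_emissions(logB: np.ndarray) -> tuple[np.ndarray, float]:
    shift = np.max(logB, axis=1)
    B = np.exp(logB - shift[:, None])
    return B, float(shift.sum())


def forward_backward(
    model: HMMModel, data: ParticipantDataset, binned: BinnedRT | None = None
) -> tuple[float, np.ndarray, np.ndarray]:
    """Scaled forward-backward pass.

    Returns (loglik, gamma, xi_sums): the data log-likelihood, the T x S
    smoothed state posteriors, and the S x S matrix of expected transition
    counts summed over time.
    """
    logB = log_emission_matrix(model, data, binned)
    B, log_shift = _scaled_emissions(logB)
    loglik, gamma, xi = _fb_core(B, log_shift, model.initial, model.transition)
    if not np.isfinite(loglik):
        raise FloatingPointError("forward pass underflowed: no state explains some trial")
    return loglik, gamma, xi


def viterbi(
    model: HMMModel, data: ParticipantDataset, binned: BinnedRT | None = None
) -> np.ndarray:
    """Maximum-probability state path, 1-based; ties break toward lower index."""
    logB = log_emission_matrix(model, data, binned)
    with np.errstate(divide="ignore"):
        log_init = np.log(model.initial)
        log_trans = np.log(model.transition)
    path, _ = _viterbi_core(logB, log_init, log_trans)
    return path + 1


def _clip_simplex(rows: np.ndarray) -> np.ndarray:
    rows = np.clip(rows, PROB_FLOOR, 1.0 - PROB_FLOOR)
    return rows / rows.sum(axis=-1, keepdims=True)


def _m_step(
    model: HMMModel,
    data: ParticipantDataset,
    binned: BinnedRT | None,
    gamma: np.ndarray,
    xi: np.ndarray,
    onehot: np.ndarray | None,
) -> HMMModel:
    S = model.n_states
    initial = _clip_simplex(gamma[0])
    row_sums = xi.sum(axis=1, keepdims=True)
    transition = np.where(row_sums > 0, xi / np.where(row_sums > 0, row_sums, 1.0), 1.0 / S)
    transition = _clip_simplex(transition)
    mass = gamma.sum(axis=0)
    safe_mass = np.where(mass > 0, mass, 1.0)
    p_correct = np.clip(
        (gamma * data.correct[:, None]).sum(axis=0) / safe_mass,
        PROB_FLOOR,
        1.0 - PROB_FLOOR,
    )
    kw: dict = {}
    if model.family is Family.PARAMETRIC:
        mean = (gamma * data.rt_ms[:, None]).sum(axis=0) / safe_mass
        var = (gamma * (data.rt_ms[:, None] - mean[None, :]) ** 2).sum(axis=0) / safe_mass
        sd = np.maximum(np.sqrt(var), GAUSS_SD_FLOOR)
        kw = {"mean": mean, "sd": sd}
    else:
        freq = gamma.T @ onehot  # (S, K) posterior-weighted bin counts
        probs = _clip_simplex(freq / safe_mass[:, None])
        if model.family is Family.SEMIPARAMETRIC:
            kw = {"cutpoints": cutpoints_from_probs(probs)}
        else:
            kw = {"bin_probs": probs}
    return HMMModel(
        family=model.family,
        initial=initial,
        transition=transition,
        p_correct=p_correct,
        **kw,
    )


def em_fit(
    init: HMMModel,
    data: ParticipantDataset,
    binned: BinnedRT | None = None,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> FitResult:
    """Baum-Welch EM from one starting model.

    Iterates until the absolute log-likelihood change drops below ``tol``
    or ``max_iter`` is reached.  A state left with less than one
    trial-equivalent of posterior mass (or a collapsed Gaussian component)
    flags the result degenerate rather than raising.
    """
    if init.family is not Family.PARAMETRIC and binned is None:
        raise ValueError("bin families require binned RTs")
    onehot = None
    if binned is not None and init.family is not Family.PARAMETRIC:
        onehot = np.zeros((data.n_trials, binned.K))
        onehot[np.arange(data.n_trials), binned.bin_index - 1] = 1.0
    model = init
    prev_ll = -np.inf
    converged = False
    gamma = xi = None
    n_iter = 0
    trace = []
    for n_iter in range(1, max_iter + 1):
        loglik, gamma, xi = forward_backward(model, data, binned)
        trace.append(loglik)
        if loglik + 1e-8 < prev_ll:
            logger.warning("EM log-likelihood decreased by %.3g", prev_ll - loglik)
        if abs(loglik - prev_ll) < tol:
            converged = True
            break
        prev_ll = loglik
        model = _m_step(model, data, binned, gamma, xi, onehot)
    else:
        loglik, gamma, xi = forward_backward(model, data, binned)
        trace.append(loglik)
    mass = gamma.sum(axis=0)
    degenerate = bool(np.any(mass < DEGENERATE_MASS))
    if model.family is Family.PARAMETRIC and np.any(model.sd < DEGENERATE_SD):
        degenerate = True
    K = binned.K if binned is not None else None
    k = count_params(model.n_states, model.family, K)
    bic, aic = information_criteria(loglik, k, data.n_trials)
    return FitResult(
        model=model,
        loglik=loglik,
        n_params=k,
        bic=bic,
        aic=aic,
        n_obs=data.n_trials,
        converged=converged,
        n_iter=n_iter,
        decoded=viterbi(model, data, binned),
        state_posteriors=gamma,
        degenerate=degenerate,
        bin_edges=None if binned is None else binned.edges,
        loglik_trace=np.asarray(trace),
    )


def _random_init(
    S: int,
    family: Family,
    data: ParticipantDataset,
    binned: BinnedRT | None,
    rng: np.random.Generator,
) -> HMMModel:
    initial = np.full(S, 1.0 / S)
    conc = np.ones((S, S))
    np.fill_diagonal(conc, INIT_DIAG_CONCENTRATION)
    transition = np.vstack([rng.dirichlet(conc[s]) for s in range(S)])
    p_correct = np.clip(rng.uniform(size=S), 0.05, 0.95)
    kw: dict = {}
    if family is Family.PARAMETRIC:
        # Random quantile split of the sorted RTs into S contiguous chunks.
        rt_sorted = np.sort(data.rt_ms)
        q = np.sort(rng.uniform(0.1, 0.9, size=S - 1)) if S > 1 else np.empty(0)
        cuts = [0, *np.maximum(1, (q * data.n_trials).astype(int)), data.n_trials]
        cuts = np.maximum.accumulate(cuts)
        mean = np.empty(S)
        sd = np.empty(S)
        for s in range(S):
            chunk = rt_sorted[cuts[s] : max(cuts[s + 1], cuts[s] + 1)]
            mean[s] = chunk.mean()
            sd[s] = max(chunk.std(), 0.05 * data.rt_ms.std(), GAUSS_SD_FLOOR)
        kw = {"mean": mean, "sd": sd}
    else:
        probs = rng.dirichlet(np.ones(binned.K), size=S)
        probs = _clip_simplex(probs)
        if family is Family.SEMIPARAMETRIC:
            kw = {"cutpoints": cutpoints_from_probs(probs)}
        else:
            kw = {"bin_probs": probs}
    return HMMModel(
        family=family, initial=initial, transition=transition, p_correct=p_correct, **kw
    )


def fit_with_restarts(
    data: ParticipantDataset,
    S: int,
    family: Family | str,
    binned: BinnedRT | None = None,
    n_restarts: int = 20,
    rng: np.random.Generator | None = None,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> FitResult:
    """Fit from ``n_restarts`` random initializations, keep the lowest BIC.

    Degenerate restarts are excluded unless every restart degenerates, in
    which case the best available is returned still flagged degenerate.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    family = Family(family)
    if rng is None:
        rng = np.random.default_rng()
    best: FitResult | None = None
    best_any: FitResult | None = None
    for r in range(n_restarts):
        init = _random_init(S, family, data, binned, rng)
        fit = em_fit(init, data, binned, tol=tol, max_iter=max_iter)
        fit.restart_index = r
        if best_any is None or fit.bic < best_any.bic:
            best_any = fit
        if not fit.degenerate and (best is None or fit.bic < best.bic):
            best = fit
    if best is None:
        logger.warning(
            "all %d restarts degenerate for S=%d %s; returning best available",
            n_restarts,
            S,
            family.value,
        )
        return best_any
    return best
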