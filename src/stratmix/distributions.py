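"""Response-time generating processes: shifted Wald and diffusion decision model.

The shifted Wald (three-parameter inverse Gaussian) is the canonical
right-skewed distribution for simple response times: a Wald (inverse
Gaussian) first-passage time with location ``mu`` (ms) and shape ``lam``
(ms), shifted right by a non-decision offset ``tau`` (ms).  Its first three
moments have closed forms,

    M  = mu + tau
    SD = sqrt(mu**3 / lam)
    SK = 3 * sqrt(mu / lam)

which are invertible, so a state can be specified directly by the mean,
standard deviation and skewness of the response times it should produce.

The diffusion decision model (DDM) describes binary choice as a Wiener
process with drift ``v`` accumulating between two absorbing boundaries
(0 and ``a``), starting at ``z``, with diffusion constant ``s``; the
response time is the first-passage time plus a non-decision time ``t0``,
and the choice is correct iff the upper boundary is hit.  For an unbiased
start (z = a/2) the mean decision time and choice probability are known in
closed form and serve as the oracle against which the sampler is validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "SWaldSpec",
    "SWaldMoments",
    "DDMSpec",
    "swald_from_moments",
    "swald_moments",
    "sample_swald",
    "sample_ddm",
    "ddm_closed_form",
]


class InfeasibleMomentsError(ValueError):
    """Requested (M, SD, SK) lie outside the shifted-Wald moment range."""


@dataclass(frozen=True)
class SWaldSpec:
    """Shifted-Wald parameters: location ``mu``, shape ``lam``, shift ``tau`` (all ms)."""

    mu: float
    lam: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.lam > 0):
            raise ValueError(f"mu and lam must be positive, got mu={self.mu}, lam={self.lam}")
        if self.tau < 0:
            raise ValueError(f"tau must be non-negative, got tau={self.tau}")


@dataclass(frozen=True)
class SWaldMoments:
    """Moment view of a shifted Wald: mean ``M`` (ms), ``SD`` (ms), skewness ``SK``."""

    M: float
    SD: float
    SK: float


@dataclass(frozen=True)
class DDMSpec:
    """Diffusion decision model parameters.

    ``v`` drift (evidence/s), ``a`` boundary separation, ``z`` starting
    point (0 < z < a), ``t0`` non-decision time (s), ``s`` diffusion
    constant (evidence/sqrt(s)).
    """

    v: float
    a: float
    z: float
    t0: float
    s: float = 0.1

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"boundary separation must be positive, got {self.a}")
        if not 0 < self.z < self.a:
            raise ValueError(f"starting point must lie strictly inside (0, {self.a}), got {self.z}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time must be non-negative, got {self.t0}")
        if not self.s > 0:
            raise ValueError(f"diffusion constant must be positive, got {self.s}")


def swald_moments(spec: SWaldSpec) -> SWaldMoments:
    """Closed-form mean, SD and skewness of a shifted Wald."""
    return SWaldMoments(
        M=spec.mu + spec.tau,
        SD=math.sqrt(spec.mu**3 / spec.lam),
        SK=3.0 * math.sqrt(spec.mu / spec.lam),
    )


def swald_from_moments(moments: SWaldMoments) -> SWaldSpec:
    """Invert (M, SD, SK) to (mu, lam, tau).

    The inversion is exact: mu = 3*SD/SK, lam = mu/(SK/3)**2, tau = M - mu.
    Feasibility requires M > 3*SD/SK so that the shift stays non-negative.
    """
    M, SD, SK = moments.M, moments.SD, moments.SK
    if not (M > 0 and SD > 0 and SK > 0):
        raise ValueError(f"moments must be strictly positive, got M={M}, SD={SD}, SK={SK}")
    mu = 3.0 * SD / SK
    tau = M - mu
    if tau < 0:
        raise InfeasibleMomentsError(
            f"infeasible moments: require M > 3*SD/SK = {mu:.6g}, got M = {M:.6g}"
        )
    lam = mu / (SK / 3.0) ** 2
    return SWaldSpec(mu=mu, lam=lam, tau=tau)


def sample_swald(spec: SWaldSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` shifted-Wald response times (ms).

    Uses the Michael-Schucany-Haas transform for the inverse-Gaussian part
    (exact, no rejection loop) and adds the shift; every draw exceeds tau.
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    if n == 0:
        return np.empty(0)
    mu, lam = spec.mu, spec.lam
    y = rng.standard_normal(n) ** 2
    x = mu + (mu**2 * y) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * y + mu**2 * y**2
    )
    u = rng.uniform(size=n)
    wald = np.where(u <= mu / (mu + x), x, mu**2 / x)
    return wald + spec.tau


def ddm_closed_form(spec: DDMSpec) -> tuple[float, float]:
    """Analytic (mean RT in seconds, P(correct)) for an unbiased start.

    For z = a/2 and v != 0:

        E[RT]      = (a / (2 v)) * tanh(a v / (2 s**2)) + t0
        P(correct) = 1 / (1 + exp(-a v / s**2))
    """
    if spec.v == 0 or abs(spec.z - spec.a / 2.0) > 1e-12 * spec.a:
        raise ValueError(
            "closed forms implemented only for the unbiased case (z = a/2, v != 0)"
        )
    av = spec.a * spec.v
    s2 = spec.s**2
    mean_rt = (spec.a / (2.0 * spec.v)) * math.tanh(av / (2.0 * s2)) + spec.t0
    p_correct = 1.0 / (1.0 + math.exp(-av / s2))
    return mean_rt, p_correct


# Euler-Maruyama step for the accumulator, in seconds.  The boundaries are
# pulled inward by 0.5826*s*sqrt(dt) (Broadie-Glasserman-Kou continuity
# correction) to cancel the O(sqrt(dt)) first-passage bias of the
# discrete-time walk; trials still running after DDM_T_MAX are resampled.
DDM_DT = 1e-4
DDM_T_MAX = 20.0
_BGK = 0.5826


@njit(cache=True)
def _ddm_walk(gen, v, a, z, s, dt, t_max, shift, n):  # pragma: no cover - numba
    rt = np.empty(n)
    correct = np.empty(n, dtype=np.int64)
    sq = s * math.sqrt(dt)
    lo = shift
    hi = a - shift
    max_steps = int(t_max / dt)
    for i in range(n):
        while True:
            x = z
            hit = -1
            for step in range(1, max_steps + 1):
                x += v * dt + sq * gen.standard_normal()
                if x >= hi:
                    hit = 1
                    rt[i] = step * dt
                    break
                if x <= lo:
                    hit = 0
                    rt[i] = step * dt
                    break
            if hit >= 0:
                correct[i] = hit
                break
    return rt, correct


def sample_ddm(
    spec: DDMSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` DDM trials; returns (rt_s, correct).

    ``rt_s`` is first-passage time plus ``t0`` in seconds; ``correct`` is 1
    where the upper boundary was hit.
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    if n == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    shift = _BGK * spec.s * math.sqrt(DDM_DT)
    if spec.z <= shift or spec.a - shift <= spec.z:
        shift = 0.0  # boundaries too tight for the correction; fall back to raw Euler
    rt, correct = _ddm_walk(
        rng, spec.v, spec.a, spec.z, spec.s, DDM_DT, DDM_T_MAX, shift, n
    )
    return rt + spec.t0, correct
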