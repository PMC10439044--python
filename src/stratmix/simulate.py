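"""Synthetic mixture data: Markov state sequences driving per-state emissions.

A participant is modelled as switching between a small number of latent
strategies according to a first-order Markov chain; each strategy emits a
response time (shifted Wald or DDM, in ms) and a correct/error outcome
(Bernoulli, or the DDM boundary hit).  The module ships the study
configurations used throughout: a two-state baseline, a one-factor-at-a-time
manipulation grid over that baseline, a three-state scenario, and a
DDM-generated scenario.

All randomness flows through :class:`numpy.random.Generator`; per-participant
generators are spawned from the master seed with ``SeedSequence`` so datasets
are reproducible and independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .distributions import (
    DDMSpec,
    SWaldMoments,
    SWaldSpec,
    ddm_closed_form,
    sample_ddm,
    sample_swald,
    swald_from_moments,
)

__all__ = [
    "StateSpec",
    "MarkovSpec",
    "ParticipantDataset",
    "ScenarioConfig",
    "sample_state_sequence",
    "generate_participant",
    "generate_dataset",
    "scenario_grid",
    "baseline_config",
    "sim2_config",
    "sim3_config",
    "write_csv",
    "read_csv",
]

CSV_COLUMNS = ["participant_id", "trial", "rt_ms", "correct", "true_state"]


@dataclass(frozen=True)
class StateSpec:
    """One latent strategy: an RT generator plus an accuracy probability.

    For a DDM state ``p_correct`` is ignored — correctness comes from which
    boundary the accumulator hits.
    """

    rt_model: SWaldSpec | DDMSpec
    p_correct: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.rt_model, SWaldSpec):
            if self.p_correct is None or not 0 < self.p_correct < 1:
                raise ValueError(
                    f"shifted-Wald states need p_correct in (0,1), got {self.p_correct}"
                )

    def expected_mean_rt_ms(self) -> float:
        """Generative mean RT in ms (closed form for either RT model)."""
        if isinstance(self.rt_model, SWaldSpec):
            return self.rt_model.mu + self.rt_model.tau
        mean_s, _ = ddm_closed_form(self.rt_model)
        return 1000.0 * mean_s

    def expected_p_correct(self) -> float:
        if isinstance(self.rt_model, SWaldSpec):
            return float(self.p_correct)
        _, p = ddm_closed_form(self.rt_model)
        return p


@dataclass(frozen=True)
class MarkovSpec:
    """First-order chain over S latent states: initial law and transition matrix."""

    transition: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        trans = np.asarray(self.transition, dtype=float)
        init = np.asarray(self.initial, dtype=float)
        object.__setattr__(self, "transition", trans)
        object.__setattr__(self, "initial", init)
        if trans.ndim != 2 or trans.shape[0] != trans.shape[1]:
            raise ValueError(f"transition must be square, got shape {trans.shape}")
        if init.shape != (trans.shape[0],):
            raise ValueError("initial length must match transition dimension")
        if np.any(trans < 0) or np.any(trans > 1) or np.any(init < 0):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(trans.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(init.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left Perron eigenvector, normalized)."""
        w, v = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        return pi / pi.sum()


@dataclass(frozen=True)
class ParticipantDataset:
    """Ordered trials for one participant; order is the HMM's time axis."""

    participant_id: str
    rt_ms: np.ndarray
    correct: np.ndarray
    true_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        rt = np.asarray(self.rt_ms, dtype=float)
        corr = np.asarray(self.correct, dtype=int)
        object.__setattr__(self, "rt_ms", rt)
        object.__setattr__(self, "correct", corr)
        if self.true_state is not None:
            object.__setattr__(self, "true_state", np.asarray(self.true_state, dtype=int))
        if rt.shape != corr.shape or rt.ndim != 1:
            raise ValueError("rt_ms and correct must be 1-D and the same length")
        if np.any(rt <= 0):
            raise ValueError("all response times must be positive")

    @property
    def n_trials(self) -> int:
        return self.rt_ms.shape[0]


def _symmetric_chain(n_states: int, stay: float) -> MarkovSpec:
    switch = (1.0 - stay) / (n_states - 1)
    trans = np.full((n_states, n_states), switch)
    np.fill_diagonal(trans, stay)
    return MarkovSpec(transition=trans, initial=np.full(n_states, 1.0 / n_states))


@dataclass(frozen=True)
class ScenarioConfig:
    """A complete simulation scenario: states, chain, sizes, bin count, seed."""

    name: str
    states: tuple[StateSpec, ...]
    markov: MarkovSpec
    n_trials: int = 500
    n_participants: int = 100
    n_bins: int = 20
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 2 <= self.n_bins <= self.n_trials:
            raise ValueError(f"n_bins must lie in [2, n_trials], got {self.n_bins}")
        if len(self.states) != self.markov.n_states:
            raise ValueError("number of states must match the Markov chain dimension")


def sample_state_sequence(markov: MarkovSpec, T: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a length-T state path (1-based labels) from the chain."""
    if T < 1:
        raise ValueError("T must be >= 1")
    S = markov.n_states
    states = np.empty(T, dtype=int)
    # Inverse-CDF draws from precomputed cumulative rows keep this loop cheap.
    cum_init = np.cumsum(markov.initial)
    cum_rows = np.cumsum(markov.transition, axis=1)
    u = rng.uniform(size=T)
    states[0] = np.searchsorted(cum_init, u[0], side="right")
    for t in range(1, T):
        states[t] = np.searchsorted(cum_rows[states[t - 1]], u[t], side="right")
    return states + 1


def generate_participant(
    config: ScenarioConfig,
    rng: np.random.Generator,
    participant_id: str = "p001",
) -> ParticipantDataset:
    """Generate one participant's trials under the scenario."""
    T = config.n_trials
    path = sample_state_sequence(config.markov, T, rng)
    rt = np.empty(T)
    correct = np.empty(T, dtype=int)
    for s, state in enumerate(config.states, start=1):
        idx = np.flatnonzero(path == s)
        if idx.size == 0:
            continue
        if isinstance(state.rt_model, SWaldSpec):
            rt[idx] = sample_swald(state.rt_model, idx.size, rng)
            correct[idx] = rng.uniform(size=idx.size) < state.p_correct
        else:
            rt_s, corr = sample_ddm(state.rt_model, idx.size, rng)
            rt[idx] = 1000.0 * rt_s  # DDM runs in seconds; datasets carry ms
            correct[idx] = corr
    return ParticipantDataset(
        participant_id=participant_id, rt_ms=rt, correct=correct, true_state=path
    )


def generate_dataset(
    config: ScenarioConfig, n_participants: int | None = None
) -> list[ParticipantDataset]:
    """Generate all participants, each from an independently spawned generator."""
    n = config.n_participants if n_participants is None else n_participants
    seeds = np.random.SeedSequence(config.master_seed).spawn(n)
    return [
        generate_participant(config, np.random.default_rng(seeds[i]), f"p{i + 1:03d}")
        for i in range(n)
    ]


# --- study configurations ---------------------------------------------------

_BASELINE_STATE1 = SWaldMoments(M=600.0, SD=100.0, SK=1.5)
_BASELINE_STATE2 = SWaldMoments(M=900.0, SD=150.0, SK=1.75)
_BASELINE_ACC = (0.70, 0.90)


def _swald_states(
    moments: list[SWaldMoments], accuracies: list[float]
) -> tuple[StateSpec, ...]:
    return tuple(
        StateSpec(rt_model=swald_from_moments(m), p_correct=p)
        for m, p in zip(moments, accuracies)
    )


def baseline_config(master_seed: int = 0, **overrides) -> ScenarioConfig:
    """Two-state baseline: (600,100,1.5,70%) and (900,150,1.75,90%), T=500, stay 0.8, K=20."""
    cfg = ScenarioConfig(
        name="baseline",
        states=_swald_states([_BASELINE_STATE1, _BASELINE_STATE2], list(_BASELINE_ACC)),
        markov=_symmetric_chain(2, 0.8),
        n_trials=500,
        n_participants=100,
        n_bins=20,
        master_seed=master_seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _cell(name: str, master_seed: int, **kw) -> ScenarioConfig:
    base = baseline_config(master_seed)
    states = kw.pop("states", base.states)
    markov = kw.pop("markov", base.markov)
    return replace(base, name=name, states=states, markov=markov, **kw)


def scenario_grid(master_seed: int = 0) -> dict[str, ScenarioConfig]:
    """Baseline plus every one-factor manipulation cell.

    Each cell changes a single feature of the generating process and keeps
    everything else at baseline: the slow state's mean (RT difference
    150/600 ms), the less-accurate state's accuracy (difference 10%/40%),
    both skewnesses or both SDs scaled by 2/3 and 4/3, the chain's stay
    probability (0.65/0.95), the trial count (126/2000), the bin count
    (5/35), and an unequal mixture proportion (stationary law (2/3, 1/3)).
    """
    m1, m2 = _BASELINE_STATE1, _BASELINE_STATE2
    a1, a2 = _BASELINE_ACC
    cells: dict[str, ScenarioConfig] = {"baseline": baseline_config(master_seed)}

    def swald2(mom1: SWaldMoments, mom2: SWaldMoments, acc1: float = a1, acc2: float = a2):
        return _swald_states([mom1, mom2], [acc1, acc2])

    cells["rt_diff_low"] = _cell(
        "rt_diff_low", master_seed, states=swald2(m1, replace(m2, M=750.0))
    )
    cells["rt_diff_high"] = _cell(
        "rt_diff_high", master_seed, states=swald2(m1, replace(m2, M=1200.0))
    )
    cells["acc_diff_low"] = _cell("acc_diff_low", master_seed, states=swald2(m1, m2, acc1=0.80))
    cells["acc_diff_high"] = _cell("acc_diff_high", master_seed, states=swald2(m1, m2, acc1=0.50))
    for label, f in [("low", 2.0 / 3.0), ("high", 4.0 / 3.0)]:
        cells[f"skew_{label}"] = _cell(
            f"skew_{label}",
            master_seed,
            states=swald2(replace(m1, SK=m1.SK * f), replace(m2, SK=m2.SK * f)),
        )
        cells[f"sd_{label}"] = _cell(
            f"sd_{label}",
            master_seed,
            states=swald2(replace(m1, SD=m1.SD * f), replace(m2, SD=m2.SD * f)),
        )
    cells["stability_low"] = _cell(
        "stability_low", master_seed, markov=_symmetric_chain(2, 0.65)
    )
    cells["stability_high"] = _cell(
        "stability_high", master_seed, markov=_symmetric_chain(2, 0.95)
    )
    cells["trials_low"] = _cell("trials_low", master_seed, n_trials=126)
    cells["trials_high"] = _cell("trials_high", master_seed, n_trials=2000)
    cells["bins_low"] = _cell("bins_low", master_seed, n_bins=5)
    cells["bins_high"] = _cell("bins_high", master_seed, n_bins=35)
    # Unequal mixture: asymmetric switch rates 0.1 / 0.2 give stationary
    # occupancy (2/3, 1/3), i.e. the majority state holds > .65 of trials.
    unequal = MarkovSpec(
        transition=np.array([[0.9, 0.1], [0.2, 0.8]]), initial=np.array([2.0 / 3.0, 1.0 / 3.0])
    )
    cells["mixture_unequal"] = _cell("mixture_unequal", master_seed, markov=unequal)
    return cells


def sim2_config(master_seed: int = 0, **overrides) -> ScenarioConfig:
    """Three-state scenario: adds a fast guessing state (300 ms, 50%) to the baseline pair.

    750 trials per participant; each state stays with probability 0.8 and
    switches to either other state with probability 0.1.
    """
    guess = SWaldMoments(M=300.0, SD=70.0, SK=1.25)
    cfg = ScenarioConfig(
        name="sim2",
        states=_swald_states(
            [guess, _BASELINE_STATE1, _BASELINE_STATE2], [0.50, *_BASELINE_ACC]
        ),
        markov=_symmetric_chain(3, 0.8),
        n_trials=750,
        n_participants=100,
        n_bins=20,
        master_seed=master_seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


SPEED_DDM = DDMSpec(v=0.081, a=0.081, z=0.081 / 2.0, t0=0.596, s=0.1)
ACCURACY_DDM = DDMSpec(v=0.081, a=0.203, z=0.203 / 2.0, t0=0.203, s=0.1)


def sim3_config(master_seed: int = 0, **overrides) -> ScenarioConfig:
    """Two DDM-generated states (speed vs accuracy regime), baseline chain and sizes."""
    cfg = ScenarioConfig(
        name="sim3",
        states=(StateSpec(rt_model=SPEED_DDM), StateSpec(rt_model=ACCURACY_DDM)),
        markov=_symmetric_chain(2, 0.8),
        n_trials=500,
        n_participants=100,
        n_bins=20,
        master_seed=master_seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# --- serialization ----------------------------------------------------------


def config_to_yaml(config: ScenarioConfig, path=None) -> str:
    """Serialize a scenario (or write it to ``path``) as YAML."""
    import yaml

    def state_dict(st: StateSpec) -> dict:
        if isinstance(st.rt_model, SWaldSpec):
            return {
                "rt_model": "swald",
                "mu": st.rt_model.mu,
                "lam": st.rt_model.lam,
                "tau": st.rt_model.tau,
                "p_correct": st.p_correct,
            }
        m = st.rt_model
        return {"rt_model": "ddm", "v": m.v, "a": m.a, "z": m.z, "t0": m.t0, "s": m.s}

    payload = {
        "name": config.name,
        "states": [state_dict(s) for s in config.states],
        "transition": config.markov.transition.tolist(),
        "initial": config.markov.initial.tolist(),
        "n_trials": config.n_trials,
        "n_participants": config.n_participants,
        "n_bins": config.n_bins,
        "master_seed": config.master_seed,
    }
    text = yaml.safe_dump(payload, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_from_yaml(source) -> ScenarioConfig:
    """Load a scenario from a YAML string or file path."""
    import os

    import yaml

    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        with open(source) as fh:
            payload = yaml.safe_load(fh)
    else:
        payload = yaml.safe_load(source)
    states = []
    for sd in payload["states"]:
        if sd["rt_model"] == "swald":
            states.append(
                StateSpec(
                    rt_model=SWaldSpec(mu=sd["mu"], lam=sd["lam"], tau=sd["tau"]),
                    p_correct=sd["p_correct"],
                )
            )
        else:
            states.append(
                StateSpec(rt_model=DDMSpec(v=sd["v"], a=sd["a"], z=sd["z"], t0=sd["t0"], s=sd["s"]))
            )
    return ScenarioConfig(
        name=payload["name"],
        states=tuple(states),
        markov=MarkovSpec(
            transition=np.array(payload["transition"]), initial=np.array(payload["initial"])
        ),
        n_trials=payload["n_trials"],
        n_participants=payload["n_participants"],
        n_bins=payload["n_bins"],
        master_seed=payload["master_seed"],
    )


# --- CSV round trip ---------------------------------------------------------


def write_csv(datasets: list[ParticipantDataset], path) -> None:
    """Write participants as tidy CSV (trial index 1-based, temporal order)."""
    frames = []
    for ds in datasets:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": ds.participant_id,
                    "trial": np.arange(1, ds.n_trials + 1),
                    "rt_ms": ds.rt_ms,
                    "correct": ds.correct,
                    "true_state": ds.true_state if ds.true_state is not None else -1,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_csv(path) -> list[ParticipantDataset]:
    """Read datasets written by :func:`write_csv` (true_state of -1 means unknown)."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"CSV is missing required columns: {sorted(missing)}")
    out = []
    for pid, grp in df.groupby("participant_id", sort=False):
        grp = grp.sort_values("trial")
        ts = None
        if "true_state" in grp.columns and (grp["true_state"] >= 1).all():
            ts = grp["true_state"].to_numpy()
        out.append(
            ParticipantDataset(
                participant_id=str(pid),
                rt_ms=grp["rt_ms"].to_numpy(),
                correct=grp["correct"].to_numpy(),
                true_state=ts,
            )
        )
    return out
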