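"""Ground-truth evaluation of fitted strategy mixtures.

Fitted state labels are arbitrary, so decoded states are first aligned to
the generative states by ascending mean RT — the fastest fitted state maps
to the fastest generative state, and so on.  Classification accuracy is the
proportion of trials whose aligned decoded state matches the true state.
Model-selection results are aggregated as the per-participant argmin of
BIC/AIC over candidate state counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import FitResult
from .simulate import ParticipantDataset, StateSpec

__all__ = [
    "AlignmentMap",
    "AccuracyReport",
    "SelectionReport",
    "align_states",
    "classification_accuracy",
    "pairwise_differences",
    "aggregate_selection",
]

logger = logging.getLogger(__name__)

# Fitted states whose mean RTs differ by less than this are ordered by
# accuracy instead, for deterministic alignment.
RT_TIE_MS = 1.0


@dataclass(frozen=True)
class AlignmentMap:
    """Bijection fitted-state label -> true-state label (both 1-based)."""

    mapping: dict[int, int]

    def apply(self, path: np.ndarray) -> np.ndarray:
        out = np.empty_like(path)
        for src, dst in self.mapping.items():
            out[path == src] = dst
        return out


def _order_by_rt(mean_rt: np.ndarray, accuracy: np.ndarray) -> np.ndarray:
    """Ascending-mean-RT order; near-ties (< RT_TIE_MS) fall back to accuracy."""
    order = np.argsort(mean_rt, kind="stable")
    for i in range(len(order) - 1):
        a, b = order[i], order[i + 1]
        if abs(mean_rt[a] - mean_rt[b]) < RT_TIE_MS and accuracy[a] > accuracy[b]:
            order[i], order[i + 1] = b, a
    return order


def align_states(
    fit: FitResult,
    data: ParticipantDataset,
    true_states: list[StateSpec] | None = None,
) -> AlignmentMap:
    """Map fitted states to true states, both sorted by ascending mean RT.

    Fitted states are characterized by the mean RT of their decoded trials
    (posterior-weighted mean when a decoded state is empty); true states by
    their generative mean RT when ``true_states`` is given, else by the
    observed mean RT of their trials.
    """
    if data.true_state is None:
        raise ValueError("alignment requires ground-truth state labels")
    S = fit.model.n_states
    n_true = len(true_states) if true_states is not None else int(data.true_state.max())
    if S != n_true:
        raise ValueError(
            f"fitted state count ({S}) differs from true state count ({n_true}); "
            "alignment is undefined — analyze via model selection instead"
        )
    dec = fit.decoded
    fit_rt = np.empty(S)
    fit_acc = np.empty(S)
    for s in range(1, S + 1):
        sel = dec == s
        if sel.any():
            fit_rt[s - 1] = data.rt_ms[sel].mean()
            fit_acc[s - 1] = data.correct[sel].mean()
        else:
            w = fit.state_posteriors[:, s - 1]
            tot = w.sum()
            fit_rt[s - 1] = (w * data.rt_ms).sum() / tot if tot > 0 else np.inf
            fit_acc[s - 1] = (w * data.correct).sum() / tot if tot > 0 else 0.0
    if true_states is not None:
        true_rt = np.array([st.expected_mean_rt_ms() for st in true_states])
        true_acc = np.array([st.expected_p_correct() for st in true_states])
    else:
        true_rt = np.array([data.rt_ms[data.true_state == s].mean() for s in range(1, S + 1)])
        true_acc = np.array([data.correct[data.true_state == s].mean() for s in range(1, S + 1)])
    fit_order = _order_by_rt(fit_rt, fit_acc)
    true_order = np.argsort(true_rt, kind="stable")
    # RT ordering governs; faster states are expected to be less accurate,
    # so flag fits where the two orderings disagree.
    if not np.array_equal(np.argsort(fit_acc, kind="stable"), fit_order):
        logger.debug("fitted accuracy ordering disagrees with RT ordering; using RT")
    mapping = {int(fit_order[i]) + 1: int(true_order[i]) + 1 for i in range(S)}
    return AlignmentMap(mapping=mapping)


def classification_accuracy(
    fit: FitResult, data: ParticipantDataset, alignment: AlignmentMap
) -> float:
    """Fraction of trials whose aligned decoded state equals the true state."""
    if data.true_state is None:
        raise ValueError("classification accuracy requires ground-truth labels")
    aligned = alignment.apply(fit.decoded)
    return float(np.mean(aligned == data.true_state))


@dataclass(frozen=True)
class AccuracyReport:
    """Per-participant accuracies by family plus pairwise difference summaries."""

    accuracies: pd.DataFrame  # index participant, one column per family
    summary: pd.DataFrame  # mean/sd per family
    differences: pd.DataFrame  # one row per ordered family pair


def pairwise_differences(acc_by_family: dict[str, np.ndarray]) -> AccuracyReport:
    """Summaries of per-participant accuracy and family-pair differences.

    Differences are minuend minus subtrahend per participant; the report
    carries their mean, SD, range, and the proportions of participants for
    whom the first family is better, worse, or tied.
    """
    lengths = {k: len(v) for k, v in acc_by_family.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"families cover different participant sets: {lengths}")
    acc = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in acc_by_family.items()})
    summary = pd.DataFrame({"mean": acc.mean(), "sd": acc.std(ddof=1)})
    rows = []
    fams = list(acc.columns)
    for i, fa in enumerate(fams):
        for fb in fams[i + 1 :]:
            d = acc[fa] - acc[fb]
            rows.append(
                {
                    "pair": f"{fa} - {fb}",
                    "mean": d.mean(),
                    "sd": d.std(ddof=1),
                    "min": d.min(),
                    "max": d.max(),
                    "prop_better": float((d > 0).mean()),
                    "prop_worse": float((d < 0).mean()),
                    "prop_equal": float((d == 0).mean()),
                }
            )
    return AccuracyReport(accuracies=acc, summary=summary, differences=pd.DataFrame(rows))


@dataclass(frozen=True)
class SelectionReport:
    """Best state count per participant and criterion, with aggregate counts."""

    best: pd.DataFrame  # index participant, columns bic/aic -> best S
    counts: pd.DataFrame  # index S, columns bic/aic -> n participants
    winning: dict[str, int]  # modal best S per criterion

    @property
    def n_participants(self) -> int:
        return len(self.best)


def aggregate_selection(
    fits: dict[str, dict[int, FitResult]], candidates: tuple[int, ...] = (1, 2, 3, 4)
) -> SelectionReport:
    """Per-participant argmin of BIC and AIC over candidate state counts.

    ``fits`` maps participant id -> {S: FitResult}.  Ties break toward the
    smaller state count.
    """
    records = {}
    for pid, by_s in fits.items():
        missing = [s for s in candidates if s not in by_s]
        if missing:
            raise ValueError(f"participant {pid} is missing fits for S={missing}")
        bics = np.array([by_s[s].bic for s in candidates])
        aics = np.array([by_s[s].aic for s in candidates])
        records[pid] = {
            "bic": candidates[int(np.argmin(bics))],
            "aic": candidates[int(np.argmin(aics))],
        }
    best = pd.DataFrame.from_dict(records, orient="index")
    counts = pd.DataFrame(
        {
            crit: [int((best[crit] == s).sum()) for s in candidates]
            for crit in ("bic", "aic")
        },
        index=list(candidates),
    )
    winning = {crit: int(best[crit].mode().min()) for crit in ("bic", "aic")}
    return SelectionReport(best=best, counts=counts, winning=winning)
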