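"""Equal-width discretization of response times.

The non-parametric and ordinal emission families operate on RT categories
rather than raw times: each participant's RTs are cut into K equal-width
bins spanning that participant's own [min, max] range, so binning is a
per-participant operation and participants stay independent.  Interior bins
with zero observations are kept as categories (they can still carry
probability mass in the fitted emission).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["BinnedRT", "bin_rts", "recommend_bins"]

logger = logging.getLogger(__name__)

# Recommended bins-to-trials ratio and the hard bounds on the bin count.
BIN_RATIO = 0.05
MIN_BINS = 5
MAX_BINS = 35

# Many empty bins usually mean extreme outliers are stretching the range.
EMPTY_BIN_WARN_FRACTION = 0.4


@dataclass(frozen=True)
class BinnedRT:
    """Bin assignment (1..K per trial) with the K+1 shared edges in ms."""

    bin_index: np.ndarray
    edges: np.ndarray
    K: int

    def counts(self) -> np.ndarray:
        """Occupancy of each bin, length K; sums to the number of trials."""
        return np.bincount(self.bin_index, minlength=self.K + 1)[1:]


def bin_rts(rt: np.ndarray, K: int) -> BinnedRT:
    """Cut an RT vector into K equal-width bins over its own range.

    Bins are half-open [lo, hi) except the last, which is closed so the
    maximum falls in bin K.
    """
    rt = np.asarray(rt, dtype=float)
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    lo, hi = float(np.min(rt)), float(np.max(rt))
    if lo == hi:
        raise ValueError("cannot bin a constant RT vector (degenerate range)")
    edges = np.linspace(lo, hi, K + 1)
    idx = np.floor((rt - lo) / (hi - lo) * K).astype(int) + 1
    idx = np.clip(idx, 1, K)
    binned = BinnedRT(bin_index=idx, edges=edges, K=K)
    empty = int(np.sum(binned.counts() == 0))
    if empty > EMPTY_BIN_WARN_FRACTION * K:
        logger.warning(
            "%d of %d bins are empty; extreme outliers may be stretching the RT range",
            empty,
            K,
        )
    return binned


def recommend_bins(n_trials: int) -> int:
    """Bin count from the trial count: round(0.05 * n), clamped to [5, 35]."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    k = round(BIN_RATIO * n_trials)
    return int(min(MAX_BINS, max(MIN_BINS, k)))
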