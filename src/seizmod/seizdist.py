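"""Seizure distance matrices: per-IMF distances, temporal distance, and
DTW-based seizure dissimilarity.

Per-IMF distances compare pairs of seizures in terms of one band-power
fluctuation: the IMF is reconstructed into the original band x channel
space, ``X'_i = W x IMF_i``, and the distance between seizures a and b is
the Euclidean norm of the difference of the X'_i columns at their onset
epochs.  Alongside the M IMF distance slices, the residue distance and the
temporal distance (|onset_a - onset_b| in seconds) are carried as extra
predictors.

Seizure dissimilarity compares the seizures' own multivariate evolutions
(time x feature trajectories, e.g. functional-network dynamics): pairs are
aligned with dynamic time warping (symmetric step pattern, boundary
anchored, no warping window, Euclidean local cost) and the dissimilarity
is the mean local cost along the optimal path, so a seizure and its
time-dilated copy are at distance zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .memd import IMFSet

logger = logging.getLogger(__name__)

__all__ = [
    "SeizureTable",
    "SeizureDistanceSet",
    "reconstruct_imf_space",
    "imf_seizure_distance",
    "temporal_distance",
    "distance_stack",
    "dtw_pair",
    "dtw_dissimilarity",
]


@dataclass
class SeizureTable:
    """Seizure onsets in seconds and the 30 s epochs containing them."""

    onsets_s: np.ndarray
    epoch_s: float
    T: int  # number of epochs in the recording

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if (np.diff(self.onsets_s) <= 0).any():
            raise ValueError("seizure onsets must be strictly increasing")
        self.onset_epochs = np.floor(self.onsets_s / self.epoch_s).astype(int)
        if (self.onset_epochs < 0).any() or (self.onset_epochs >= self.T).any():
            raise ValueError("seizure onset epochs fall outside the recording")
        if len(np.unique(self.onset_epochs)) < len(self.onset_epochs):
            warnings.warn(
                "two seizures share one 30 s epoch; their IMF distance will be zero"
            )

    @property
    def S(self) -> int:
        return len(self.onsets_s)


@dataclass
class SeizureDistanceSet:
    """Stack of (M + 2) S x S distance matrices: one per IMF, the residue
    distance, and the temporal distance, with labels per slice."""

    D: np.ndarray  # (M + 2, S, S)
    labels: list[str]


def reconstruct_imf_space(W: np.ndarray, imfset: IMFSet) -> tuple[list[np.ndarray], np.ndarray]:
    """Reconstruct each IMF (and the residue) in band x channel space.

    Returns ``([W @ IMF_i for i], W @ residue)``; their sum equals
    ``W @ H`` by linearity of the decomposition.
    """
    W = np.asarray(W, dtype=float)
    if W.shape[1] != imfset.k:
        raise ValueError(
            f"W has {W.shape[1]} components but the IMF set has {imfset.k} dimensions"
        )
    recons = [W @ imfset.imfs[i] for i in range(imfset.M)]
    return recons, W @ imfset.residue


def imf_seizure_distance(
    X_imf: np.ndarray, seizures: SeizureTable, lag: int = 0
) -> np.ndarray:
    """Pairwise Euclidean distance of X'_i columns at seizure onset epochs.

    ``lag`` shifts the sampled epoch back (lag=1 reproduces the pre-ictal
    variant that reads the epoch before onset).
    """
    epochs = seizures.onset_epochs - lag
    if (epochs < 0).any() or (epochs >= X_imf.shape[1]).any():
        raise ValueError("onset epoch minus lag falls outside the recording")
    cols = X_imf[:, epochs].T  # (S, n)
    return squareform(pdist(cols))


def temporal_distance(seizures: SeizureTable) -> np.ndarray:
    """|onset_a - onset_b| in seconds."""
    if seizures.S < 2:
        raise ValueError("need at least 2 seizures")
    o = seizures.onsets_s
    return np.abs(o[:, None] - o[None, :])


def distance_stack(
    W: np.ndarray, imfset: IMFSet, seizures: SeizureTable, lag: int = 0
) -> SeizureDistanceSet:
    """All (M + 2) predictor distance matrices for the regression stage."""
    recons, resid = reconstruct_imf_space(W, imfset)
    slices = [imf_seizure_distance(Xi, seizures, lag) for Xi in recons]
    slices.append(imf_seizure_distance(resid, seizures, lag))
    slices.append(temporal_distance(seizures))
    labels = [f"IMF{i + 1}" for i in range(imfset.M)] + ["residue", "temporal"]
    return SeizureDistanceSet(D=np.stack(slices), labels=labels)


def dtw_pair(a: np.ndarray, b: np.ndarray) -> float:
    """DTW dissimilarity of two (time, feature) trajectories.

    Dynamic programming over the Euclidean local-cost matrix with
    symmetric steps (diagonal/horizontal/vertical), boundary anchored and
    unconstrained; returns the mean local cost along the optimal path
    (backtracked with diagonal-preferred tie-breaks).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"feature dimensions differ: {a.shape[1]} vs {b.shape[1]}")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each evolution needs at least 2 time steps")
    cost = cdist(a, b)
    n, m = cost.shape
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(n):
        row = acc[i]
        prev = acc[i - 1] if i else None
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i and j:
                best = prev[j - 1]
            if i and prev[j] < best:
                best = prev[j]
            if j and row[j - 1] < best:
                best = row[j - 1]
            row[j] = cost[i, j] + best
    # backtrack, preferring diagonal, then horizontal, then vertical
    i, j = n - 1, m - 1
    length = 1
    while i or j:
        if i and j:
            options = (acc[i - 1, j - 1], acc[i, j - 1], acc[i - 1, j])
            choice = int(np.argmin(options))
            if choice == 0:
                i, j = i - 1, j - 1
            elif choice == 1:
                j -= 1
            else:
                i -= 1
        elif i:
            i -= 1
        else:
            j -= 1
        length += 1
    return float(acc[n - 1, m - 1] / length)


def dtw_dissimilarity(evolutions: list[np.ndarray]) -> np.ndarray:
    """Pairwise DTW dissimilarity matrix of seizure evolutions
    (symmetric, zero diagonal, nonnegative)."""
    S = len(evolutions)
    out = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            out[i, j] = out[j, i] = dtw_pair(evolutions[i], evolutions[j])
    return out
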