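"""Band and channel contributions to each IMF, and channel heterogeneity.

How much a frequency band or a recording channel contributes to an IMF is
inferred by combining two pieces: the NMF basis vectors W (which map each
component to weights over all band/channel rows) and the realised relative
power R of each IMF dimension.  The mean power of dimension j in IMF i is
``E_ij = mean_t a_ij(t)^2`` (squared instantaneous Hilbert amplitude) and
``R_ij = E_ij / sum_j E_ij``.  Weighting the per-band sums of W's columns
by R and normalising gives the percent contribution of each band to the
IMF; weighting full W columns gives the channel-and-band contribution
vector ``C_i = sum_j R_ij W_j``, whose within-band distribution over
channels is summarised by the Gini sparsity index

    G(x) = 1 - 2 * sum_i (x_i / ||x||_1) * (N - i + 1/2) / N   (x ascending)

G = 0 for a perfectly even distribution and 1 - 1/N for a one-hot vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bands import BAND_NAMES
from .hht import AnalyticTrace
from .memd import IMFSet

logger = logging.getLogger(__name__)

__all__ = [
    "ContributionTable",
    "HeterogeneityTable",
    "imf_power",
    "band_contribution",
    "gini",
    "channel_heterogeneity",
]


@dataclass
class ContributionTable:
    """Per-IMF power decomposition: E (M, k), R (M, k) rows summing to 1,
    band_contrib (M, n_bands) rows summing to 100 (%), and the
    channel-and-band contribution vectors C (M, n)."""

    E: np.ndarray
    R: np.ndarray
    band_contrib: np.ndarray
    C: np.ndarray
    band_names: list[str]


@dataclass
class HeterogeneityTable:
    """Gini index per (IMF, band); higher = more channel-concentrated."""

    gini: np.ndarray  # (M, n_bands), nan where a band slice has no mass
    band_names: list[str]
    peak_cycle_length_days: np.ndarray | None = None


def imf_power(
    imfset: IMFSet,
    traces: list[list[AnalyticTrace]],
    include_residue: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean Hilbert power E_ij of each IMF dimension and relative power R.

    The mean runs over each trace's valid samples (edge-masked), mirroring
    the masking of the spectral stage.  With ``include_residue`` an extra
    final row holds the residue's raw mean square power (the residue is
    not oscillatory, so no Hilbert amplitude is computed for it).
    """
    M, k = imfset.M, imfset.k
    rows = M + 1 if include_residue else M
    E = np.empty((rows, k))
    for i in range(M):
        for j in range(k):
            tr = traces[i][j]
            sel = tr.valid_mask if tr.valid_mask.any() else slice(None)
            E[i, j] = np.mean(tr.amplitude[sel] ** 2)
    if include_residue:
        E[M] = np.mean(imfset.residue**2, axis=1)
    totals = E.sum(axis=1)
    zero = totals <= 0
    if zero[:M].any():
        bad = int(np.flatnonzero(zero[:M])[0])
        raise ValueError(f"IMF {bad} has zero power in every dimension")
    if include_residue and zero[M]:
        logger.warning("residue is identically zero; its relative power row is 0")
        totals[M] = 1.0  # leaves R[M] = 0
    R = E / totals[:, None]
    return E, R


def band_contribution(
    W: np.ndarray,
    R: np.ndarray,
    row_index: list[tuple[str, str]],
    band_names: list[str] | None = None,
) -> np.ndarray:
    """Percent contribution of each frequency band to each IMF.

    W's rows are summed within each band per component (a (n_bands, k)
    matrix), weighted by the IMF's relative powers R_i and normalised to
    percentages.  Rows sum to 100.
    """
    W = np.asarray(W, dtype=float)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if band_names is None:
        band_names = [b for b in BAND_NAMES if any(bi == b for bi, _ in row_index)]
    if len(row_index) != W.shape[0]:
        raise ValueError("row_index must have one entry per W row")
    band_sums = np.zeros((len(band_names), W.shape[1]))
    for b, name in enumerate(band_names):
        rows = [i for i, (bi, _) in enumerate(row_index) if bi == name]
        if not rows:
            raise ValueError(f"band {name!r} missing from row_index")
        band_sums[b] = W[rows].sum(axis=0)
    raw = R @ band_sums.T  # (M, n_bands)
    totals = raw.sum(axis=1, keepdims=True)
    zero_rows = totals[:, 0] <= 0
    if zero_rows.any():
        if (R[zero_rows] > 0).any():
            raise ValueError("an IMF with nonzero power received zero band contribution")
        logger.warning("rows with zero relative power get NaN band contributions")
        totals[zero_rows] = np.nan
    return 100.0 * raw / totals


def gini(x: np.ndarray) -> float:
    """Gini sparsity index of a nonnegative vector, in [0, 1).

    0 for a constant vector, 1 - 1/N for a one-hot vector of length N.
    Sorting is internal, so the measure is permutation-invariant, and it
    is scale-invariant by construction.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty vector")
    if (x < 0).any():
        raise ValueError("entries must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero vector has no Gini index")
    xs = np.sort(x)  # ascending, stable for ties
    N = xs.size
    ranks = np.arange(1, N + 1)
    return float(1.0 - 2.0 * np.sum(xs / total * (N - ranks + 0.5) / N))


def channel_heterogeneity(
    W: np.ndarray,
    R: np.ndarray,
    row_index: list[tuple[str, str]],
    band_names: list[str] | None = None,
    peak_cycle_length_days: np.ndarray | None = None,
) -> HeterogeneityTable:
    """Gini index of each IMF's contribution across channels, per band.

    ``C_i = sum_j R_ij W_j`` is split by band and the Gini index taken
    over the channel entries of each band slice.  A band slice with no
    mass yields NaN (with a warning) rather than aborting the table.
    """
    W = np.asarray(W, dtype=float)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if band_names is None:
        band_names = [b for b in BAND_NAMES if any(bi == b for bi, _ in row_index)]
    C = R @ W.T  # (M, n)
    out = np.full((R.shape[0], len(band_names)), np.nan)
    for b, name in enumerate(band_names):
        rows = [i for i, (bi, _) in enumerate(row_index) if bi == name]
        if not rows:
            raise ValueError(f"band {name!r} missing from row_index")
        for i in range(R.shape[0]):
            slice_i = C[i, rows]
            if slice_i.sum() <= 0:
                logger.warning("IMF %d has zero mass in band %s; Gini set to NaN", i, name)
                continue
            out[i, b] = gini(slice_i)
    return HeterogeneityTable(
        gini=out, band_names=list(band_names), peak_cycle_length_days=peak_cycle_length_days
    )


def contribution_table(
    W: np.ndarray,
    imfset: IMFSet,
    traces: list[list[AnalyticTrace]],
    row_index: list[tuple[str, str]],
    include_residue: bool = True,
) -> ContributionTable:
    """Convenience wrapper building E, R, band contributions and C in one go.

    The residue is carried as an extra final row so summaries can show it
    separately from the oscillatory modes.
    """
    E, R = imf_power(imfset, traces, include_residue=include_residue)
    band_names = [b for b in BAND_NAMES if any(bi == b for bi, _ in row_index)]
    bc = band_contribution(W, R, row_index, band_names)
    C = R @ W.T
    return ContributionTable(E=E, R=R, band_contrib=bc, C=C, band_names=band_names)
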