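"""Hilbert spectral analysis of IMFs (the Hilbert-Huang transform).

Each IMF dimension is turned into an analytic signal ``v(t) = u(t) +
i*H[u](t) = a(t) exp(i theta(t))`` via the frequency-domain Hilbert
transform; the instantaneous amplitude ``a(t)``, unwrapped phase
``theta(t)`` and instantaneous frequency ``f(t) = dtheta/dt`` (reported in
cycles/day) follow directly.  The Hilbert energy spectrum places the
energy ``a(t)^2`` at frequency ``f(t)``; integrating it over the recording
gives the marginal spectrum ``h(f)``.  For a multivariate IMF the energy
is averaged across the k dimensions before integration.

The frequency axis is log-spaced (48 bins per decade by default, anchored
so that 1 cycle/day is a bin centre) spanning from two cycles per record
up to the Nyquist frequency of the epoch series.  Instantaneous
frequencies at the signal edges (first/last 4% of samples) and
non-positive frequencies from phase-unwrapping glitches are masked rather
than clamped, so energy bookkeeping stays exact on the valid set.

The per-IMF peak fluctuation frequency is the geometric centre of the
highest-energy bin; an IMF peaking within the circadian tolerance band
(peak period in [0.8, 1.25] days) is the circadian IMF, with the larger
total marginal power breaking ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal as sg

from .memd import IMFSet

logger = logging.getLogger(__name__)

__all__ = [
    "AnalyticTrace",
    "MarginalSpectrum",
    "analytic_signal",
    "analytic_traces",
    "marginal_spectrum",
    "peak_frequency",
    "find_circadian_imf",
]

SECONDS_PER_DAY = 86400.0
EDGE_FRACTION = 0.04


@dataclass
class AnalyticTrace:
    """Instantaneous amplitude/phase/frequency of one univariate series."""

    amplitude: np.ndarray  # a(t) >= 0
    phase: np.ndarray  # unwrapped, radians
    inst_freq: np.ndarray  # cycles/day
    valid_mask: np.ndarray  # edges excluded


def analytic_signal(x: np.ndarray, epoch_s: float = 30.0) -> AnalyticTrace:
    """Analytic signal of a real series sampled every ``epoch_s`` seconds.

    The instantaneous frequency is the central difference of the unwrapped
    phase converted to cycles/day; the first and last 4% of samples are
    masked as invalid, which measurably bounds the boundary ripple of the
    frequency-domain transform and of the phase derivative.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("analytic_signal expects a 1-D series")
    T = x.size
    if T < 16:
        raise ValueError(f"series too short (T={T} < 16)")
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite values")

    v = sg.hilbert(x)
    amplitude = np.abs(v)
    phase = np.unwrap(np.angle(v))
    samples_per_day = SECONDS_PER_DAY / epoch_s
    inst_freq = np.gradient(phase) / (2 * np.pi) * samples_per_day

    edge = max(1, int(np.ceil(EDGE_FRACTION * T)))
    valid = np.zeros(T, dtype=bool)
    valid[edge:-edge] = True
    valid &= amplitude > 0  # phase (hence frequency) undefined where a == 0
    return AnalyticTrace(amplitude=amplitude, phase=phase, inst_freq=inst_freq, valid_mask=valid)


def analytic_traces(imfset: IMFSet) -> list[list[AnalyticTrace]]:
    """Analytic traces for every (IMF, dimension) pair of an IMFSet."""
    return [
        [analytic_signal(imfset.imfs[i, j], imfset.epoch_s) for j in range(imfset.k)]
        for i in range(imfset.M)
    ]


@dataclass
class MarginalSpectrum:
    """Marginal Hilbert-Huang energy spectrum on a log frequency axis.

    ``density[i, b]`` is the energy of IMF i accumulated in frequency bin
    b; ``total`` sums across IMFs (the across-IMF marginal spectrum).
    Frequencies are in cycles/day; ``freq_centers`` are geometric bin
    centres.  ``imf_power[i]`` is the total binned energy of IMF i.
    """

    freq_edges: np.ndarray
    freq_centers: np.ndarray
    density: np.ndarray  # (M, n_bins)
    T: int

    @property
    def total(self) -> np.ndarray:
        return self.density.sum(axis=0)

    @property
    def imf_power(self) -> np.ndarray:
        return self.density.sum(axis=1)


def _log_bins(f_lo: float, f_hi: float, bins_per_decade: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced bin edges anchored so that 1 cycle/day is a bin centre."""
    step = 1.0 / bins_per_decade
    j_lo = int(np.floor((np.log10(f_lo) + step / 2) / step)) - 1
    j_hi = int(np.ceil((np.log10(f_hi) + step / 2) / step)) + 1
    edges = 10.0 ** ((np.arange(j_lo, j_hi + 1) - 0.5) * step)
    centers = 10.0 ** (np.arange(j_lo, j_hi) * step)
    return edges, centers


def marginal_spectrum(
    imfset: IMFSet,
    n_bins_per_decade: int = 48,
    traces: list[list[AnalyticTrace]] | None = None,
) -> MarginalSpectrum:
    """Marginal Hilbert-Huang spectrum of every IMF in the set.

    Per IMF, each dimension's squared instantaneous amplitude (divided by
    k, i.e. the across-dimension average) is accumulated into the log
    frequency bin containing that sample's instantaneous frequency.
    Binning partitions the valid samples, so the bin sum equals the total
    valid energy exactly.
    """
    if traces is None:
        traces = analytic_traces(imfset)
    T, k = imfset.T, imfset.k
    f_lo = 2.0 * SECONDS_PER_DAY / (T * imfset.epoch_s)  # two cycles per record
    f_hi = 0.5 * SECONDS_PER_DAY / imfset.epoch_s  # Nyquist of the epoch series
    edges, centers = _log_bins(f_lo, f_hi, n_bins_per_decade)
    density = np.zeros((imfset.M, centers.size))
    for i in range(imfset.M):
        for j in range(k):
            tr = traces[i][j]
            ok = tr.valid_mask & (tr.inst_freq > 0)
            if not ok.any():
                continue
            f = np.clip(tr.inst_freq[ok], edges[0] * (1 + 1e-12), edges[-1] * (1 - 1e-12))
            idx = np.searchsorted(edges, f, side="right") - 1
            np.add.at(density[i], idx, tr.amplitude[ok] ** 2 / k)
    return MarginalSpectrum(freq_edges=edges, freq_centers=centers, density=density, T=T)


def peak_frequency(spectrum: MarginalSpectrum, imf_index: int) -> float:
    """Peak fluctuation frequency (cycles/day) of one IMF: the geometric
    centre of its highest-energy bin, ties broken toward lower frequency."""
    row = spectrum.density[imf_index]
    if not (row > 0).any():
        raise ValueError(f"IMF {imf_index} has an all-zero marginal spectrum")
    best = int(np.argmax(row))  # argmax returns the first (lowest-frequency) tie
    ties = np.flatnonzero(row == row[best])
    if len(ties) > 1:
        logger.warning(
            "IMF %d: %d tied peak bins; reporting the lowest frequency", imf_index, len(ties)
        )
    return float(spectrum.freq_centers[best])


def find_circadian_imf(
    spectrum: MarginalSpectrum,
    period_band_days: tuple[float, float] = (0.8, 1.25),
) -> int | None:
    """Index of the circadian IMF, or None when no IMF peaks in-band.

    Candidates are IMFs whose peak fluctuation period lies within
    ``period_band_days``; with several candidates the one with the larger
    total marginal power wins.
    """
    lo_p, hi_p = period_band_days
    candidates = []
    for i in range(spectrum.density.shape[0]):
        if not (spectrum.density[i] > 0).any():
            continue
        f = peak_frequency(spectrum, i)
        if lo_p <= 1.0 / f <= hi_p:
            candidates.append((spectrum.imf_power[i], i))
    if not candidates:
        logger.info(
            "no IMF peaks within the circadian band (period %.3g-%.3g days)", lo_p, hi_p
        )
        return None
    if len(candidates) > 1:
        logger.info("%d IMFs peak in the circadian band; picking the most powerful", len(candidates))
    return max(candidates)[1]
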