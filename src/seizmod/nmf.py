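"""Nonnegative matrix factorization of the band-power matrix X.

X (n x T, entries in [0, 1]) is approximated as W x H with W (n x k) the
basis vectors (spectral/spatial patterns) and H (k x T) their expression
coefficient time series.  Initialization uses nonnegative SVD with
low-rank correction (NNSVD-LRC): nonnegative parts of the truncated
singular triplets seed the factors, followed by a few cheap refinement
passes against the rank-p approximation of X.  The factors are then
refined with standard Frobenius multiplicative updates, whose objective is
non-increasing.

Model-order selection scans k and keeps, among all k whose relative
reconstruction error ``sum |X - WH| / (n T)`` is below 5%, the one with
the smallest redundancy ``c = max(max |Corr[W]|, max |Corr[H]|)`` -- the
strongest correlation or anticorrelation between any two components.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Factorization",
    "nnsvd_lrc_init",
    "factorize",
    "relative_error",
    "redundancy",
    "select_k",
    "write_factorization",
    "read_factorization",
]

_EPS = 1e-12


@dataclass
class Factorization:
    """NMF result: nonnegative factors, rank, error and redundancy."""

    W: np.ndarray
    H: np.ndarray
    k: int
    rel_error: float
    c: float
    converged: bool = True
    objective_trace: np.ndarray | None = None
    error_below_threshold: bool = True
    selection_table: list | None = None

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.H


def relative_error(X: np.ndarray, Xp: np.ndarray) -> float:
    """Mean absolute elementwise deviation ``sum |X - X'| / (n T)``."""
    X = np.asarray(X)
    Xp = np.asarray(Xp)
    if X.shape != Xp.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Xp.shape}")
    return float(np.abs(X - Xp).mean())


def redundancy(W: np.ndarray, H: np.ndarray) -> float:
    """Maximum absolute Pearson correlation over all column pairs of W and
    all row pairs of H.  Defined as 0 for k = 1 (no pairs)."""
    k = W.shape[1]
    if k != H.shape[0]:
        raise ValueError("W columns must match H rows")
    if k == 1:
        logger.info("redundancy undefined for k=1; returning 0")
        return 0.0

    def _max_abs_corr(mat: np.ndarray) -> float:
        # rows of `mat` are the variables
        sd = mat.std(axis=1)
        ok = sd > 1e-15
        if ok.sum() < 2:
            return 0.0
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(mat[ok])
        np.fill_diagonal(corr, 0.0)
        return float(np.nanmax(np.abs(corr)))

    return max(_max_abs_corr(W.T), _max_abs_corr(H))


def _mu_iterations(
    X: np.ndarray, W: np.ndarray, H: np.ndarray, n_iter: int, tol: float | None = None
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """Frobenius multiplicative updates with a zero-locking guard."""
    trace: list[float] = []
    prev = None
    converged = False
    for _ in range(n_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = float(np.linalg.norm(X - W @ H, "fro"))
        trace.append(obj)
        if tol is not None and prev is not None:
            if abs(prev - obj) <= tol * max(prev, _EPS):
                converged = True
                break
        prev = obj
    return W, H, trace, converged


def _hals_iterations(
    X: np.ndarray, W: np.ndarray, H: np.ndarray, n_iter: int, tol: float | None = None
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """Hierarchical ALS refinement of the Frobenius objective.

    Each component's row of H (column of W) is minimised exactly in turn
    under nonnegativity, so the objective is non-increasing; unlike plain
    multiplicative updates the iteration converges linearly and reaches
    exact reconstructions on exactly low-rank inputs.
    """
    k = W.shape[1]
    floor = 1e-15 * max(X.max(), 1.0)
    trace: list[float] = []
    prev = None
    converged = False
    for _ in range(n_iter):
        WtX = W.T @ X
        WtW = W.T @ W
        for j in range(k):
            denom = max(WtW[j, j], _EPS)
            H[j] = np.maximum(H[j] + (WtX[j] - WtW[j] @ H) / denom, floor)
        XHt = X @ H.T
        HHt = H @ H.T
        for j in range(k):
            denom = max(HHt[j, j], _EPS)
            W[:, j] = np.maximum(W[:, j] + (XHt[:, j] - W @ HHt[:, j]) / denom, floor)
        obj = float(np.linalg.norm(X - W @ H, "fro"))
        trace.append(obj)
        if tol is not None and prev is not None:
            if abs(prev - obj) <= tol * max(prev, _EPS):
                converged = True
                break
        prev = obj
    return W, H, trace, converged


def nnsvd_lrc_init(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative SVD with low-rank correction initialization.

    Builds candidate rank-1 nonnegative terms from the dominant-sign parts
    of the first ``ceil(k/2) + 1`` singular triplets, keeps the k largest,
    then refines them with a few multiplicative passes against the rank-p
    approximation of X (clipped at zero).  Deterministic.
    """
    X = np.asarray(X, dtype=float)
    n, T = X.shape
    if not 1 <= k <= min(n, T):
        raise ValueError(f"k={k} must lie in [1, min(n, T)={min(n, T)}]")
    if X.min() < 0:
        raise ValueError("X must be nonnegative")

    p = min(int(np.ceil(k / 2)) + 1, min(n, T))
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, s, Vt = U[:, :p], s[:p], Vt[:p]

    # leading triplet is nonnegative up to a global sign (Perron-Frobenius)
    if U[:, 0].sum() < 0:
        U[:, 0] = -U[:, 0]
        Vt[0] = -Vt[0]
    candidates: list[tuple[float, np.ndarray, np.ndarray]] = []
    u0, v0 = np.maximum(U[:, 0], 0), np.maximum(Vt[0], 0)
    candidates.append((s[0] * np.linalg.norm(u0) * np.linalg.norm(v0), u0, v0))
    for j in range(1, p):
        u, v = U[:, j], Vt[j]
        for uu, vv in ((np.maximum(u, 0), np.maximum(v, 0)), (np.maximum(-u, 0), np.maximum(-v, 0))):
            weight = s[j] * np.linalg.norm(uu) * np.linalg.norm(vv)
            candidates.append((float(weight), uu, vv))
    # stable sort by decreasing weight; take the k strongest terms
    order = sorted(range(len(candidates)), key=lambda i: -candidates[i][0])[:k]
    W0 = np.empty((n, k))
    H0 = np.empty((k, T))
    for col, idx in enumerate(order):
        weight, u, v = candidates[idx]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if weight <= 0 or nu == 0 or nv == 0:
            # rank-deficient input: seed with the scaled mean profile
            W0[:, col] = X.mean(axis=1) + _EPS
            H0[col] = X.mean(axis=0) + _EPS
            continue
        scale = np.sqrt(weight)
        W0[:, col] = scale * u / nu
        H0[col] = scale * v / nv

    # low-rank correction: cheap refinement against the rank-p approximation
    Xp = np.maximum((U * s) @ Vt, 0.0)
    W0, H0, _, _ = _mu_iterations(Xp, W0, H0, n_iter=15)
    return W0, H0


def factorize(
    X: np.ndarray,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> Factorization:
    """NMF via NNSVD-LRC initialization + Frobenius multiplicative updates.

    Iterates until the relative change of the objective falls below
    ``tol`` or ``max_iter`` is reached (non-convergence is logged, not an
    error).
    """
    X = np.asarray(X, dtype=float)
    W, H = nnsvd_lrc_init(X, k)
    # un-lock exact zeros so every component can be revived by the updates
    W = np.maximum(W, 1e-9 * max(W.max(), 1.0))
    H = np.maximum(H, 1e-9 * max(H.max(), 1.0))
    W, H, trace, converged = _hals_iterations(X, W, H, n_iter=max_iter, tol=tol)
    if not converged:
        logger.warning("NMF (k=%d) did not converge within %d iterations", k, max_iter)
    rel = relative_error(X, W @ H)
    c = redundancy(W, H) if k >= 2 else 0.0
    return Factorization(
        W=W, H=H, k=k, rel_error=rel, c=c, converged=converged,
        objective_trace=np.asarray(trace),
    )


def select_k(
    X: np.ndarray,
    k_min: int = 3,
    k_max: int = 15,
    error_threshold: float = 0.05,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> Factorization:
    """Scan k in [k_min, k_max]; among factorizations with relative error
    below ``error_threshold`` return the one with smallest redundancy c
    (ties within 1e-12 go to the smallest k).  If no k reaches the error
    threshold, the smallest-error factorization is returned flagged."""
    X = np.asarray(X, dtype=float)
    k_max = min(k_max, min(X.shape))
    if k_min > k_max:
        raise ValueError("k_min exceeds the largest admissible k")
    results: list[Factorization] = []
    for k in range(k_min, k_max + 1):
        results.append(factorize(X, k, max_iter=max_iter, tol=tol))
    table = [(f.k, f.rel_error, f.c) for f in results]
    admissible = [f for f in results if f.rel_error < error_threshold]
    if admissible:
        # tie-break: smallest k within 1e-12 of the minimal c
        c_min = min(f.c for f in admissible)
        best = next(f for f in sorted(admissible, key=lambda f: f.k) if f.c <= c_min + 1e-12)
        best.error_below_threshold = True
    else:
        best = min(results, key=lambda f: f.rel_error)
        best.error_below_threshold = False
        logger.warning(
            "no k in [%d, %d] reached relative error < %.3g (best %.3g at k=%d); "
            "returning the smallest-error factorization",
            k_min, k_max, error_threshold, best.rel_error, best.k,
        )
    best.selection_table = table
    return best


def write_factorization(f: Factorization, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("W", data=f.W)
        h5.create_dataset("H", data=f.H)
        h5.attrs["k"] = f.k
        h5.attrs["rel_error"] = f.rel_error
        h5.attrs["c"] = f.c
        h5.attrs["error_below_threshold"] = f.error_below_threshold
        if f.selection_table is not None:
            h5.attrs["selection_table"] = json.dumps(f.selection_table)


def read_factorization(path: str | Path) -> Factorization:
    with h5py.File(path, "r") as h5:
        return Factorization(
            W=h5["W"][()],
            H=h5["H"][()],
            k=int(h5.attrs["k"]),
            rel_error=float(h5.attrs["rel_error"]),
            c=float(h5.attrs["c"]),
            error_below_threshold=bool(h5.attrs["error_below_threshold"]),
            selection_table=json.loads(h5.attrs["selection_table"])
            if "selection_table" in h5.attrs
            else None,
        )
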