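"""Shared fixtures.

The expensive end-to-end states (five desk-scale synthetic subjects run
through band power -> NMF -> MEMD -> Hilbert spectra) are session-scoped
and built lazily, so unit-test-only runs never pay for them.
"""

from __future__ import annotations

import numpy as np
import pytest

import seizmod
from seizmod.pipeline import RunConfig, analyze_recording

#: configuration of the desk-scale fixture subject used across tests
FIXTURE_CONFIG = dict(k_max=8, n_permutations=200)
FIXTURE_SEEDS = (0, 1, 2, 3, 4)


def _build_state(seed: int):
    rec = seizmod.generate_subject(seed=seed)
    cfg = RunConfig(seed=seed, **FIXTURE_CONFIG)
    res = analyze_recording(rec, cfg, run_permutations=False)
    # keep the light parts; the raw waveforms are large and no longer needed
    res_truth = rec.truth
    del rec
    return res, res_truth


@pytest.fixture(scope="session")
def fixture_states():
    """Five end-to-end pipeline states for seeds 0..4 (no permutations)."""
    return [_build_state(seed) for seed in FIXTURE_SEEDS]


@pytest.fixture(scope="session")
def state0(fixture_states):
    """The first fixture subject's pipeline state and generator truth."""
    return fixture_states[0]


@pytest.fixture(scope="session")
def null_permutation_pvalues(state0):
    """Random-times permutation p-values under the global null.

    One hundred replicates: the response is drawn independently of every
    modulator (iid normal over seizure pairs) and the observed onsets are
    redrawn uniformly, so observed and permuted statistics are
    exchangeable.  200 permutations per replicate.

    Returns ``(plain, randomized)``: the plain strictly-larger-fraction
    p-values, and tie-randomized p-values ``(b + U (e + 1)) / (n + 1)``.
    The adjusted R^2 of a CV LASSO under the null has a large atom at 0
    (empty selections), so only the tie-randomized version can be exactly
    uniform.
    """
    from seizmod import regress

    res, _ = state0
    preds = regress.DistancePredictors.from_factorization(
        res.factorization.W, res.imfset
    )
    S = res.seizures.S
    rng = np.random.default_rng(20240)
    plain, randomized = [], []
    for _ in range(100):
        epochs = rng.integers(0, preds.T, size=S)
        onsets_s = (epochs + 0.5) * preds.epoch_s
        Zraw = preds.predictor_matrix(epochs, onsets_s)
        labels = preds.labels
        y = rng.standard_normal(S * (S - 1) // 2)
        y = (y - y.mean()) / y.std()
        cols = []
        kept = []
        for j in range(Zraw.shape[1]):
            sd = Zraw[:, j].std()
            if sd < 1e-12:
                continue
            cols.append((Zraw[:, j] - Zraw[:, j].mean()) / sd)
            kept.append(labels[j])
        ds = regress.RegressionDataset(
            y=y, Z=np.column_stack(cols), predictor_labels=kept, S=S
        )
        pr = regress.permutation_test_random_times(
            ds, preds, n_iter=200, seed=int(rng.integers(2**31))
        )
        plain.append(pr.p_value)
        null = pr.null_adjusted_R2
        obs = pr.observed_adjusted_R2
        b = int((null > obs + 1e-12).sum())
        e = int((np.abs(null - obs) <= 1e-12).sum())
        randomized.append((b + rng.random() * (e + 1)) / (null.size + 1))
    return np.asarray(plain), np.asarray(randomized)
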