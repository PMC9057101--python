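"""Synthetic-data generator: determinism, planted rhythms, seizures, I/O."""

import json

import numpy as np
import pytest
import scipy.signal as sg

import seizmod
from seizmod.synthdata import (
    ModulatorSpec,
    generate_band_power,
    generate_recording,
    generate_seizures,
    load_recording,
    modulator_states,
    write_recording,
)

FS = 180.0  # keeps the gamma band below Nyquist while staying cheap


def _delta_loading(n_channels):
    loading = np.zeros((5, n_channels))
    loading[0] = 1.0
    return loading


def test_same_seed_is_bit_identical():
    mods = [ModulatorSpec(0.5, 1.0, 0.3, _delta_loading(2))]
    a = generate_recording(2, FS, 0.5, mods, seed=11)
    b = generate_recording(2, FS, 0.5, mods, seed=11)
    assert np.array_equal(a.signals, b.signals)
    c = generate_recording(2, FS, 0.5, mods, seed=12)
    assert not np.array_equal(a.signals, c.signals)


def test_planted_circadian_modulator_appears_in_delta_envelope():
    """The realised delta log-envelope (30 s RMS of the band-passed signal)
    must track the planted one-day sinusoid with r >= 0.9."""
    mods = [ModulatorSpec(1.0, 1.0, 0.9, _delta_loading(2))]
    rec = generate_recording(2, FS, 1.0, mods, noise_sd=0.05, seed=3)
    sos = sg.butter(4, [1, 4], btype="bandpass", fs=FS, output="sos")
    delta = sg.sosfilt(sos, rec.signals[0].astype(float))
    spe = int(30 * FS)
    n_ep = len(delta) // spe
    rms = np.sqrt((delta[: n_ep * spe].reshape(n_ep, spe) ** 2).mean(axis=1))
    centers = (np.arange(n_ep) + 0.5) * 30.0
    planted = np.sin(2 * np.pi * centers / 86400.0 + 0.9)
    r = np.corrcoef(np.log(rms), planted)[0, 1]
    assert r >= 0.9


def test_zero_amplitude_leaves_no_daily_rhythm():
    mods = [ModulatorSpec(1.0, 0.0, 0.0, _delta_loading(2))]
    rec = generate_recording(2, FS, 1.0, mods, noise_sd=0.05, seed=4)
    sos = sg.butter(4, [1, 4], btype="bandpass", fs=FS, output="sos")
    delta = sg.sosfilt(sos, rec.signals[0].astype(float))
    spe = int(30 * FS)
    n_ep = len(delta) // spe
    env = np.log(np.sqrt((delta[: n_ep * spe].reshape(n_ep, spe) ** 2).mean(axis=1)))
    centers = (np.arange(n_ep) + 0.5) * 30.0
    design = np.column_stack(
        [np.ones(n_ep), np.sin(2 * np.pi * centers / 86400), np.cos(2 * np.pi * centers / 86400)]
    )
    beta, *_ = np.linalg.lstsq(design, env, rcond=None)
    fitted = design @ beta
    r2 = 1 - ((env - fitted) ** 2).sum() / ((env - env.mean()) ** 2).sum()
    assert r2 < 0.05


def test_band_power_fast_path_periodogram_peak():
    """Planted-rhythm recoverability: the 30 s band-power series of a loaded
    band peaks within one frequency bin of 1/period."""
    loading = np.zeros((5, 3))
    loading[3] = 1.0  # beta
    mods = [ModulatorSpec(0.25, 1.0, 0.0, loading)]
    power = generate_band_power(3, 2.0, mods, noise_sd=0.1, seed=5)
    series = np.log(power[3, 0])
    freqs, pxx = sg.periodogram(series - series.mean(), fs=2880.0)  # cycles/day
    peak = freqs[np.argmax(pxx)]
    df = freqs[1] - freqs[0]
    assert abs(peak - 4.0) <= df + 1e-9


def test_period_jitter_is_deterministic_and_perturbs_states():
    """With the jitter flag the realised modulator frequency wanders, so
    the latent states deviate from the pure sinusoid but stay reproducible."""
    mods = [ModulatorSpec(0.25, 1.0, 0.0, _delta_loading(2))]
    a = generate_recording(2, FS, 0.5, mods, seed=6, period_jitter=True)
    b = generate_recording(2, FS, 0.5, mods, seed=6, period_jitter=True)
    assert np.array_equal(a.signals, b.signals)
    assert a.truth["period_jitter"]
    pure = generate_recording(2, FS, 0.5, mods, seed=6, period_jitter=False)
    sa = np.asarray(a.truth["epoch_center_states"])
    sp = np.asarray(pure.truth["epoch_center_states"])
    assert sa.shape == sp.shape
    assert not np.allclose(sa, sp)
    assert np.abs(sa).max() <= 1.0 + 1e-9  # amplitude bound respected


def test_band_above_nyquist_names_band():
    mods = [ModulatorSpec(1.0, 1.0, 0.0, _delta_loading(2))]
    with pytest.raises(ValueError, match="gamma"):
        generate_recording(2, 150.0, 1.0, mods, seed=0)


def test_modulator_spec_validation():
    with pytest.raises(ValueError):
        ModulatorSpec(-1.0, 1.0, 0.0, np.ones((5, 2)))
    with pytest.raises(ValueError):
        ModulatorSpec(1.0, -0.5, 0.0, np.ones((5, 2)))
    with pytest.raises(ValueError):
        ModulatorSpec(1.0, 1.0, 0.0, 2 * np.ones((5, 2)))


class TestSeizures:
    mods = [
        ModulatorSpec(1.0, 1.0, 0.0, np.ones((5, 4))),
        ModulatorSpec(0.25, 0.8, 1.0, np.ones((5, 4))),
    ]

    def test_too_few_seizures_rejected(self):
        with pytest.raises(ValueError):
            generate_seizures(4.0, 1, 2, [1.0, 1.0], self.mods, seed=0)

    def test_identical_phase_no_noise_gives_identical_evolutions(self):
        mods = [ModulatorSpec(1.0, 1.0, 0.0, np.ones((5, 2)))]
        onsets = [10_000.0, 10_000.0 + 86400.0]  # exactly one period apart
        _, evos, planted = generate_seizures(
            3.0, 2, 2, [1.0], mods, noise_sd=0.0, seed=1, onsets_s=onsets
        )
        assert planted[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.array_equal(evos[0], evos[1])

    def test_planted_dissimilarity_is_symmetric_zero_diagonal(self):
        _, _, planted = generate_seizures(4.0, 8, 2, [0.7, 0.3], self.mods, seed=2)
        assert np.allclose(planted, planted.T)
        assert np.all(np.diag(planted) == 0)
        assert planted.min() >= 0

    def test_planted_dissimilarity_tracks_modulator_state_distance(self):
        from scipy.stats import spearmanr

        onsets, _, planted = generate_seizures(
            6.0, 10, 2, [0.7, 0.3], self.mods, noise_sd=0.1, seed=3
        )
        states = modulator_states(self.mods, onsets)
        true_dist = 0.7 * np.abs(states[0][:, None] - states[0][None, :]) + 0.3 * np.abs(
            states[1][:, None] - states[1][None, :]
        )
        iu = np.triu_indices(len(onsets), 1)
        rho = spearmanr(planted[iu], true_dist[iu]).statistic
        assert rho >= 0.9

    def test_onsets_inside_span_and_increasing(self):
        onsets, evos, _ = generate_seizures(4.0, 8, 2, [1.0, 0.5], self.mods, seed=4)
        assert (np.diff(onsets) > 0).all()
        assert onsets.min() >= 0 and onsets.max() < 4.0 * 86400
        for evo in evos:
            assert evo.ndim == 2 and 20 <= evo.shape[0] <= 60 and evo.shape[1] == 2


def test_write_and_load_round_trip(tmp_path):
    mods = [ModulatorSpec(0.5, 1.0, 0.3, _delta_loading(2))]
    rec = generate_recording(2, FS, 0.5, mods, seed=8)
    onsets, evos, _ = generate_seizures(0.5, 3, 2, [1.0], mods, seed=8)
    rec.seizure_onsets_s = onsets
    rec.seizure_offsets_s = onsets + 60
    rec.seizure_evolutions = evos
    out = write_recording(rec, tmp_path / "subject")
    assert (out / "signals.bin").exists() and (out / "seizures.csv").exists()
    truth = json.loads((out / "truth.json").read_text())
    assert truth["modulators"][0]["period_days"] == 0.5
    back = load_recording(out)
    assert np.array_equal(back.signals, rec.signals)
    assert np.allclose(back.seizure_onsets_s, onsets)
    assert len(back.seizure_evolutions) == 3
    assert np.allclose(back.seizure_evolutions[0], evos[0])
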