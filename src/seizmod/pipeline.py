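"""End-to-end orchestration: band power -> NMF -> MEMD -> Hilbert spectra
-> contributions -> seizure distances -> regression -> permutation tests.

`analyze_recording` runs the whole analysis in memory and returns a
`PipelineResult`; `run_pipeline` drives the same stages against a run
directory with per-stage artifacts, parameter-hash manifests and resume
support; `make_fixtures` writes the default desk-scale synthetic subject.

One master seed derives per-stage seeds through `numpy.random.SeedSequence`
spawning, so partial reruns reproduce the full run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bandpower, contrib, hht, memd, nmf, regress, seizdist, synthdata
from .bands import DEFAULT_BANDS

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "analyze_recording", "run_pipeline", "make_fixtures"]


@dataclass
class RunConfig:
    """All tunables of the pipeline, serialisable to/from YAML."""

    recording: str = ""
    seizures: str = ""
    evolutions: str = ""
    out_dir: str = "run"
    epoch_s: float = 30.0
    exclude_seizure_epochs: bool = False
    k_min: int = 3
    k_max: int = 15
    nmf_error_threshold: float = 0.05
    nmf_max_iter: int = 500
    nmf_tol: float = 1.0e-5
    n_dirs: int = 64
    sift_theta1: float = 0.075
    sift_theta2: float = 0.75
    sift_alpha: float = 0.075
    max_sift: int = 100
    bins_per_decade: int = 48
    circadian_period_band: tuple[float, float] = (0.8, 1.25)
    lambda_log10_lo: float = -3.0
    lambda_log10_hi: float = 2.0
    lambda_log10_step: float = 0.05
    cv_folds: int = 10
    n_permutations: int = 500
    corrected_p: bool = False
    onset_lag_epochs: int = 0
    min_seizures: int = 6
    seed: int = 0

    def lambda_grid(self) -> np.ndarray:
        return 10.0 ** np.arange(
            self.lambda_log10_lo, self.lambda_log10_hi + 1e-9, self.lambda_log10_step
        )

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        offsets = {"synth": 0, "memd": 1, "cv": 2, "perm_times": 3, "perm_order": 4}
        ss = np.random.SeedSequence([self.seed, offsets[stage]])
        return int(ss.generate_state(1, dtype=np.uint32)[0] >> 1)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["circadian_period_band"] = list(self.circadian_period_band)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "circadian_period_band" in d:
            d["circadian_period_band"] = tuple(d["circadian_period_band"])
        return cls(**d)


@dataclass
class PipelineResult:
    """Everything the pipeline computes for one subject."""

    config: RunConfig
    data_matrix: bandpower.DataMatrix | None = None
    factorization: nmf.Factorization | None = None
    imfset: memd.IMFSet | None = None
    traces: list | None = None
    spectrum: hht.MarginalSpectrum | None = None
    peak_frequencies: np.ndarray | None = None
    circadian_imf: int | None = None
    contributions: contrib.ContributionTable | None = None
    heterogeneity: contrib.HeterogeneityTable | None = None
    seizures: seizdist.SeizureTable | None = None
    distances: seizdist.SeizureDistanceSet | None = None
    dissimilarity: np.ndarray | None = None
    dataset: regress.RegressionDataset | None = None
    regression: regress.RegressionResult | None = None
    perm_random_times: regress.PermutationResult | None = None
    perm_shuffled_order: regress.PermutationResult | None = None
    regression_skipped_reason: str | None = None


def analyze_recording(
    rec: synthdata.SyntheticRecording,
    config: RunConfig | None = None,
    run_permutations: bool = True,
    dissimilarity: np.ndarray | None = None,
) -> PipelineResult:
    """Run every stage on an in-memory recording.

    ``dissimilarity`` overrides the DTW dissimilarity of the recording's
    evolution matrices (useful for sensitivity analyses); with fewer than
    ``config.min_seizures`` seizures the regression stage is skipped with
    an explicit message, and earlier stages still complete.
    """
    cfg = config or RunConfig()
    res = PipelineResult(config=cfg)

    intervals = list(zip(rec.seizure_onsets_s, rec.seizure_offsets_s))
    res.data_matrix = bandpower.compute_data_matrix(
        rec.signals,
        rec.fs,
        bands=DEFAULT_BANDS,
        epoch_s=cfg.epoch_s,
        channel_names=rec.channel_names,
        exclude_seizure_epochs=cfg.exclude_seizure_epochs,
        seizure_intervals_s=intervals if cfg.exclude_seizure_epochs else None,
    )
    return _analyze_from_data_matrix(res, rec, cfg, run_permutations, dissimilarity)


def _analyze_from_data_matrix(res, rec, cfg, run_permutations, dissimilarity=None):
    X = res.data_matrix
    res.factorization = nmf.select_k(
        X.values,
        k_min=cfg.k_min,
        k_max=cfg.k_max,
        error_threshold=cfg.nmf_error_threshold,
        max_iter=cfg.nmf_max_iter,
        tol=cfg.nmf_tol,
    )
    res.imfset = memd.memd(
        res.factorization.H,
        n_dirs=cfg.n_dirs,
        seed=cfg.stage_seed("memd"),
        theta1=cfg.sift_theta1,
        theta2=cfg.sift_theta2,
        alpha=cfg.sift_alpha,
        max_sift=cfg.max_sift,
        epoch_s=cfg.epoch_s,
    )
    res.traces = hht.analytic_traces(res.imfset)
    res.spectrum = hht.marginal_spectrum(
        res.imfset, n_bins_per_decade=cfg.bins_per_decade, traces=res.traces
    )
    res.peak_frequencies = np.array(
        [hht.peak_frequency(res.spectrum, i) for i in range(res.imfset.M)]
    )
    res.circadian_imf = hht.find_circadian_imf(res.spectrum, cfg.circadian_period_band)
    res.contributions = contrib.contribution_table(
        res.factorization.W, res.imfset, res.traces, X.row_index
    )
    peak_cycles = np.concatenate([1.0 / res.peak_frequencies, [np.inf]])  # residue row
    res.heterogeneity = contrib.channel_heterogeneity(
        res.factorization.W,
        res.contributions.R,
        X.row_index,
        peak_cycle_length_days=peak_cycles,
    )

    if rec is None or len(rec.seizure_onsets_s) == 0:
        res.regression_skipped_reason = "no seizure annotations"
        return res
    res.seizures = seizdist.SeizureTable(rec.seizure_onsets_s, cfg.epoch_s, X.T)
    res.distances = seizdist.distance_stack(
        res.factorization.W, res.imfset, res.seizures, lag=cfg.onset_lag_epochs
    )
    if dissimilarity is not None:
        res.dissimilarity = np.asarray(dissimilarity, dtype=float)
    elif rec.seizure_evolutions:
        res.dissimilarity = seizdist.dtw_dissimilarity(rec.seizure_evolutions)
    else:
        res.regression_skipped_reason = "no seizure evolutions or dissimilarity provided"
        return res

    if res.seizures.S < cfg.min_seizures:
        res.regression_skipped_reason = (
            f"only {res.seizures.S} seizures; the regression stage requires at "
            f"least {cfg.min_seizures} recorded seizures"
        )
        logger.info(res.regression_skipped_reason)
        return res

    res.dataset = regress.build_dataset(
        res.dissimilarity, res.distances, min_seizures=cfg.min_seizures
    )
    res.regression = regress.fit_dataset(
        res.dataset,
        lambda_grid=cfg.lambda_grid(),
        n_folds=cfg.cv_folds,
        seed=cfg.stage_seed("cv"),
    )
    if run_permutations:
        preds = regress.DistancePredictors.from_factorization(
            res.factorization.W, res.imfset
        )
        res.perm_random_times = regress.permutation_test_random_times(
            res.dataset,
            preds,
            n_iter=cfg.n_permutations,
            seed=cfg.stage_seed("perm_times"),
            lambda_grid=cfg.lambda_grid(),
            n_folds=cfg.cv_folds,
            lag=cfg.onset_lag_epochs,
            corrected=cfg.corrected_p,
            observed=res.regression.adjusted_R2,
        )
        res.perm_shuffled_order = regress.permutation_test_shuffled_order(
            res.dissimilarity,
            res.dataset,
            n_iter=cfg.n_permutations,
            seed=cfg.stage_seed("perm_order"),
            lambda_grid=cfg.lambda_grid(),
            n_folds=cfg.cv_folds,
            corrected=cfg.corrected_p,
            observed=res.regression.adjusted_R2,
        )
    return res


# ---------------------------------------------------------------------------
# run-directory orchestration with resume


_STAGES = ("bandpower", "nmf", "memd", "hht", "contrib", "distances", "regress")


def _params_hash(cfg: RunConfig, stage: str) -> str:
    relevant = dataclasses.asdict(cfg)
    relevant.pop("out_dir", None)
    payload = json.dumps({"stage": stage, "params": relevant}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, resume: bool = False) -> Path:
    """Execute all stages against a run directory.

    Each stage writes its artifact plus a manifest entry carrying the
    producing parameters' hash; with ``resume`` a stage whose artifact
    exists under a matching hash is skipped, and a mismatching hash aborts
    loudly.  Returns the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}

    def fresh(stage: str, artifact: Path) -> bool:
        h = _params_hash(config, stage)
        if not resume:
            return False
        entry = manifest.get(stage)
        if entry is None or not artifact.exists():
            return False
        if entry["hash"] != h:
            raise RuntimeError(
                f"stage {stage!r}: existing artifact was produced with different "
                "parameters; delete it or the run directory to proceed"
            )
        return True

    def record(stage: str) -> None:
        manifest[stage] = {"hash": _params_hash(config, stage)}
        manifest_path.write_text(json.dumps(manifest, indent=2))

    rec = synthdata.load_recording(config.recording)
    if config.seizures:
        onsets, offsets = synthdata.load_seizures(config.seizures)
        rec.seizure_onsets_s, rec.seizure_offsets_s = onsets, offsets
    if config.evolutions:
        evo_dir = Path(config.evolutions)
        rec.seizure_evolutions = [
            np.atleast_2d(np.loadtxt(f, delimiter=","))
            for f in sorted(evo_dir.glob("*.csv"))
        ]

    res = PipelineResult(config=config)

    x_path = out / "X.h5"
    if fresh("bandpower", x_path):
        res.data_matrix = bandpower.read_data_matrix(x_path)
    else:
        intervals = list(zip(rec.seizure_onsets_s, rec.seizure_offsets_s))
        res.data_matrix = bandpower.compute_data_matrix(
            rec.signals,
            rec.fs,
            epoch_s=config.epoch_s,
            channel_names=rec.channel_names,
            exclude_seizure_epochs=config.exclude_seizure_epochs,
            seizure_intervals_s=intervals if config.exclude_seizure_epochs else None,
        )
        bandpower.write_data_matrix(res.data_matrix, x_path)
        record("bandpower")

    nmf_path = out / "nmf.h5"
    if fresh("nmf", nmf_path):
        res.factorization = nmf.read_factorization(nmf_path)
        _resume_after_nmf(res, rec, config, out, manifest, fresh, record)
    else:
        _analyze_from_data_matrix(res, rec, config, run_permutations=True)
        nmf.write_factorization(res.factorization, nmf_path)
        record("nmf")
        memd.write_imfset(res.imfset, out / "imfs.h5", params={"n_dirs": config.n_dirs})
        record("memd")
        _write_tail_artifacts(res, out)
        for stage in ("hht", "contrib", "distances", "regress"):
            record(stage)
    return out


def _resume_after_nmf(res, rec, config, out, manifest, fresh, record):
    imf_path = out / "imfs.h5"
    if fresh("memd", imf_path):
        res.imfset = memd.read_imfset(imf_path)
        # recompute the cheap downstream stages (spectra, tables, regression)
        res.traces = hht.analytic_traces(res.imfset)
        res.spectrum = hht.marginal_spectrum(
            res.imfset, n_bins_per_decade=config.bins_per_decade, traces=res.traces
        )
        res.peak_frequencies = np.array(
            [hht.peak_frequency(res.spectrum, i) for i in range(res.imfset.M)]
        )
        res.circadian_imf = hht.find_circadian_imf(res.spectrum, config.circadian_period_band)
        res.contributions = contrib.contribution_table(
            res.factorization.W, res.imfset, res.traces, res.data_matrix.row_index
        )
        res.heterogeneity = contrib.channel_heterogeneity(
            res.factorization.W, res.contributions.R, res.data_matrix.row_index
        )
        if len(rec.seizure_onsets_s):
            res.seizures = seizdist.SeizureTable(
                rec.seizure_onsets_s, config.epoch_s, res.data_matrix.T
            )
            res.distances = seizdist.distance_stack(
                res.factorization.W, res.imfset, res.seizures, lag=config.onset_lag_epochs
            )
            if rec.seizure_evolutions:
                res.dissimilarity = seizdist.dtw_dissimilarity(rec.seizure_evolutions)
                if res.seizures.S >= config.min_seizures:
                    res.dataset = regress.build_dataset(res.dissimilarity, res.distances)
                    res.regression = regress.fit_dataset(
                        res.dataset,
                        lambda_grid=config.lambda_grid(),
                        n_folds=config.cv_folds,
                        seed=config.stage_seed("cv"),
                    )
                    preds = regress.DistancePredictors.from_factorization(
                        res.factorization.W, res.imfset
                    )
                    res.perm_random_times = regress.permutation_test_random_times(
                        res.dataset, preds, n_iter=config.n_permutations,
                        seed=config.stage_seed("perm_times"),
                        lambda_grid=config.lambda_grid(), n_folds=config.cv_folds,
                        lag=config.onset_lag_epochs, corrected=config.corrected_p,
                    )
                    res.perm_shuffled_order = regress.permutation_test_shuffled_order(
                        res.dissimilarity, res.dataset, n_iter=config.n_permutations,
                        seed=config.stage_seed("perm_order"),
                        lambda_grid=config.lambda_grid(), n_folds=config.cv_folds,
                        corrected=config.corrected_p,
                    )
    else:
        H = res.factorization.H
        res.imfset = memd.memd(
            H, n_dirs=config.n_dirs, seed=config.stage_seed("memd"),
            theta1=config.sift_theta1, theta2=config.sift_theta2,
            alpha=config.sift_alpha, max_sift=config.max_sift, epoch_s=config.epoch_s,
        )
        memd.write_imfset(res.imfset, imf_path, params={"n_dirs": config.n_dirs})
        record("memd")
        _resume_after_nmf(res, rec, config, out, manifest, fresh, record)
        return
    _write_tail_artifacts(res, out)
    for stage in ("hht", "contrib", "distances", "regress"):
        record(stage)


def _write_tail_artifacts(res: PipelineResult, out: Path) -> None:
    """Delimited-text artifacts for the spectral/contribution/regression stages."""
    np.savetxt(out / "marginal_spectrum.csv",
               np.column_stack([res.spectrum.freq_centers, res.spectrum.density.T]),
               delimiter=",", header="freq_cycles_per_day,then one column per IMF")
    np.savetxt(out / "peak_frequencies.csv", res.peak_frequencies, delimiter=",")
    np.savetxt(out / "band_contribution_percent.csv", res.contributions.band_contrib,
               delimiter=",", header=",".join(res.contributions.band_names))
    np.savetxt(out / "gini_heterogeneity.csv", res.heterogeneity.gini,
               delimiter=",", header=",".join(res.heterogeneity.band_names))
    report: dict = {"circadian_imf": res.circadian_imf}
    if res.regression is not None:
        report["regression"] = {
            "lambda_selected": res.regression.lambda_selected,
            "selected": res.regression.selected,
            "coefficients": res.regression.coefficients.tolist(),
            "conf_int": res.regression.conf_int.tolist(),
            "adjusted_R2": res.regression.adjusted_R2,
            "p_random_times": res.perm_random_times.p_value
            if res.perm_random_times else None,
            "p_shuffled_order": res.perm_shuffled_order.p_value
            if res.perm_shuffled_order else None,
        }
    elif res.regression_skipped_reason:
        report["regression_skipped"] = res.regression_skipped_reason
    (out / "report.json").write_text(json.dumps(report, indent=2))


def make_fixtures(seed: int = 0, out_dir: str | Path = "fixtures", **kwargs) -> Path:
    """Write the default desk-scale synthetic subject (4 channels, 256 Hz,
    4 days, 8 seizures, 2 modulators) in the formats every stage reads."""
    rec = synthdata.generate_subject(seed=seed, **kwargs)
    return synthdata.write_recording(rec, out_dir)
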