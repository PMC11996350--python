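"""End-to-end orchestration: simulation/loading through the results report.

Stage order mirrors the analysis: simulate (or load) -> preprocess ->
R peaks -> cardiac/spectral features -> heartbeat epochs -> trialwise
regression -> cluster inference -> ECG confound check -> median-split /
surrogate control -> hierarchical group models -> anxiety correlations.

A single master seed determines every stochastic quantity; named
sub-seeds are derived from it per stage. Heavy stages are cached on
disk keyed by a content hash of the configuration, so partial reruns
resume from cached outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .channels import POSTERIOR_CHANNELS
from . import hep as hep_mod
from . import io as io_mod
from . import models as models_mod
from . import physio as physio_mod
from .cluster import build_adjacency, one_sample_cluster_test
from .simulate import RecordingBundle, SimConfig, simulate_cohort
from .surrogate import ParticipantData, observed_median_split_stat, surrogate_test

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run; round-trips through YAML unchanged."""

    simulation: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    input_dir: str | None = None  # load bundles instead of simulating
    output_dir: str | None = None
    ptp_threshold: float = 150.0
    exclusion_gap_s: float = 0.7
    cluster_forming_p: float = 0.01
    n_permutations: int = 5000
    adjacency_max_dist: float = 0.062
    surrogate_iterations: int = 100
    surrogate_n_permutations: int = 1000
    alpha_band: tuple[float, float] = (8.0, 12.0)
    sampler_chains: int = 4
    sampler_draws: int = 5000
    sampler_warmup: int = 2500
    use_ground_truth_rpeaks: bool = False
    stages: dict = field(default_factory=lambda: {
        "surrogate": True, "models": True, "anxiety": True, "confound": True,
    })

    def validate(self) -> None:
        self.simulation.validate()
        if self.ptp_threshold <= 0 or self.exclusion_gap_s <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.cluster_forming_p < 1:
            raise ValueError("cluster_forming_p must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = dataclasses.asdict(self.simulation)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim.get("probe_interval"), list):
            sim["probe_interval"] = tuple(sim["probe_interval"])
        if isinstance(sim.get("cfa_gain_range"), list):
            sim["cfa_gain_range"] = tuple(sim["cfa_gain_range"])
        if isinstance(d.get("alpha_band"), list):
            d["alpha_band"] = tuple(d["alpha_band"])
        return cls(simulation=SimConfig(**sim), **d)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def subseed(master: int, name: str) -> int:
    """Stable named sub-seed below 2^31."""
    return int(np.random.SeedSequence([master, zlib.crc32(name.encode())])
               .generate_state(1)[0] % (2**31))


class _StageCache:
    def __init__(self, config: PipelineConfig):
        self.dir = None
        if config.output_dir:
            self.dir = Path(config.output_dir) / "cache"
            self.dir.mkdir(parents=True, exist_ok=True)
        self.key = config.content_hash()

    def get_or_compute(self, name: str, fn):
        if self.dir is None:
            return fn()
        path = self.dir / f"{name}-{self.key}.pkl"
        if path.exists():
            logger.info("stage %s: using cached output %s", name, path.name)
            with open(path, "rb") as fh:
                return pickle.load(fh)
        result = fn()
        with open(path, "wb") as fh:
            pickle.dump(result, fh)
        return result


def _load_cohort(config: PipelineConfig):
    in_dir = Path(config.input_dir)
    bundles = [io_mod.read_bundle(p) for p in sorted(in_dir.glob("*_eeg.json"))]
    ratings = io_mod.read_ratings_csv(in_dir / "ratings.csv")
    participants = io_mod.read_participants_tsv(in_dir / "participants.tsv")
    return bundles, ratings, participants


@dataclass
class RunReport:
    """JSON-serializable record of a complete pipeline run."""

    payload: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.payload, indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text

    def __getitem__(self, key):
        return self.payload[key]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages and assemble the run report."""
    config.validate()
    t_start = time.time()
    master = config.seed
    cache = _StageCache(config)
    completed: list[str] = []
    report: dict = {
        "software_version": __version__,
        "seed": master,
        "config_hash": config.content_hash(),
        "stages_completed": completed,
    }

    # --- simulate / load ---------------------------------------------------
    truths = None
    if config.input_dir:
        bundles, ratings_df, participants = _load_cohort(config)
        ratings_by_pid = {
            pid: g.drop(columns=["participant"])
            for pid, g in ratings_df.groupby("participant")
        }
    else:
        sessions, participants = cache.get_or_compute(
            "simulate", lambda: simulate_cohort(config.simulation, master))
        bundles = [b for b, _ in sessions]
        truths = [t for _, t in sessions]
        ratings_by_pid = {t.participant_id: t.trials for t in truths}
    completed.append("simulate")
    report["n_participants"] = len(bundles)

    # --- per-participant processing ---------------------------------------
    def _process():
        per_participant = []
        for bundle in bundles:
            rec = hep_mod.preprocess(bundle)
            if config.use_ground_truth_rpeaks and truths is not None:
                truth = next(t for t in truths if t.participant_id == rec.participant_id)
                rpeaks = physio_mod.RPeakSeries(truth.true_r_peaks, rec.sfreq,
                                                "ground_truth")
            else:
                rpeaks = physio_mod.detect_r_peaks(rec.ecg, rec.sfreq)
            windows = hep_mod.extract_preprobe_windows(
                rec, ratings_by_pid[rec.participant_id])
            per_participant.append(ParticipantData(rec=rec, windows=windows,
                                                   rpeaks=rpeaks))
        return per_participant

    cohort = cache.get_or_compute("preprocess", _process)
    completed.append("preprocess")

    # --- cardiac + spectral features --------------------------------------
    feat_rows = []
    posterior = list(POSTERIOR_CHANNELS)
    for part in cohort:
        rec = part.rec
        pos_idx = [rec.channel_index(c) for c in posterior]
        for order, w in enumerate(part.windows):
            cf = physio_mod.cardiac_features(part.rpeaks, (w.start_s, w.end_s),
                                             window_id=w.trial_id)
            a = int(round(w.start_s * rec.sfreq))
            b = int(round(w.end_s * rec.sfreq))
            sp = physio_mod.morlet_power(rec.data[pos_idx, a:b], rec.sfreq, posterior)
            alpha = physio_mod.alpha_power(sp, band=config.alpha_band)
            feat_rows.append({
                "participant": rec.participant_id,
                "run": w.trial_id[0], "trial": w.trial_id[1],
                "time_on_task": order + 1,
                "heart_rate_bpm": cf.heart_rate,
                "rmssd_ms": cf.rmssd,
                "log_alpha_power": float(np.log(alpha)) if alpha > 0 else np.nan,
                "n_beats": cf.n_beats,
                "arousal": w.arousal_rating,
            })
    features = pd.DataFrame(feat_rows)
    completed.append("features")

    # --- heartbeat epochs, trial HEPs, slope maps --------------------------
    def _hep_stage():
        slope_maps, trial_tables, ecg_trials, split_stats = [], [], [], []
        n_total = n_excluded = n_retained_epochs = n_trials_used = 0
        epochs_per_trial = []
        for part in cohort:
            rec = part.rec
            kept = physio_mod.exclude_close_beats(part.rpeaks, config.exclusion_gap_s)
            t_all = part.rpeaks.peak_times
            t_kept = kept.peak_times
            for w in part.windows:
                n_w = int(((t_all >= w.start_s) & (t_all < w.end_s)).sum())
                k_w = int(((t_kept >= w.start_s) & (t_kept < w.end_s)).sum())
                n_total += n_w
                n_excluded += n_w - k_w
            sets = [hep_mod.build_heartbeat_epochs(w, kept, rec)
                    for w in part.windows]
            epochs = hep_mod.concatenate_epochs(sets)
            epochs = hep_mod.reject_artifacts(epochs, config.ptp_threshold)
            trials = hep_mod.trial_average(epochs, part.windows)
            n_retained_epochs += epochs.n_retained
            n_trials_used += len(trials)
            epochs_per_trial.extend(t.n_epochs_retained for t in trials)
            slope_maps.append(hep_mod.regress_arousal(trials, rec.participant_id))
            trial_tables.append(trials)
            ecg_sets = [hep_mod.build_heartbeat_epochs(w, kept, rec, picks="ecg")
                        for w in part.windows]
            ecg_epochs = hep_mod.concatenate_epochs(ecg_sets)
            ecg_trials.append(hep_mod.trial_average(ecg_epochs, part.windows))
        counts = {
            "n_probes": sum(len(p.windows) for p in cohort),
            "n_heartbeats_in_windows": n_total,
            "n_excluded_700ms": n_excluded,
            "dropout_rate_pct": 100.0 * n_excluded / max(n_total, 1),
            "n_epochs_retained": n_retained_epochs,
            "n_trials_used": n_trials_used,
            "epochs_per_trial_mean": float(np.mean(epochs_per_trial)),
        }
        return slope_maps, trial_tables, ecg_trials, counts

    slope_maps, trial_tables, ecg_trials, counts = cache.get_or_compute(
        "hep", _hep_stage)
    report["counts"] = counts
    completed.append("hep")

    # --- cluster inference on slope maps -----------------------------------
    ref = slope_maps[0]
    adjacency = build_adjacency(
        {c: cohort[0].rec.channel_positions[c] for c in ref.ch_names},
        max_dist=config.adjacency_max_dist)
    maps = np.stack([sm.slopes for sm in slope_maps])
    cluster_result = one_sample_cluster_test(
        maps, adjacency, cluster_forming_p=config.cluster_forming_p,
        n_perm=config.n_permutations, seed=subseed(master, "cluster"),
        ch_names=ref.ch_names, times=ref.times)
    significant = cluster_result.significant()
    best = significant[0] if significant else cluster_result.max_mass_cluster()
    report["cluster"] = {
        "n_clusters": len(cluster_result.clusters),
        "n_significant": len(significant),
        "clusters": [
            {"p": c.p_value, "sum_t": c.sum_t, "sign": c.sign, "size": c.size}
            for c in cluster_result.clusters[:5]
        ],
    }
    if best is not None:
        pts = best.labeled_points(ref.ch_names, ref.times)
        report["cluster"]["best"] = {
            "p": best.p_value, "sum_t": best.sum_t,
            "channels": sorted({ch for ch, _ in pts}),
            "tmin_s": min(t for _, t in pts), "tmax_s": max(t for _, t in pts),
        }
    completed.append("cluster")

    # --- ECG confound check -------------------------------------------------
    if config.stages.get("confound", True):
        if best is not None:
            pts = best.labeled_points(ref.ch_names, ref.times)
            conf_window = (min(t for _, t in pts), max(t for _, t in pts) + 1e-9)
        else:
            conf_window = (0.340, 0.356)
        confound = hep_mod.ecg_confound_check(ecg_trials, window=conf_window)
        report["ecg_confound"] = {
            "window_s": list(confound.window),
            "peak_slope": confound.peak_slope, "peak_bf01": confound.peak_bf01,
            "mean_slope": confound.mean_slope, "mean_bf01": confound.mean_bf01,
        }
        completed.append("confound")

    # epochs-retained vs arousal check (pooled regression BF)
    n_ep = np.array([t.n_epochs_retained for trials in trial_tables for t in trials],
                    dtype=float)
    ar = np.array([t.arousal_rating for trials in trial_tables for t in trials],
                  dtype=float)
    if np.std(n_ep) > 0 and np.std(ar) > 0:
        xc = ar - ar.mean()
        report["epochs_vs_arousal"] = {
            "slope": float(xc @ (n_ep - n_ep.mean()) / (xc @ xc)),
            "bf01": models_mod.jzs_bf_regression(ar, n_ep).bf01,
            "n": len(n_ep),
        }

    # --- surrogate control --------------------------------------------------
    if config.stages.get("surrogate", True):
        def _surrogate_stage():
            _, observed = observed_median_split_stat(
                cohort, adjacency, cluster_forming_p=config.cluster_forming_p,
                n_perm=config.n_permutations,
                seed=subseed(master, "median_split"),
                ptp_threshold=config.ptp_threshold)
            return observed, surrogate_test(
                observed, cohort, adjacency,
                n_iterations=config.surrogate_iterations,
                seed=subseed(master, "surrogate"),
                cluster_forming_p=config.cluster_forming_p,
                n_perm=config.surrogate_n_permutations,
                ptp_threshold=config.ptp_threshold)

        observed, surr = cache.get_or_compute("surrogate", _surrogate_stage)
        report["surrogate"] = {
            "observed_stat": surr.observed_stat,
            "percentile": surr.percentile,
            "significant": surr.significant,
            "n_iterations": surr.n_iterations,
            "null_mean": float(surr.null_stats.mean()),
            "null_sd": float(surr.null_stats.std()),
        }
        completed.append("surrogate")

    # --- hierarchical group models -----------------------------------------
    if config.stages.get("models", True):
        usable = features.dropna(subset=["heart_rate_bpm", "rmssd_ms",
                                         "log_alpha_power"])
        y = models_mod.zscore_within(usable["arousal"].to_numpy(),
                                     usable["participant"].to_numpy())
        pids = usable["participant"].to_numpy()
        model_report = {}
        for name, col in (
            ("heart_rate", "heart_rate_bpm"), ("hrv_rmssd", "rmssd_ms"),
            ("time_on_task", "time_on_task"), ("alpha_power", "log_alpha_power"),
        ):
            fit = models_mod.fit_random_slope_model(
                usable[col].to_numpy(dtype=float), y, pids,
                n_chains=config.sampler_chains, n_draws=config.sampler_draws,
                n_warmup=config.sampler_warmup,
                seed=subseed(master, f"model_{name}"))
            entry = {"converged": fit.converged,
                     "rhat_max": max(fit.rhat.values())}
            if fit.converged:
                s = fit.summary()["beta1"]
                entry.update(beta=s["mean"], ci_low=s["ci_low"],
                             ci_high=s["ci_high"],
                             excludes_zero=fit.slope_excludes_zero())
            model_report[name] = entry
        report["group_models"] = model_report
        completed.append("models")

    # --- anxiety moderation -------------------------------------------------
    if config.stages.get("anxiety", True) and best is not None:
        pts = best.labeled_points(ref.ch_names, ref.times)
        effects = np.array([hep_mod.effect_magnitude(sm, pts) for sm in slope_maps])
        anxiety_report = {}
        for scale in ("gad7", "stai_s"):
            scores = np.array([
                float(participants.loc[participants["participant"] == sm.participant_id,
                                       scale].iloc[0])
                for sm in slope_maps
            ])
            try:
                corr = models_mod.correlate_effect_with_anxiety(effects, scores)
                anxiety_report[scale] = {"r": corr.r, "p": corr.p, "n": corr.n,
                                         "df": corr.df}
            except ValueError as exc:
                anxiety_report[scale] = {"error": str(exc)}
        report["anxiety"] = anxiety_report
        completed.append("anxiety")

    report["runtime_s"] = time.time() - t_start
    report["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        RunReport(report).to_json(out / "report.json")
        features.to_csv(out / "features.csv", index=False)
        io_mod.write_slope_maps(slope_maps, out / "slope_maps.npz")
    return RunReport(report)
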