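"""Surrogate-heartbeat control analysis.

To show that a median-split cluster effect is specifically locked to
heartbeats, the whole epoching / rejection / median-split / paired
cluster pipeline is rebuilt on randomly timed pseudo-heartbeats: within
each 10 s pre-probe window, k surrogate event times are drawn uniformly
(k = the number of true heartbeats in that window), excluding the true
R-peak samples. Each iteration records the signed mass of the cluster
with the largest absolute t-sum (0 if none forms); 100 iterations yield
an empirical null, and the observed statistic is significant when it
falls beyond the null's 2.5th or 97.5th percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from . import hep as _hep
from .cluster import Adjacency, paired_cluster_test
from .hep import ANALYSIS_WINDOW, HeartbeatEpochSet, PreProbeWindow, ParticipantExcluded
from .physio import RPeakSeries
from .simulate import RecordingBundle

__all__ = [
    "ParticipantData", "SurrogateNull",
    "sample_surrogate_times", "surrogate_iteration", "surrogate_test",
]


@dataclass
class ParticipantData:
    """Preprocessed inputs needed to re-run the median-split pipeline."""

    rec: RecordingBundle  # preprocessed recording
    windows: list[PreProbeWindow]
    rpeaks: RPeakSeries  # detected R peaks, before the 700 ms exclusion


@dataclass
class SurrogateNull:
    null_stats: np.ndarray
    observed_stat: float
    percentile: float
    significant: bool
    n_iterations: int
    seed: int | None


def sample_surrogate_times(window: PreProbeWindow, k: int,
                           true_peaks: np.ndarray, rng: np.random.Generator,
                           sfreq: float) -> np.ndarray:
    """k distinct sample indices uniform in the window, avoiding true peaks.

    No minimum-gap constraint is applied between surrogate events; only
    the collision constraint with true heartbeat samples.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return np.array([], dtype=int)
    lo = int(np.ceil(window.start_s * sfreq))
    hi = int(np.floor(window.end_s * sfreq))  # exclusive
    candidates = np.arange(lo, hi)
    forbidden = np.asarray(true_peaks, dtype=int)
    candidates = candidates[~np.isin(candidates, forbidden)]
    if k > candidates.size:
        raise ValueError(
            f"cannot draw {k} distinct surrogate samples from "
            f"{candidates.size} available in window {window.trial_id}"
        )
    picked = rng.choice(candidates, size=k, replace=False)
    return np.sort(picked)


def _median_split_arrays(cohort: list[ParticipantData],
                         event_samples: dict[int, dict[tuple[int, int], np.ndarray]] | None,
                         ptp_threshold: float,
                         window: tuple[float, float],
                         ) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """High/low median-split arrays per participant.

    ``event_samples`` maps participant index -> trial_id -> event sample
    indices; ``None`` means use the participant's real (700 ms-excluded)
    R peaks. The identical epoching / rejection / averaging / split code
    path (module ``hep``) runs in both cases.
    """
    from .physio import exclude_close_beats

    highs, lows = [], []
    ch_names: list[str] = []
    times = None
    for pi, part in enumerate(cohort):
        if event_samples is None:
            events_by_trial = None
            rpeaks = exclude_close_beats(part.rpeaks)
        else:
            events_by_trial = event_samples[pi]
        sets: list[HeartbeatEpochSet] = []
        for w in part.windows:
            if events_by_trial is None:
                series = rpeaks
            else:
                series = RPeakSeries(events_by_trial[w.trial_id], part.rec.sfreq,
                                     provenance="surrogate")
            sets.append(_hep.build_heartbeat_epochs(w, series, part.rec))
        epochs = _hep.concatenate_epochs(sets)
        epochs = _hep.reject_artifacts(epochs, ptp_threshold)
        trials = _hep.trial_average(epochs, part.windows)
        try:
            split = _hep.median_split(trials, part.rec.participant_id, window=window)
        except ParticipantExcluded:
            warnings.warn(
                f"participant {part.rec.participant_id} dropped from split"
            )
            continue
        highs.append(split.high)
        lows.append(split.low)
        ch_names = split.ch_names
        times = split.times
    return np.stack(highs), np.stack(lows), ch_names, times


def observed_median_split_stat(cohort: list[ParticipantData],
                               adjacency: Adjacency,
                               cluster_forming_p: float = 0.01,
                               n_perm: int | str = 5000,
                               seed: int | None = None,
                               ptp_threshold: float = 150.0,
                               window: tuple[float, float] = ANALYSIS_WINDOW):
    """Median-split paired cluster test on the real heartbeats.

    Returns the ClusterTestResult and the signed t-sum of the cluster
    with the largest absolute mass (0 if no cluster forms).
    """
    high, low, ch_names, times = _median_split_arrays(
        cohort, None, ptp_threshold, window)
    result = paired_cluster_test(high, low, adjacency,
                                 cluster_forming_p=cluster_forming_p,
                                 n_perm=n_perm, seed=seed,
                                 ch_names=ch_names, times=times)
    best = result.max_mass_cluster()
    return result, (float(best.sum_t) if best is not None else 0.0)


def surrogate_iteration(cohort: list[ParticipantData], rng: np.random.Generator,
                        adjacency: Adjacency,
                        cluster_forming_p: float = 0.01,
                        n_perm: int = 1000,
                        ptp_threshold: float = 150.0,
                        window: tuple[float, float] = ANALYSIS_WINDOW) -> float:
    """One draw of the surrogate null: pseudo-heartbeat median-split stat.

    k per window equals the number of true heartbeats in that window
    (before the 700 ms exclusion, which applies to real epochs only).
    Returns the signed sum_t of the cluster maximizing |sum_t|, or 0.
    """
    event_samples: dict[int, dict[tuple[int, int], np.ndarray]] = {}
    for pi, part in enumerate(cohort):
        t = part.rpeaks.peak_times
        per_trial = {}
        for w in part.windows:
            true_in = part.rpeaks.peak_samples[(t >= w.start_s) & (t < w.end_s)]
            per_trial[w.trial_id] = sample_surrogate_times(
                w, len(true_in), part.rpeaks.peak_samples, rng, part.rec.sfreq)
        event_samples[pi] = per_trial
    high, low, ch_names, times = _median_split_arrays(
        cohort, event_samples, ptp_threshold, window)
    result = paired_cluster_test(
        high, low, adjacency, cluster_forming_p=cluster_forming_p,
        n_perm=n_perm, seed=int(rng.integers(2**31)),
        ch_names=ch_names, times=times)
    best = result.max_mass_cluster()
    return float(best.sum_t) if best is not None else 0.0


def surrogate_test(observed_stat: float, cohort: list[ParticipantData],
                   adjacency: Adjacency, n_iterations: int = 100,
                   seed: int | None = None,
                   cluster_forming_p: float = 0.01,
                   n_perm: int = 1000,
                   ptp_threshold: float = 150.0,
                   window: tuple[float, float] = ANALYSIS_WINDOW) -> SurrogateNull:
    """Empirical-null decision for the observed median-split cluster statistic.

    Significant iff the observed statistic exceeds the 97.5th or falls
    below the 2.5th percentile of the surrogate null (two-tailed 5%).
    """
    if n_iterations < 40:
        warnings.warn(
            f"{n_iterations} surrogate iterations give coarse percentile resolution"
        )
    rng = np.random.default_rng(seed)
    null = np.array([
        surrogate_iteration(cohort, rng, adjacency,
                            cluster_forming_p=cluster_forming_p,
                            n_perm=n_perm, ptp_threshold=ptp_threshold,
                            window=window)
        for _ in range(n_iterations)
    ])
    pct = float(scipy.stats.percentileofscore(null, observed_stat, kind="mean"))
    lo, hi = np.percentile(null, [2.5, 97.5])
    significant = bool(observed_stat > hi or observed_stat < lo)
    return SurrogateNull(null_stats=null, observed_stat=float(observed_stat),
                         percentile=pct, significant=significant,
                         n_iterations=n_iterations, seed=seed)
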