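"""From continuous recordings to per-participant HEP summaries.

Preprocessing (resample to 250 Hz, 1-55 Hz band-pass, common-average
reference over scalp channels), 10 s pre-probe windows, R-peak-locked
epoching (-100 to +650 ms) after the 700 ms exclusion, peak-to-peak
artifact rejection, trial-level averaging, per-participant channel x
time regression of voltage on arousal ratings, median-split averages,
cluster-averaged effect magnitudes, and the ECG cardiac-field-artifact
confound check.

No baseline correction is applied anywhere: heartbeat-locked designs
lack a true baseline because cardiac activity is cyclical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import ECG_CHANNEL
from .physio import RPeakSeries
from .simulate import EPOCH_TMIN, RecordingBundle, epoch_time_axis

logger = logging.getLogger(__name__)

TARGET_SFREQ = 250.0
ANALYSIS_WINDOW = (0.250, 0.450)


class ParticipantExcluded(RuntimeError):
    """Raised when a participant cannot contribute to group analysis."""


@dataclass
class PreProbeWindow:
    """The 10 s of recording immediately before one thought probe."""

    trial_id: tuple[int, int]  # (run, trial within run)
    start_s: float
    end_s: float
    arousal_rating: float
    other_ratings: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs((self.end_s - self.start_s) - 10.0) > 1e-9:
            raise ValueError("pre-probe window must be exactly 10 s")


@dataclass
class HeartbeatEpochSet:
    """R-peak-locked segments sharing one time axis."""

    data: np.ndarray  # (n_epochs, n_channels, n_times) microvolts
    times: np.ndarray  # seconds relative to R peak
    ch_names: list[str]
    trial_ids: list[tuple[int, int]]
    rpeak_samples: np.ndarray
    rejected: np.ndarray  # bool per epoch

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_retained(self) -> int:
        return int((~self.rejected).sum())

    def retained(self) -> "HeartbeatEpochSet":
        keep = ~self.rejected
        return HeartbeatEpochSet(
            data=self.data[keep], times=self.times, ch_names=self.ch_names,
            trial_ids=[t for t, k in zip(self.trial_ids, keep) if k],
            rpeak_samples=self.rpeak_samples[keep],
            rejected=np.zeros(int(keep.sum()), dtype=bool),
        )


@dataclass
class TrialHEP:
    """Mean heartbeat-locked waveform for one trial."""

    trial_id: tuple[int, int]
    mean_waveform: np.ndarray  # (n_channels, n_times)
    n_epochs_retained: int
    arousal_rating: float
    ch_names: list[str]
    times: np.ndarray


@dataclass
class SlopeMap:
    """Per-participant OLS slopes of voltage on arousal, channels x time."""

    participant_id: str
    slopes: np.ndarray  # (n_channels, n_window_times) microvolts per rating unit
    ch_names: list[str]
    times: np.ndarray  # analysis-window subset of the epoch grid
    n_trials: int


@dataclass
class MedianSplitHEP:
    """Low/high-arousal mean waveforms from a within-participant median split."""

    participant_id: str
    low: np.ndarray  # (n_channels, n_times)
    high: np.ndarray
    n_low: int
    n_high: int
    ch_names: list[str]
    times: np.ndarray


def preprocess(raw: RecordingBundle) -> RecordingBundle:
    """Resample to 250 Hz, band-pass scalp EEG 1-55 Hz (zero-phase), and
    re-reference scalp channels to their common average.

    The ECG channel is band-pass filtered with the rest of the recording
    but excluded from the common-average reference.
    """
    import mne.filter

    if raw.sfreq < TARGET_SFREQ:
        raise ValueError(f"sfreq {raw.sfreq} Hz below the 250 Hz target")
    data = np.asarray(raw.data, dtype=np.float64)
    sfreq = raw.sfreq
    probe_onsets = raw.probe_onsets
    if sfreq > TARGET_SFREQ:
        data = mne.filter.resample(data, down=sfreq / TARGET_SFREQ, verbose="error")
        sfreq = TARGET_SFREQ
    data = mne.filter.filter_data(data, sfreq, l_freq=1.0, h_freq=55.0,
                                  verbose="error")
    eeg_idx = [i for i, c in enumerate(raw.channel_names) if c != ECG_CHANNEL]
    data[eeg_idx] -= data[eeg_idx].mean(axis=0, keepdims=True)
    return RecordingBundle(
        data=data, channel_names=list(raw.channel_names),
        channel_positions=raw.channel_positions, sfreq=sfreq,
        probe_onsets=probe_onsets, run_boundaries=raw.run_boundaries,
        participant_id=raw.participant_id,
    )


def extract_preprobe_windows(rec: RecordingBundle, ratings) -> list[PreProbeWindow]:
    """One 10 s window per probe, with ratings joined by (run, trial).

    ``ratings`` is a DataFrame with columns ``run``, ``trial``,
    ``arousal`` and optionally further 0-100 items. Probes without a
    rating row are excluded with a logged count.
    """
    other_items = [c for c in ratings.columns
                   if c not in ("run", "trial", "probe_onset_s", "latent", "arousal")]
    keyed = ratings.set_index(["run", "trial"])
    windows: list[PreProbeWindow] = []
    n_missing = 0
    per_run_count: dict[int, int] = {}
    for i, onset in enumerate(rec.probe_onsets):
        run = rec.run_of_probe(i)
        trial = per_run_count.get(run, 0)
        per_run_count[run] = trial + 1
        if onset - rec.run_boundaries[run] < 10.0 - 1e-9:
            raise ValueError(
                f"probe {i} (run {run}, trial {trial}) occurs "
                f"{onset - rec.run_boundaries[run]:.1f} s into its run; the full "
                "10 s pre-probe window does not exist"
            )
        if (run, trial) not in keyed.index:
            n_missing += 1
            continue
        row = keyed.loc[(run, trial)]
        windows.append(PreProbeWindow(
            trial_id=(run, trial), start_s=onset - 10.0, end_s=onset,
            arousal_rating=float(row["arousal"]),
            other_ratings={k: float(row[k]) for k in other_items},
        ))
    if n_missing:
        logger.warning("%d probes excluded for missing ratings", n_missing)
    return windows


def build_heartbeat_epochs(window: PreProbeWindow, rpeaks: RPeakSeries,
                           rec: RecordingBundle,
                           picks: str = "eeg") -> HeartbeatEpochSet:
    """Epochs from -100 to +650 ms around each R peak inside the window.

    ``rpeaks`` should already have passed :func:`exclude_close_beats`.
    The window gates R-peak selection only; an epoch may extend past the
    window end and is retained as long as it lies within the recording.
    """
    sfreq = rec.sfreq
    times = epoch_time_axis(sfreq)
    start_off = int(round(EPOCH_TMIN * sfreq))
    n_ep_samples = len(times)

    if picks == "eeg":
        ch_idx = [i for i, c in enumerate(rec.channel_names) if c != ECG_CHANNEL]
    elif picks == "ecg":
        ch_idx = [rec.channel_index(ECG_CHANNEL)]
    elif picks == "all":
        ch_idx = list(range(len(rec.channel_names)))
    else:
        raise ValueError(f"unknown picks {picks!r}")
    ch_names = [rec.channel_names[i] for i in ch_idx]

    t = rpeaks.peak_times
    sel = rpeaks.peak_samples[(t >= window.start_s) & (t < window.end_s)]
    epochs = []
    kept_peaks = []
    for p in sel:
        a = p + start_off
        b = a + n_ep_samples
        if a < 0 or b > rec.n_samples:
            continue
        epochs.append(rec.data[np.ix_(ch_idx, np.arange(a, b))])
        kept_peaks.append(p)
    data = (np.stack(epochs) if epochs
            else np.empty((0, len(ch_idx), n_ep_samples)))
    if not epochs:
        logger.warning("trial %s: no R peaks in pre-probe window", window.trial_id)
    return HeartbeatEpochSet(
        data=data, times=times, ch_names=ch_names,
        trial_ids=[window.trial_id] * len(epochs),
        rpeak_samples=np.asarray(kept_peaks, dtype=int),
        rejected=np.zeros(len(epochs), dtype=bool),
    )


def concatenate_epochs(sets: list[HeartbeatEpochSet]) -> HeartbeatEpochSet:
    """Stack per-trial epoch sets that share a time axis and channels."""
    sets = [s for s in sets if len(s)]
    if not sets:
        raise ValueError("no epochs to concatenate")
    ref = sets[0]
    for s in sets[1:]:
        if s.ch_names != ref.ch_names or len(s.times) != len(ref.times):
            raise ValueError("epoch sets are not alignable")
    return HeartbeatEpochSet(
        data=np.concatenate([s.data for s in sets]),
        times=ref.times, ch_names=ref.ch_names,
        trial_ids=[t for s in sets for t in s.trial_ids],
        rpeak_samples=np.concatenate([s.rpeak_samples for s in sets]),
        rejected=np.concatenate([s.rejected for s in sets]),
    )


def reject_artifacts(epochs: HeartbeatEpochSet,
                     ptp_threshold: float = 150.0) -> HeartbeatEpochSet:
    """Flag epochs whose peak-to-peak amplitude exceeds ``ptp_threshold`` uV.

    A deliberately simple, fully deterministic stand-in for learned
    artifact-rejection procedures: the maximum peak-to-peak amplitude
    across the set's channels decides rejection.
    """
    if ptp_threshold <= 0:
        raise ValueError("ptp_threshold must be positive")
    if len(epochs) == 0:
        return epochs
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (n_ep, n_ch)
    rejected = epochs.rejected | (ptp.max(axis=1) > ptp_threshold)
    rate = rejected.mean()
    logger.info("artifact rejection: %.1f%% of %d epochs", 100 * rate, len(epochs))
    if rejected.all():
        warnings.warn("all epochs rejected; affected trials will be dropped")
    return replace(epochs, rejected=rejected)


def trial_average(epochs: HeartbeatEpochSet,
                  windows: list[PreProbeWindow]) -> list[TrialHEP]:
    """Arithmetic mean over retained epochs, per trial.

    Trials with zero retained epochs are dropped (logged); their ratings
    never reach the regression or median split.
    """
    rating_by_trial = {w.trial_id: w.arousal_rating for w in windows}
    keep = ~epochs.rejected
    out: list[TrialHEP] = []
    seen: dict[tuple[int, int], list[int]] = {}
    for i, tid in enumerate(epochs.trial_ids):
        if keep[i]:
            seen.setdefault(tid, []).append(i)
    for w in windows:
        idx = seen.get(w.trial_id, [])
        if not idx:
            logger.warning("trial %s dropped: no retained epochs", w.trial_id)
            continue
        out.append(TrialHEP(
            trial_id=w.trial_id,
            mean_waveform=epochs.data[idx].mean(axis=0),
            n_epochs_retained=len(idx),
            arousal_rating=rating_by_trial[w.trial_id],
            ch_names=epochs.ch_names, times=epochs.times,
        ))
    return out


def _window_slice(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)


def regress_arousal(trials: list[TrialHEP], participant_id: str = "",
                    window: tuple[float, float] = ANALYSIS_WINDOW) -> SlopeMap:
    """OLS slope (with intercept) of voltage on the raw 0-100 arousal
    rating, at every channel and timepoint inside the analysis window.

    Timepoints below 250 ms are excluded to avoid cardiac-field-artifact
    overlap; HEP effects beyond 450 ms are outside the window of
    interest. Slopes are in microvolts per rating point.
    """
    if len(trials) < 3:
        raise ParticipantExcluded(
            f"participant {participant_id!r}: need >= 3 trials, have {len(trials)}"
        )
    x = np.array([t.arousal_rating for t in trials], dtype=float)
    if np.unique(x).size < 2:
        raise ParticipantExcluded(
            f"participant {participant_id!r}: constant arousal ratings"
        )
    ref = trials[0]
    tsel = _window_slice(ref.times, window)
    y = np.stack([t.mean_waveform[:, tsel] for t in trials])  # (n, ch, T)
    xc = x - x.mean()
    slopes = np.tensordot(xc, y - y.mean(axis=0), axes=(0, 0)) / (xc @ xc)
    return SlopeMap(
        participant_id=participant_id or getattr(ref, "participant_id", ""),
        slopes=slopes, ch_names=ref.ch_names, times=ref.times[tsel],
        n_trials=len(trials),
    )


def median_split(trials: list[TrialHEP], participant_id: str = "",
                 window: tuple[float, float] = ANALYSIS_WINDOW) -> MedianSplitHEP:
    """Within-participant median split on arousal ratings.

    Trials with rating <= the participant median form the low condition,
    the rest the high condition (ties go to low). Waveforms are averaged
    over trials and restricted to the analysis window.
    """
    if len(trials) < 2:
        raise ParticipantExcluded("median split requires >= 2 trials")
    x = np.array([t.arousal_rating for t in trials], dtype=float)
    med = float(np.median(x))
    low_idx = np.flatnonzero(x <= med)
    high_idx = np.flatnonzero(x > med)
    if high_idx.size == 0:
        raise ParticipantExcluded(
            f"participant {participant_id!r}: median split impossible "
            "(no ratings above the median)"
        )
    ref = trials[0]
    tsel = _window_slice(ref.times, window)
    stack = np.stack([t.mean_waveform[:, tsel] for t in trials])
    return MedianSplitHEP(
        participant_id=participant_id,
        low=stack[low_idx].mean(axis=0), high=stack[high_idx].mean(axis=0),
        n_low=int(low_idx.size), n_high=int(high_idx.size),
        ch_names=ref.ch_names, times=ref.times[tsel],
    )


def effect_magnitude(sm: SlopeMap,
                     cluster_points: list[tuple[str, float]]) -> float:
    """Mean regression slope over a cluster's (channel, time) points.

    ``cluster_points`` uses channel labels and times in seconds; times
    are matched to the nearest sample on the slope map's grid.
    """
    if not cluster_points:
        raise ValueError("cluster is empty")
    vals = []
    for ch, t in cluster_points:
        if ch not in sm.ch_names:
            raise KeyError(f"unknown channel {ch!r} in cluster")
        ti = int(np.argmin(np.abs(sm.times - t)))
        if abs(sm.times[ti] - t) > 0.5 / 250.0 + 1e-9:
            raise ValueError(f"time {t:.3f} s outside the analysis window")
        vals.append(sm.slopes[sm.ch_names.index(ch), ti])
    return float(np.mean(vals))


@dataclass
class ECGConfoundResult:
    """Pooled regressions of ECG amplitude in the cluster window on arousal."""

    window: tuple[float, float]
    peak_slope: float
    peak_bf01: float
    mean_slope: float
    mean_bf01: float
    n_trials: int


def ecg_confound_check(ecg_trials_per_participant: list[list[TrialHEP]],
                       window: tuple[float, float] = (0.340, 0.356),
                       cauchy_scale: float | None = None) -> ECGConfoundResult:
    """Test whether cardiac-field-artifact amplitude tracks arousal.

    For each trial, the peak and mean ECG amplitude inside the
    cluster-derived window are computed from the trial-mean ECG epoch;
    amplitudes are pooled over participants and regressed on arousal
    ratings, with a default-prior regression Bayes factor reported as
    BF01 (evidence for no association).
    """
    from .models import jzs_bf_regression

    if window[1] <= window[0]:
        raise ValueError("empty confound window")
    peak_amp, mean_amp, ratings = [], [], []
    for trials in ecg_trials_per_participant:
        for tr in trials:
            tsel = _window_slice(tr.times, window)
            if not tsel.any():
                raise ValueError(f"window {window} contains no epoch samples")
            seg = tr.mean_waveform[:, tsel]
            peak_amp.append(seg.max())
            mean_amp.append(seg.mean())
            ratings.append(tr.arousal_rating)
    x = np.asarray(ratings, dtype=float)
    results = {}
    for name, y in (("peak", np.asarray(peak_amp)), ("mean", np.asarray(mean_amp))):
        xc, yc = x - x.mean(), y - y.mean()
        denom = xc @ xc
        slope = float(xc @ yc / denom) if denom > 0 else 0.0
        if np.allclose(yc, 0) or denom == 0:
            bf01 = np.inf
        else:
            kwargs = {} if cauchy_scale is None else {"cauchy_scale": cauchy_scale}
            bf01 = jzs_bf_regression(x, y, **kwargs).bf01
        results[name] = (slope, bf01)
    return ECGConfoundResult(
        window=window,
        peak_slope=results["peak"][0], peak_bf01=results["peak"][1],
        mean_slope=results["mean"][0], mean_bf01=results["mean"][1],
        n_trials=len(x),
    )
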