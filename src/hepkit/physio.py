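"""Cardiac and spectral features.

R-peak detection (Pan-Tompkins-style), the 700 ms overlapping-beat
exclusion rule, pre-probe heart rate and RMSSD heart-rate variability,
and Morlet-wavelet spectral power at parieto-occipital channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .channels import POSTERIOR_CHANNELS

__all__ = [
    "RPeakSeries", "CardiacFeatures", "SpectralPower",
    "detect_r_peaks", "exclude_close_beats", "cardiac_features",
    "morlet_power", "alpha_power", "POSTERIOR_CHANNELS",
]


@dataclass
class RPeakSeries:
    """Strictly increasing R-peak sample indices."""

    peak_samples: np.ndarray
    sfreq: float
    provenance: str = "detected"  # "detected" | "ground_truth" | "surrogate"

    def __post_init__(self) -> None:
        self.peak_samples = np.asarray(self.peak_samples, dtype=int)
        if self.peak_samples.size and np.any(np.diff(self.peak_samples) <= 0):
            raise ValueError("peak samples must be strictly increasing")

    @property
    def peak_times(self) -> np.ndarray:
        return self.peak_samples / self.sfreq

    def __len__(self) -> int:
        return len(self.peak_samples)


@dataclass
class CardiacFeatures:
    """Summary of beats inside one pre-probe window."""

    window_id: object
    n_beats: int
    heart_rate: float | None  # bpm; None when < 2 beats
    rmssd: float | None  # ms; None when < 3 beats


@dataclass
class SpectralPower:
    """Morlet power, channels x frequencies x time, in microvolts squared."""

    freqs: np.ndarray
    power: np.ndarray
    channels: list[str]
    sfreq: float
    edge_mask: np.ndarray  # (n_freqs, n_times) True where edge-contaminated

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.power.shape[-1]) / self.sfreq


def detect_r_peaks(ecg: np.ndarray, sfreq: float,
                   refractory: float = 0.25) -> RPeakSeries:
    """Detect one R peak per cardiac cycle at the local ECG maximum.

    Pan-Tompkins-style front end: 5-35 Hz band-pass, squared derivative,
    150 ms moving-window integration, then peak picking with an adaptive
    threshold and a 250 ms refractory period. Each detection is refined
    to the raw-signal maximum within +/-50 ms.
    """
    ecg = np.asarray(ecg, dtype=float)
    if sfreq < 100:
        raise ValueError("detector requires sfreq >= 100 Hz")
    if ecg.size < 2 * sfreq:
        raise ValueError("detector requires at least 2 s of signal")
    if np.ptp(ecg) < 1e-9:
        warnings.warn("flat ECG signal: no R peaks detected")
        return RPeakSeries(np.array([], dtype=int), sfreq)

    sos = scipy.signal.butter(2, [5.0, 35.0], btype="bandpass", fs=sfreq, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, ecg)
    energy = np.gradient(filtered) ** 2
    win = max(int(round(0.150 * sfreq)), 1)
    integrated = np.convolve(energy, np.ones(win) / win, mode="same")

    height = 0.2 * np.percentile(integrated, 99.5)
    locs, _ = scipy.signal.find_peaks(
        integrated, height=height, distance=max(int(round(refractory * sfreq)), 1)
    )
    if locs.size == 0:
        warnings.warn("no QRS energy above threshold: no R peaks detected")
        return RPeakSeries(np.array([], dtype=int), sfreq)

    # refine to the raw local maximum
    half = int(round(0.05 * sfreq))
    refined = []
    for loc in locs:
        a, b = max(0, loc - half), min(len(ecg), loc + half + 1)
        refined.append(a + int(np.argmax(ecg[a:b])))
    refined = np.unique(refined)
    # re-enforce refractory after refinement, keeping the larger peak
    keep: list[int] = []
    for p in refined:
        if keep and p - keep[-1] < refractory * sfreq:
            if ecg[p] > ecg[keep[-1]]:
                keep[-1] = int(p)
        else:
            keep.append(int(p))
    return RPeakSeries(np.asarray(keep, dtype=int), sfreq)


def exclude_close_beats(rpeaks: RPeakSeries, min_gap: float = 0.7) -> RPeakSeries:
    """Drop beats closer than ``min_gap`` seconds to the last retained beat.

    Greedy forward scan; idempotent. Mirrors the rule of excluding
    heartbeats within 700 ms of each other so that heartbeat epochs do
    not overlap.
    """
    gap = min_gap * rpeaks.sfreq
    kept: list[int] = []
    for p in rpeaks.peak_samples:
        if not kept or p - kept[-1] >= gap:
            kept.append(int(p))
    return RPeakSeries(np.asarray(kept, dtype=int), rpeaks.sfreq, rpeaks.provenance)


def cardiac_features(rpeaks: RPeakSeries, window: tuple[float, float],
                     window_id: object = None) -> CardiacFeatures:
    """Heart rate and RMSSD over ``window = [start_s, end_s)``.

    Uses the unfiltered peak series (the 700 ms exclusion applies to HEP
    epoching only). Heart rate is ``60 * n_intervals / sum(RR)``; RMSSD
    is the root-mean-square of successive R-R interval differences, in
    ms, over intervals whose both beats fall inside the window.
    """
    start, end = window
    if end <= start:
        raise ValueError("window length must be positive")
    t = rpeaks.peak_times
    in_win = t[(t >= start) & (t < end)]
    n = len(in_win)
    heart_rate = None
    rmssd = None
    if n >= 2:
        rr = np.diff(in_win)
        heart_rate = 60.0 * len(rr) / rr.sum()
    if n >= 3:
        rr_ms = np.diff(in_win) * 1000.0
        d = np.diff(rr_ms)
        rmssd = float(np.sqrt(np.mean(d**2)))
    return CardiacFeatures(window_id=window_id, n_beats=n,
                           heart_rate=heart_rate, rmssd=rmssd)


def default_freqs() -> np.ndarray:
    """50 logarithmically spaced frequencies from 2 to 30 Hz."""
    return np.logspace(np.log10(2.0), np.log10(30.0), 50)


def morlet_power(eeg: np.ndarray, sfreq: float, channels: list[str],
                 freqs: np.ndarray | None = None) -> SpectralPower:
    """Morlet-wavelet power with ``n_cycles = freq / 2``.

    ``eeg`` is (n_channels, n_samples) aligned with ``channels``.
    Samples inside the wavelet half-support at each frequency are
    flagged in ``edge_mask`` and should not be averaged.
    """
    from mne.time_frequency import tfr_array_morlet

    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    if eeg.shape[0] != len(channels):
        raise ValueError("channel list does not match data rows")
    if freqs is None:
        freqs = default_freqs()
    n_cycles = freqs / 2.0
    # wavelet temporal SD = n_cycles / (2 pi f); support ~ +/- 5 SD
    sigma_t = n_cycles / (2.0 * np.pi * freqs)
    half_support = 5.0 * sigma_t
    n_samples = eeg.shape[1]
    min_len = int(np.ceil(2 * half_support.max() * sfreq))
    if n_samples < min_len:
        raise ValueError(
            f"segment of {n_samples} samples shorter than the lowest-frequency "
            f"wavelet support ({min_len} samples at {freqs.min():.2f} Hz)"
        )
    # plain (non-zero-mean) Morlet: symmetric frequency response, so a pure
    # tone peaks at the nearest bin even at low f*sigma_t; DC leakage is
    # immaterial downstream of the 1 Hz high-pass
    power = tfr_array_morlet(
        eeg[np.newaxis], sfreq=sfreq, freqs=freqs, n_cycles=n_cycles,
        output="power", zero_mean=False, verbose="error",
    )[0]
    t = np.arange(n_samples) / sfreq
    edge = (t[np.newaxis, :] < half_support[:, np.newaxis]) | (
        t[np.newaxis, :] > t[-1] - half_support[:, np.newaxis]
    )
    return SpectralPower(freqs=freqs, power=power, channels=list(channels),
                         sfreq=sfreq, edge_mask=edge)


def alpha_power(sp: SpectralPower, band: tuple[float, float] = (8.0, 12.0),
                window: tuple[float, float] | None = None,
                exclude_edges: bool = False) -> float:
    """Mean power over the band's frequency bins, channels, and window.

    Downstream models receive the natural log of this value.
    """
    f_lo, f_hi = band
    if not (sp.freqs.min() - 1e-9 <= f_lo <= f_hi <= sp.freqs.max() + 1e-9):
        raise ValueError(f"band {band} outside decomposed range "
                         f"[{sp.freqs.min():.1f}, {sp.freqs.max():.1f}] Hz")
    bins = (sp.freqs >= f_lo) & (sp.freqs <= f_hi)
    if not bins.any():
        raise ValueError(f"no frequency bins inside band {band}")
    times = sp.times
    if window is None:
        tsel = np.ones(len(times), dtype=bool)
    else:
        tsel = (times >= window[0]) & (times < window[1])
        if not tsel.any():
            raise ValueError(f"window {window} contains no samples")
    sub = sp.power[:, bins][:, :, tsel]
    if exclude_edges:
        ok = ~sp.edge_mask[bins][:, tsel]
        if not ok.any():
            raise ValueError("window entirely edge-contaminated")
        return float(sub.transpose(1, 2, 0)[ok].mean())
    return float(sub.mean())
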