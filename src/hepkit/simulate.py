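"""Synthetic EEG+ECG sessions with known ground truth.

The generator emulates a wakeful-rest experience-sampling study: a
participant fixates while EEG (31 scalp channels) and ECG are recorded;
at randomized integer intervals of 15-45 s a thought probe collects
0-100 ratings, 10 probes per run, 5 runs, 50 trials in all.

Every quantity the downstream analysis estimates is planted with a known
value, so recovery can be scored exactly:

* ECG is a PQRST train (five Gaussian bumps) on a jittered R-R process;
  R-peak times are recorded as ground truth.
* Each scalp channel carries 1/f noise plus a cardiac-field artifact
  (CFA): the cardiac template scaled by a per-channel gain that decays
  with distance from a posterior source (the ECG lead sits on the back,
  so posterior channels are most contaminated).
* Posterior channels carry amplitude-modulated 10 Hz alpha.
* Frontal channels carry a heartbeat-locked Gaussian bump (the HEP)
  whose per-trial amplitude is ``hep_base_amp + slope_i * latent_t``,
  where ``latent_t`` is an AR(1) trial-level arousal state and
  ``slope_i`` is the participant's arousal sensitivity, optionally
  moderated by trait anxiety.
* Optionally, a probe-locked but *not* heartbeat-locked oscillatory
  component coupled to arousal (``drift_component``) can be injected to
  probe the specificity of surrogate-heartbeat controls.

Observed ratings are ``round(50 + 15 * latent)`` clipped to [0, 100].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import (
    ECG_CHANNEL,
    EEG_CHANNELS,
    FRONTAL_CHANNELS,
    POSTERIOR_CHANNELS,
    standard_positions,
)

RATING_ITEMS = ("arousal", "future", "deliberate", "self", "disengage", "confidence")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration cannot produce a valid session."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Amplitudes are in microvolts; times in seconds; rates in Hz/bpm.
    ``hep_arousal_slope`` is in microvolts per arousal z-unit and is
    negative by default (higher arousal, smaller HEP).
    """

    n_participants: int = 20
    sfreq: float = 250.0
    n_runs: int = 5
    probes_per_run: int = 10
    probe_interval: tuple[int, int] = (15, 45)
    mean_hr: float = 70.0
    ibi_sd: float = 0.06
    cfa_gain_range: tuple[float, float] = (0.002, 0.010)
    hep_latency: float = 0.348
    hep_width: float = 0.012
    hep_base_amp: float = 1.0
    hep_arousal_slope: float = -0.75
    slope_heterogeneity: float = 0.25
    arousal_ar1: float = 0.6
    participant_mean_sd: float = 0.3
    anxiety_moderation: float = 0.3
    alpha_amp: float = 5.0
    noise_exponent: float = 1.0
    noise_rms: float = 10.0
    drift_component: float = 0.0
    drift_freq: float = 1.3
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.probe_interval
        if not (float(lo).is_integer() and float(hi).is_integer()):
            raise ConfigurationError("probe_interval bounds must be integers")
        if not (15 <= lo <= hi <= 45):
            raise ConfigurationError(
                f"probe_interval must lie within [15, 45] s, got {self.probe_interval}"
            )
        if lo < 10:
            raise ConfigurationError("probe interval shorter than the 10 s pre-probe window")
        if self.sfreq < 2 * 55:
            raise ConfigurationError("sfreq must exceed twice the highest simulated frequency")
        if not -1 < self.arousal_ar1 < 1:
            raise ConfigurationError("arousal_ar1 must be in (-1, 1)")
        amps = (
            self.hep_base_amp, self.hep_arousal_slope, self.alpha_amp,
            self.noise_rms, self.drift_component, self.slope_heterogeneity,
            self.anxiety_moderation,
        )
        if not all(np.isfinite(a) for a in amps):
            raise ConfigurationError("all amplitude parameters must be finite")
        if self.mean_hr <= 0 or self.ibi_sd < 0:
            raise ConfigurationError("mean_hr must be positive and ibi_sd non-negative")

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.probes_per_run


@dataclass
class RecordingBundle:
    """Continuous multichannel recording with probe events."""

    data: np.ndarray  # (n_channels, n_samples) microvolts
    channel_names: list[str]
    channel_positions: dict[str, np.ndarray]
    sfreq: float
    probe_onsets: np.ndarray  # seconds, strictly increasing
    run_boundaries: np.ndarray  # run start times, seconds
    participant_id: str

    def __post_init__(self) -> None:
        if list(self.channel_names).count(ECG_CHANNEL) != 1:
            raise ValueError("bundle must contain exactly one ECG channel")
        n_eeg = len(self.channel_names) - 1
        if n_eeg != 31:
            raise ValueError(f"expected 31 EEG channels, got {n_eeg}")
        if np.any(np.diff(self.probe_onsets) <= 0):
            raise ValueError("probe onsets must be strictly increasing")

    @property
    def eeg_names(self) -> list[str]:
        return [c for c in self.channel_names if c != ECG_CHANNEL]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)

    @property
    def ecg(self) -> np.ndarray:
        return self.data[self.channel_index(ECG_CHANNEL)]

    @property
    def eeg(self) -> np.ndarray:
        idx = [self.channel_index(c) for c in self.eeg_names]
        return self.data[idx]

    def run_of_probe(self, probe_idx: int) -> int:
        onset = self.probe_onsets[probe_idx]
        return int(np.searchsorted(self.run_boundaries, onset, side="right") - 1)


@dataclass
class ParticipantProfile:
    """Participant-level latent parameters drawn before signal synthesis."""

    participant_id: str
    anxiety_z: float
    gad7: int
    stai_s: int
    arousal_mean: float
    hep_slope_per_z: float  # microvolts per arousal z-unit, after moderation


@dataclass
class GroundTruth:
    """Everything the analysis should recover, recorded at synthesis time."""

    participant_id: str
    profile: ParticipantProfile
    true_r_peaks: np.ndarray  # sample indices
    trials: pd.DataFrame  # run, trial, probe_onset_s, latent, + rating items
    true_slope_map: np.ndarray  # (n_eeg, n_epoch_samples) microvolts per z
    epoch_times: np.ndarray  # epoch grid, seconds relative to R

    @property
    def trial_arousal_latent(self) -> np.ndarray:
        return self.trials["latent"].to_numpy()

    @property
    def trial_arousal_rating(self) -> np.ndarray:
        return self.trials["arousal"].to_numpy()


# --- building blocks -------------------------------------------------------

# PQRST template: (latency s, width s, amplitude microvolts)
_PQRST = (
    (-0.180, 0.025, 120.0),
    (-0.028, 0.008, -150.0),
    (0.000, 0.010, 900.0),
    (0.030, 0.009, -250.0),
    (0.250, 0.050, 280.0),
)

EPOCH_TMIN = -0.100
EPOCH_TMAX = 0.650


def epoch_time_axis(sfreq: float) -> np.ndarray:
    """Epoch grid ``t = -0.100 + i / sfreq`` with last sample <= +0.650 s."""
    n = int(np.floor((EPOCH_TMAX - EPOCH_TMIN) * sfreq)) + 1
    return EPOCH_TMIN + np.arange(n) / sfreq


def _pqrst_template(sfreq: float) -> tuple[np.ndarray, int]:
    """Sampled PQRST complex; returns (waveform, index of the R sample)."""
    half = int(round(0.45 * sfreq))
    offsets = np.arange(-half, half + 1) / sfreq
    wave = np.zeros_like(offsets)
    for lat, width, amp in _PQRST:
        wave += amp * np.exp(-0.5 * ((offsets - lat) / width) ** 2)
    return wave, half


def _one_over_f_noise(n_samples: int, sfreq: float, exponent: float,
                      rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum and given RMS."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n_samples)
    sd = shaped.std()
    if sd > 0:
        shaped *= rms / sd
    return shaped


def _smooth_envelope(n_samples: int, sfreq: float, rng: np.random.Generator) -> np.ndarray:
    """Slowly varying positive envelope with mean ~1 (alpha waxing/waning)."""
    slow = _one_over_f_noise(n_samples, sfreq, 2.0, 1.0, rng)
    env = 1.0 + 0.4 * slow / max(slow.std(), 1e-12)
    return np.clip(env, 0.1, None)


def _probe_schedule(config: SimConfig, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Absolute probe onsets and run start times, in integer seconds."""
    lo, hi = config.probe_interval
    run_starts = []
    onsets = []
    t = 0.0
    for run in range(config.n_runs):
        run_starts.append(t)
        for _ in range(config.probes_per_run):
            interval = int(rng.integers(lo, hi + 1))
            t += interval
            if t - run_starts[-1] < 10.0:
                raise ConfigurationError(
                    f"run {run}: probe scheduled {t - run_starts[-1]:.0f} s after "
                    "run start, shorter than the 10 s pre-probe window"
                )
            onsets.append(t)
        t += 5.0  # inter-run pause
    return np.asarray(onsets, dtype=float), np.asarray(run_starts, dtype=float)


def _r_peak_times(duration: float, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    mean_ibi = 60.0 / config.mean_hr
    n_max = int(duration / max(mean_ibi - 4 * config.ibi_sd, 0.3)) + 4
    ibis = mean_ibi + config.ibi_sd * rng.standard_normal(n_max)
    ibis = np.clip(ibis, 0.3, None)
    times = 0.5 + np.cumsum(ibis)
    return np.concatenate([[0.5], times[times < duration - 0.5]])


def _latent_arousal(config: SimConfig, mean: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) trial series with stationary unit variance, plus participant mean."""
    phi = config.arousal_ar1
    n = config.n_trials
    innov_sd = np.sqrt(1.0 - phi**2)
    latent = np.empty(n)
    latent[0] = rng.standard_normal()
    for k in range(1, n):
        latent[k] = phi * latent[k - 1] + innov_sd * rng.standard_normal()
    return mean + latent


def latent_to_rating(latent: np.ndarray) -> np.ndarray:
    """Observed 0-100 rating: monotone affine map, rounded and clipped."""
    return np.clip(np.round(50.0 + 15.0 * np.asarray(latent)), 0, 100).astype(int)


def draw_participant_profile(config: SimConfig, participant_index: int,
                             rng: np.random.Generator) -> ParticipantProfile:
    """Draw participant-level parameters (anxiety, arousal sensitivity)."""
    anxiety_z = rng.standard_normal()
    gad7 = int(np.clip(round(8 + 4 * anxiety_z), 0, 21))
    stai_z = 0.6 * anxiety_z + 0.8 * rng.standard_normal()
    stai_s = int(np.clip(round(40 + 10 * stai_z), 20, 80))
    base = config.hep_arousal_slope
    moderation = np.sign(base) if base != 0 else -1.0
    slope = (
        base
        + moderation * config.anxiety_moderation * anxiety_z
        + config.slope_heterogeneity * rng.standard_normal()
    )
    return ParticipantProfile(
        participant_id=f"sub-{participant_index:03d}",
        anxiety_z=float(anxiety_z),
        gad7=gad7,
        stai_s=stai_s,
        arousal_mean=float(config.participant_mean_sd * rng.standard_normal()),
        hep_slope_per_z=float(slope),
    )


def _cfa_gains(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-channel leakage gains decaying with distance from a posterior source."""
    pos = standard_positions()
    source = pos["Oz"] + np.array([0.0, -0.05, -0.08])
    lo, hi = config.cfa_gain_range
    gains = np.empty(len(EEG_CHANNELS))
    for i, ch in enumerate(EEG_CHANNELS):
        d = np.linalg.norm(pos[ch] - source)
        gains[i] = lo + (hi - lo) * np.exp(-(d - 0.10) / 0.08)
    gains = np.clip(gains, lo, hi)
    # small multiplicative jitter keeps gains participant-specific
    gains *= np.exp(0.1 * rng.standard_normal(len(gains)))
    return gains


def simulate_session(config: SimConfig, participant_index: int,
                     rng_seed: int) -> tuple[RecordingBundle, GroundTruth]:
    """Synthesize one participant's continuous recording plus ground truth.

    Identical ``(config, participant_index, rng_seed)`` yields bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(rng_seed)
    profile = draw_participant_profile(config, participant_index, rng)

    probe_onsets, run_starts = _probe_schedule(config, rng)
    duration = probe_onsets[-1] + 10.0
    sfreq = config.sfreq
    n_samples = int(round(duration * sfreq))
    n_eeg = len(EEG_CHANNELS)

    r_times = _r_peak_times(duration, config, rng)
    r_samples = np.round(r_times * sfreq).astype(int)
    r_samples = r_samples[(r_samples >= 0) & (r_samples < n_samples)]
    r_samples = np.unique(r_samples)

    # cardiac trace: PQRST template train
    template, r_off = _pqrst_template(sfreq)
    cardiac = np.zeros(n_samples)
    for p in r_samples:
        a, b = p - r_off, p + r_off + 1
        ta, tb = max(0, -a), len(template) - max(0, b - n_samples)
        cardiac[max(a, 0):min(b, n_samples)] += template[ta:tb]

    data = np.zeros((n_eeg + 1, n_samples))
    ecg_noise = rng.standard_normal(n_samples) * 5.0
    data[n_eeg] = cardiac + ecg_noise

    gains = _cfa_gains(config, rng)
    for i, ch in enumerate(EEG_CHANNELS):
        data[i] = _one_over_f_noise(n_samples, sfreq, config.noise_exponent,
                                    config.noise_rms, rng)
        data[i] += gains[i] * cardiac
        if ch in POSTERIOR_CHANNELS and config.alpha_amp > 0:
            env = _smooth_envelope(n_samples, sfreq, rng)
            phase = rng.uniform(0, 2 * np.pi)
            t = np.arange(n_samples) / sfreq
            data[i] += config.alpha_amp * env * np.sin(2 * np.pi * 10.0 * t + phase)

    # trial-level arousal and ratings
    latent = _latent_arousal(config, profile.arousal_mean, rng)
    trials = pd.DataFrame({
        "run": np.repeat(np.arange(config.n_runs), config.probes_per_run),
        "trial": np.tile(np.arange(config.probes_per_run), config.n_runs),
        "probe_onset_s": probe_onsets,
        "latent": latent,
        "arousal": latent_to_rating(latent),
    })
    for item in RATING_ITEMS[1:]:
        coupled = 0.5 * latent + np.sqrt(1 - 0.5**2) * rng.standard_normal(len(latent))
        trials[item] = latent_to_rating(coupled)

    # heartbeat-locked evoked component at frontal channels
    times = epoch_time_axis(sfreq)
    bump = np.exp(-0.5 * ((times - config.hep_latency) / config.hep_width) ** 2)
    frontal_idx = [EEG_CHANNELS.index(c) for c in FRONTAL_CHANNELS]
    n_ep = len(times)
    start_off = int(round(EPOCH_TMIN * sfreq))

    in_window = np.zeros(len(r_samples), dtype=bool)
    beat_amp = np.full(len(r_samples), config.hep_base_amp)
    for onset, lat in zip(probe_onsets, latent):
        w0, w1 = (onset - 10.0) * sfreq, onset * sfreq
        sel = (r_samples >= w0) & (r_samples < w1)
        beat_amp[sel] = config.hep_base_amp + profile.hep_slope_per_z * lat
        in_window |= sel

    for p, amp in zip(r_samples, beat_amp):
        a = p + start_off
        b = a + n_ep
        if a < 0 or b > n_samples:
            continue
        for ci in frontal_idx:
            data[ci, a:b] += amp * bump

    # optional probe-locked, non-heartbeat-locked arousal-coupled component
    if config.drift_component != 0.0:
        t = np.arange(n_samples) / sfreq
        for onset, lat in zip(probe_onsets, latent):
            a = int(round((onset - 10.0) * sfreq))
            b = int(round(onset * sfreq))
            phase = rng.uniform(0, 2 * np.pi)
            wave = np.sin(2 * np.pi * config.drift_freq * t[a:b] + phase)
            for ci in frontal_idx:
                data[ci, a:b] += config.drift_component * lat * wave

    slope_map = np.zeros((n_eeg, n_ep))
    for ci in frontal_idx:
        slope_map[ci] = profile.hep_slope_per_z * bump

    bundle = RecordingBundle(
        data=data,
        channel_names=list(EEG_CHANNELS) + [ECG_CHANNEL],
        channel_positions=dict(standard_positions()),
        sfreq=sfreq,
        probe_onsets=probe_onsets,
        run_boundaries=run_starts,
        participant_id=profile.participant_id,
    )
    truth = GroundTruth(
        participant_id=profile.participant_id,
        profile=profile,
        true_r_peaks=r_samples,
        trials=trials,
        true_slope_map=slope_map,
        epoch_times=times,
    )
    return bundle, truth


def participant_seed(master_seed: int, participant_index: int) -> int:
    """Deterministic per-participant seed derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, participant_index]).generate_state(1)[0])


def simulate_cohort(config: SimConfig, rng_seed: int | None = None
                    ) -> tuple[list[tuple[RecordingBundle, GroundTruth]], pd.DataFrame]:
    """Simulate ``config.n_participants`` sessions plus a participants table.

    Per-participant seeds are derived deterministically from the master
    seed, so any participant can be regenerated alone via
    ``simulate_session(config, i, participant_seed(master, i))``.
    """
    if config.n_participants < 2:
        raise ConfigurationError("group inference requires at least 2 participants")
    master = config.seed if rng_seed is None else rng_seed
    sessions = [
        simulate_session(config, i, participant_seed(master, i))
        for i in range(config.n_participants)
    ]
    table = pd.DataFrame([
        {
            "participant": truth.participant_id,
            "gad7": truth.profile.gad7,
            "stai_s": truth.profile.stai_s,
            "anxiety_z": truth.profile.anxiety_z,
            "hep_slope_per_z": truth.profile.hep_slope_per_z,
        }
        for _, truth in sessions
    ])
    return sessions, table


def draw_cohort_profiles(config: SimConfig, rng_seed: int | None = None) -> pd.DataFrame:
    """Participant-level ground truth only (no signals), same seeds as the cohort.

    Useful for large calibration studies of participant-level statistics
    (e.g., anxiety moderation of the arousal slope) where synthesizing
    full recordings would be wasteful.
    """
    master = config.seed if rng_seed is None else rng_seed
    rows = []
    for i in range(config.n_participants):
        rng = np.random.default_rng(participant_seed(master, i))
        p = draw_participant_profile(config, i, rng)
        rows.append(dataclasses.asdict(p))
    return pd.DataFrame(rows)
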