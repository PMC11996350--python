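"""Shared fixtures: small simulated cohorts reused across test modules."""

import logging
import warnings

import numpy as np
import pytest

from hepkit import SimConfig, simulate_session, simulate_cohort
from hepkit.hep import extract_preprobe_windows, preprocess
from hepkit.physio import detect_r_peaks
from hepkit.cluster import build_adjacency
from hepkit.surrogate import ParticipantData

logging.getLogger("hepkit").setLevel(logging.ERROR)


def small_config(**overrides) -> SimConfig:
    """2 runs x 5 probes at short intervals: quick but structurally complete."""
    defaults = dict(
        n_participants=6, n_runs=2, probes_per_run=5, probe_interval=(15, 20),
        hep_arousal_slope=-1.5, anxiety_moderation=0.0, slope_heterogeneity=0.2,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def processed_cohort(cfg: SimConfig, seed: int) -> tuple[list[ParticipantData], list, object]:
    """Simulate, preprocess, detect R peaks, and extract windows for a cohort."""
    sessions, participants = simulate_cohort(cfg, seed)
    cohort = []
    truths = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for bundle, truth in sessions:
            rec = preprocess(bundle)
            rpeaks = detect_r_peaks(rec.ecg, rec.sfreq)
            windows = extract_preprobe_windows(rec, truth.trials)
            cohort.append(ParticipantData(rec=rec, windows=windows, rpeaks=rpeaks))
            truths.append(truth)
    return cohort, truths, participants


@pytest.fixture(scope="session")
def session_and_truth():
    """One simulated participant with a strong planted arousal slope."""
    cfg = small_config()
    return simulate_session(cfg, 0, 123), cfg


@pytest.fixture(scope="session")
def cohort6():
    """Six preprocessed participants with a strong planted negative slope."""
    cfg = small_config()
    cohort, truths, participants = processed_cohort(cfg, 77)
    return cfg, cohort, truths, participants


@pytest.fixture(scope="session")
def adjacency31(cohort6):
    _, cohort, _, _ = cohort6
    rec = cohort[0].rec
    return build_adjacency(
        {c: rec.channel_positions[c] for c in rec.eeg_names})


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
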