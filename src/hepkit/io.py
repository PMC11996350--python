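"""File I/O: recording bundles, event tables, ratings, participants.

Recordings are stored as raw little-endian float32 channels x samples
binaries with a JSON sidecar (channel names, 3D positions, sampling
rate, probe events, run boundaries); the round-trip is lossless at
float32 precision. Events are tab-separated, ratings CSV, participants
TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import ECG_CHANNEL
from .simulate import GroundTruth, RecordingBundle

RATING_COLUMNS = ("participant", "run", "trial", "arousal", "future",
                  "deliberate", "self", "disengage", "confidence")


def write_bundle(bundle: RecordingBundle, directory: str | Path) -> Path:
    """Write ``<participant>_eeg.dat`` + ``<participant>_eeg.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = directory / f"{bundle.participant_id}_eeg"
    data32 = np.ascontiguousarray(bundle.data, dtype="<f4")
    data32.tofile(stem.with_suffix(".dat"))
    sidecar = {
        "participant_id": bundle.participant_id,
        "sfreq": bundle.sfreq,
        "channel_names": list(bundle.channel_names),
        "channel_positions": {k: list(map(float, v))
                              for k, v in bundle.channel_positions.items()},
        "n_samples": int(bundle.data.shape[1]),
        "probe_onsets_s": [float(t) for t in bundle.probe_onsets],
        "run_boundaries_s": [float(t) for t in bundle.run_boundaries],
        "dtype": "<f4",
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return stem.with_suffix(".json")


def read_bundle(sidecar_path: str | Path) -> RecordingBundle:
    """Read a bundle from its JSON sidecar path."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    names = meta["channel_names"]
    if ECG_CHANNEL not in names:
        raise ValueError(
            f"sidecar {sidecar_path.name}: required channel {ECG_CHANNEL!r} missing"
        )
    dat_path = sidecar_path.with_suffix(".dat")
    raw = np.fromfile(dat_path, dtype=meta.get("dtype", "<f4"))
    n_ch, n_samp = len(names), meta["n_samples"]
    if raw.size != n_ch * n_samp:
        raise ValueError(
            f"{dat_path.name}: expected {n_ch} x {n_samp} samples, got {raw.size}"
        )
    missing = [c for c in names if c not in meta["channel_positions"]]
    if missing:
        raise ValueError(f"sidecar missing positions for channels {missing}")
    return RecordingBundle(
        data=raw.reshape(n_ch, n_samp).astype(np.float64),
        channel_names=list(names),
        channel_positions={k: np.asarray(v, dtype=float)
                           for k, v in meta["channel_positions"].items()},
        sfreq=float(meta["sfreq"]),
        probe_onsets=np.asarray(meta["probe_onsets_s"], dtype=float),
        run_boundaries=np.asarray(meta["run_boundaries_s"], dtype=float),
        participant_id=meta["participant_id"],
    )


def write_events_tsv(bundle: RecordingBundle, path: str | Path) -> None:
    """Probe events: onset_s, duration_s, run, trial."""
    rows = []
    per_run: dict[int, int] = {}
    for i, onset in enumerate(bundle.probe_onsets):
        run = bundle.run_of_probe(i)
        trial = per_run.get(run, 0)
        per_run[run] = trial + 1
        rows.append({"onset_s": onset, "duration_s": 0.0, "run": run, "trial": trial})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"onset_s", "duration_s", "run", "trial"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: events table missing columns {sorted(missing)}")
    bad = df.index[df["onset_s"].isna() | (df["onset_s"] < 0)]
    if len(bad):
        raise ValueError(f"{path}: malformed onset at data row(s) {list(bad + 2)}")
    return df


def write_ratings_csv(truths: list[GroundTruth], path: str | Path) -> None:
    frames = []
    for truth in truths:
        df = truth.trials[["run", "trial", "arousal", "future", "deliberate",
                           "self", "disengage", "confidence"]].copy()
        df.insert(0, "participant", truth.participant_id)
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False)


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RATING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: ratings table missing columns {sorted(missing)}")
    items = list(RATING_COLUMNS[3:])
    bad_rows = df.index[
        df[items].isna().any(axis=1)
        | (df[items] < 0).any(axis=1) | (df[items] > 100).any(axis=1)
    ]
    if len(bad_rows):
        raise ValueError(
            f"{path}: ratings outside [0, 100] or missing at data row(s) "
            f"{list(bad_rows + 2)}"
        )
    return df


def write_participants_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table[["participant", "gad7", "stai_s"]].to_csv(path, sep="\t", index=False)


def read_participants_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"participant", "gad7", "stai_s"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: participants table missing columns {sorted(missing)}")
    return df


def write_slope_maps(slope_maps, path: str | Path) -> None:
    """Slope maps as a compressed array bundle with a JSON-style manifest."""
    arrays = {f"slopes_{sm.participant_id}": sm.slopes for sm in slope_maps}
    ref = slope_maps[0]
    np.savez_compressed(
        path, times=ref.times,
        manifest=json.dumps({
            "participants": [sm.participant_id for sm in slope_maps],
            "channels": ref.ch_names,
            "n_trials": {sm.participant_id: sm.n_trials for sm in slope_maps},
        }),
        **arrays,
    )
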