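"""Standard channel layout for the 31-scalp-channel + ECG montage.

Scalp labels follow the extended 10/20 system as used by 32-channel
Brain Products caps (one cap position given over to ECG). 3D positions
come from MNE's template montage and are used both by the simulator
(cardiac-field-artifact gains, spatial profile of injected components)
and by cluster inference (channel adjacency).
"""

from __future__ import annotations

import functools

import numpy as np

#: 31 scalp channels, frontal to occipital.
EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2",
)

ECG_CHANNEL = "ECG"

#: Channels carrying the heartbeat-evoked component in the simulator.
FRONTAL_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4", "Fz", "FC1", "FC2")

#: Parieto-occipital channels used for alpha power.
POSTERIOR_CHANNELS: tuple[str, ...] = ("O1", "O2", "Oz", "P3", "P4", "P7", "P8", "Pz")


@functools.lru_cache(maxsize=1)
def standard_positions() -> dict[str, np.ndarray]:
    """3D scalp positions (meters, head frame) for the 31 EEG channels.

    The ECG channel gets a sentinel position well below the head so that
    distance-based adjacency never links it to scalp channels.
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:
            montage = mne.channels.make_standard_montage("standard_1020")
        except ValueError:  # pragma: no cover - montage renamed in newer MNE
            montage = mne.channels.make_standard_montage("colin27_1020")
    ch_pos = montage.get_positions()["ch_pos"]
    pos = {name: np.asarray(ch_pos[name], dtype=float) for name in EEG_CHANNELS}
    pos[ECG_CHANNEL] = np.array([0.0, 0.0, -0.5])
    return pos


def position_array(names: tuple[str, ...] | list[str]) -> np.ndarray:
    """Stack positions for ``names`` into an (n, 3) array."""
    pos = standard_positions()
    return np.stack([pos[n] for n in names])
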