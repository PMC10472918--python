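"""Channel layout for the 21-channel clinical 10-20 montage plus one ECG reference.

Positions are unitless 2D head-schematic coordinates (x: left->right,
y: back->front, nose up), used for neighbor definitions when interpolating
bad channels and for topographic plotting.  They are not digitized electrode
positions and carry no physical unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Standard clinical 10-20 electrode set (21 channels) and schematic coordinates.
_POSITIONS_1020 = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.55), "Fz": (0.0, 0.50),
    "F4": (0.45, 0.55), "F8": (0.81, 0.59),
    "A1": (-1.10, 0.00), "T3": (-1.00, 0.00),
    "C3": (-0.50, 0.00), "Cz": (0.0, 0.00), "C4": (0.50, 0.00),
    "T4": (1.00, 0.00), "A2": (1.10, 0.00),
    "T5": (-0.81, -0.59), "P3": (-0.45, -0.55), "Pz": (0.0, -0.50),
    "P4": (0.45, -0.55), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

EEG_1020_LABELS = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "C3", "C4", "Cz", "T3", "T4", "T5", "T6",
    "P3", "P4", "Pz", "O1", "O2", "A1", "A2",
)


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered EEG channel set plus the single ECG reference channel.

    Parameters
    ----------
    eeg_labels
        Ordered tuple of 21 unique EEG channel names.
    ecg_label
        Name of the ECG reference channel; must not collide with EEG names.
    positions
        Mapping from EEG label to 2D schematic coordinates.
    """

    eeg_labels: tuple[str, ...] = EEG_1020_LABELS
    ecg_label: str = "ECG"
    positions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_POSITIONS_1020)
    )

    def __post_init__(self) -> None:
        if len(self.eeg_labels) != 21:
            raise ConfigurationError(
                f"expected 21 EEG labels, got {len(self.eeg_labels)}"
            )
        if len(set(self.eeg_labels)) != len(self.eeg_labels):
            raise ConfigurationError("EEG labels must be unique")
        if self.ecg_label in self.eeg_labels:
            raise ConfigurationError("ECG label must differ from all EEG labels")
        missing = [l for l in self.eeg_labels if l not in self.positions]
        if missing:
            raise ConfigurationError(f"missing positions for channels: {missing}")

    @property
    def n_eeg(self) -> int:
        return len(self.eeg_labels)

    @property
    def all_labels(self) -> tuple[str, ...]:
        """EEG labels followed by the ECG label (row order of Recording.signal)."""
        return self.eeg_labels + (self.ecg_label,)

    def index(self, label: str) -> int:
        """Row index of an EEG channel in the signal matrix."""
        return self.eeg_labels.index(label)

    def neighbors(self, label: str, k: int = 4) -> tuple[str, ...]:
        """The ``k`` spatially nearest EEG channels to ``label``."""
        x0, y0 = self.positions[label]
        others = [l for l in self.eeg_labels if l != label]
        d = [np.hypot(self.positions[l][0] - x0, self.positions[l][1] - y0)
             for l in others]
        order = np.argsort(d, kind="stable")
        return tuple(others[i] for i in order[:k])


def standard_1020() -> ChannelLayout:
    """The default 21-channel 10-20 layout with an 'ECG' reference channel."""
    return ChannelLayout()
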