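"""Multichannel EEG/EOG recording container, 10-20 layout and scalp ROIs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: 19-channel 10-20 scalp montage used throughout the package.
EEG_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: Horizontal EOG pair (left / right outer canthus).
EOG_PAIR: tuple[str, str] = ("EOGh-L", "EOGh-R")

DEFAULT_LAYOUT: tuple[str, ...] = EEG_1020 + EOG_PAIR

#: Scalp regions-of-interest used for band-power features.  The anterior /
#: posterior split carries the alpha-frontalization contrast; "global" is the
#: whole scalp and feeds the slow-wave (theta/delta) feature.
DEFAULT_ROIS: dict[str, tuple[str, ...]] = {
    "anterior": ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"),
    "posterior": ("T5", "P3", "Pz", "P4", "T6", "O1", "O2"),
    "global": EEG_1020,
}


def normalize_label(label: str) -> str:
    """Strip common modality prefixes and canonicalize 10-20 capitalization."""
    lab = label.strip()
    for prefix in ("EEG ", "EOG ", "eeg ", "eog "):
        if lab.startswith(prefix) and len(lab) > len(prefix):
            lab = lab[len(prefix):]
    by_lower = {c.lower(): c for c in DEFAULT_LAYOUT}
    return by_lower.get(lab.lower(), lab)


@dataclass
class Recording:
    """Voltage matrix (channels x samples, µV) with labels and sampling rate."""

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    eog_pair: tuple[str, str] = EOG_PAIR

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        self.eog_pair = tuple(self.eog_pair)  # type: ignore[assignment]
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("one label per channel row required")
        for lab in self.eog_pair:
            if lab not in self.channel_labels:
                raise ValueError(f"EOG channel {lab!r} missing from recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def eeg_labels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channel_labels if c not in self.eog_pair)

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise ValueError(f"channel {label!r} not in recording") from None
        return self.samples[idx]

    def channels(self, labels) -> np.ndarray:
        return np.stack([self.channel(lab) for lab in labels])

    def copy_with(self, samples: np.ndarray) -> "Recording":
        return Recording(samples=samples, fs=self.fs,
                         channel_labels=self.channel_labels,
                         eog_pair=self.eog_pair)
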