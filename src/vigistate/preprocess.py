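"""Filtering, 1-s segmentation, artifact screening and alpha calibration.

The preprocessing contract mirrors standard resting-state practice: zero-phase
band-pass 0.5-70 Hz plus a 50 Hz notch on the EEG channels, segmentation into
contiguous 1-s epochs, and amplitude-based rejection of epochs containing
circumscribed artifacts.  The EOG channels are low-pass/notch filtered but by
default not high-passed, because sub-0.5 Hz slow eye movements are signal for
the drowsiness stages and would be destroyed by the EEG high-pass.

Per-subject thresholds come from an eyes-closed calibration segment (the
output of a Berger maneuver): the alpha threshold is a configured fraction of
the subject's median posterior alpha power, and subjects whose eyes-closed
alpha is below an absolute floor are flagged as low-voltage (their EEG does
not support alpha-based staging).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import signal as sps

from .recording import Recording, DEFAULT_ROIS

ALPHA_BAND = (8.0, 12.0)
SLOW_BAND = (2.0, 7.0)


@dataclass
class EpochGrid:
    """Contiguous, non-overlapping 1-s epochs with a sticky artifact mask."""

    n_epochs: int
    fs: float
    artifact_mask: np.ndarray
    epoch_length_s: int = 1

    def __post_init__(self) -> None:
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.size != self.n_epochs:
            raise ValueError("mask length must equal epoch count")

    def epoch_slice(self, i: int) -> slice:
        spr = int(round(self.fs))
        return slice(i * spr, (i + 1) * spr)


@dataclass
class CalibrationProfile:
    """Subject-specific thresholds derived from an eyes-closed segment."""

    eyes_closed_alpha_power: float  # µV², median posterior alpha power
    alpha_threshold: float
    slowwave_threshold: float
    low_voltage_flag: bool
    iaf_hz: Optional[float] = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationProfile":
        with open(path) as fh:
            return cls(**json.load(fh))


def _filter_channel_bank(
    x: np.ndarray, fs: float, hp: Optional[float], lp: float, notch: Optional[float]
) -> np.ndarray:
    out = x
    if hp is not None:
        sos_hp = sps.butter(4, hp, btype="highpass", fs=fs, output="sos")
        out = sps.sosfiltfilt(sos_hp, out, axis=-1)
    sos_lp = sps.butter(4, lp, btype="lowpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos_lp, out, axis=-1)
    if notch is not None and notch < fs / 2:
        b, a = sps.iirnotch(notch, Q=30.0, fs=fs)
        out = sps.filtfilt(b, a, out, axis=-1)
    return out


def filter_recording(
    rec: Recording,
    hp: float = 0.5,
    lp: float = 70.0,
    notch: Optional[float] = 50.0,
    hp_eog: Optional[float] = None,
) -> Recording:
    """Zero-phase band-pass + notch filtering.

    EEG channels get the full high-pass/low-pass/notch chain; EOG channels
    get the low-pass and notch but, with the default ``hp_eog=None``, no
    high-pass, preserving slow-eye-movement deflections below 0.5 Hz.
    """
    if lp >= rec.fs / 2:
        raise ValueError(f"low-pass {lp} Hz must lie below Nyquist {rec.fs / 2} Hz")
    if hp <= 0:
        raise ValueError("high-pass cut-off must be positive")
    is_eog = np.array([c in rec.eog_pair for c in rec.channel_labels])
    out = np.empty_like(rec.samples)
    out[~is_eog] = _filter_channel_bank(rec.samples[~is_eog], rec.fs, hp, lp, notch)
    out[is_eog] = _filter_channel_bank(rec.samples[is_eog], rec.fs, hp_eog, lp, notch)
    return rec.copy_with(out)


def segment_epochs(rec: Recording) -> EpochGrid:
    """Cut the recording into contiguous 1-s epochs; a trailing partial
    second is dropped.  Recordings shorter than 1 s cannot be segmented."""
    n_epochs = int(rec.duration_s)  # floor
    if n_epochs < 1:
        raise ValueError("recording shorter than one 1-s epoch")
    return EpochGrid(n_epochs=n_epochs, fs=rec.fs,
                     artifact_mask=np.zeros(n_epochs, dtype=bool))


def screen_artifacts(
    rec: Recording, grid: EpochGrid, amp_limit: float = 200.0
) -> EpochGrid:
    """Flag epochs whose peak-to-peak amplitude on any EEG channel exceeds
    ``amp_limit`` (µV).  Existing flags are sticky — never cleared."""
    if amp_limit <= 0:
        raise ValueError("amplitude limit must be positive")
    eeg = rec.channels(rec.eeg_labels)
    spr = int(round(rec.fs))
    usable = eeg[:, : grid.n_epochs * spr].reshape(eeg.shape[0], grid.n_epochs, spr)
    ptp = usable.max(axis=2) - usable.min(axis=2)
    flagged = (ptp > amp_limit).any(axis=0)
    return EpochGrid(
        n_epochs=grid.n_epochs,
        fs=grid.fs,
        artifact_mask=grid.artifact_mask | flagged,
    )


def band_power_epochs(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Integrated periodogram power (µV²) in ``band`` for each 1-s epoch.

    ``x`` is (channels, samples); returns (channels, n_epochs).  A plain
    (boxcar) periodogram on the 1-s window gives 1 Hz resolution, adequate
    for 4-5 Hz wide bands.
    """
    spr = int(round(fs))
    n_ep = x.shape[-1] // spr
    segs = x[..., : n_ep * spr].reshape(*x.shape[:-1], n_ep, spr)
    freqs = np.fft.rfftfreq(spr, d=1.0 / fs)
    spec = np.fft.rfft(segs, axis=-1)
    # one-sided power spectral density, df = 1 Hz
    psd = (np.abs(spec) ** 2) / (fs * spr)
    psd[..., 1:-1] *= 2.0
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return psd[..., sel].sum(axis=-1) * (fs / spr)


def calibrate(
    segment: Recording,
    f_alpha: float = 0.25,
    f_slow: float = 1.0,
    low_voltage_floor: float = 10.0,
    rois: dict[str, tuple[str, ...]] | None = None,
    estimate_iaf: bool = False,
) -> CalibrationProfile:
    """Derive per-subject thresholds from an eyes-closed calibration segment.

    The reference quantity is the median posterior-ROI alpha power (8-12 Hz,
    µV²) over the segment's 1-s epochs.  ``alpha_threshold`` and
    ``slowwave_threshold`` are the configured fractions of that reference;
    ``low_voltage_flag`` is set when the reference falls below
    ``low_voltage_floor`` (µV²), marking EEGs that cannot be staged by alpha
    criteria.
    """
    if segment.duration_s < 10:
        raise ValueError("calibration segment must span at least 10 s")
    rois = rois or DEFAULT_ROIS
    post = segment.channels(
        [c for c in rois["posterior"] if c in segment.channel_labels]
    )
    if post.size == 0:
        raise ValueError("no posterior channels available for calibration")
    powers = band_power_epochs(post, segment.fs, ALPHA_BAND).mean(axis=0)
    ref = float(np.median(powers))
    low = ref < low_voltage_floor

    iaf = None
    if estimate_iaf and not low:
        spr = int(round(segment.fs))
        freqs, psd = sps.welch(post, fs=segment.fs, nperseg=min(post.shape[1], 4 * spr))
        sel = (freqs >= 7) & (freqs <= 13)
        iaf = float(freqs[sel][psd.mean(axis=0)[sel].argmax()])

    return CalibrationProfile(
        eyes_closed_alpha_power=ref,
        alpha_threshold=f_alpha * ref,
        slowwave_threshold=f_slow * ref,
        low_voltage_flag=bool(low),
        iaf_hz=iaf,
    )
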