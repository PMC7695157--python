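"""Rule-based vigilance staging of 1-s epochs.

Each non-artifact epoch is described by anterior/posterior alpha-band power
(8-12 Hz, or the individual alpha frequency ±2 Hz if calibrated), global
slow-wave power (2-7 Hz), a slow-eye-movement (SEM) flag from the horizontal
EOG pair, and a spindle/K-complex marker flag.  The staging decision is a
fixed precedence ladder:

1. spindle/K-complex marker present      -> C (sleep onset)
2. slow-wave power dominant, alpha below -> B2/3 (theta/delta drowsiness)
3. alpha above threshold                 -> A branch, sub-stage from the
   anterior/posterior power ratio r: r < r1 -> A1; r1 <= r < r2 -> A2;
   r >= r2 -> A3 (increasing frontalization)
4. SEM present                           -> B1 (drowsiness without alpha)
5. otherwise                             -> 0 (activated wakefulness)

Band powers are scalp-ROI means; thresholds come from the subject's
eyes-closed calibration profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import (ALPHA_BAND, SLOW_BAND, CalibrationProfile, EpochGrid,
                         band_power_epochs, filter_recording, screen_artifacts,
                         segment_epochs)
from .recording import DEFAULT_ROIS, Recording
from .stages import StageSequence, score_of


@dataclass(frozen=True)
class SemParams:
    """Slow-eye-movement detector settings: low-pass for the sub-Hz EOG
    component, minimum peak-to-peak deflection (µV), maximum left/right
    correlation (anti-phase means strongly negative), and the context padding
    around each 1-s epoch used to catch deflections that overlap it."""

    lowpass_hz: float = 0.7
    min_amp: float = 25.0
    max_corr: float = -0.5
    pad_s: float = 0.5


@dataclass(frozen=True)
class ClassifierConfig:
    """Cut-points and detector settings of the staging rules.

    ``r1``/``r2`` are the anterior/posterior alpha power-ratio boundaries of
    the A1/A2/A3 frontalization split; alpha and slow-wave thresholds come
    from the calibration profile at classification time.
    """

    r1: float = 0.5
    r2: float = 1.0
    alpha_band: tuple[float, float] = ALPHA_BAND
    slow_band: tuple[float, float] = SLOW_BAND
    sem: SemParams = field(default_factory=SemParams)
    use_iaf: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.r1 < self.r2:
            raise ValueError("need 0 < r1 < r2")


def detect_sem(
    eog_left: np.ndarray,
    eog_right: np.ndarray,
    fs: float,
    n_epochs: Optional[int] = None,
    params: SemParams = SemParams(),
) -> np.ndarray:
    """Flag epochs overlapped by a slow horizontal eye movement.

    Both EOG traces are low-pass filtered below 1 Hz; an epoch is flagged
    when, in its padded window, the slow component shows a deflection of at
    least ``min_amp`` µV peak-to-peak on both traces with an anti-phase
    left/right correlation at or below ``max_corr``.
    """
    spr = int(round(fs))
    if n_epochs is None:
        n_epochs = eog_left.size // spr
    sos = sps.butter(3, params.lowpass_hz, btype="lowpass", fs=fs, output="sos")
    slow_l = sps.sosfiltfilt(sos, eog_left)
    slow_r = sps.sosfiltfilt(sos, eog_right)
    pad = int(params.pad_s * fs)
    flags = np.zeros(n_epochs, dtype=bool)
    for i in range(n_epochs):
        a = max(0, i * spr - pad)
        b = min(slow_l.size, (i + 1) * spr + pad)
        wl, wr = slow_l[a:b], slow_r[a:b]
        if np.ptp(wl) < params.min_amp or np.ptp(wr) < params.min_amp:
            continue
        denom = wl.std() * wr.std()
        if denom == 0:
            continue
        corr = float(np.mean((wl - wl.mean()) * (wr - wr.mean())) / denom)
        flags[i] = corr <= params.max_corr
    return flags


def _roi_channels(rec: Recording, names: Sequence[str]) -> list[str]:
    present = [c for c in names if c in rec.channel_labels]
    if not present:
        raise ValueError(f"no ROI channels among {tuple(names)} present in recording")
    return present


def extract_features(
    rec: Recording,
    grid: EpochGrid,
    rois: dict[str, tuple[str, ...]] | None = None,
    calib: Optional[CalibrationProfile] = None,
    markers: Optional[Sequence[tuple[int, str]]] = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Per-epoch feature table: ROI band powers, SEM flag, marker flag.

    Band powers are periodogram powers on the 1-s epoch averaged over the
    ROI channels (µV²).  Markers are point events (sample_index, type); the
    epoch containing the sample gets the marker flag.
    """
    rois = rois or DEFAULT_ROIS
    if rec.fs < 100:
        raise ValueError("feature extraction requires fs >= 100 Hz")
    alpha_band = config.alpha_band
    if config.use_iaf and calib is not None and calib.iaf_hz is not None:
        alpha_band = (calib.iaf_hz - 2.0, calib.iaf_hz + 2.0)

    ant = rec.channels(_roi_channels(rec, rois["anterior"]))
    post = rec.channels(_roi_channels(rec, rois["posterior"]))
    glob = rec.channels(_roi_channels(rec, rois.get("global", rec.eeg_labels)))

    alpha_ant = band_power_epochs(ant, rec.fs, alpha_band).mean(axis=0)[: grid.n_epochs]
    alpha_post = band_power_epochs(post, rec.fs, alpha_band).mean(axis=0)[: grid.n_epochs]
    slow = band_power_epochs(glob, rec.fs, config.slow_band).mean(axis=0)[: grid.n_epochs]

    sem = detect_sem(rec.channel(rec.eog_pair[0]), rec.channel(rec.eog_pair[1]),
                     rec.fs, n_epochs=grid.n_epochs, params=config.sem)

    marker_flag = np.array(["none"] * grid.n_epochs, dtype=object)
    spr = int(round(rec.fs))
    for sample, kind in (markers or []):
        ep = int(sample) // spr
        if 0 <= ep < grid.n_epochs:
            marker_flag[ep] = kind.lower()

    return pd.DataFrame(
        {
            "alpha_power_anterior": alpha_ant,
            "alpha_power_posterior": alpha_post,
            "slowwave_power": slow,
            "sem_flag": sem,
            "marker_flag": marker_flag,
            "artifact": grid.artifact_mask,
        }
    )


def classify_epoch(
    features, calib: CalibrationProfile, config: ClassifierConfig = ClassifierConfig()
) -> str:
    """Stage one epoch's feature row; artifact epochs must be masked upstream."""
    if features["artifact"]:
        raise ValueError("cannot classify an artifact epoch; mask it upstream")
    if features["marker_flag"] != "none":
        return "C"
    a_ant = float(features["alpha_power_anterior"])
    a_post = float(features["alpha_power_posterior"])
    slow = float(features["slowwave_power"])
    alpha = max(a_ant, a_post)
    if slow >= calib.slowwave_threshold and alpha < calib.alpha_threshold:
        return "B23"
    if alpha >= calib.alpha_threshold:
        r = a_ant / a_post if a_post > 0 else np.inf
        if r < config.r1:
            return "A1"
        if r < config.r2:
            return "A2"
        return "A3"
    if features["sem_flag"]:
        return "B1"
    return "0"


def classify_features(
    feats: pd.DataFrame,
    calib: CalibrationProfile,
    config: ClassifierConfig = ClassifierConfig(),
) -> StageSequence:
    """Stage every non-artifact epoch of a feature table."""
    mask = feats["artifact"].to_numpy(dtype=bool)
    scores = np.ones(len(feats), dtype=np.int8)
    for i, (_, row) in enumerate(feats.iterrows()):
        if not mask[i]:
            scores[i] = score_of(classify_epoch(row, calib, config))
    return StageSequence(scores=scores, artifact_mask=mask)


def classify_recording(
    rec: Recording,
    calib: CalibrationProfile,
    markers: Optional[Sequence[tuple[int, str]]] = None,
    config: ClassifierConfig = ClassifierConfig(),
    rois: dict[str, tuple[str, ...]] | None = None,
    amp_limit: float = 200.0,
    prefilter: bool = True,
) -> StageSequence:
    """Full staging chain for one raw recording.

    Filters (EEG band-pass + notch; EOG without high-pass), segments into
    1-s epochs, screens amplitude artifacts, extracts features and applies
    the staging rules.  Low-voltage subjects (per calibration) are rejected:
    their EEG cannot be staged by alpha criteria.
    """
    if calib.low_voltage_flag:
        raise ValueError("low-voltage EEG: subject not stageable by alpha criteria")
    work = filter_recording(rec) if prefilter else rec
    grid = segment_epochs(work)
    grid = screen_artifacts(work, grid, amp_limit=amp_limit)
    feats = extract_features(work, grid, rois=rois, calib=calib,
                             markers=markers, config=config)
    return classify_features(feats, calib, config)


def detect_events_auto(
    rec: Recording, config: ClassifierConfig = ClassifierConfig()
) -> list[tuple[int, str]]:
    """Heuristic spindle/K-complex detector for synthetic data.

    This is *not* the canonical marking route (markers are normally set by a
    human scorer and read from a file); it exists so fully automatic runs on
    generated recordings are possible.  Spindles: 12-15 Hz bursts whose
    band-limited envelope exceeds 15 µV for 0.4-1.2 s on central channels.
    K-complexes: biphasic 0.5-2 Hz deflections exceeding 50 µV peak-to-peak
    within a 1-s window on fronto-central channels.
    """
    fs = rec.fs
    central = [c for c in ("C3", "Cz", "C4") if c in rec.channel_labels]
    x = rec.channels(central).mean(axis=0)
    sos = sps.butter(4, (12.0, 15.0), btype="bandpass", fs=fs, output="sos")
    sigma = sps.sosfiltfilt(sos, x)
    env = np.abs(sps.hilbert(sigma))
    above = env > 10.0
    events: list[tuple[int, str]] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for a, b in zip(edges[::2], edges[1::2]):
        if 0.3 * fs <= (b - a) <= 1.5 * fs:
            events.append(((a + b) // 2, "SPINDLE"))
    fc = [c for c in ("F3", "Fz", "F4", "Cz") if c in rec.channel_labels]
    y = rec.channels(fc).mean(axis=0)
    sos_k = sps.butter(3, (0.5, 2.0), btype="bandpass", fs=fs, output="sos")
    slow = sps.sosfiltfilt(sos_k, y)
    spr = int(round(fs))
    spindle_epochs = {s // spr for s, _ in events}
    for ep in range(rec.n_samples // spr):
        if ep in spindle_epochs:
            continue
        w = slow[ep * spr:(ep + 1) * spr]
        if np.ptp(w) > 50.0 and w.max() > 10 and w.min() < -10:
            events.append((ep * spr + spr // 2, "KCOMPLEX"))
    return sorted(events)
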