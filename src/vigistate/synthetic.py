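"""Synthetic stage courses, EEG/EOG signals and cohort tables.

The generator exists so the whole analysis chain — staging, stability
scoring, prototype assignment, cohort statistics — can be exercised and
validated on known ground truth.  Three layers:

* :func:`simulate_stage_course` realizes the four verbal arousal-regulation
  prototypes (adaptive, unstable, stable, hyperstable) as minute-level
  Markov chains over the 7-stage ladder, expanded to seconds with boundary
  jitter.
* :func:`simulate_recording` renders a stage course as a 10-20 multichannel
  voltage matrix whose per-second spectral content matches the planted
  stage: occipital-dominant alpha in A1, progressively frontalized alpha in
  A2/A3, theta-delta dominance in B2/3, low-voltage EEG with anti-phase
  slow eye movements in B1, and spindle/K-complex events (with emitted
  markers) in C.
* :func:`simulate_cohort` draws regulation types per group, simulates
  courses, and generates covariates from a linear model on the realized
  arousal stability score.

One integer seed governs everything through ``numpy.random.SeedSequence``
spawning, so a fixed seed reproduces whole cohorts bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import Recording, DEFAULT_LAYOUT, EOG_PAIR
from .stages import SCORE_OF, StageSequence

REGULATION_TYPES: tuple[str, ...] = ("adaptive", "unstable", "stable", "hyperstable")

_B23 = SCORE_OF["B23"]
_C = SCORE_OF["C"]


# --------------------------------------------------------------------------
# stage-course simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StageCourseParams:
    """Minute-level Markov-chain parameters for one regulation type.

    ``descend`` / ``ascend`` are per-minute probabilities of moving one stage
    down (toward sleep) or up; ``floor`` and ``ceiling`` are numeric-score
    bounds confining the chain (the hyperstable floor of 6 restricts it to
    stages 0/A1); ``c_entry`` is the per-minute probability that a B2/3
    minute contains C seconds (spindle/K-complex events); ``dwell_jitter_s``
    randomizes minute boundaries when expanding to seconds.
    """

    descend: float
    ascend: float
    floor: int = 2
    ceiling: int = 7
    start: int = 6
    c_entry: float = 0.0
    c_seconds: tuple[int, int] = (1, 3)
    dwell_jitter_s: int = 8

    def __post_init__(self) -> None:
        for name in ("descend", "ascend", "c_entry"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if not 1 <= self.floor <= self.start <= self.ceiling <= 7:
            raise ValueError("need 1 <= floor <= start <= ceiling <= 7")


#: Default chain parameters per regulation type.  Chosen so the expected
#: minute course matches each verbal prototype: hyperstable never leaves
#: 0/A1; stable settles in the A stages without reaching B or C; adaptive
#: declines gradually across the 20 minutes; unstable collapses into the B
#: stages within the first quartile in well over 90% of runs.
DEFAULT_COURSE_PARAMS: dict[str, StageCourseParams] = {
    "adaptive": StageCourseParams(descend=0.26, ascend=0.02, floor=2, c_entry=0.12),
    "unstable": StageCourseParams(descend=0.88, ascend=0.01, floor=2, c_entry=0.12),
    "stable": StageCourseParams(descend=0.35, ascend=0.35, floor=4, ceiling=6,
                                start=5),
    "hyperstable": StageCourseParams(descend=0.30, ascend=0.08, floor=6),
}


def _check_reg_type(reg_type: str) -> str:
    if reg_type not in REGULATION_TYPES:
        raise ValueError(
            f"unknown regulation type {reg_type!r}; "
            f"expected one of {REGULATION_TYPES}"
        )
    return reg_type


def simulate_minute_chain(
    params: StageCourseParams, duration_min: int, rng: np.random.Generator
) -> np.ndarray:
    """One numeric stage score per minute, from the bounded random walk."""
    scores = np.empty(duration_min, dtype=np.int8)
    s = params.start
    for m in range(duration_min):
        scores[m] = s
        u = rng.random()
        if u < params.descend:
            if s > params.floor:  # blocked attempts leave the state unchanged
                s -= 1
        elif u < params.descend + params.ascend:
            if s < params.ceiling:
                s += 1
    return scores


def simulate_stage_course(
    reg_type: str,
    params: Optional[StageCourseParams] = None,
    duration_min: int = 20,
    seed: int | np.random.SeedSequence = 0,
) -> StageSequence:
    """Simulate a per-second stage course for one regulation type.

    Returns a :class:`StageSequence` of ``duration_min * 60`` seconds with an
    all-false artifact mask.  Minute-level chain states are expanded to
    seconds with jittered block boundaries; C seconds are then planted inside
    B2/3 minutes according to ``c_entry``.
    """
    _check_reg_type(reg_type)
    if params is None:
        params = DEFAULT_COURSE_PARAMS[reg_type]
    if duration_min < 4:
        raise ValueError("duration_min must be at least 4 minutes")
    rng = np.random.default_rng(seed)

    minutes = simulate_minute_chain(params, duration_min, rng)

    # jittered minute boundaries (first/last fixed)
    bounds = np.arange(duration_min + 1) * 60
    if params.dwell_jitter_s > 0 and duration_min > 1:
        j = rng.integers(-params.dwell_jitter_s, params.dwell_jitter_s + 1,
                         size=duration_min - 1)
        bounds[1:-1] = bounds[1:-1] + j
    seconds = np.empty(duration_min * 60, dtype=np.int8)
    for m in range(duration_min):
        seconds[bounds[m]:bounds[m + 1]] = minutes[m]

    # plant C events strictly within their minute's nominal window so that
    # quartile attribution matches the minute-level chain
    for m in np.flatnonzero(minutes == _B23):
        if rng.random() < params.c_entry:
            k = rng.integers(params.c_seconds[0], params.c_seconds[1] + 1)
            idx = rng.choice(60, size=int(k), replace=False) + 60 * m
            seconds[idx] = _C
    return StageSequence(scores=seconds)


def block_course(blocks: list[tuple[str, int]]) -> StageSequence:
    """Deterministic course from (stage_label, n_seconds) blocks — handy for
    constructing recall fixtures and worked examples."""
    labels: list[str] = []
    for lab, n in blocks:
        labels.extend([lab] * int(n))
    return StageSequence.from_labels(labels)


# --------------------------------------------------------------------------
# signal synthesis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalParams:
    """Amplitude recipe (µV) of the stage-conditional signal generator.

    Alpha entries give the posterior-ROI alpha rms and the target
    anterior/posterior alpha *power* ratio per A sub-stage; amplitudes are
    set so default classifier thresholds separate the stages with a wide
    margin at 1-s periodogram resolution.
    """

    background_rms: float = 10.0
    alpha: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "A1": (18.0, 0.20),
            "A2": (16.0, 0.70),
            "A3": (13.0, 1.50),
        }
    )
    slow_rms_b23: float = 30.0
    slow_rms_c: float = 12.0
    sem_freq_hz: float = 0.3
    sem_amp: float = 100.0
    spindle_freq_hz: float = 13.0
    spindle_dur_s: float = 0.7
    spindle_amp: float = 30.0
    kcomplex_dur_s: float = 1.0
    kcomplex_amp: float = 75.0
    snr_scale: float = 1.0  # multiplies every non-background amplitude


_ANTERIOR = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")
_POSTERIOR = ("T5", "P3", "Pz", "P4", "T6", "O1", "O2")
_CENTRAL = ("C3", "Cz", "C4", "Pz")
_FRONTOCENTRAL = ("F3", "Fz", "F4", "Cz")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-rms 1/f-shaped noise (flat below 1 Hz bin)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = 1.0 / np.sqrt(np.maximum(f, f[1] if n > 1 else 1.0))
    spec *= scale
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    sos = sps.butter(6, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def simulate_recording(
    course: StageSequence,
    layout: tuple[str, ...] = DEFAULT_LAYOUT,
    fs: float = 200.0,
    seed: int | np.random.SeedSequence = 0,
    params: Optional[SignalParams] = None,
) -> tuple[Recording, list[tuple[int, str]]]:
    """Render a stage course as a multichannel recording plus event markers.

    Returns ``(recording, markers)`` where markers is a list of
    ``(sample_index, type)`` with type in {"SPINDLE", "KCOMPLEX"}; exactly
    one event is emitted per C second.
    """
    params = params or SignalParams()
    if course.n_seconds < 1:
        raise ValueError("empty stage course")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("fs must be a positive integer sampling rate")
    eog = [c for c in layout if "eog" in c.lower()]
    if len(eog) < 2:
        raise ValueError("layout must include a horizontal EOG pair")
    eog_pair = (eog[0], eog[1])
    for roi in (_ANTERIOR, _POSTERIOR):
        if not any(c in layout for c in roi):
            raise ValueError("layout must cover anterior and posterior regions")

    spr = int(round(fs))
    n_sec = course.n_seconds
    n = n_sec * spr
    rng = np.random.default_rng(seed)
    ch_index = {c: i for i, c in enumerate(layout)}
    labels = np.array(course.labels)
    snr = params.snr_scale

    data = np.empty((len(layout), n))
    for i in range(len(layout)):
        data[i] = params.background_rms * _pink_noise(n, rng)

    # ---- alpha: one coherent carrier, per-second region gains ------------
    carrier = _band_noise(n, fs, (8.0, 12.0), rng)
    g_post = np.zeros(n_sec)
    g_ant = np.zeros(n_sec)
    for stage, (post_rms, power_ratio) in params.alpha.items():
        sel = labels == stage
        g_post[sel] = post_rms * snr
        g_ant[sel] = post_rms * np.sqrt(power_ratio) * snr
    alpha_post = np.repeat(g_post, spr) * carrier
    alpha_ant = np.repeat(g_ant, spr) * carrier
    for c in _POSTERIOR:
        if c in ch_index:
            data[ch_index[c]] += alpha_post
    for c in _ANTERIOR:
        if c in ch_index:
            data[ch_index[c]] += alpha_ant

    # ---- theta/delta dominance in B2/3 (global), mild slow in C ----------
    slow = _band_noise(n, fs, (2.0, 7.0), rng)
    g_slow = np.zeros(n_sec)
    g_slow[labels == "B23"] = params.slow_rms_b23 * snr
    g_slow[labels == "C"] = params.slow_rms_c * snr
    slow_sig = np.repeat(g_slow, spr) * slow
    for c in layout:
        if c not in eog_pair:
            data[ch_index[c]] += slow_sig

    # ---- slow horizontal eye movements in B1 (anti-phase EOG) ------------
    b1 = labels == "B1"
    if b1.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([0], b1.view(np.int8), [0]))))
        for s0, s1 in zip(edges[::2], edges[1::2]):
            t = np.arange((s1 - s0) * spr) / fs
            wave = params.sem_amp * snr * np.sin(2 * np.pi * params.sem_freq_hz * t)
            data[ch_index[eog_pair[0]], s0 * spr:s1 * spr] += wave
            data[ch_index[eog_pair[1]], s0 * spr:s1 * spr] -= wave

    # ---- spindles / K-complexes in C seconds, with markers ---------------
    markers: list[tuple[int, str]] = []
    for sec in np.flatnonzero(labels == "C"):
        kind = "SPINDLE" if rng.random() < 0.6 else "KCOMPLEX"
        if kind == "SPINDLE":
            dur = int(params.spindle_dur_s * fs)
            t = np.arange(dur) / fs
            ev = (params.spindle_amp * snr * np.hanning(dur)
                  * np.sin(2 * np.pi * params.spindle_freq_hz * t))
            chans = _CENTRAL
        else:
            dur = int(params.kcomplex_dur_s * fs)
            t = np.arange(dur) / fs
            ev = (params.kcomplex_amp * snr * np.hanning(dur)
                  * np.sin(2 * np.pi * t / params.kcomplex_dur_s))
            chans = _FRONTOCENTRAL
        start = sec * spr + (spr - dur) // 2
        for c in chans:
            if c in ch_index:
                data[ch_index[c], start:start + dur] += ev
        markers.append((start + dur // 2, kind))

    rec = Recording(samples=data, fs=fs, channel_labels=tuple(layout),
                    eog_pair=eog_pair)
    return rec, markers


def simulate_calibration_segment(
    duration_s: int = 30,
    fs: float = 200.0,
    seed: int | np.random.SeedSequence = 1,
    params: Optional[SignalParams] = None,
) -> Recording:
    """Eyes-closed calibration segment: pure A1-like occipital alpha."""
    course = block_course([("A1", duration_s)])
    rec, _ = simulate_recording(course, fs=fs, seed=seed, params=params)
    return rec


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateSpec:
    """Linear model ``value = intercept + slope * ASS + N(0, sd)``, clipped."""

    intercept: float
    slope: float
    sd: float
    lo: Optional[float] = None
    hi: Optional[float] = None


#: Default regulation-type mixtures: a hyperstable/stable-enriched patient
#: group versus adaptive-dominated controls.
DEFAULT_MIXTURES: dict[str, dict[str, float]] = {
    "patient": {"adaptive": 0.15, "unstable": 0.05, "stable": 0.40,
                "hyperstable": 0.40},
    "control": {"adaptive": 0.55, "unstable": 0.30, "stable": 0.10,
                "hyperstable": 0.05},
}

#: Default covariate model: stability (high ASS) goes with lower sleep
#: efficiency, more nocturnal wake and arousals, and higher insomnia /
#: stress-reactivity scores, with noise levels giving cohort means and
#: spreads in the range reported for clinical insomnia samples.
DEFAULT_COVARIATE_MODEL: dict[str, CovariateSpec] = {
    "sleep_efficiency": CovariateSpec(95.0, -1.5, 8.0, 0.0, 100.0),
    "arousal_index": CovariateSpec(4.0, 0.9, 4.0, 0.0, None),
    "waso": CovariateSpec(0.0, 6.5, 25.0, 0.0, None),
    "total_sleep_time": CovariateSpec(430.0, -7.0, 40.0, 0.0, None),
    "isi": CovariateSpec(-3.0, 1.4, 3.0, 0.0, 28.0),
    "psrs23": CovariateSpec(11.0, 1.0, 5.0, 0.0, None),
    "aps": CovariateSpec(24.0, 0.7, 4.0, 0.0, None),
}


@dataclass
class CohortSpec:
    """Group sizes, regulation-type mixtures and the covariate model."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"patient": 34, "control": 25})
    group_mixtures: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(m) for g, m in DEFAULT_MIXTURES.items()})
    duration_min: int = 20
    covariate_model: dict[str, CovariateSpec] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MODEL))
    course_params: dict[str, StageCourseParams] = field(
        default_factory=lambda: dict(DEFAULT_COURSE_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.n_per_group) != set(self.group_mixtures):
            raise ValueError("group names of n_per_group and group_mixtures differ")
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"group {g!r} must have at least one subject")
        for g, mix in self.group_mixtures.items():
            for t in mix:
                _check_reg_type(t)
            tot = sum(mix.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"mixture of group {g!r} sums to {tot}, not 1")
        if self.duration_min < 4 or self.duration_min % 4:
            raise ValueError("duration_min must be >= 4 and divisible by 4")
        for name, cv in self.covariate_model.items():
            if cv.sd == 0 and cv.slope != 0:
                warnings.warn(
                    f"covariate {name!r} has zero noise with a nonzero slope; "
                    "it will be a deterministic function of the ASS",
                    stacklevel=2,
                )


@dataclass
class CohortResult:
    """Subject table plus the per-subject ground-truth stage courses."""

    table: pd.DataFrame
    courses: dict[str, StageSequence]


def simulate_cohort(spec: CohortSpec) -> CohortResult:
    """Simulate a full cohort: courses, stability metrics and covariates.

    The subject table records the planted regulation type next to the
    realized ASS/MVV and the covariates drawn from the linear model, so
    recovery of both the types and the covariate structure can be checked
    against ground truth.
    """
    from . import metrics  # local import: metrics does not import synthetic

    root = np.random.SeedSequence(spec.seed)
    rows = []
    courses: dict[str, StageSequence] = {}
    for group in sorted(spec.n_per_group):
        n = spec.n_per_group[group]
        mix = spec.group_mixtures[group]
        types = list(mix)
        probs = np.array([mix[t] for t in types])
        for i, ss in enumerate(root.spawn(n)):
            sid = f"{group}_{i:03d}"
            s_type, s_course, s_cov = ss.spawn(3)
            reg = types[np.random.default_rng(s_type).choice(len(types), p=probs)]
            course = simulate_stage_course(
                reg, spec.course_params[reg], spec.duration_min, seed=s_course)
            ass = metrics.arousal_stability_score(course)
            mvv = metrics.mean_vigilance_value(course)
            c_count = int((course.clean_scores() == _C).sum())
            rng_cov = np.random.default_rng(s_cov)
            covs = {}
            for name, cv in spec.covariate_model.items():
                val = cv.intercept + cv.slope * ass.score + rng_cov.normal(0, cv.sd)
                covs[name] = float(np.clip(
                    val,
                    -np.inf if cv.lo is None else cv.lo,
                    np.inf if cv.hi is None else cv.hi,
                ))
            rows.append(dict(subject_id=sid, group=group, true_type=reg,
                             ass=ass.score, mvv_total=mvv.total,
                             c_stage_count=c_count, **covs))
            courses[sid] = course
    return CohortResult(table=pd.DataFrame(rows), courses=courses)
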