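"""EDF (European Data Format) input/output.

Reading goes through MNE's native EDF reader.  Writing uses a small 16-bit
EDF writer implemented here: one data record per second, physical units µV.
The writer covers exactly what this package produces (continuous EEG/EOG at
a single sampling rate); it is not a general-purpose EDF library.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .recording import Recording, normalize_label, EOG_PAIR

_PHYS_MIN, _PHYS_MAX = -2000.0, 2000.0  # µV
_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path) -> None:
    """Write a recording as 16-bit EDF, one 1-s data record per second.

    Trailing samples beyond the last full second are dropped (EDF records
    must be complete).  Voltages outside ±2000 µV are clipped.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    ns = rec.n_channels

    hdr = bytearray()
    hdr += _pad("0", 8)                             # version
    hdr += _pad("X X X X", 80)                      # patient id (anonymous)
    hdr += _pad("Startdate X X X X", 80)            # recording id
    t0 = _dt.datetime(2000, 1, 1)
    hdr += _pad(t0.strftime("%d.%m.%y"), 8)
    hdr += _pad(t0.strftime("%H.%M.%S"), 8)
    hdr += _pad(str(256 * (1 + ns)), 8)             # header bytes
    hdr += _pad("", 44)                             # reserved
    hdr += _pad(str(n_records), 8)
    hdr += _pad("1", 8)                             # record duration (s)
    hdr += _pad(str(ns), 4)

    for lab in rec.channel_labels:
        hdr += _pad(lab, 16)
    for _ in range(ns):
        hdr += _pad("AgAgCl electrode", 80)         # transducer
    for _ in range(ns):
        hdr += _pad("uV", 8)
    for _ in range(ns):
        hdr += _pad(f"{_PHYS_MIN:g}", 8)
    for _ in range(ns):
        hdr += _pad(f"{_PHYS_MAX:g}", 8)
    for _ in range(ns):
        hdr += _pad(str(_DIG_MIN), 8)
    for _ in range(ns):
        hdr += _pad(str(_DIG_MAX), 8)
    for _ in range(ns):
        hdr += _pad("", 80)                         # prefiltering
    for _ in range(ns):
        hdr += _pad(str(spr), 8)
    for _ in range(ns):
        hdr += _pad("", 32)                         # reserved

    gain = (_DIG_MAX - _DIG_MIN) / (_PHYS_MAX - _PHYS_MIN)
    clipped = np.clip(rec.samples[:, : n_records * spr], _PHYS_MIN, _PHYS_MAX)
    digital = np.round((clipped - _PHYS_MIN) * gain + _DIG_MIN).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        # record-major interleaving: for each second, each channel's block
        blocks = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(blocks).tobytes())


def read_recording(path, eog_pair: tuple[str, str] | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` (voltages in µV).

    Channel labels are normalized to plain 10-20 names; the EOG pair is
    auto-detected from labels containing ``EOG`` unless given explicitly.
    Missing EOG channels raise a :class:`ValueError` naming the channel.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = tuple(normalize_label(c) for c in raw.ch_names)
    data = raw.get_data() * 1e6  # MNE returns volts

    if eog_pair is None:
        eogs = [c for c in labels if "eog" in c.lower()]
        if len(eogs) >= 2:
            eog_pair = (eogs[0], eogs[1])
        else:
            eog_pair = EOG_PAIR
    for lab in eog_pair:
        if lab not in labels:
            raise ValueError(f"required EOG channel {lab!r} not found in {path}")
    return Recording(samples=data, fs=float(raw.info["sfreq"]),
                     channel_labels=labels, eog_pair=eog_pair)


def write_markers(markers, path) -> None:
    """Write spindle/K-complex markers as two-column text (sample_index, type)."""
    with open(path, "w") as fh:
        fh.write("sample_index\tmarker_type\n")
        for sample, kind in markers:
            fh.write(f"{int(sample)}\t{kind}\n")


def read_markers(path) -> list[tuple[int, str]]:
    out: list[tuple[int, str]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("sample_index"):
            fh.seek(0)
        for line in fh:
            if not line.strip():
                continue
            sample, kind = line.split()
            kind = kind.upper()
            if kind not in ("SPINDLE", "KCOMPLEX"):
                raise ValueError(f"unknown marker type {kind!r}")
            out.append((int(sample), kind))
    return out
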