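"""Vigilance stage ladder and per-second stage sequences.

Seven stages span the continuum from activated wakefulness to sleep onset.
Each stage carries a fixed numeric score used for mean-vigilance averaging:

====== ===== =========================================================
label  score phenomenology
====== ===== =========================================================
0        7   activated wake, low-amplitude desynchronized EEG
A1       6   relaxed wake, dominant occipital alpha
A2       5   alpha partly frontalized, reduced amplitude
A3       4   alpha predominantly fronto-temporal
B1       3   drowsiness, low-voltage non-alpha EEG with slow eye movements
B23      2   drowsiness dominated by theta/delta activity
C        1   sleep onset, marked by spindles or K-complexes
====== ===== =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Stage labels ordered by ascending numeric score (C=1 ... 0=7).
STAGE_ORDER: tuple[str, ...] = ("C", "B23", "B1", "A3", "A2", "A1", "0")

#: label -> numeric vigilance score (1..7)
SCORE_OF: dict[str, int] = {lab: i + 1 for i, lab in enumerate(STAGE_ORDER)}

#: numeric score -> label
LABEL_OF: dict[int, str] = {v: k for k, v in SCORE_OF.items()}

#: Reporting categories with A2/A3 merged, as used in amount tables.
REPORT_CATEGORIES: tuple[str, ...] = ("0", "A1", "A2/3", "B1", "B2/3", "C")

_REPORT_OF = {"0": "0", "A1": "A1", "A2": "A2/3", "A3": "A2/3",
              "B1": "B1", "B23": "B2/3", "C": "C"}


def score_of(label: str) -> int:
    """Numeric score of a stage label; raises for unknown labels."""
    try:
        return SCORE_OF[label]
    except KeyError:
        raise ValueError(
            f"unknown vigilance stage {label!r}; expected one of {STAGE_ORDER}"
        ) from None


def report_category(label: str) -> str:
    """Map a stage label to its reporting category (A2 and A3 merge to A2/3)."""
    return _REPORT_OF[label]


@dataclass
class StageSequence:
    """Per-second vigilance stages plus an artifact mask.

    ``scores`` holds the numeric score (1..7) of each second; entries under
    the artifact mask carry no stage information and are ignored by every
    downstream metric.
    """

    scores: np.ndarray
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    epoch_length_s: int = 1

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int8)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.scores.shape, dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.scores.ndim != 1:
            raise ValueError("scores must be one-dimensional")
        if self.artifact_mask.shape != self.scores.shape:
            raise ValueError("artifact mask length must equal sequence length")
        clean = self.scores[~self.artifact_mask]
        if clean.size and (clean.min() < 1 or clean.max() > 7):
            raise ValueError("non-artifact scores must lie in 1..7")

    @classmethod
    def from_labels(
        cls,
        labels: Sequence[str] | Iterable[str],
        artifact_mask: Sequence[bool] | None = None,
    ) -> "StageSequence":
        labels = list(labels)
        mask = (np.zeros(len(labels), dtype=bool) if artifact_mask is None
                else np.asarray(artifact_mask, dtype=bool))
        scores = np.array(
            [score_of(lab) if not m else 1 for lab, m in zip(labels, mask)],
            dtype=np.int8,
        )
        return cls(scores=scores, artifact_mask=mask)

    @property
    def n_seconds(self) -> int:
        return int(self.scores.size)

    @property
    def n_minutes(self) -> int:
        """Number of complete minutes covered by the sequence."""
        return self.n_seconds // 60

    @property
    def labels(self) -> list[str]:
        """Stage labels; artifact seconds are reported as ``'ART'``."""
        return ["ART" if m else LABEL_OF[int(s)]
                for s, m in zip(self.scores, self.artifact_mask)]

    def clean_scores(self) -> np.ndarray:
        """Scores of non-artifact seconds only."""
        return self.scores[~self.artifact_mask]

    def minute_slices(self) -> list[slice]:
        """Slices delimiting each complete minute."""
        return [slice(60 * m, 60 * (m + 1)) for m in range(self.n_minutes)]

    def to_frame(self):
        """Tab-separated-friendly table (second_index, stage_label, artifact)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "second_index": np.arange(self.n_seconds),
                "stage_label": self.labels,
                "artifact_flag": self.artifact_mask.astype(int),
            }
        )

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "StageSequence":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"stage_label": str})
        mask = df["artifact_flag"].to_numpy().astype(bool)
        labels = ["A1" if m else lab for lab, m in zip(df["stage_label"], mask)]
        return cls.from_labels(labels, mask)
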