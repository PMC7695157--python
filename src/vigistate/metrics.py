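"""Stage amounts, mean vigilance value (MVV) and arousal stability score (ASS).

All metrics operate on a :class:`~vigistate.stages.StageSequence` and use only
its non-artifact seconds.  Percent amounts are normalised by the number of
non-artifact seconds in the window; minute-block criteria use inclusive
("at least") fraction boundaries; the ASS summarises in which of four
consecutive quartiles of the recording the vigilance decline first reaches a
given depth, on a 1-14 scale where higher means more stable arousal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .stages import SCORE_OF, REPORT_CATEGORIES, StageSequence

# score groups used by the minute criteria
_SCORES_0A = {SCORE_OF[s] for s in ("0", "A1", "A2", "A3")}
_SCORES_0A1 = {SCORE_OF["0"], SCORE_OF["A1"]}
_SCORES_B = {SCORE_OF["B1"], SCORE_OF["B23"]}
_SCORE_B23 = SCORE_OF["B23"]
_SCORE_C = SCORE_OF["C"]

_CAT_OF_SCORE = {
    SCORE_OF["0"]: "0",
    SCORE_OF["A1"]: "A1",
    SCORE_OF["A2"]: "A2/3",
    SCORE_OF["A3"]: "A2/3",
    SCORE_OF["B1"]: "B1",
    SCORE_OF["B23"]: "B2/3",
    SCORE_OF["C"]: "C",
}


@dataclass
class AmountTable:
    """Percent stage amounts per minute and for the total recording.

    ``per_minute`` has one row per complete minute and one column per
    reporting category (A2 and A3 merged into A2/3); rows of minutes with no
    evaluable seconds are NaN (missing, not zero).  ``total`` covers every
    non-artifact second of the recording.
    """

    per_minute: pd.DataFrame
    total: pd.Series
    non_artifact_total: int


@dataclass
class MvvCourse:
    """Mean vigilance value per minute and for the whole recording."""

    per_minute: np.ndarray  # NaN where a minute has no evaluable seconds
    total: float

    def __len__(self) -> int:
        return int(self.per_minute.size)


@dataclass
class AssResult:
    """Arousal stability score with provenance.

    score ∈ {1..14}; 13/14 mean that no B- or C-based criterion was ever met
    (14 when every evaluable minute consisted of at least two thirds 0/A1
    seconds, 13 otherwise).  For scores ≤ 12 the decisive criterion (II, III
    or IV) and the quartile (1-4) in which it was first met are recorded.
    """

    score: int
    decisive_criterion: str  # "none", "II", "III", "IV"
    decisive_quartile: Optional[int]
    n_minutes: int


def _require_clean(seq: StageSequence) -> None:
    if seq.n_seconds == 0:
        raise ValueError("empty stage sequence")
    if not (~seq.artifact_mask).any():
        raise ValueError("all seconds are artifact-flagged; metrics undefined")


def stage_amounts(seq: StageSequence) -> AmountTable:
    """Percent amount of each stage category per minute and in total.

    The denominator is the number of non-artifact seconds of the window, so
    each evaluable window's percentages sum to 100.
    """
    _require_clean(seq)

    def window_amounts(scores: np.ndarray, mask: np.ndarray) -> dict[str, float]:
        clean = scores[~mask]
        if clean.size == 0:
            return {c: np.nan for c in REPORT_CATEGORIES} | {"n_non_artifact": 0}
        out = {c: 0.0 for c in REPORT_CATEGORIES}
        vals, counts = np.unique(clean, return_counts=True)
        for v, n in zip(vals, counts):
            out[_CAT_OF_SCORE[int(v)]] += n * 100.0 / clean.size
        out["n_non_artifact"] = int(clean.size)
        return out

    rows = [window_amounts(seq.scores[sl], seq.artifact_mask[sl])
            for sl in seq.minute_slices()]
    per_minute = pd.DataFrame(rows, index=pd.RangeIndex(len(rows), name="minute"))

    tot = window_amounts(seq.scores, seq.artifact_mask)
    n_tot = int(tot.pop("n_non_artifact"))
    total = pd.Series(tot, name="total")
    return AmountTable(per_minute=per_minute, total=total, non_artifact_total=n_tot)


def mean_vigilance_value(seq: StageSequence) -> MvvCourse:
    """Average the 1-7 stage scores of all non-artifact seconds.

    Returns the per-minute course (NaN for minutes without evaluable
    seconds) and the grand mean over the whole recording.
    """
    _require_clean(seq)
    per_min = np.full(seq.n_minutes, np.nan)
    for m, sl in enumerate(seq.minute_slices()):
        clean = seq.scores[sl][~seq.artifact_mask[sl]]
        if clean.size:
            per_min[m] = float(clean.mean())
    total = float(seq.clean_scores().mean())
    return MvvCourse(per_minute=per_min, total=total)


def minute_criteria(seq: StageSequence, min_non_artifact: int = 20) -> pd.DataFrame:
    """Evaluate the four stability criteria for each complete 1-min block.

    Per block (fractions over its non-artifact seconds, boundaries inclusive):

    * ``crit_I_0A``  — at least 2/3 of seconds in stages 0/A1/A2/A3
    * ``crit_I_0A1`` — at least 2/3 of seconds in stages 0/A1
    * ``crit_II``    — at least 1/3 of seconds in B stages (B1 + B2/3)
    * ``crit_III``   — at least 1/3 of seconds in B2/3
    * ``crit_IV``    — at least one C second

    Blocks with fewer than ``min_non_artifact`` evaluable seconds are marked
    not ``evaluable`` and their criteria are left as NA.
    """
    if seq.n_minutes < 1:
        raise ValueError("sequence shorter than one full minute")
    records = []
    for m, sl in enumerate(seq.minute_slices()):
        clean = seq.scores[sl][~seq.artifact_mask[sl]]
        n = clean.size
        if n < min_non_artifact:
            records.append(
                dict(minute=m, evaluable=False, n_non_artifact=n,
                     crit_I_0A=pd.NA, crit_I_0A1=pd.NA,
                     crit_II=pd.NA, crit_III=pd.NA, crit_IV=pd.NA)
            )
            continue
        in_0a = np.isin(clean, list(_SCORES_0A)).sum()
        in_0a1 = np.isin(clean, list(_SCORES_0A1)).sum()
        in_b = np.isin(clean, list(_SCORES_B)).sum()
        in_b23 = (clean == _SCORE_B23).sum()
        n_c = (clean == _SCORE_C).sum()
        records.append(
            dict(
                minute=m,
                evaluable=True,
                n_non_artifact=n,
                crit_I_0A=bool(3 * in_0a >= 2 * n),
                crit_I_0A1=bool(3 * in_0a1 >= 2 * n),
                crit_II=bool(3 * in_b >= n),
                crit_III=bool(3 * in_b23 >= n),
                crit_IV=bool(n_c >= 1),
            )
        )
    return pd.DataFrame.from_records(records).set_index("minute")


def _quartile_of_minute(minute: int, minutes_per_quartile: int) -> int:
    return minute // minutes_per_quartile + 1


def arousal_stability_score(
    seq: StageSequence, min_non_artifact: int = 20
) -> AssResult:
    """Score the speed and depth of the vigilance decline on a 1-14 scale.

    The recording is split into four consecutive equal quartiles of minutes.
    Let qII, qIII, qIV be the earliest quartile containing a minute that
    fulfils criterion II, III, IV respectively.  The score is::

        qIV defined              ->  qIV           (1..4)
        else qIII defined        ->  4 + qIII      (5..8)
        else qII defined         ->  8 + qII       (9..12)
        else                     ->  14 if every evaluable minute fulfils
                                     the 0/A1 form of criterion I, else 13

    Deeper criteria take precedence, and an earlier quartile gives a lower
    score, so earlier or deeper declines never raise the score.
    """
    n_min = seq.n_minutes
    if n_min < 4 or n_min % 4 != 0:
        raise ValueError(
            f"recording spans {n_min} full minutes; the score requires a "
            "duration divisible into 4 equal quartiles"
        )
    mpq = n_min // 4
    crit = minute_criteria(seq, min_non_artifact=min_non_artifact)
    ev = crit[crit["evaluable"].astype(bool)]
    if ev.empty:
        raise ValueError("no evaluable minutes; cannot score")
    quart_cover = {_quartile_of_minute(int(m), mpq) for m in ev.index}
    if quart_cover != {1, 2, 3, 4}:
        missing = sorted({1, 2, 3, 4} - quart_cover)
        raise ValueError(f"quartile(s) {missing} contain no evaluable minute")

    def first_quartile(col: str) -> Optional[int]:
        hit = ev.index[ev[col].astype(bool)]
        if len(hit) == 0:
            return None
        return _quartile_of_minute(int(hit[0]), mpq)

    q_iv = first_quartile("crit_IV")
    q_iii = first_quartile("crit_III")
    q_ii = first_quartile("crit_II")

    if q_iv is not None:
        return AssResult(q_iv, "IV", q_iv, n_min)
    if q_iii is not None:
        return AssResult(4 + q_iii, "III", q_iii, n_min)
    if q_ii is not None:
        return AssResult(8 + q_ii, "II", q_ii, n_min)
    all_0a1 = bool(ev["crit_I_0A1"].astype(bool).all())
    return AssResult(14 if all_0a1 else 13, "none", None, n_min)
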