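"""Prototype arousal-regulation time courses and least-squares assignment.

A subject's per-minute mean-vigilance course is compared with fixed
prototypical courses and assigned to the one with the smallest sum of
squared deviations.  Two models are supported: the classical three-type
model (adaptive / unstable / (hyper)stable) and a four-type refinement that
splits the stable pole into a stable and a hyperstable type.

The prototype curves are parameterized, since only their shape classes are
fixed by the model: hyperstable retention at the relaxed-wake level (A1, 6);
stable constancy one level lower (A2, 5); adaptive, a graded linear decline
from 6 to 2 across the recording; unstable, the same drop compressed into
the first quartile followed by retention at the floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .metrics import MvvCourse

#: Tie-break preference: more stable prototypes win equal-ssq comparisons.
STABILITY_ORDER: tuple[str, ...] = ("hyperstable", "stable", "adaptive", "unstable")


@dataclass(frozen=True)
class PrototypeParams:
    """End points of the default curve family (vigilance score units)."""

    high: float = 6.0       # retention level of the hyperstable type
    stable_level: float = 5.0
    low: float = 2.0        # floor reached by the declining types
    drop_fraction: float = 0.25  # fraction of the recording over which the
                                 # unstable type completes its decline


def build_prototypes(
    model: str = "four",
    duration_min: int = 20,
    params: PrototypeParams = PrototypeParams(),
) -> dict[str, np.ndarray]:
    """Per-minute prototype curves for the three- or four-type model.

    The three-type model merges stable and hyperstable into a single
    "stable" prototype held at the retention level.
    """
    if duration_min < 4:
        raise ValueError("prototype curves need at least 4 minutes")
    n = duration_min
    adaptive = np.linspace(params.high, params.low, n)
    n_drop = max(2, int(round(params.drop_fraction * n)))
    unstable = np.concatenate([
        np.linspace(params.high, params.low, n_drop),
        np.full(n - n_drop, params.low),
    ])
    if model == "four":
        return {
            "hyperstable": np.full(n, params.high),
            "stable": np.full(n, params.stable_level),
            "adaptive": adaptive,
            "unstable": unstable,
        }
    if model == "three":
        return {
            "stable": np.full(n, params.high),
            "adaptive": adaptive,
            "unstable": unstable,
        }
    raise ValueError(f"unknown prototype model {model!r}; use 'three' or 'four'")


@dataclass
class PrototypeAssignment:
    """Least-squares assignment of one course to a prototype."""

    model: str
    label: str
    ssq: float
    ssq_by_prototype: dict[str, float] = field(default_factory=dict)


def assign_prototype(
    mvv: MvvCourse | np.ndarray,
    prototypes: Mapping[str, np.ndarray],
    model: str = "four",
) -> PrototypeAssignment:
    """Assign a per-minute course to the prototype with the smallest sum of
    squared deviations.

    Missing minutes (NaN) are excluded pairwise from every sum.  Ties go to
    the more stable prototype.
    """
    course = mvv.per_minute if isinstance(mvv, MvvCourse) else np.asarray(mvv, float)
    valid = ~np.isnan(course)
    if not valid.any():
        raise ValueError("course has no evaluable minutes")
    ssqs: dict[str, float] = {}
    for label, curve in prototypes.items():
        curve = np.asarray(curve, dtype=float)
        if curve.size != course.size:
            raise ValueError(
                f"prototype {label!r} has {curve.size} minutes, course has "
                f"{course.size}")
        ssqs[label] = float(((course[valid] - curve[valid]) ** 2).sum())
    order = [lab for lab in STABILITY_ORDER if lab in ssqs]
    order += [lab for lab in ssqs if lab not in order]
    best = min(order, key=lambda lab: ssqs[lab])
    return PrototypeAssignment(model=model, label=best, ssq=ssqs[best],
                               ssq_by_prototype=ssqs)


def prototype_distribution(
    assignments_by_group: Mapping[str, list[str]],
    categories: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Contingency table of prototype counts per group."""
    if not assignments_by_group:
        raise ValueError("no groups given")
    for g, labels in assignments_by_group.items():
        if len(labels) == 0:
            raise ValueError(f"group {g!r} is empty")
    if categories is None:
        seen = {lab for labels in assignments_by_group.values() for lab in labels}
        categories = tuple(lab for lab in STABILITY_ORDER if lab in seen)
        categories += tuple(sorted(seen - set(categories)))
    rows = {
        g: [labels.count(c) for c in categories]
        for g, labels in assignments_by_group.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(categories))
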