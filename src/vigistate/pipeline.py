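"""End-to-end cohort analysis driver.

Runs the full analysis sequence on a simulated (or pre-staged) cohort:
stage courses -> stability metrics -> prototype assignment -> group-level
statistics, and emits a machine-readable report.  With a fixed seed the
report is byte-identical across runs.
"""

from __future__ import annotations

import json
from typing import Any, Mapping, Optional

import numpy as np

from . import metrics
from .prototypes import assign_prototype, build_prototypes, prototype_distribution
from .stages import StageSequence
from .stats import chi_square_independence, mann_whitney_u, median_split, spearman, t_test
from .synthetic import CohortSpec, CovariateSpec, StageCourseParams, simulate_cohort


def _round(obj: Any) -> Any:
    if isinstance(obj, float):
        return round(obj, 6)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), 6)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {k: _round(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v) for v in obj]
    return obj


def cohort_spec_from_config(config: Mapping[str, Any]) -> CohortSpec:
    """Build a :class:`CohortSpec` from a plain config mapping (e.g. YAML)."""
    c = dict(config.get("cohort", {}))
    kwargs: dict[str, Any] = {}
    for key in ("n_per_group", "group_mixtures", "duration_min"):
        if key in c:
            kwargs[key] = c[key]
    if "covariate_model" in c:
        kwargs["covariate_model"] = {
            name: CovariateSpec(**vals) for name, vals in c["covariate_model"].items()
        }
    if "course_params" in c:
        kwargs["course_params"] = {
            name: StageCourseParams(**vals) for name, vals in c["course_params"].items()
        }
    kwargs["seed"] = int(config.get("seed", 0))
    return CohortSpec(**kwargs)


def subject_summary(course: StageSequence) -> dict[str, Any]:
    """Stability metrics and prototype assignments for one stage course."""
    ass = metrics.arousal_stability_score(course)
    mvv = metrics.mean_vigilance_value(course)
    amounts = metrics.stage_amounts(course)
    n_min = course.n_minutes
    p3 = assign_prototype(mvv, build_prototypes("three", n_min), model="three")
    p4 = assign_prototype(mvv, build_prototypes("four", n_min), model="four")
    return {
        "ass": ass.score,
        "decisive_criterion": ass.decisive_criterion,
        "decisive_quartile": ass.decisive_quartile,
        "mvv_total": mvv.total,
        "mvv_per_min": [None if np.isnan(v) else v for v in mvv.per_minute],
        "amounts_total": amounts.total.to_dict(),
        "prototype_3": p3.label,
        "prototype_4": p4.label,
    }


def run_pipeline(config: Optional[Mapping[str, Any]] = None) -> dict[str, Any]:
    """Simulate a cohort and reproduce the group-level analysis sequence.

    Returns a JSON-serializable report with per-subject results, the
    prototype contingency tables, and every group test: a one-tailed
    Mann-Whitney U on the arousal stability score, a t-test on C-stage
    counts, chi-square tests on the three- and four-prototype frequencies,
    and — after a median split of the patient group by sleep efficiency —
    per-subgroup score comparisons and directed Spearman correlations of
    the score with sleep efficiency and arousal index.
    """
    if not config:
        raise ValueError(
            "empty pipeline config; provide at least a seed "
            "(e.g. {'seed': 0}) and optionally a 'cohort' block")
    config = dict(config)
    spec = cohort_spec_from_config(config)
    patient_g = config.get("patient_group", "patient")
    control_g = config.get("control_group", "control")
    for g in (patient_g, control_g):
        if g not in spec.n_per_group:
            raise ValueError(f"group {g!r} not in cohort spec")

    cohort = simulate_cohort(spec)
    subjects: dict[str, Any] = {}
    failures: dict[str, str] = {}
    for sid, course in cohort.courses.items():
        try:
            subjects[sid] = subject_summary(course)
        except ValueError as exc:  # isolate per-subject failures
            failures[sid] = str(exc)

    tbl = cohort.table.set_index("subject_id")
    ok = tbl.index[tbl.index.isin(subjects)]
    tbl = tbl.loc[ok]
    for col in ("prototype_3", "prototype_4"):
        tbl[col] = [subjects[s][col] for s in tbl.index]

    pat = tbl[tbl["group"] == patient_g]
    ctl = tbl[tbl["group"] == control_g]
    tests: dict[str, Any] = {}
    tests["ass_mann_whitney"] = mann_whitney_u(
        pat["ass"], ctl["ass"], tail="greater").as_dict()
    tests["c_count_t_test"] = t_test(
        pat["c_stage_count"], ctl["c_stage_count"], tail="two-sided").as_dict()

    contingency: dict[str, Any] = {}
    for model, col in (("three", "prototype_3"), ("four", "prototype_4")):
        table = prototype_distribution({
            patient_g: list(pat[col]), control_g: list(ctl[col]),
        })
        contingency[model] = {
            "categories": list(table.columns),
            "counts": {g: [int(v) for v in table.loc[g]] for g in table.index},
        }
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            tests[f"prototype_chi2_{model}"] = chi_square_independence(
                table.to_numpy(), tail="one-sided").as_dict()

    # insomnia-style subgrouping of the patient group by sleep efficiency
    subgroups: dict[str, Any] = {}
    if "sleep_efficiency" in pat.columns and len(pat) >= 4:
        split = median_split(pat["sleep_efficiency"].to_numpy())
        sub = {"high": pat.iloc[split.high], "low": pat.iloc[split.low]}
        subgroups["threshold"] = split.threshold
        for name, grp in sub.items():
            entry: dict[str, Any] = {
                "n": int(len(grp)),
                "subject_ids": list(grp.index),
                "ass_vs_controls": mann_whitney_u(
                    grp["ass"], ctl["ass"], tail="greater").as_dict(),
            }
            if len(grp) >= 4:
                pairs = [("spearman_ass_sleep_efficiency", "sleep_efficiency",
                          "less"),
                         ("spearman_ass_arousal_index", "arousal_index",
                          "greater")]
                for key, cov, tail in pairs:
                    if cov not in grp.columns:
                        continue
                    try:
                        entry[key] = spearman(grp["ass"], grp[cov],
                                              tail=tail).as_dict()
                    except ValueError as exc:  # e.g. constant scores
                        entry[key] = {"error": str(exc)}
            subgroups[name] = entry

    report = {
        "config": {"seed": spec.seed,
                   "n_per_group": dict(spec.n_per_group),
                   "duration_min": spec.duration_min},
        "subjects": subjects,
        "failures": failures,
        "prototype_tables": contingency,
        "tests": tests,
        "subgroups": subgroups,
        "group_medians_ass": {
            patient_g: float(np.median(pat["ass"])),
            control_g: float(np.median(ctl["ass"])),
        },
    }
    return _round(report)


def report_json(report: Mapping[str, Any]) -> str:
    """Canonical JSON rendering (sorted keys) — byte-identical per seed."""
    return json.dumps(report, sort_keys=True, indent=2)


def report_markdown(report: Mapping[str, Any]) -> str:
    """Short human-readable summary of a pipeline report."""
    lines = ["# Cohort vigilance report", ""]
    med = report["group_medians_ass"]
    lines.append("Median arousal stability score: "
                 + ", ".join(f"{g} = {v}" for g, v in med.items()))
    lines.append("")
    lines.append("## Group tests")
    for name, t in report["tests"].items():
        lines.append(
            f"- {name}: statistic = {t['statistic']}, p = {t['p_value']} "
            f"({t['tail']}, {t['method']})")
    if report.get("subgroups"):
        lines.append("")
        lines.append("## Patient subgroups (median split on sleep efficiency at "
                     f"{report['subgroups'].get('threshold')}%)")
        for name in ("high", "low"):
            if name in report["subgroups"]:
                t = report["subgroups"][name]["ass_vs_controls"]
                lines.append(f"- {name} sleep efficiency vs controls: "
                             f"U = {t['statistic']}, p = {t['p_value']}")
    return "\n".join(lines) + "\n"
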