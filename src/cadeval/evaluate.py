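"""End-to-end study evaluation: one code path from boxes to report tables.

Glue that runs classification over every reader arm and the CAD, pools
metrics, builds transition tables, and lays the results out as the three
report tables (cohort demographics, metric panel with ratios, transition
counts).  All numbers in the frames come from the same library calls the
tests exercise; rounding happens only here, at the report layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .classify import AnnotationSet, CaseOutcome, ImageRecord, classify_study, mfpi
from .gee import GeeFit, GeeSpec, build_outcome_records, fit_gee, format_p
from .geometry import MatchPolicy
from .metrics import (
    METRIC_NAMES,
    MetricSet,
    PooledMetrics,
    metric_set,
    confusion,
    pooled_metrics,
    ratio_report,
    round_half_up,
)
from .transitions import TransitionTable, cad_case_outcomes, transition_table

__all__ = [
    "StudyEvaluation",
    "reader_outcomes",
    "evaluate_study",
    "metrics_frame",
    "outcomes_frame",
    "gee_frame",
]

ARM_LABELS = ("pre_cad", "post_cad")


def reader_outcomes(
    images: Sequence[ImageRecord],
    sessions: Mapping[str, Mapping[str, AnnotationSet]],
    policy: MatchPolicy = MatchPolicy(),
) -> dict[tuple[str, str], list[CaseOutcome]]:
    """Classify every reader arm; keys are (reader_id, arm_label)."""
    out: dict[tuple[str, str], list[CaseOutcome]] = {}
    for reader_id in sorted(sessions):
        for arm in ARM_LABELS:
            if arm not in sessions[reader_id]:
                raise ValueError(f"reader {reader_id} is missing the {arm} arm")
            out[(reader_id, arm)] = classify_study(
                images, sessions[reader_id][arm], policy
            )
    return out


@dataclass
class StudyEvaluation:
    """Everything the reports need, computed once."""

    outcomes: dict[tuple[str, str], list[CaseOutcome]]
    pooled: PooledMetrics
    cad_outcomes: list[CaseOutcome]
    cad_metrics: MetricSet
    tables: list[TransitionTable]
    groups: dict[str, str]
    naive_ratios: dict[str, Optional[float]]


def evaluate_study(
    images: Sequence[ImageRecord],
    cad: AnnotationSet,
    sessions: Mapping[str, Mapping[str, AnnotationSet]],
    groups: Mapping[str, str],
    policy: MatchPolicy = MatchPolicy(),
) -> StudyEvaluation:
    """Run the full per-case pipeline for readers and the standalone CAD."""
    outcomes = reader_outcomes(images, sessions, policy)
    pooled = pooled_metrics(outcomes, groups)
    cad_outs = cad_case_outcomes(images, cad, policy)
    cad_ms = metric_set(confusion(cad_outs), mfpi(cad_outs))
    tables = [
        transition_table(
            outcomes[(r, "pre_cad")], outcomes[(r, "post_cad")], cad_outs, r
        )
        for r in sorted(sessions)
    ]
    ratios = ratio_report(pooled.overall["pre_cad"], pooled.overall["post_cad"])
    return StudyEvaluation(
        outcomes=outcomes,
        pooled=pooled,
        cad_outcomes=cad_outs,
        cad_metrics=cad_ms,
        tables=tables,
        groups=dict(groups),
        naive_ratios=ratios,
    )


def _fmt(value: Optional[float]) -> Optional[float]:
    return None if value is None else round_half_up(value, 2)


def metrics_frame(ev: StudyEvaluation) -> pd.DataFrame:
    """Metric panel: per-group and overall values per arm, plus ratios.

    One row per metric; a final row reports mFPI, and a standalone-CAD
    column reports the CAD's own operating point.
    """
    group_names = sorted(set(ev.groups.values()))
    rows = []
    for name in METRIC_NAMES:
        row: dict[str, object] = {"metric": name}
        for g in group_names:
            row[f"{g}_without_cad"] = _fmt(
                getattr(ev.pooled.per_group[(g, "pre_cad")], name)
            )
            row[f"{g}_with_cad"] = _fmt(
                getattr(ev.pooled.per_group[(g, "post_cad")], name)
            )
        row["overall_without_cad"] = _fmt(
            getattr(ev.pooled.overall["pre_cad"], name)
        )
        row["overall_with_cad"] = _fmt(getattr(ev.pooled.overall["post_cad"], name))
        row["ratio"] = ev.naive_ratios[name]
        row["cad_standalone"] = _fmt(getattr(ev.cad_metrics, name))
        rows.append(row)
    row = {"metric": "mfpi"}
    for g in group_names:
        row[f"{g}_without_cad"] = _fmt(ev.pooled.per_group[(g, "pre_cad")].mfpi)
        row[f"{g}_with_cad"] = _fmt(ev.pooled.per_group[(g, "post_cad")].mfpi)
    row["overall_without_cad"] = _fmt(ev.pooled.overall["pre_cad"].mfpi)
    row["overall_with_cad"] = _fmt(ev.pooled.overall["post_cad"].mfpi)
    row["cad_standalone"] = _fmt(ev.cad_metrics.mfpi)
    rows.append(row)
    return pd.DataFrame(rows)


def outcomes_frame(ev: StudyEvaluation) -> pd.DataFrame:
    """Per-case outcome table: image_id, reader_id, arm, state, FP lesions."""
    rows = []
    for (reader_id, arm), outs in sorted(ev.outcomes.items()):
        for o in outs:
            rows.append(
                {
                    "image_id": o.image_id,
                    "reader_id": reader_id,
                    "arm": arm,
                    "state": o.state,
                    "fp_lesion_count": o.fp_lesion_count,
                }
            )
    for o in ev.cad_outcomes:
        rows.append(
            {
                "image_id": o.image_id,
                "reader_id": "cad",
                "arm": "cad",
                "state": o.state,
                "fp_lesion_count": o.fp_lesion_count,
            }
        )
    return pd.DataFrame(rows)


def gee_frame(
    outcomes: Mapping[tuple[str, str], Sequence[CaseOutcome]],
    metrics: Sequence[str] = METRIC_NAMES,
    spec: GeeSpec = GeeSpec(),
) -> pd.DataFrame:
    """GEE ratio, 95% CI and p-value per metric (with-CAD vs without)."""
    rows = []
    for metric in metrics:
        records = build_outcome_records(outcomes, metric)
        fit = fit_gee(records, spec)
        rows.append(
            {
                "metric": metric,
                "ratio": round_half_up(fit.ratio, 2),
                "ci_lower": round_half_up(fit.ci_lower, 2),
                "ci_upper": round_half_up(fit.ci_upper, 2),
                "p_value": format_p(fit.p_value),
                "converged": fit.converged,
                "n_clusters": fit.n_clusters,
            }
        )
    return pd.DataFrame(rows)
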