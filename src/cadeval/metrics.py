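"""Aggregate case outcomes into the study's metric panel.

Provides the confusion-count aggregation, the five case-level metrics
(sensitivity, specificity, accuracy, PPV, NPV), pooling across readers and
reader groups (micro-average: confusion counts are summed before metrics
are computed), descriptive with-CAD / without-CAD ratios, the eligibility
cascade that reduces a collected malignant cohort to the analysable set,
and the cohort demographics summary.

A metric with a zero denominator is *undefined* and represented as
``None`` — never silently zero — and undefinedness propagates through
ratios.  Display rounding is half-up (two decimals for metrics and ratios,
integer percent for demographics); everything upstream of a report stays
full precision.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .classify import (
    LOCATIONS,
    LATERALITIES,
    OVERLAP_STRUCTURES,
    SIZE_BINS,
    VENDORS,
    CaseOutcome,
    ImageRecord,
    mfpi,
)

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "EligibilityReport",
    "LesionCandidate",
    "PooledMetrics",
    "confusion",
    "metric_set",
    "pooled_metrics",
    "ratio_report",
    "eligibility_filter",
    "cohort_summary",
    "round_half_up",
    "METRIC_NAMES",
]

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "ppv", "npv")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used for displayed values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fn + other.fn,
            self.tn + other.tn,
            self.fp + other.fp,
        )


@dataclass(frozen=True)
class MetricSet:
    """The five case-level metrics; ``None`` flags an undefined value."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    mfpi: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(outcomes: Iterable[CaseOutcome]) -> ConfusionCounts:
    """Tally case states into confusion counts."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("cannot build confusion counts from no outcomes")
    states = [o.state for o in outcomes]
    return ConfusionCounts(
        tp=states.count("TP"),
        fn=states.count("FN"),
        tn=states.count("TN"),
        fp=states.count("FP"),
    )


def _ratio_or_none(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def metric_set(counts: ConfusionCounts, mfpi_value: Optional[float] = None) -> MetricSet:
    """Compute the metric panel from confusion counts.

    sensitivity = tp/(tp+fn); specificity = tn/(tn+fp);
    accuracy = (tp+tn)/total; ppv = tp/(tp+fp); npv = tn/(tn+fn).
    """
    if counts.total == 0:
        raise ValueError("metric panel undefined for zero cases")
    return MetricSet(
        sensitivity=_ratio_or_none(counts.tp, counts.tp + counts.fn),
        specificity=_ratio_or_none(counts.tn, counts.tn + counts.fp),
        accuracy=(counts.tp + counts.tn) / counts.total,
        ppv=_ratio_or_none(counts.tp, counts.tp + counts.fp),
        npv=_ratio_or_none(counts.tn, counts.tn + counts.fn),
        mfpi=mfpi_value,
    )


@dataclass
class PooledMetrics:
    """Per-reader, per-group and overall metric panels for both arms."""

    per_reader: dict[tuple[str, str], MetricSet]
    per_group: dict[tuple[str, str], MetricSet]
    overall: dict[str, MetricSet]
    per_reader_counts: dict[tuple[str, str], ConfusionCounts]
    per_group_counts: dict[tuple[str, str], ConfusionCounts]
    overall_counts: dict[str, ConfusionCounts]


def pooled_metrics(
    outcomes: Mapping[tuple[str, str], Sequence[CaseOutcome]],
    groups: Mapping[str, str],
) -> PooledMetrics:
    """Pool case outcomes across readers.

    ``outcomes`` maps ``(reader_id, arm)`` to that reader-arm's case
    outcomes; ``groups`` maps reader_id to its reader group.  Group and
    overall panels are micro-averages: confusion counts are summed across
    readers before the metrics are computed.  All readers must contribute
    the same arms over the same image set.
    """
    readers = sorted({r for r, _ in outcomes})
    arms = sorted({a for _, a in outcomes})
    missing = [
        (r, a) for r in readers for a in arms if (r, a) not in outcomes
    ]
    if missing:
        raise ValueError(f"missing reader-arm outcome lists: {missing}")
    image_sets = {
        key: frozenset(o.image_id for o in outs) for key, outs in outcomes.items()
    }
    reference = next(iter(image_sets.values()))
    mismatched = sorted(k for k, s in image_sets.items() if s != reference)
    if mismatched:
        raise ValueError(
            f"reader-arm outcome lists cover different image sets: {mismatched}"
        )
    unknown = sorted(set(readers) - set(groups))
    if unknown:
        raise ValueError(f"readers without a group assignment: {unknown}")

    per_reader_counts = {
        key: confusion(outs) for key, outs in outcomes.items()
    }
    per_reader = {
        key: metric_set(cnt, mfpi(outcomes[key]))
        for key, cnt in per_reader_counts.items()
    }

    per_group_counts: dict[tuple[str, str], ConfusionCounts] = {}
    per_group: dict[tuple[str, str], MetricSet] = {}
    group_names = sorted(set(groups[r] for r in readers))
    for g in group_names:
        for a in arms:
            members = [r for r in readers if groups[r] == g]
            cnt = ConfusionCounts(0, 0, 0, 0)
            pooled_outs: list[CaseOutcome] = []
            for r in members:
                cnt = cnt + per_reader_counts[(r, a)]
                pooled_outs.extend(outcomes[(r, a)])
            per_group_counts[(g, a)] = cnt
            per_group[(g, a)] = metric_set(cnt, mfpi(pooled_outs))

    overall_counts: dict[str, ConfusionCounts] = {}
    overall: dict[str, MetricSet] = {}
    for a in arms:
        cnt = ConfusionCounts(0, 0, 0, 0)
        pooled_outs = []
        for r in readers:
            cnt = cnt + per_reader_counts[(r, a)]
            pooled_outs.extend(outcomes[(r, a)])
        overall_counts[a] = cnt
        overall[a] = metric_set(cnt, mfpi(pooled_outs))

    return PooledMetrics(
        per_reader=per_reader,
        per_group=per_group,
        overall=overall,
        per_reader_counts=per_reader_counts,
        per_group_counts=per_group_counts,
        overall_counts=overall_counts,
    )


def ratio_report(
    pre: MetricSet, post: MetricSet, ndigits: int = 2
) -> dict[str, Optional[float]]:
    """Descriptive with/without ratios, rounded half-up for display.

    These are plain elementwise divisions of the two panels; inferential
    ratios with CIs live in :mod:`cadeval.gee`.  An undefined metric in
    either arm propagates as ``None``.
    """
    out: dict[str, Optional[float]] = {}
    for name in METRIC_NAMES:
        a, b = getattr(post, name), getattr(pre, name)
        if a is None or b is None or b == 0.0:
            out[name] = None
        else:
            out[name] = round_half_up(a / b, ndigits)
    return out


@dataclass(frozen=True)
class LesionCandidate:
    """A collected lesion-bearing radiograph with its exclusion attributes."""

    image_id: str
    is_metastasis: bool
    size_mm: float
    is_nodular: bool
    visible_on_radiograph: bool
    is_ggn_under_5mm: bool = False


@dataclass(frozen=True)
class EligibilityReport:
    collected: int
    excluded_metastasis: int
    excluded_over_30mm: int
    excluded_non_nodular: int
    excluded_not_visible: int
    remaining: int

    def __post_init__(self) -> None:
        excluded = (
            self.excluded_metastasis
            + self.excluded_over_30mm
            + self.excluded_non_nodular
            + self.excluded_not_visible
        )
        if self.remaining != self.collected - excluded:
            raise ValueError("eligibility cascade counts are not conserved")


def eligibility_filter(
    candidates: Sequence[LesionCandidate],
) -> tuple[list[LesionCandidate], EligibilityReport]:
    """Apply the eligibility cascade to a collected malignant cohort.

    Exclusions are applied in order — metastasis, mass (> 30 mm longest
    diameter), non-nodular appearance, then not visible on the radiograph
    (sub-5 mm ground-glass nodules count as not visible) — and each
    candidate is counted once, at the first criterion it fails, so the
    cascade counts are conserved.
    """
    n_meta = n_mass = n_shape = n_invisible = 0
    retained: list[LesionCandidate] = []
    for c in candidates:
        if c.is_metastasis:
            n_meta += 1
        elif c.size_mm > 30.0:
            n_mass += 1
        elif not c.is_nodular:
            n_shape += 1
        elif c.is_ggn_under_5mm or not c.visible_on_radiograph:
            n_invisible += 1
        else:
            retained.append(c)
    report = EligibilityReport(
        collected=len(candidates),
        excluded_metastasis=n_meta,
        excluded_over_30mm=n_mass,
        excluded_non_nodular=n_shape,
        excluded_not_visible=n_invisible,
        remaining=len(retained),
    )
    return retained, report


@dataclass
class CohortSummary:
    """Demographics of a test cohort (counts with integer percentages).

    Lesion attributes use the number of cancers as denominator; vendor rows
    report malignant/total with the malignant fraction per vendor.
    """

    n_images: int
    n_cancers: int
    size_mean_mm: Optional[float]
    size_sd_mm: Optional[float]
    size_bins: dict[str, tuple[int, Optional[int]]]
    laterality: dict[str, tuple[int, Optional[int]]]
    location: dict[str, tuple[int, Optional[int]]]
    overlap: dict[str, tuple[int, Optional[int]]]
    vendors: dict[str, tuple[int, int, Optional[int]]]

    def to_frame(self) -> pd.DataFrame:
        rows: list[dict[str, object]] = []
        rows.append({"section": "total", "category": "images", "count": self.n_images})
        rows.append({"section": "total", "category": "cancers", "count": self.n_cancers})
        if self.size_mean_mm is not None:
            rows.append(
                {
                    "section": "size_mm",
                    "category": "mean±sd",
                    "count": round_half_up(self.size_mean_mm, 1),
                    "extra": None if self.size_sd_mm is None
                    else round_half_up(self.size_sd_mm, 2),
                }
            )
        for section, table in (
            ("size_bin", self.size_bins),
            ("laterality", self.laterality),
            ("location", self.location),
            ("overlap", self.overlap),
        ):
            for cat, (n, pct) in table.items():
                rows.append(
                    {"section": section, "category": cat, "count": n, "percent": pct}
                )
        for vendor, (mal, total, pct) in self.vendors.items():
            rows.append(
                {
                    "section": "vendor",
                    "category": vendor,
                    "count": mal,
                    "extra": total,
                    "percent": pct,
                }
            )
        return pd.DataFrame(rows)


def _count_pct(
    values: list[str], categories: Sequence[str], denom: int
) -> dict[str, tuple[int, Optional[int]]]:
    out = {}
    for cat in categories:
        n = values.count(cat)
        pct = int(round_half_up(100.0 * n / denom, 0)) if denom else None
        out[cat] = (n, pct)
    return out


def cohort_summary(images: Sequence[ImageRecord]) -> CohortSummary:
    """Summarise cohort demographics (counts and rounded percentages)."""
    lesions = [im.lesion for im in images if im.lesion is not None]
    n_cancers = len(lesions)
    sizes = [l.size_mm for l in lesions]
    return CohortSummary(
        n_images=len(images),
        n_cancers=n_cancers,
        size_mean_mm=statistics.fmean(sizes) if sizes else None,
        size_sd_mm=statistics.stdev(sizes) if len(sizes) > 1 else None,
        size_bins=_count_pct([l.size_bin for l in lesions], SIZE_BINS, n_cancers),
        laterality=_count_pct(
            [l.laterality for l in lesions], LATERALITIES, n_cancers
        ),
        location=_count_pct([l.location for l in lesions], LOCATIONS, n_cancers),
        overlap=_count_pct(
            [l.overlap_structure for l in lesions], OVERLAP_STRUCTURES, n_cancers
        ),
        vendors={
            v: (
                sum(
                    1
                    for im in images
                    if im.vendor == v and im.label == "malignant"
                ),
                sum(1 for im in images if im.vendor == v),
                (
                    int(
                        round_half_up(
                            100.0
                            * sum(
                                1
                                for im in images
                                if im.vendor == v and im.label == "malignant"
                            )
                            / sum(1 for im in images if im.vendor == v),
                            0,
                        )
                    )
                    if any(im.vendor == v for im in images)
                    else None
                ),
            )
            for v in VENDORS
        },
    )
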