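"""Axis-aligned box geometry, IoU, and box-to-lesion matching.

Coordinate convention: origin at the top-left of the image, x rightward,
y downward, continuous pixel units.  A box is stored as
``(x_min, y_min, x_max, y_max)`` with strictly positive extent in both
dimensions; files that use an ``(x, y, width, height)`` dialect are
converted on read (see :mod:`cadeval.io`).

The matching policy operationalises the localisation correctness rule used
throughout the package: a mark is correct when its intersection over union
with a ground-truth lesion box is at least the threshold (default 0.3, the
comparison is inclusive).  Matching is one-to-one; marks left unmatched are
false-positive lesions, lesions left unmatched are misses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "BoundingBox",
    "InvalidBoxError",
    "MatchPolicy",
    "MatchResult",
    "area",
    "iou",
    "match_annotations",
]


class InvalidBoxError(ValueError):
    """A bounding box violates its invariants (degenerate or non-finite)."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle in continuous image coordinates (pixels)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        coords = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(c) for c in coords):
            raise InvalidBoxError(f"non-finite coordinates: {coords}")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise InvalidBoxError(
                f"box must have strictly positive extent, got {coords}"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def translated(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(
            self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy
        )


def area(box: BoundingBox) -> float:
    """Area of a valid box in squared pixels."""
    return box.width * box.height


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 when equal.

    Uses continuous (closed-rectangle) areas, not pixel rasterisation.
    """
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    union = area(a) + area(b) - inter
    return inter / union


@dataclass(frozen=True)
class MatchPolicy:
    """How annotation boxes are paired with ground-truth lesion boxes.

    ``greedy_desc_iou`` accepts candidate pairs above the threshold in order
    of descending IoU (ties broken by lower annotation index, then lower
    lesion index).  ``optimal`` maximises the number of matched pairs, then
    the total IoU.  The two agree whenever each lesion has at most one
    above-threshold annotation, the regime of a one-lesion-per-image study.
    """

    iou_threshold: float = 0.3
    assignment: Literal["greedy_desc_iou", "optimal"] = "greedy_desc_iou"

    def __post_init__(self) -> None:
        if not (0.0 < self.iou_threshold <= 1.0):
            raise ValueError(
                f"iou_threshold must be in (0, 1], got {self.iou_threshold}"
            )
        if self.assignment not in ("greedy_desc_iou", "optimal"):
            raise ValueError(f"unknown assignment policy {self.assignment!r}")


@dataclass(frozen=True)
class MatchResult:
    """One-to-one matching between annotations and lesions.

    ``matched_pairs`` holds ``(annotation_index, lesion_index, iou)``
    triples; every pair has IoU at or above the policy threshold.
    Unmatched annotations are false-positive lesion marks; unmatched lesions
    are misses.
    """

    matched_pairs: tuple[tuple[int, int, float], ...]
    unmatched_annotations: tuple[int, ...]
    unmatched_lesions: tuple[int, ...]

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)


def _greedy_match(
    candidates: list[tuple[float, int, int]],
    n_annotations: int,
    n_lesions: int,
) -> list[tuple[int, int, float]]:
    # candidates: (iou, ann_idx, les_idx); sort by descending iou then index
    order = sorted(candidates, key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_l: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for v, i, j in order:
        if i in used_a or j in used_l:
            continue
        used_a.add(i)
        used_l.add(j)
        pairs.append((i, j, v))
    return pairs


def _optimal_match(
    candidates: list[tuple[float, int, int]],
    n_annotations: int,
    n_lesions: int,
) -> list[tuple[int, int, float]]:
    # Max-cardinality then max-total-IoU via a profit matrix: each eligible
    # pair is worth (B + iou) with B large enough that one extra match always
    # beats any redistribution of IoU among fewer matches.
    if not candidates:
        return []
    bonus = float(max(n_annotations, n_lesions) + 1)
    profit = np.zeros((n_annotations, n_lesions))
    for v, i, j in candidates:
        profit[i, j] = bonus + v
    rows, cols = linear_sum_assignment(profit, maximize=True)
    eligible = {(i, j): v for v, i, j in candidates}
    pairs = [
        (int(i), int(j), eligible[(int(i), int(j))])
        for i, j in zip(rows, cols)
        if (int(i), int(j)) in eligible
    ]
    pairs.sort(key=lambda t: (t[0], t[1]))
    return pairs


def match_annotations(
    annotations: Sequence[BoundingBox],
    lesions: Sequence[BoundingBox],
    policy: MatchPolicy = MatchPolicy(),
) -> MatchResult:
    """One-to-one matching of annotation boxes to lesion boxes.

    Only pairs with ``iou >= policy.iou_threshold`` are candidates; the
    threshold comparison is inclusive.  Either list may be empty.
    """
    candidates: list[tuple[float, int, int]] = []
    for i, a in enumerate(annotations):
        for j, l in enumerate(lesions):
            v = iou(a, l)
            if v >= policy.iou_threshold:
                candidates.append((v, i, j))

    if policy.assignment == "greedy_desc_iou":
        pairs = _greedy_match(candidates, len(annotations), len(lesions))
        pairs.sort(key=lambda t: (t[0], t[1]))
    else:
        pairs = _optimal_match(candidates, len(annotations), len(lesions))

    matched_a = {i for i, _, _ in pairs}
    matched_l = {j for _, j, _ in pairs}
    return MatchResult(
        matched_pairs=tuple(pairs),
        unmatched_annotations=tuple(
            i for i in range(len(annotations)) if i not in matched_a
        ),
        unmatched_lesions=tuple(
            j for j in range(len(lesions)) if j not in matched_l
        ),
    )
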