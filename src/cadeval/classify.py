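"""Case-level classification of annotation sets against ground truth.

Each radiograph in the study regime is either malignant with exactly one
ground-truth nodule, or normal with none.  For a given set of annotation
boxes on an image:

* malignant image -> TP iff at least one box matches the lesion at or above
  the IoU threshold, otherwise FN;
* normal image -> TN iff there are no boxes, otherwise FP.

Boxes not matched to the lesion are false-positive *lesions* regardless of
the case state (on a normal image every box is one).  mFPI — mean false
positive indications per image — is the total FP lesion count divided by
the total number of images, malignant and normal alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

from .geometry import BoundingBox, MatchPolicy, match_annotations

__all__ = [
    "SIZE_BINS",
    "LesionTruth",
    "ImageRecord",
    "AnnotationSet",
    "CaseOutcome",
    "classify_case",
    "classify_study",
    "mfpi",
]

SIZE_BINS = ("<=10", "11-20", "21-30")
LATERALITIES = ("right", "left")
LOCATIONS = ("upper", "middle", "lower")
OVERLAP_STRUCTURES = ("heart", "clavicle", "diaphragm", "hilar_vessels", "none")
VENDORS = ("FUJIFILM", "KONICA", "Philips")

CaseState = Literal["TP", "FN", "TN", "FP"]


def size_bin_of(size_mm: float) -> str:
    """Size bin for a nodule diameter in mm (bins: <=10, 11-20, 21-30)."""
    if size_mm <= 10.0:
        return "<=10"
    if size_mm <= 20.0:
        return "11-20"
    return "21-30"


@dataclass(frozen=True)
class LesionTruth:
    """One ground-truth nodule: box, size and anatomical descriptors.

    Eligible lesions are nodules, i.e. at most 30 mm longest diameter.
    """

    image_id: str
    box: BoundingBox
    size_mm: float
    size_bin: str
    laterality: str
    location: str
    overlap_structure: str = "none"

    def __post_init__(self) -> None:
        if not (0.0 < self.size_mm <= 30.0):
            raise ValueError(
                f"{self.image_id}: nodule size must be in (0, 30] mm, "
                f"got {self.size_mm}"
            )
        if self.size_bin != size_bin_of(self.size_mm):
            raise ValueError(
                f"{self.image_id}: size_bin {self.size_bin!r} inconsistent "
                f"with size_mm {self.size_mm}"
            )
        if self.laterality not in LATERALITIES:
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.overlap_structure not in OVERLAP_STRUCTURES:
            raise ValueError(f"unknown overlap {self.overlap_structure!r}")


@dataclass(frozen=True)
class ImageRecord:
    """One radiograph: label, optional lesion, and acquisition metadata."""

    image_id: str
    label: Literal["malignant", "normal"]
    lesion: Optional[LesionTruth] = None
    vendor: str = "FUJIFILM"
    patient_age: Optional[float] = None
    patient_sex: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in ("malignant", "normal"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == "malignant" and self.lesion is None:
            raise ValueError(f"{self.image_id}: malignant image needs a lesion")
        if self.label == "normal" and self.lesion is not None:
            raise ValueError(f"{self.image_id}: normal image must have no lesion")
        if self.lesion is not None and self.lesion.image_id != self.image_id:
            raise ValueError(
                f"lesion image_id {self.lesion.image_id!r} does not match "
                f"image {self.image_id!r}"
            )
        if self.vendor not in VENDORS:
            raise ValueError(f"unknown vendor {self.vendor!r}")


@dataclass
class AnnotationSet:
    """All boxes of one source (a reader's arm, or the CAD) over a study."""

    source: Literal["reader", "cad"]
    arm: Literal["pre_cad", "post_cad", "cad"]
    boxes_by_image: dict[str, list[BoundingBox]]
    reader_id: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.source == "cad") != (self.arm == "cad"):
            raise ValueError("source 'cad' if and only if arm 'cad'")
        if (self.reader_id is not None) != (self.source == "reader"):
            raise ValueError("reader_id present iff source is 'reader'")


@dataclass(frozen=True)
class CaseOutcome:
    """Per-image classification of one annotation set.

    ``fp_lesion_count`` is the number of boxes not matched to the lesion;
    ``matched_iou`` is the IoU of the matched box on a TP case.
    """

    image_id: str
    state: CaseState
    fp_lesion_count: int
    matched_iou: Optional[float] = None

    def __post_init__(self) -> None:
        if self.state in ("TN",) and self.fp_lesion_count != 0:
            raise ValueError("TN case cannot carry FP lesions")
        if self.state == "FP" and self.fp_lesion_count < 1:
            raise ValueError("FP case must carry at least one FP lesion")
        if self.fp_lesion_count < 0:
            raise ValueError("fp_lesion_count must be non-negative")


def classify_case(
    image: ImageRecord,
    boxes: Sequence[BoundingBox],
    policy: MatchPolicy = MatchPolicy(),
) -> CaseOutcome:
    """Classify one image given the boxes drawn on it.

    Boxes carry no image identifier of their own; identifier consistency is
    enforced where ids exist, in :func:`classify_study` and at bundle load.
    """
    if image.label == "malignant":
        assert image.lesion is not None
        result = match_annotations(boxes, [image.lesion.box], policy)
        if result.n_matched:
            return CaseOutcome(
                image_id=image.image_id,
                state="TP",
                fp_lesion_count=len(result.unmatched_annotations),
                matched_iou=result.matched_pairs[0][2],
            )
        return CaseOutcome(
            image_id=image.image_id,
            state="FN",
            fp_lesion_count=len(boxes),
        )
    if boxes:
        return CaseOutcome(
            image_id=image.image_id, state="FP", fp_lesion_count=len(boxes)
        )
    return CaseOutcome(image_id=image.image_id, state="TN", fp_lesion_count=0)


def classify_study(
    images: Sequence[ImageRecord],
    annotations: AnnotationSet,
    policy: MatchPolicy = MatchPolicy(),
) -> list[CaseOutcome]:
    """Classify every image of a study under one annotation set.

    Images absent from ``annotations.boxes_by_image`` are treated as carrying
    zero boxes (readers mark only suspected nodules).  The result is ordered
    by image_id.  Annotations referencing unknown images are an error.
    """
    known = {im.image_id for im in images}
    unknown = sorted(set(annotations.boxes_by_image) - known)
    if unknown:
        raise KeyError(
            f"annotations reference unknown image ids: {', '.join(unknown)}"
        )
    outcomes = []
    for image in sorted(images, key=lambda im: im.image_id):
        boxes = annotations.boxes_by_image.get(image.image_id, [])
        outcomes.append(classify_case(image, boxes, policy))
    return outcomes


def mfpi(outcomes: Iterable[CaseOutcome]) -> float:
    """Mean false positive indications per image.

    Total FP lesion marks divided by the total number of images in the
    outcome list (all images, not only normals).
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("mFPI is undefined for an empty outcome list")
    return sum(o.fp_lesion_count for o in outcomes) / len(outcomes)
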