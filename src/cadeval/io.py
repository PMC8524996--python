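"""Study-bundle serialization: a JSON manifest plus plain CSV tables.

A bundle directory holds::

    manifest.json     study metadata: name, seed, box dialect, provenance
    images.csv        image_id, label, vendor, patient_age, patient_sex
    lesions.csv       image_id, box coordinates, size and descriptors
    readers.csv       reader_id, group, baseline operating point
    annotations.csv   source, reader_id, arm, image_id, box coordinates

Box coordinates are written as corner fields (x_min, y_min, x_max, y_max);
files using the (x, y, width, height) dialect are accepted when the
manifest says ``"box_format": "xywh"`` and converted on read.  Reading
validates referential integrity (every annotation's image exists, every
lesion's image is malignant, no duplicate boxes) with row-numbered error
messages, and ``read_bundle(write_bundle(b)) == b``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .classify import AnnotationSet, ImageRecord, LesionTruth
from .geometry import BoundingBox
from .simulate import ReaderProfile, StudyConfig, SyntheticStudy

__all__ = [
    "StudyBundle",
    "BundleError",
    "bundle_from_study",
    "write_bundle",
    "read_bundle",
]

_CORNER_COLS = ["x_min", "y_min", "x_max", "y_max"]
_XYWH_COLS = ["x", "y", "width", "height"]


class BundleError(ValueError):
    """A bundle violates its schema or referential integrity."""


@dataclass
class StudyBundle:
    """In-memory form of a serialized study."""

    manifest: dict
    images: list[ImageRecord]
    readers: list[ReaderProfile]
    cad: AnnotationSet
    sessions: dict[str, dict[str, AnnotationSet]]

    @property
    def reader_groups(self) -> dict[str, str]:
        return {p.reader_id: p.group for p in self.readers}


def _jsonable(obj: object) -> object:
    return json.loads(json.dumps(obj, default=lambda o: dataclasses.asdict(o)))


def bundle_from_study(study: SyntheticStudy, name: str = "synthetic") -> StudyBundle:
    manifest = {
        "name": name,
        "seed": study.seed,
        "box_format": "corners",
        "provenance": {"generator": "cadeval.simulate", "config": _jsonable(study.config)},
    }
    return StudyBundle(
        manifest=manifest,
        images=sorted(study.images, key=lambda im: im.image_id),
        readers=sorted(study.readers, key=lambda p: p.reader_id),
        cad=study.cad,
        sessions=study.sessions,
    )


def _box_row(box: BoundingBox) -> dict[str, float]:
    return {
        "x_min": box.x_min,
        "y_min": box.y_min,
        "x_max": box.x_max,
        "y_max": box.y_max,
    }


def write_bundle(bundle: Union[StudyBundle, SyntheticStudy], path: Union[str, Path]) -> Path:
    """Write a bundle directory; returns its path."""
    if isinstance(bundle, SyntheticStudy):
        bundle = bundle_from_study(bundle)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    (path / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n"
    )

    images_rows = []
    lesion_rows = []
    for im in sorted(bundle.images, key=lambda im: im.image_id):
        images_rows.append(
            {
                "image_id": im.image_id,
                "label": im.label,
                "vendor": im.vendor,
                "patient_age": im.patient_age,
                "patient_sex": im.patient_sex,
            }
        )
        if im.lesion is not None:
            lesion_rows.append(
                {"image_id": im.image_id}
                | _box_row(im.lesion.box)
                | {
                    "size_mm": im.lesion.size_mm,
                    "size_bin": im.lesion.size_bin,
                    "laterality": im.lesion.laterality,
                    "location": im.lesion.location,
                    "overlap_structure": im.lesion.overlap_structure,
                }
            )
    pd.DataFrame(images_rows).to_csv(path / "images.csv", index=False)
    pd.DataFrame(
        lesion_rows,
        columns=["image_id", *_CORNER_COLS, "size_mm", "size_bin", "laterality",
                 "location", "overlap_structure"],
    ).to_csv(path / "lesions.csv", index=False)

    pd.DataFrame(
        [
            {
                "reader_id": p.reader_id,
                "group": p.group,
                "baseline_sensitivity": p.baseline_sensitivity,
                "specificity": p.specificity,
            }
            for p in sorted(bundle.readers, key=lambda p: p.reader_id)
        ],
        columns=["reader_id", "group", "baseline_sensitivity", "specificity"],
    ).to_csv(path / "readers.csv", index=False)

    ann_rows = []

    def add_set(aset: AnnotationSet) -> None:
        for image_id in sorted(aset.boxes_by_image):
            for box in aset.boxes_by_image[image_id]:
                ann_rows.append(
                    {
                        "source": aset.source,
                        "reader_id": aset.reader_id or "",
                        "arm": aset.arm,
                        "image_id": image_id,
                    }
                    | _box_row(box)
                )

    add_set(bundle.cad)
    for reader_id in sorted(bundle.sessions):
        for arm in ("pre_cad", "post_cad"):
            add_set(bundle.sessions[reader_id][arm])
    pd.DataFrame(
        ann_rows, columns=["source", "reader_id", "arm", "image_id", *_CORNER_COLS]
    ).to_csv(path / "annotations.csv", index=False)
    return path


def _opt(value) -> Optional[object]:
    return None if pd.isna(value) else value


def _read_box(row: pd.Series, box_format: str, where: str) -> BoundingBox:
    try:
        if box_format == "corners":
            vals = [float(row[c]) for c in _CORNER_COLS]
            return BoundingBox(*vals)
        x, y, w, h = (float(row[c]) for c in _XYWH_COLS)
        return BoundingBox(x, y, x + w, y + h)
    except (KeyError, ValueError) as exc:
        raise BundleError(f"{where}: invalid box ({exc})") from exc


def read_bundle(path: Union[str, Path]) -> StudyBundle:
    """Load and validate a bundle directory."""
    path = Path(path)
    try:
        manifest = json.loads((path / "manifest.json").read_text())
    except FileNotFoundError as exc:
        raise BundleError(f"missing manifest.json in {path}") from exc
    box_format = manifest.get("box_format", "corners")
    if box_format not in ("corners", "xywh"):
        raise BundleError(f"unknown box_format {box_format!r}")

    # round_trip parsing so serialized coordinates reload bit-exactly
    images_df = pd.read_csv(path / "images.csv", float_precision="round_trip")
    lesions_df = pd.read_csv(path / "lesions.csv", float_precision="round_trip")
    readers_df = pd.read_csv(path / "readers.csv", float_precision="round_trip")
    ann_df = pd.read_csv(path / "annotations.csv", keep_default_na=False,
                         na_values=[""], float_precision="round_trip")

    lesions: dict[str, LesionTruth] = {}
    for i, row in lesions_df.iterrows():
        image_id = str(row["image_id"])
        if image_id in lesions:
            raise BundleError(f"lesions.csv row {i + 2}: duplicate image {image_id}")
        lesions[image_id] = LesionTruth(
            image_id=image_id,
            box=_read_box(row, box_format, f"lesions.csv row {i + 2}"),
            size_mm=float(row["size_mm"]),
            size_bin=str(row["size_bin"]),
            laterality=str(row["laterality"]),
            location=str(row["location"]),
            overlap_structure=str(row["overlap_structure"]),
        )

    images: list[ImageRecord] = []
    seen_ids: set[str] = set()
    for i, row in images_df.iterrows():
        image_id = str(row["image_id"])
        if image_id in seen_ids:
            raise BundleError(f"images.csv row {i + 2}: duplicate image {image_id}")
        seen_ids.add(image_id)
        label = str(row["label"])
        lesion = lesions.get(image_id)
        if label == "malignant" and lesion is None:
            raise BundleError(
                f"images.csv row {i + 2}: malignant image {image_id} has no lesion"
            )
        if label == "normal" and lesion is not None:
            raise BundleError(
                f"images.csv row {i + 2}: normal image {image_id} has a lesion"
            )
        age = _opt(row.get("patient_age"))
        sex = _opt(row.get("patient_sex"))
        images.append(
            ImageRecord(
                image_id=image_id,
                label=label,  # type: ignore[arg-type]
                lesion=lesion,
                vendor=str(row["vendor"]),
                patient_age=None if age is None else float(age),
                patient_sex=None if sex is None else str(sex),
            )
        )
    orphan = sorted(set(lesions) - seen_ids)
    if orphan:
        raise BundleError(f"lesions.csv references unknown images: {orphan}")

    readers = [
        ReaderProfile(
            reader_id=str(row["reader_id"]),
            group=str(row["group"]),
            baseline_sensitivity=float(row["baseline_sensitivity"]),
            specificity=float(row["specificity"]),
        )
        for _, row in readers_df.iterrows()
    ]
    reader_ids = {p.reader_id for p in readers}
    if len(reader_ids) != len(readers):
        raise BundleError("readers.csv contains duplicate reader ids")

    cad_boxes: dict[str, list[BoundingBox]] = {}
    session_boxes: dict[tuple[str, str], dict[str, list[BoundingBox]]] = {
        (r, arm): {} for r in reader_ids for arm in ("pre_cad", "post_cad")
    }
    seen_rows: set[tuple] = set()
    for i, row in ann_df.iterrows():
        where = f"annotations.csv row {i + 2}"
        image_id = str(row["image_id"])
        if image_id not in seen_ids:
            raise BundleError(f"{where}: unknown image {image_id}")
        box = _read_box(row, box_format, where)
        source, arm = str(row["source"]), str(row["arm"])
        reader_id = _opt(row["reader_id"])
        reader_id = None if reader_id in (None, "") else str(reader_id)
        key = (source, reader_id, arm, image_id,
               box.x_min, box.y_min, box.x_max, box.y_max)
        if key in seen_rows:
            raise BundleError(f"{where}: duplicate annotation")
        seen_rows.add(key)
        if source == "cad":
            if arm != "cad":
                raise BundleError(f"{where}: CAD annotations must have arm 'cad'")
            cad_boxes.setdefault(image_id, []).append(box)
        elif source == "reader":
            if reader_id is None or reader_id not in reader_ids:
                raise BundleError(f"{where}: unknown reader {reader_id!r}")
            if arm not in ("pre_cad", "post_cad"):
                raise BundleError(f"{where}: unknown arm {arm!r}")
            session_boxes[(reader_id, arm)].setdefault(image_id, []).append(box)
        else:
            raise BundleError(f"{where}: unknown source {source!r}")

    sessions = {
        r: {
            arm: AnnotationSet(
                source="reader",
                arm=arm,  # type: ignore[arg-type]
                boxes_by_image=session_boxes[(r, arm)],
                reader_id=r,
            )
            for arm in ("pre_cad", "post_cad")
        }
        for r in sorted(reader_ids)
    }
    return StudyBundle(
        manifest=manifest,
        images=images,
        readers=sorted(readers, key=lambda p: p.reader_id),
        cad=AnnotationSet(source="cad", arm="cad", boxes_by_image=cad_boxes),
        sessions=sessions,
    )
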