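"""Synthetic reader studies with the statistical structure the analysis assumes.

The generator emulates a fixed single-institution test set read by two
groups of readers, with and without CAD assistance:

* a cohort of malignant radiographs (one nodule each) and normal
  radiographs, with nodule size / laterality / location / overlapping
  structure and acquisition-vendor composition apportioned *exactly* from
  the configured distributions — the study design evaluates one fixed test
  set, so cohort composition is deterministic and only detection outcomes
  are stochastic;
* a standalone CAD operating point: each nodule is detected independently
  with the configured sensitivity, detected nodules get a bounding box
  whose IoU with truth is drawn from ``iou_range`` (always above the 0.3
  correctness threshold), and false-positive boxes arrive as a Poisson
  count per image, placed so they never match the lesion;
* per-reader baseline operating points (group sensitivity mean plus
  Beta-distributed heterogeneity, fixed specificity), and a post-CAD arm
  modelled purely as case-state switching conditioned on the CAD's case
  correctness, with one switch probability per (CAD state, pre state) cell;
* a shared per-nodule *conspicuity* multiplier (two-point mixture: a fixed
  fraction of nodules are subtle) applied to both the CAD's and every
  reader's detection probability.  Real readers and CAD miss the same hard
  cases; without this shared-difficulty term the configured marginal
  operating points and the configured switch rates could not jointly
  reproduce a realistic post-CAD arm.  The mixture leaves every marginal
  operating point untouched (the multiplier has mean 1).

Identical config and seed give a byte-identical study bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .classify import (
    AnnotationSet,
    ImageRecord,
    LesionTruth,
    classify_study,
    size_bin_of,
)
from .geometry import BoundingBox, MatchPolicy, iou

__all__ = [
    "SwitchProbs",
    "GroupConfig",
    "StudyConfig",
    "ReaderProfile",
    "SyntheticStudy",
    "generate_truth",
    "sample_conspicuity",
    "perturbed_box",
    "generate_cad",
    "generate_readers",
    "generate_study",
]


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be a probability, got {p}")


def _check_dist(name: str, d: Mapping[str, float]) -> None:
    for k, v in d.items():
        _check_prob(f"{name}[{k}]", v)
    if abs(sum(d.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1, got {sum(d.values())}")


@dataclass(frozen=True)
class SwitchProbs:
    """Per-cell probabilities that a reader flips the case state post-CAD."""

    fn_to_tp: float  # given CAD TP on a pre-CAD FN case
    fp_to_tn: float  # given CAD TN on a pre-CAD FP case
    tp_to_fn: float  # given CAD FN on a pre-CAD TP case
    tn_to_fp: float  # given CAD FP on a pre-CAD TN case

    def __post_init__(self) -> None:
        for name in ("fn_to_tp", "fp_to_tn", "tp_to_fn", "tn_to_fp"):
            _check_prob(name, getattr(self, name))

    def for_pair(self, cad_state: str, before_state: str) -> float:
        return {
            ("TP", "FN"): self.fn_to_tp,
            ("TN", "FP"): self.fp_to_tn,
            ("FN", "TP"): self.tp_to_fn,
            ("FP", "TN"): self.tn_to_fp,
        }[(cad_state, before_state)]


@dataclass(frozen=True)
class GroupConfig:
    """One reader group: size, baseline operating point, switching behaviour."""

    name: str
    n_readers: int
    sensitivity_mean: float
    specificity: float
    switch: SwitchProbs

    def __post_init__(self) -> None:
        if self.n_readers < 1:
            raise ValueError("each group needs at least one reader")
        _check_prob("sensitivity_mean", self.sensitivity_mean)
        _check_prob("specificity", self.specificity)


# Default switch probabilities are the exact group-level transition
# proportions of the emulated study (changed / (changed + unchanged) per
# discordant cell); the TP->FN cell is a loose small default since the
# event is observed but too rare to estimate per group.
_DEFAULT_GROUPS = (
    GroupConfig(
        name="general_physician",
        n_readers=9,
        sensitivity_mean=0.47,
        specificity=0.96,
        switch=SwitchProbs(
            fn_to_tp=68 / 116, fp_to_tn=29 / 81, tp_to_fn=0.02, tn_to_fp=14 / 95
        ),
    ),
    GroupConfig(
        name="radiologist",
        n_readers=9,
        sensitivity_mean=0.51,
        specificity=0.96,
        switch=SwitchProbs(
            fn_to_tp=49 / 101, fp_to_tn=24 / 82, tp_to_fn=0.02, tn_to_fp=21 / 95
        ),
    ),
)


def _default_dict(d: dict) -> field:
    return field(default_factory=lambda: dict(d))


@dataclass
class StudyConfig:
    """Everything the generator needs; defaults emulate the reference study.

    The cohort defaults (59 malignant + 253 normal images, the size /
    laterality / location / overlap bin fractions, the per-vendor mixes)
    and the operating points (CAD sensitivity 0.66 at 0.05 FP per image,
    group baseline sensitivities 0.47 / 0.51 at specificity 0.96, the
    switch probabilities) are the printed characteristics of the emulated
    study.  ``subtle_fraction``/``subtle_multiplier`` parametrise the
    shared-conspicuity mixture; the defaults are calibrated so the joint
    frequency of (reader miss, CAD hit) matches the study's transition
    counts, which makes the post-CAD pooled sensitivity land on the
    printed 0.60.
    """

    n_malignant: int = 59
    n_normal: int = 253
    image_width: float = 2000.0
    image_height: float = 2000.0
    px_per_mm: float = 5.0
    size_bin_probs: dict[str, float] = _default_dict(
        {"<=10": 7 / 59, "11-20": 33 / 59, "21-30": 19 / 59}
    )
    laterality_probs: dict[str, float] = _default_dict(
        {"right": 39 / 59, "left": 20 / 59}
    )
    location_probs: dict[str, float] = _default_dict(
        {"upper": 23 / 59, "middle": 31 / 59, "lower": 5 / 59}
    )
    overlap_probs: dict[str, float] = _default_dict(
        {
            "heart": 2 / 59,
            "clavicle": 6 / 59,
            "diaphragm": 1 / 59,
            "hilar_vessels": 3 / 59,
            "none": 47 / 59,
        }
    )
    vendor_malignant_probs: dict[str, float] = _default_dict(
        {"FUJIFILM": 6 / 59, "KONICA": 31 / 59, "Philips": 22 / 59}
    )
    vendor_normal_probs: dict[str, float] = _default_dict(
        {"FUJIFILM": 83 / 253, "KONICA": 82 / 253, "Philips": 88 / 253}
    )
    cad_sensitivity: float = 0.66
    cad_fp_rate: float = 0.05
    groups: tuple[GroupConfig, ...] = _DEFAULT_GROUPS
    sens_concentration: float = 150.0
    subtle_fraction: float = 21 / 59
    subtle_multiplier: float = 0.127
    iou_range: tuple[float, float] = (0.4, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_malignant < 0 or self.n_normal < 0:
            raise ValueError("cohort sizes must be non-negative")
        _check_dist("size_bin_probs", self.size_bin_probs)
        _check_dist("laterality_probs", self.laterality_probs)
        _check_dist("location_probs", self.location_probs)
        _check_dist("overlap_probs", self.overlap_probs)
        _check_dist("vendor_malignant_probs", self.vendor_malignant_probs)
        _check_dist("vendor_normal_probs", self.vendor_normal_probs)
        _check_prob("cad_sensitivity", self.cad_sensitivity)
        if self.cad_fp_rate < 0:
            raise ValueError("cad_fp_rate must be non-negative")
        _check_prob("subtle_fraction", self.subtle_fraction)
        if self.subtle_multiplier < 0:
            raise ValueError("subtle_multiplier must be non-negative")
        lo, hi = self.iou_range
        if not (0.3 <= lo <= hi <= 1.0):
            raise ValueError(
                "iou_range must lie within [0.3, 1] so generated detections "
                f"pass the correctness threshold, got {self.iou_range}"
            )
        if self.sens_concentration <= 2:
            raise ValueError("sens_concentration must exceed 2")

    @property
    def reader_group_of(self) -> dict[str, str]:
        return {p.reader_id: p.group for p in make_reader_profiles_static(self)}


@dataclass(frozen=True)
class ReaderProfile:
    reader_id: str
    group: str
    baseline_sensitivity: float
    specificity: float


@dataclass
class SyntheticStudy:
    """A complete generated study: truth, CAD output, reader sessions."""

    images: list[ImageRecord]
    cad: AnnotationSet
    readers: list[ReaderProfile]
    sessions: dict[str, dict[str, AnnotationSet]]
    config: StudyConfig
    seed: int

    @property
    def reader_groups(self) -> dict[str, str]:
        return {p.reader_id: p.group for p in self.readers}


# ---------------------------------------------------------------------------
# deterministic apportionment

def _apportion(probs: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n items over categories."""
    quotas = {k: p * n for k, p in probs.items()}
    counts = {k: int(math.floor(q)) for k, q in quotas.items()}
    shortfall = n - sum(counts.values())
    by_remainder = sorted(
        probs, key=lambda k: (-(quotas[k] - counts[k]), k)
    )
    for k in by_remainder[:shortfall]:
        counts[k] += 1
    return counts


def _category_list(
    probs: Mapping[str, float], n: int, rng: np.random.Generator
) -> list[str]:
    counts = _apportion(probs, n)
    out: list[str] = []
    for k in sorted(counts):
        out.extend([k] * counts[k])
    return [out[i] for i in rng.permutation(n)]


# ---------------------------------------------------------------------------
# truth generation

_SIZE_RANGES = {"<=10": (5.0, 10.0), "11-20": (11.0, 20.0), "21-30": (21.0, 30.0)}
# lung-field band as fractions of the image extent (margins exclude
# shoulders, abdomen and the image border)
_FIELD_X = (0.08, 0.92)
_FIELD_Y = (0.10, 0.85)
_LOCATION_Y = {"upper": (0.10, 0.35), "middle": (0.35, 0.60), "lower": (0.60, 0.85)}


def _lesion_region(
    config: StudyConfig, laterality: str, location: str
) -> tuple[float, float, float, float]:
    W, H = config.image_width, config.image_height
    mid = 0.5 * (_FIELD_X[0] + _FIELD_X[1])
    # posterior-anterior view: the patient's right lung is on the image left
    if laterality == "right":
        x0, x1 = _FIELD_X[0] * W, (mid - 0.02) * W
    else:
        x0, x1 = (mid + 0.02) * W, _FIELD_X[1] * W
    y0f, y1f = _LOCATION_Y[location]
    return x0, y0f * H, x1, y1f * H


def generate_truth(
    config: StudyConfig, rng: np.random.Generator
) -> list[ImageRecord]:
    """Generate the ground-truth cohort (images and their lesions).

    Categorical attributes are apportioned exactly from the configured
    distributions (largest remainder) and randomly co-assigned; nodule
    diameters are uniform within their size bin; lesion boxes are square
    (diameter times ``px_per_mm``), placed uniformly inside the lung-field
    sub-region for their laterality and location.
    """
    n_mal, n_nor = config.n_malignant, config.n_normal
    size_bins = _category_list(config.size_bin_probs, n_mal, rng)
    lateralities = _category_list(config.laterality_probs, n_mal, rng)
    locations = _category_list(config.location_probs, n_mal, rng)
    overlaps = _category_list(config.overlap_probs, n_mal, rng)
    vendors_mal = _category_list(config.vendor_malignant_probs, n_mal, rng)
    vendors_nor = _category_list(config.vendor_normal_probs, n_nor, rng)

    images: list[ImageRecord] = []
    for i in range(n_mal):
        image_id = f"M{i + 1:03d}"
        bin_name = size_bins[i]
        lo, hi = _SIZE_RANGES[bin_name]
        size_mm = float(rng.uniform(lo, hi))
        side = size_mm * config.px_per_mm
        x0, y0, x1, y1 = _lesion_region(config, lateralities[i], locations[i])
        if side > (x1 - x0) or side > (y1 - y0):
            raise ValueError(
                f"{image_id}: lesion of {size_mm:.1f} mm does not fit the "
                "lung-field region; increase the image extent"
            )
        cx = float(rng.uniform(x0 + side / 2, x1 - side / 2))
        cy = float(rng.uniform(y0 + side / 2, y1 - side / 2))
        box = BoundingBox(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)
        lesion = LesionTruth(
            image_id=image_id,
            box=box,
            size_mm=size_mm,
            size_bin=size_bin_of(size_mm),
            laterality=lateralities[i],
            location=locations[i],
            overlap_structure=overlaps[i],
        )
        images.append(
            ImageRecord(
                image_id=image_id,
                label="malignant",
                lesion=lesion,
                vendor=vendors_mal[i],
                patient_age=float(np.clip(rng.normal(61.6, 11.4), 33, 92)),
                patient_sex="male" if rng.random() < 153 / 312 else "female",
            )
        )
    for i in range(n_nor):
        images.append(
            ImageRecord(
                image_id=f"N{i + 1:03d}",
                label="normal",
                vendor=vendors_nor[i],
                patient_age=float(np.clip(rng.normal(61.6, 11.4), 33, 92)),
                patient_sex="male" if rng.random() < 153 / 312 else "female",
            )
        )
    return images


def sample_conspicuity(
    images: Sequence[ImageRecord],
    config: StudyConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Per-image detectability multipliers (malignant images only).

    A fixed ``subtle_fraction`` of the nodules get ``subtle_multiplier``;
    the remainder get the complementary multiplier that makes the mixture
    mean exactly 1, so configured marginal sensitivities are preserved.
    The subtle set is drawn uniformly at random per study.
    """
    mal_ids = [im.image_id for im in images if im.label == "malignant"]
    n = len(mal_ids)
    if n == 0:
        return {}
    n_subtle = int(round(config.subtle_fraction * n))
    if n_subtle in (0, n):
        return {mid: 1.0 for mid in mal_ids}
    m_sub = config.subtle_multiplier
    m_consp = (n - n_subtle * m_sub) / (n - n_subtle)
    subtle = set(np.array(mal_ids)[rng.permutation(n)[:n_subtle]])
    return {mid: (m_sub if mid in subtle else m_consp) for mid in mal_ids}


# ---------------------------------------------------------------------------
# box synthesis

def perturbed_box(
    truth: BoundingBox,
    target_iou: float,
    rng: np.random.Generator,
    tol: float = 0.05,
    max_tries: int = 50,
) -> BoundingBox:
    """A box whose IoU with ``truth`` is within ``tol`` of ``target_iou``.

    Construction: draw a random isotropic rescale of the truth box within
    the range whose concentric IoU still exceeds the target, then bisect on
    the translation distance along a random direction (IoU is monotone
    decreasing under translation) until the target is hit; accept-reject
    against the tolerance band with bounded retries.
    """
    if not (0.0 < target_iou <= 1.0):
        raise ValueError(f"target_iou must be in (0, 1], got {target_iou}")
    if target_iou >= 0.999:
        return truth
    s_hi = 1.0 / math.sqrt(min(0.999, target_iou + 0.01))
    for _ in range(max_tries):
        s = float(rng.uniform(1.0 / s_hi, s_hi))
        w, h = truth.width * s, truth.height * s
        cx, cy = truth.center
        base = BoundingBox(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
        theta = float(rng.uniform(0.0, 2.0 * math.pi))
        ux, uy = math.cos(theta), math.sin(theta)
        lo, hi = 0.0, truth.width + w + truth.height + h
        if iou(base, truth) < target_iou:
            continue
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if iou(base.translated(mid * ux, mid * uy), truth) >= target_iou:
                lo = mid
            else:
                hi = mid
        candidate = base.translated(lo * ux, lo * uy)
        if abs(iou(candidate, truth) - target_iou) <= tol:
            return candidate
    raise RuntimeError(
        f"could not construct a box with IoU {target_iou:.3f} +/- {tol} "
        f"after {max_tries} attempts"
    )


def _random_fp_box(
    config: StudyConfig,
    rng: np.random.Generator,
    avoid: Optional[BoundingBox],
    threshold: float = 0.3,
    max_tries: int = 200,
) -> BoundingBox:
    """A nodule-sized box in the lung field that does not match ``avoid``."""
    W, H = config.image_width, config.image_height
    for _ in range(max_tries):
        side = float(rng.uniform(8.0, 28.0)) * config.px_per_mm
        cx = float(rng.uniform(_FIELD_X[0] * W + side / 2, _FIELD_X[1] * W - side / 2))
        cy = float(rng.uniform(_FIELD_Y[0] * H + side / 2, _FIELD_Y[1] * H - side / 2))
        box = BoundingBox(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)
        if avoid is None or iou(box, avoid) < threshold:
            return box
    raise RuntimeError("could not place a non-matching false-positive box")


# ---------------------------------------------------------------------------
# CAD and readers

def generate_cad(
    images: Sequence[ImageRecord],
    config: StudyConfig,
    rng: np.random.Generator,
    conspicuity: Optional[Mapping[str, float]] = None,
) -> AnnotationSet:
    """Simulate the standalone CAD output on every image.

    Each nodule is detected with probability ``cad_sensitivity`` (times the
    image's conspicuity multiplier when given); detections get a box with
    IoU drawn from ``iou_range``.  Every image additionally receives a
    Poisson(``cad_fp_rate``) number of false-positive boxes placed below
    the matching threshold.
    """
    boxes_by_image: dict[str, list[BoundingBox]] = {}
    lo, hi = config.iou_range
    for im in sorted(images, key=lambda im: im.image_id):
        boxes: list[BoundingBox] = []
        lesion_box = im.lesion.box if im.lesion is not None else None
        if im.lesion is not None:
            m = conspicuity.get(im.image_id, 1.0) if conspicuity else 1.0
            p = float(np.clip(config.cad_sensitivity * m, 0.0, 1.0))
            if rng.random() < p:
                boxes.append(
                    perturbed_box(im.lesion.box, float(rng.uniform(lo, hi)), rng)
                )
        for _ in range(rng.poisson(config.cad_fp_rate)):
            boxes.append(_random_fp_box(config, rng, lesion_box))
        if boxes:
            boxes_by_image[im.image_id] = boxes
    return AnnotationSet(source="cad", arm="cad", boxes_by_image=boxes_by_image)


def make_reader_profiles_static(config: StudyConfig) -> list[ReaderProfile]:
    """Reader ids and groups (baselines set to group means; no draw)."""
    profiles = []
    for g in config.groups:
        for i in range(g.n_readers):
            profiles.append(
                ReaderProfile(
                    reader_id=f"{g.name}-{i + 1:02d}",
                    group=g.name,
                    baseline_sensitivity=g.sensitivity_mean,
                    specificity=g.specificity,
                )
            )
    return profiles


def _draw_reader_profiles(
    config: StudyConfig, rng: np.random.Generator
) -> list[ReaderProfile]:
    profiles = []
    kappa = config.sens_concentration
    for g in config.groups:
        a = g.sensitivity_mean * kappa
        b = (1.0 - g.sensitivity_mean) * kappa
        for i in range(g.n_readers):
            s = float(rng.beta(a, b)) if 0 < g.sensitivity_mean < 1 else g.sensitivity_mean
            profiles.append(
                ReaderProfile(
                    reader_id=f"{g.name}-{i + 1:02d}",
                    group=g.name,
                    baseline_sensitivity=s,
                    specificity=g.specificity,
                )
            )
    return profiles


def generate_readers(
    images: Sequence[ImageRecord],
    cad: AnnotationSet,
    config: StudyConfig,
    rng: np.random.Generator,
    conspicuity: Optional[Mapping[str, float]] = None,
    policy: MatchPolicy = MatchPolicy(),
) -> tuple[list[ReaderProfile], dict[str, dict[str, AnnotationSet]]]:
    """Simulate every reader's pre-CAD and post-CAD annotation sets.

    Pre-CAD: each nodule is detected with the reader's baseline sensitivity
    (times conspicuity); a detection gets an own independently perturbed
    box.  Each normal image is called positive (one false-positive box)
    with probability 1 - specificity.  Post-CAD: the pre-CAD case state is
    flipped with the group's switch probability for the realized
    (CAD state, pre state) cell — adopting the CAD's box on FN->TP and
    TN->FP flips, deleting boxes on FP->TN and TP->FN flips — otherwise the
    pre-CAD boxes are kept unchanged.
    """
    profiles = _draw_reader_profiles(config, rng)
    switch_of = {g.name: g.switch for g in config.groups}

    cad_state = {o.image_id: o.state for o in classify_study(images, cad, policy)}
    # the CAD's matching (detection) box per malignant image, for adoption
    cad_detection: dict[str, BoundingBox] = {}
    for im in images:
        if im.lesion is None:
            continue
        for b in cad.boxes_by_image.get(im.image_id, []):
            if iou(b, im.lesion.box) >= policy.iou_threshold:
                cad_detection[im.image_id] = b
                break

    lo, hi = config.iou_range
    images_sorted = sorted(images, key=lambda im: im.image_id)
    sessions: dict[str, dict[str, AnnotationSet]] = {}
    for prof in profiles:
        switch = switch_of[prof.group]
        pre_boxes: dict[str, list[BoundingBox]] = {}
        post_boxes: dict[str, list[BoundingBox]] = {}
        for im in images_sorted:
            if im.lesion is not None:
                m = conspicuity.get(im.image_id, 1.0) if conspicuity else 1.0
                p = float(np.clip(prof.baseline_sensitivity * m, 0.0, 1.0))
                detected = rng.random() < p
                boxes = (
                    [perturbed_box(im.lesion.box, float(rng.uniform(lo, hi)), rng)]
                    if detected
                    else []
                )
                before = "TP" if detected else "FN"
            else:
                called = rng.random() < (1.0 - prof.specificity)
                boxes = [_random_fp_box(config, rng, None)] if called else []
                before = "FP" if called else "TN"
            if boxes:
                pre_boxes[im.image_id] = boxes

            cad_s = cad_state[im.image_id]
            pair = (cad_s, before)
            after = list(boxes)
            if pair == ("TP", "FN") and rng.random() < switch.fn_to_tp:
                after = [cad_detection[im.image_id]]
            elif pair == ("TN", "FP") and rng.random() < switch.fp_to_tn:
                after = []
            elif pair == ("FN", "TP") and rng.random() < switch.tp_to_fn:
                after = []
            elif pair == ("FP", "TN") and rng.random() < switch.tn_to_fp:
                after = list(cad.boxes_by_image[im.image_id])
            if after:
                post_boxes[im.image_id] = after

        sessions[prof.reader_id] = {
            "pre_cad": AnnotationSet(
                source="reader",
                arm="pre_cad",
                boxes_by_image=pre_boxes,
                reader_id=prof.reader_id,
            ),
            "post_cad": AnnotationSet(
                source="reader",
                arm="post_cad",
                boxes_by_image=post_boxes,
                reader_id=prof.reader_id,
            ),
        }
    return profiles, sessions


def generate_study(config: StudyConfig = StudyConfig()) -> SyntheticStudy:
    """Generate a complete synthetic reader study from a config and seed."""
    rng = np.random.default_rng(config.seed)
    images = generate_truth(config, rng)
    conspicuity = sample_conspicuity(images, config, rng)
    cad = generate_cad(images, config, rng, conspicuity)
    readers, sessions = generate_readers(images, cad, config, rng, conspicuity)
    return SyntheticStudy(
        images=images,
        cad=cad,
        readers=readers,
        sessions=sessions,
        config=config,
        seed=config.seed,
    )
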