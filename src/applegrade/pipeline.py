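"""Multi-view grading decision logic.

A fruit rolling through the detection area yields several camera views.  The
decision chain is:

1. **Defect override** — any view with a surface-defect detection sends the
   fruit straight to grade 3; later evidence is ignored.
2. **View filtering** — views showing the stem/calyx are discarded (top poses
   hide defects and bias the color measurement); only side views are graded.
3. **Rule grading** — each side view is graded on the national-standard
   thresholds (color coverage, shape index, diameter, defect area); the
   per-fruit grade on one view is the worst of its per-characteristic grades.
4. **Aggregation** — surviving per-view grades are combined by a
   confidence-weighted vote, ties broken toward the worse grade.

Grades are 1 (best), 2, 3; fruit below every grade-3 floor is ``reject``
(such fruit is normally culled before grading, so it is reported distinctly
rather than folded into grade 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import AppleFeatures, CalibrationConfig, extract_features

__all__ = [
    "Detection",
    "ViewRecord",
    "GradeDecision",
    "GRADE_RULES",
    "rule_grade",
    "filter_views",
    "defect_override",
    "aggregate_grades",
    "decide_for_apple",
    "run_pipeline",
    "iou",
]

logger = logging.getLogger("applegrade.pipeline")

REJECT = "reject"

#: National-standard thresholds (GB/T10651-2008 as used for Red Fuji):
#: each characteristic maps measured value -> per-characteristic grade.
GRADE_RULES = {
    "color": ((0.80, 1), (0.55, 2), (0.0, 3)),
    "shape": ((0.85, 1), (0.80, 2), (0.75, 3)),
    "diameter_mm": ((70.0, 1), (65.0, 2), (60.0, 3)),
}
MAX_DEFECT_CM2 = 3.0


@dataclass(frozen=True)
class Detection:
    """One detector output box in pixel coordinates (half-open intervals)."""

    label: str
    bbox: tuple[float, float, float, float]  # x_min, y_min, x_max, y_max
    confidence: float

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate bbox {self.bbox}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")


@dataclass
class ViewRecord:
    """Everything one frame contributes about one fruit."""

    frame_id: str
    apple_id: int
    detections: list[Detection] = field(default_factory=list)
    grade_prediction: tuple[int, float] | None = None  # (grade, confidence)


@dataclass
class GradeDecision:
    final_grade: int | str  # 1 | 2 | 3 | "reject"
    rule_fired: str  # defect_override | weighted_vote | rule_table | reject
    views_used: list[str] = field(default_factory=list)
    score_breakdown: dict[int, float] = field(default_factory=dict)
    low_confidence: bool = False
    apple_id: int | None = None


def _characteristic_grade(value: float, thresholds) -> int | str:
    for floor, grade in thresholds:
        if value >= floor:
            return grade
    return REJECT


def rule_grade(features: AppleFeatures) -> int | str:
    """Grade one view's measurements against the standard's thresholds.

    The final grade is the worst per-characteristic grade; any characteristic
    below its grade-3 floor (or a defect above 3 cm²) rejects the fruit.  Any
    nonzero defect already caps the fruit at grade 3.
    """
    grades = [
        _characteristic_grade(features.color_ratio, GRADE_RULES["color"]),
        _characteristic_grade(features.shape_index, GRADE_RULES["shape"]),
        _characteristic_grade(features.diameter_mm, GRADE_RULES["diameter_mm"]),
    ]
    if features.defect_area_cm2 > MAX_DEFECT_CM2:
        return REJECT
    if features.defect_area_cm2 > 0:
        grades.append(3)
    if REJECT in grades:
        return REJECT
    return max(grades)


def filter_views(views: list[ViewRecord], stem_conf_min: float = 0.5) -> list[ViewRecord]:
    """Drop views containing a stem/calyx detection at or above threshold."""
    kept = []
    for view in views:
        has_stem = any(
            d.label == "stem_calyx" and d.confidence >= stem_conf_min for d in view.detections
        )
        if not has_stem:
            kept.append(view)
    return kept


def defect_override(views: list[ViewRecord], defect_conf_min: float = 0.5) -> GradeDecision | None:
    """Grade-3 short-circuit if any view shows a confident surface defect."""
    for view in views:
        for det in view.detections:
            if det.label == "defect" and det.confidence >= defect_conf_min:
                return GradeDecision(
                    final_grade=3,
                    rule_fired="defect_override",
                    views_used=[view.frame_id],
                    apple_id=view.apple_id,
                )
    return None


def aggregate_grades(kept_views: list[ViewRecord]) -> GradeDecision:
    """Confidence-weighted vote over per-view grades; worse grade wins ties."""
    if not kept_views:
        logger.warning("no views left to aggregate; emitting reject decision")
        return GradeDecision(final_grade=REJECT, rule_fired="reject")
    weights: dict[int | str, float] = {}
    for view in kept_views:
        if view.grade_prediction is None:
            raise ValueError(f"view {view.frame_id} has no grade prediction")
        grade, conf = view.grade_prediction
        weights[grade] = weights.get(grade, 0.0) + conf
    best_weight = max(weights.values())
    severity = {1: 1, 2: 2, 3: 3, REJECT: 4}
    # ties toward the worse grade (reject counts as worst)
    final = max(
        (g for g, w in weights.items() if w >= best_weight - 1e-12),
        key=lambda g: severity[g],
    )
    return GradeDecision(
        final_grade=final,
        rule_fired="weighted_vote",
        views_used=[v.frame_id for v in kept_views],
        score_breakdown={g: weights[g] for g in sorted(weights, key=lambda g: severity[g])},
        apple_id=kept_views[0].apple_id,
    )


def decide_for_apple(
    views: list[ViewRecord],
    stem_conf_min: float = 0.5,
    defect_conf_min: float = 0.5,
) -> GradeDecision:
    """Full per-fruit decision: override, filter, aggregate (with fallback).

    If every view is discarded by the stem filter, all views are used instead
    and the decision is flagged low-confidence — a running line must still
    emit a grade.
    """
    override = defect_override(views, defect_conf_min)
    if override is not None:
        return override
    kept = filter_views(views, stem_conf_min)
    low_confidence = False
    if not kept and views:
        logger.warning(
            "apple %s: every view shows a stem; falling back to all views",
            views[0].apple_id,
        )
        kept = views
        low_confidence = True
    kept = [v for v in kept if v.grade_prediction is not None]
    decision = aggregate_grades(kept)
    decision.low_confidence = decision.low_confidence or low_confidence
    return decision


def iou(a: tuple[float, float, float, float], b: tuple[float, float, float, float]) -> float:
    """Intersection-over-union of two half-open axis-aligned boxes."""
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(0.0, ix1 - ix0) * max(0.0, iy1 - iy0)
    if inter == 0.0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def detect_apples_classical(
    image: np.ndarray,
    min_area: int = 2000,
    margin: int = 4,
) -> list[dict]:
    """Find fruit candidates in a full frame by threshold segmentation.

    Thresholds the max-channel projection (fruit bright in at least one
    channel, belt dark in all), labels connected components and returns one
    record per sufficiently large component: ``bbox`` plus an image ``crop``
    suitable for :func:`applegrade.features.extract_features`.
    """
    from scipy import ndimage as ndi

    from .features import clean_mask, otsu_threshold

    arr = np.asarray(image, dtype=np.float64)
    gray = arr.max(axis=2) if arr.ndim == 3 else arr
    thresh, degenerate = otsu_threshold(gray)
    if degenerate:
        return []
    mask = clean_mask(gray > thresh, min_area=min_area)
    labels, n = ndi.label(mask)
    records = []
    for idx in range(1, n + 1):
        component = labels == idx
        if component.sum() < min_area:
            continue
        ys, xs = np.nonzero(component)
        y0 = max(0, ys.min() - margin)
        x0 = max(0, xs.min() - margin)
        y1 = min(arr.shape[0], ys.max() + 1 + margin)
        x1 = min(arr.shape[1], xs.max() + 1 + margin)
        records.append(
            {
                "bbox": (float(x0), float(y0), float(x1), float(y1)),
                "image": arr[y0:y1, x0:x1],
                # frame-level silhouette: more reliable than re-thresholding a
                # crop whose intensity statistics are foreground-dominated
                "mask": component[y0:y1, x0:x1],
            }
        )
    return records


def frames_from_images(
    images: list[np.ndarray],
    frame_ids: list[str] | None = None,
    min_area: int = 2000,
) -> list[dict]:
    """Build the :func:`run_pipeline` frame structure from raw frames."""
    frames = []
    for i, image in enumerate(images):
        frame_id = frame_ids[i] if frame_ids else f"frame_{i:04d}"
        frames.append({"frame_id": frame_id, "apples": detect_apples_classical(image, min_area)})
    return frames


class _Track:
    __slots__ = ("apple_id", "bbox", "views")

    def __init__(self, apple_id: int, bbox, view: ViewRecord):
        self.apple_id = apple_id
        self.bbox = bbox
        self.views = [view]


def run_pipeline(
    frames: list[dict],
    stem_conf_min: float = 0.5,
    defect_conf_min: float = 0.5,
    iou_min: float = 0.3,
    calib: CalibrationConfig | None = None,
    classical_grading: bool = False,
) -> list[GradeDecision]:
    """Grade every fruit track across an ordered frame sequence.

    Each frame is a dict with keys:

    * ``frame_id`` — identifier;
    * ``apples`` — list of per-fruit records, each with ``bbox`` and either
      scripted ``detections`` / ``grade_prediction`` (stub mode) or an
      ``image`` crop plus optional ``defect_mask`` for classical grading.

    Fruit are associated frame-to-frame by greedy IoU matching (threshold
    ``iou_min``); the conveyor keeps fruit in lanes so overlap tracking is
    sufficient.  With ``classical_grading=True`` the per-view grade comes
    from the measured features via :func:`rule_grade` (confidence 1.0)
    instead of a scripted prediction.
    """
    calib = calib or CalibrationConfig()
    tracks: list[_Track] = []
    next_id = 0
    for frame in frames:
        frame_id = str(frame.get("frame_id", ""))
        apples = frame.get("apples", [])
        matched: set[int] = set()
        for record in apples:
            bbox = tuple(record["bbox"])
            view = ViewRecord(
                frame_id=frame_id,
                apple_id=-1,
                detections=[
                    d if isinstance(d, Detection) else Detection(**d)
                    for d in record.get("detections", [])
                ],
                grade_prediction=record.get("grade_prediction"),
            )
            if classical_grading and "image" in record:
                try:
                    feats = extract_features(
                        record["image"],
                        calib,
                        mask=record.get("mask"),
                        defect_mask=record.get("defect_mask"),
                    )
                    view.grade_prediction = (rule_grade(feats), 1.0)
                except ValueError as exc:
                    logger.warning("frame %s: feature extraction failed (%s)", frame_id, exc)

            best_track, best_iou = None, iou_min
            for t_idx, track in enumerate(tracks):
                if t_idx in matched:
                    continue
                overlap = iou(bbox, track.bbox)
                if overlap >= best_iou:
                    best_track, best_iou = t_idx, overlap
            if best_track is None:
                view.apple_id = next_id
                tracks.append(_Track(next_id, bbox, view))
                matched.add(len(tracks) - 1)
                next_id += 1
            else:
                track = tracks[best_track]
                view.apple_id = track.apple_id
                track.bbox = bbox
                track.views.append(view)
                matched.add(best_track)

    decisions = []
    for track in tracks:
        decision = decide_for_apple(track.views, stem_conf_min, defect_conf_min)
        decision.apple_id = track.apple_id
        grade_views = [v for v in track.views if v.grade_prediction is not None]
        if decision.rule_fired == "weighted_vote" and not decision.views_used and grade_views:
            decision.views_used = [v.frame_id for v in grade_views]
        logger.info(
            "apple %d -> %s via %s (%d views)",
            track.apple_id,
            decision.final_grade,
            decision.rule_fired,
            len(decision.views_used),
        )
        decisions.append(decision)
    return decisions
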