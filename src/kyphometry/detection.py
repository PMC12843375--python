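"""Vertebra detection stand-in and detection-evaluation harness.

The harness implements the standard object-detection protocol: a prediction
counts as a true positive when it overlaps an unmatched ground-truth box with
IoU ≥ 0.5 (greedy matching in descending confidence order), image-level
success requires every visible vertebra to be detected, and the summary
metrics are precision, recall, F1, AP@0.5, AP@0.5:0.95 (101-point
interpolation) and mean IoU ± SD over matched pairs.  Ground-truth boxes
flagged as partially visible are excluded from evaluation: they count
neither as false negatives nor toward the IoU pool, and predictions matched
to them are ignored.

``detect_blobs`` is a classical intensity-threshold detector for the
synthetic phantoms: it exists so the evaluation harness can be exercised
end-to-end on images without any trained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import EmptyDatasetError
from .geometry import THORACIC_LEVELS, VertebraLevel

__all__ = [
    "BoundingBox",
    "MatchResult",
    "LevelMetrics",
    "DetectionEvalReport",
    "detect_blobs",
    "iou",
    "match_detections",
    "evaluate_detections",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel-edge coordinates (x_min < x_max,
    y_min < y_max).  ``level`` is the vertebral level when known, ``partial``
    marks ground-truth boxes of partially visible vertebrae (excluded from
    evaluation)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    level: VertebraLevel | None = None
    confidence: float = 1.0
    partial: bool = False

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("box must have positive width and height")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 when equal."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def detect_blobs(
    image: np.ndarray,
    min_area: float = 40.0,
    intensity_threshold: float = 0.5,
) -> list[BoundingBox]:
    """Classical blob detector for phantom images.

    Thresholds the image at ``intensity_threshold``, extracts connected
    components, drops components smaller than ``min_area`` pixels and returns
    each survivor's tight axis-aligned box with confidence equal to the mean
    interior intensity.  Boxes are sorted cranially (ascending center y).
    When exactly nine survive they are assigned levels Th4…Th12 in
    cranio-caudal order; otherwise levels stay unassigned.
    """
    img = np.asarray(image, dtype=float)
    mask = img > intensity_threshold
    labels = cc_label(mask)
    boxes: list[BoundingBox] = []
    for prop in regionprops(labels, intensity_image=img):
        if prop.area < min_area:
            continue
        r0, c0, r1, c1 = prop.bbox
        boxes.append(
            BoundingBox(
                x_min=float(c0),
                y_min=float(r0),
                x_max=float(c1),
                y_max=float(r1),
                confidence=float(min(prop.intensity_mean, 1.0)),
            )
        )
    boxes.sort(key=lambda b: b.center[1])
    if len(boxes) == len(THORACIC_LEVELS):
        boxes = [
            BoundingBox(
                b.x_min, b.y_min, b.x_max, b.y_max,
                level=THORACIC_LEVELS[i], confidence=b.confidence,
            )
            for i, b in enumerate(boxes)
        ]
    return boxes


@dataclass
class MatchResult:
    """Outcome of matching one image's predictions against its truths.

    ``matches`` holds (pred_index, truth_index, iou) triples; indices not in
    any match are false positives (predictions) / false negatives (truths).
    ``ignored_preds`` are predictions whose only admissible match was a
    partial truth box.  ``image_success`` is true iff every non-partial truth
    was matched.
    """

    matches: list[tuple[int, int, float]] = field(default_factory=list)
    fp_indices: list[int] = field(default_factory=list)
    fn_indices: list[int] = field(default_factory=list)
    ignored_preds: list[int] = field(default_factory=list)
    ignored_truths: list[int] = field(default_factory=list)
    image_success: bool = False


def match_detections(
    pred: Sequence[BoundingBox],
    truth: Sequence[BoundingBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground truth.

    Predictions are visited in descending confidence order; each is matched
    to the unmatched non-partial truth box of highest IoU ≥ ``iou_threshold``.
    A prediction that only reaches a partial truth at or above threshold is
    ignored (neither TP nor FP), as is the partial truth itself.
    """
    order = sorted(range(len(pred)), key=lambda i: -pred[i].confidence)
    matched_truth: set[int] = set()
    result = MatchResult()
    real_truth = [j for j, t in enumerate(truth) if not t.partial]
    partial_truth = [j for j, t in enumerate(truth) if t.partial]
    result.ignored_truths = list(partial_truth)
    for i in order:
        best_j, best_iou = -1, -1.0
        for j in real_truth:
            if j in matched_truth:
                continue
            v = iou(pred[i], truth[j])
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched_truth.add(best_j)
            result.matches.append((i, best_j, best_iou))
            continue
        # no admissible real truth: ignore if a partial truth would match
        best_partial = 0.0
        for j in partial_truth:
            if j in matched_truth:
                continue
            best_partial = max(best_partial, iou(pred[i], truth[j]))
        if best_partial >= iou_threshold:
            result.ignored_preds.append(i)
        else:
            result.fp_indices.append(i)
    result.fn_indices = [j for j in real_truth if j not in matched_truth]
    result.image_success = not result.fn_indices and bool(real_truth)
    return result


@dataclass(frozen=True)
class LevelMetrics:
    precision: float | None
    recall: float | None
    f1: float | None
    mean_iou: float | None
    missed_count: int


@dataclass(frozen=True)
class DetectionEvalReport:
    """Pooled and per-level detection metrics over a dataset."""

    n_images: int
    precision: float
    recall: float
    f1: float
    ap50: float
    ap50_95: float
    mean_iou: float
    iou_sd: float
    image_success_rate: float
    tp: int
    fp: int
    fn: int
    per_level: dict[VertebraLevel, LevelMetrics] = field(default_factory=dict)

    def missed_counts(self) -> dict[VertebraLevel, int]:
        return {lvl: m.missed_count for lvl, m in self.per_level.items()}


def _f1(p: float | None, r: float | None) -> float | None:
    if p is None or r is None or (p + r) == 0:
        return 0.0 if (p is not None and r is not None) else None
    return 2 * p * r / (p + r)


def _average_precision(
    dataset: Sequence[tuple[Sequence[BoundingBox], Sequence[BoundingBox]]],
    iou_threshold: float,
) -> float:
    """AP at one IoU threshold with 101-point interpolated PR integration."""
    n_pos = sum(sum(1 for t in truth if not t.partial) for _, truth in dataset)
    if n_pos == 0:
        return 0.0
    # global ranking of predictions by confidence
    ranked: list[tuple[float, int, int]] = []  # (conf, image_idx, pred_idx)
    for k, (pred, _) in enumerate(dataset):
        for i, p in enumerate(pred):
            ranked.append((p.confidence, k, i))
    ranked.sort(key=lambda t: -t[0])

    matched: list[set[int]] = [set() for _ in dataset]
    tps, fps = [], []
    for conf, k, i in ranked:
        pred, truth = dataset[k]
        best_j, best_iou = -1, -1.0
        for j, t in enumerate(truth):
            if t.partial or j in matched[k]:
                continue
            v = iou(pred[i], truth[j])
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched[k].add(best_j)
            tps.append(1.0)
            fps.append(0.0)
            continue
        best_partial = max(
            (iou(pred[i], t) for t in truth if t.partial), default=0.0
        )
        if best_partial >= iou_threshold:
            continue  # ignored prediction
        tps.append(0.0)
        fps.append(1.0)
    if not tps:
        return 0.0
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(fps)
    recall = tp_cum / n_pos
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        mask = recall >= r
        ap += float(precision[mask].max()) if mask.any() else 0.0
    return ap / 101.0


def evaluate_detections(
    dataset: Sequence[tuple[Sequence[BoundingBox], Sequence[BoundingBox]]],
    iou_threshold: float = 0.5,
) -> DetectionEvalReport:
    """Evaluate a dataset of (predictions, ground truth) image pairs.

    Pooled precision/recall/F1 use TP/FP/FN tallies from greedy matching at
    ``iou_threshold``; AP@0.5 and AP@0.5:0.95 use 101-point interpolation;
    mean IoU ± SD is over matched pairs.  Per-level metrics are reported
    where the boxes carry level labels (recall and missed counts need truth
    labels; precision additionally needs prediction labels).
    """
    if len(dataset) == 0:
        raise EmptyDatasetError("detection evaluation needs at least one image")

    tp = fp = fn = 0
    ious: list[float] = []
    successes = 0
    lvl_tp: dict[VertebraLevel, int] = {}
    lvl_fp: dict[VertebraLevel, int] = {}
    lvl_fn: dict[VertebraLevel, int] = {}
    lvl_iou: dict[VertebraLevel, list[float]] = {}
    seen_levels: set[VertebraLevel] = set()

    for pred, truth in dataset:
        res = match_detections(pred, truth, iou_threshold)
        tp += len(res.matches)
        fp += len(res.fp_indices)
        fn += len(res.fn_indices)
        successes += res.image_success
        ious.extend(v for _, _, v in res.matches)
        for t in truth:
            if t.level is not None and not t.partial:
                seen_levels.add(t.level)
        for i, j, v in res.matches:
            lvl = truth[j].level
            if lvl is not None:
                lvl_tp[lvl] = lvl_tp.get(lvl, 0) + 1
                lvl_iou.setdefault(lvl, []).append(v)
        for j in res.fn_indices:
            lvl = truth[j].level
            if lvl is not None:
                lvl_fn[lvl] = lvl_fn.get(lvl, 0) + 1
        for i in res.fp_indices:
            lvl = pred[i].level
            if lvl is not None:
                lvl_fp[lvl] = lvl_fp.get(lvl, 0) + 1
                seen_levels.add(lvl)

    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    ap50 = _average_precision(dataset, 0.5)
    ap_grid = [
        _average_precision(dataset, t) for t in np.arange(0.50, 0.951, 0.05)
    ]
    per_level: dict[VertebraLevel, LevelMetrics] = {}
    for lvl in sorted(seen_levels):
        ltp = lvl_tp.get(lvl, 0)
        lfp = lvl_fp.get(lvl, 0)
        lfn = lvl_fn.get(lvl, 0)
        lp = ltp / (ltp + lfp) if (ltp + lfp) else None
        lr = ltp / (ltp + lfn) if (ltp + lfn) else None
        per_level[lvl] = LevelMetrics(
            precision=lp,
            recall=lr,
            f1=_f1(lp, lr),
            mean_iou=float(np.mean(lvl_iou[lvl])) if lvl in lvl_iou else None,
            missed_count=lfn,
        )

    iou_arr = np.asarray(ious, dtype=float)
    return DetectionEvalReport(
        n_images=len(dataset),
        precision=precision,
        recall=recall,
        f1=_f1(precision, recall) or 0.0,
        ap50=ap50,
        ap50_95=float(np.mean(ap_grid)),
        mean_iou=float(iou_arr.mean()) if iou_arr.size else 0.0,
        iou_sd=float(iou_arr.std()) if iou_arr.size else 0.0,
        image_success_rate=successes / len(dataset),
        tp=tp,
        fp=fp,
        fn=fn,
        per_level=per_level,
    )
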