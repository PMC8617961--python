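"""Segmentation and counting evaluation.

Three levels of assessment:

* pixel level — a TP/FP/FN/TN confusion tally at the 0.5 probability
  threshold and the IOU metric ``TP / (TP + FN + FP)``;
* count level — detected blobs vs ground-truth instances, reported as a
  ratio truncated (not rounded) to three decimals, the convention under
  which 337/361 prints as 0.933;
* instance level — greedy one-to-one matching of predicted blobs to
  annotated instances (a blob matches when its centroid lies inside an
  unmatched instance mask; pairs are taken in decreasing overlap
  order), yielding strict FP/FN totals, plus a *forgiving* re-count
  that excludes false positives sitting on a real organism (centroid
  inside a full-shape annotation) and false negatives whose central
  disc is effectively invisible (rasterized disc area below a
  visibility threshold).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .annotations import AnnotationSet
from .quantify import CountingConfig, CountReport, count_pipeline
from .segmentation import binarize


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion tallies of two equally shaped binary masks."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def iou(c: ConfusionCounts) -> float:
    """Intersection over union TP / (TP + FN + FP)."""
    denom = c.tp + c.fn + c.fp
    if denom == 0:
        raise ValueError("IOU undefined: prediction and truth are both empty")
    return c.tp / denom


def count_ratio(detected: int, ground_truth: int) -> float:
    """Detected/ground-truth ratio truncated to three decimals."""
    if ground_truth <= 0:
        raise ValueError("ground truth count must be positive")
    return (detected * 1000 // ground_truth) / 1000


@dataclass
class InstanceMatchReport:
    """Instance-level accounting with strict and forgiving totals."""

    n_matched: int
    fp_blobs: list[int]  # unmatched predicted blob labels
    fn_instances: list[int]  # unmatched ground-truth polygon indices
    fp_excluded: list[int] = field(default_factory=list)
    fn_excluded: list[int] = field(default_factory=list)

    @property
    def strict_fp(self) -> int:
        return len(self.fp_blobs)

    @property
    def strict_fn(self) -> int:
        return len(self.fn_instances)

    @property
    def forgiving_fp(self) -> int:
        return self.strict_fp - len(self.fp_excluded)

    @property
    def forgiving_fn(self) -> int:
        return self.strict_fn - len(self.fn_excluded)

    def to_dict(self) -> dict:
        return {
            "n_matched": self.n_matched,
            "strict_fp": self.strict_fp,
            "strict_fn": self.strict_fn,
            "forgiving_fp": self.forgiving_fp,
            "forgiving_fn": self.forgiving_fn,
            "fp_blobs": list(self.fp_blobs),
            "fn_instances": list(self.fn_instances),
            "fp_excluded": list(self.fp_excluded),
            "fn_excluded": list(self.fn_excluded),
        }


def _instance_masks(truth: AnnotationSet, height: int, width: int) -> list[np.ndarray]:
    return [p.mask(height, width) for p in truth.polygons]


def match_instances(
    pred_labels: np.ndarray, truth: AnnotationSet
) -> InstanceMatchReport:
    """Greedy one-to-one matching of predicted blobs to annotations.

    Candidate (blob, instance) pairs where the blob centroid lies
    inside the instance mask are assigned in decreasing overlap order;
    each blob and each instance matches at most once.
    """
    pred_labels = np.asarray(pred_labels)
    h, w = pred_labels.shape
    n_blobs = int(pred_labels.max())
    blob_ids = list(range(1, n_blobs + 1))
    masks = _instance_masks(truth, h, w)

    centroids = ndimage.center_of_mass(
        pred_labels > 0, pred_labels, blob_ids
    ) if n_blobs else []

    candidates = []  # (overlap, blob, instance)
    for b, (cy, cx) in zip(blob_ids, centroids):
        ry, rx = int(round(cy)), int(round(cx))
        ry = min(max(ry, 0), h - 1)
        rx = min(max(rx, 0), w - 1)
        blob_mask = pred_labels == b
        for i, imask in enumerate(masks):
            if imask[ry, rx]:
                overlap = int(np.count_nonzero(blob_mask & imask))
                candidates.append((overlap, b, i))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    matched_blobs: set[int] = set()
    matched_instances: set[int] = set()
    for _, b, i in candidates:
        if b in matched_blobs or i in matched_instances:
            continue
        matched_blobs.add(b)
        matched_instances.add(i)

    fp = [b for b in blob_ids if b not in matched_blobs]
    fn = [i for i in range(len(masks)) if i not in matched_instances]
    return InstanceMatchReport(
        n_matched=len(matched_blobs), fp_blobs=fp, fn_instances=fn
    )


def forgiving_adjust(
    report: InstanceMatchReport,
    pred_labels: np.ndarray,
    truth: AnnotationSet,
    full_truth: AnnotationSet,
    disc_truth: AnnotationSet,
    visibility_min_area: int = 40,
) -> InstanceMatchReport:
    """Apply the forgiving exclusions to a strict instance report.

    A false-positive blob is excluded when its centroid falls inside
    any full-shape instance (the organism is present even though its
    disc was missed).  A false negative is excluded when the disc
    belonging to the missed instance rasterizes to fewer than
    ``visibility_min_area`` pixels (no distinguishable disc; a missing
    disc polygon counts as area 0).
    """
    pred_labels = np.asarray(pred_labels)
    h, w = pred_labels.shape
    full_masks = _instance_masks(full_truth, h, w)

    fp_excluded = []
    if report.fp_blobs:
        centroids = ndimage.center_of_mass(
            pred_labels > 0, pred_labels, report.fp_blobs
        )
        for b, (cy, cx) in zip(report.fp_blobs, centroids):
            ry = min(max(int(round(cy)), 0), h - 1)
            rx = min(max(int(round(cx)), 0), w - 1)
            if any(m[ry, rx] for m in full_masks):
                fp_excluded.append(b)

    fn_excluded = []
    if report.fn_instances:
        truth_masks = _instance_masks(truth, h, w)
        disc_centroids = [p.centroid() for p in disc_truth.polygons]
        for i in report.fn_instances:
            imask = truth_masks[i]
            area = 0
            for dpoly, (dx, dy) in zip(disc_truth.polygons, disc_centroids):
                rx = min(max(int(round(dx)), 0), w - 1)
                ry = min(max(int(round(dy)), 0), h - 1)
                if imask[ry, rx]:
                    area = dpoly.area(h, w)
                    break
            if area < visibility_min_area:
                fn_excluded.append(i)

    return InstanceMatchReport(
        n_matched=report.n_matched,
        fp_blobs=list(report.fp_blobs),
        fn_instances=list(report.fn_instances),
        fp_excluded=fp_excluded,
        fn_excluded=fn_excluded,
    )


@dataclass
class EvalReport:
    """Aggregate of the pixel, count and instance level results."""

    iou: float
    blobs_detected: int
    ground_truth_count: int
    count_ratio: float
    confusion: ConfusionCounts
    count_report: CountReport | None = None
    instance_report: InstanceMatchReport | None = None

    def to_dict(self) -> dict:
        d = {
            "iou": self.iou,
            "blobs_detected": self.blobs_detected,
            "ground_truth_count": self.ground_truth_count,
            "count_ratio": self.count_ratio,
            "confusion": dataclasses.asdict(self.confusion),
        }
        if self.count_report is not None:
            d["count_report"] = self.count_report.to_dict()
        if self.instance_report is not None:
            d["instance_report"] = self.instance_report.to_dict()
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate(
    pred_prob: np.ndarray,
    truth: AnnotationSet,
    config: CountingConfig | None = None,
    threshold: float = 0.5,
    full_truth: AnnotationSet | None = None,
    disc_truth: AnnotationSet | None = None,
    visibility_min_area: int = 40,
) -> EvalReport:
    """Binarize, score pixels, count blobs and match instances.

    When both annotation variants are supplied the instance report also
    carries the forgiving totals.
    """
    from .annotations import rasterize

    config = config or CountingConfig()
    prob = np.asarray(pred_prob)
    h, w = prob.shape[:2]
    pred_mask = prob if prob.dtype == bool else binarize(prob, threshold)
    truth_mask = rasterize(truth, h, w)

    conf = confusion(pred_mask, truth_mask)
    the_iou = iou(conf) if (conf.tp + conf.fp + conf.fn) > 0 else 1.0

    labels, count_report = count_pipeline(pred_mask, config)
    gt = len(truth)
    ratio = count_ratio(count_report.blobs_detected, gt) if gt > 0 else float("nan")

    instance_report = match_instances(labels, truth)
    if full_truth is not None and disc_truth is not None:
        instance_report = forgiving_adjust(
            instance_report, labels, truth, full_truth, disc_truth,
            visibility_min_area,
        )

    return EvalReport(
        iou=the_iou,
        blobs_detected=count_report.blobs_detected,
        ground_truth_count=gt,
        count_ratio=ratio,
        confusion=conf,
        count_report=count_report,
        instance_report=instance_report,
    )
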