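"""Object-detection evaluation: IoU matching, precision/sensitivity/F1,
per-class one-vs-rest accuracy, average precision, and Cohen's kappa.

The report layout mirrors the standard per-class table of a three-class
lesion detector (normal / dysplasia / SCC): one row per class with accuracy,
precision, sensitivity, F1 and AP as percentages, a macro-mean row, and a
single chance-corrected kappa for the model.  Percentages are rounded
half-up to one decimal for display only; full precision is kept internally
and means are taken before rounding.

Conventions (configurable where noted):

* Boxes are half-open pixel rectangles ``[x_min, x_max) × [y_min, y_max)``.
* A prediction is a true positive when its IoU with an unmatched same-class
  ground truth reaches the threshold (default 0.5); matching is greedy in
  descending confidence, ties broken by input order.
* Per-class accuracy is one-vs-rest over the item universe consisting of all
  ground-truth boxes plus unmatched (false-positive) detections.
* Kappa is computed on the item-level class-assignment confusion matrix from
  class-agnostic matching, with a background row/column for unmatched items.
* AP uses all-point interpolation by default; 11-point is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Box",
    "MatchResult",
    "ClassMetrics",
    "ModelReport",
    "DEFAULT_CLASSES",
    "iou",
    "match_detections",
    "class_metrics",
    "average_precision",
    "cohens_kappa",
    "confusion_from_matches",
    "build_report",
    "evaluate_detections",
    "read_detections_json",
    "write_detections_json",
    "make_synthetic_detections",
    "round_half_up",
]

DEFAULT_CLASSES = ("normal", "dysplasia", "SCC")
BACKGROUND = "background"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (display convention for percentages)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Box:
    """Axis-aligned box, half-open [x_min, x_max) x [y_min, y_max) in pixels."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_label: str
    confidence: float | None = None  # predictions only

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("box must have positive width and height")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must be in [0, 1]")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1]."""
    iw = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    ih = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


@dataclass
class MatchResult:
    """Greedy matching outcome: per-class counts plus matched index pairs."""

    counts: dict            # class -> {"tp": int, "fp": int, "fn": int}
    matches: list           # (pred_index, gt_index, iou) in match order
    rankings: dict          # class -> list of (confidence, is_tp) for AP
    n_gt: dict              # class -> number of ground truths


def match_detections(
    preds: list[Box],
    gts: list[Box],
    iou_threshold: float = 0.5,
    class_aware: bool = True,
) -> MatchResult:
    """Greedily match predictions to ground truths.

    Predictions are taken in descending confidence (stable: equal confidences
    keep input order); each is matched to the unmatched ground truth — of the
    same class when ``class_aware`` — with the highest IoU at or above the
    threshold.  Unmatched predictions are false positives, unmatched ground
    truths false negatives.
    """
    order = sorted(range(len(preds)), key=lambda i: -(preds[i].confidence or 0.0))
    gt_taken = [False] * len(gts)
    classes = sorted({b.class_label for b in preds} | {b.class_label for b in gts})
    counts = {c: {"tp": 0, "fp": 0, "fn": 0} for c in classes}
    rankings: dict = {c: [] for c in classes}
    matches = []
    for pi in order:
        p = preds[pi]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if gt_taken[j]:
                continue
            if class_aware and g.class_label != p.class_label:
                continue
            v = iou(p, g)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            gt_taken[best_j] = True
            counts[p.class_label]["tp"] += 1
            matches.append((pi, best_j, best_iou))
            rankings[p.class_label].append((p.confidence or 0.0, True))
        else:
            counts[p.class_label]["fp"] += 1
            rankings[p.class_label].append((p.confidence or 0.0, False))
    for j, g in enumerate(gts):
        if not gt_taken[j]:
            counts[g.class_label]["fn"] += 1
    n_gt = {c: sum(1 for g in gts if g.class_label == c) for c in classes}
    return MatchResult(counts, matches, rankings, n_gt)


# ---------------------------------------------------------------------------
# scalar metrics

@dataclass
class ClassMetrics:
    """Per-class metrics as fractions in [0, 1]; None marks an undefined
    metric (zero denominator), which is reported as not-a-value, never 0."""

    tp: int
    fp: int
    fn: int
    tn: int = 0
    accuracy: float | None = None
    precision: float | None = None
    sensitivity: float | None = None
    f1: float | None = None
    ap: float | None = None

    def pct(self, name: str) -> float | None:
        """Metric as a percentage rounded half-up to one decimal."""
        v = getattr(self, name)
        return None if v is None else round_half_up(100.0 * v, 1)


def class_metrics(tp: int, fp: int, fn: int, tn: int = 0) -> ClassMetrics:
    """Precision, sensitivity, F1 and accuracy from a one-vs-rest count table."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    m = ClassMetrics(tp=tp, fp=fp, fn=fn, tn=tn)
    m.precision = tp / (tp + fp) if tp + fp > 0 else None
    m.sensitivity = tp / (tp + fn) if tp + fn > 0 else None
    if m.precision is not None and m.sensitivity is not None:
        s = m.precision + m.sensitivity
        m.f1 = 2 * m.precision * m.sensitivity / s if s > 0 else None
    total = tp + fp + fn + tn
    m.accuracy = (tp + tn) / total if total > 0 else None
    return m


def average_precision(
    ranked: list[tuple[float, bool]],
    n_gt: int,
    interpolation: str = "all_point",
) -> float:
    """Area under the precision-recall curve.

    ``ranked`` holds (confidence, is_tp) per prediction; ``n_gt`` the number
    of ground truths.  ``all_point`` integrates the precision envelope over
    every recall step; ``eleven_point`` averages the envelope at recalls
    0, 0.1, ..., 1.0.
    """
    if n_gt < 1:
        raise ValueError("n_gt must be >= 1")
    if interpolation not in ("all_point", "eleven_point"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = sorted(range(len(ranked)), key=lambda i: -ranked[i][0])
    tps = np.array([1.0 if ranked[i][1] else 0.0 for i in order])
    if tps.size == 0:
        return 0.0
    cum_tp = np.cumsum(tps)
    cum_fp = np.cumsum(1.0 - tps)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope: max precision at recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "eleven_point":
        pts = []
        for r in np.linspace(0.0, 1.0, 11):
            mask = recall >= r - 1e-12
            pts.append(float(env[mask].max()) if mask.any() else 0.0)
        return float(np.mean(pts))
    ap = 0.0
    prev_r = 0.0
    for i in range(len(recall)):
        if tps[i]:
            ap += (recall[i] - prev_r) * env[i]
            prev_r = recall[i]
    return float(ap)


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement (p_o - p_e)/(1 - p_e) of a square count
    matrix (rows: truth, columns: prediction).  Returns NaN when expected
    agreement is 1 (degenerate marginals)."""
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or c.size == 0:
        raise ValueError("confusion must be a non-empty square matrix")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    p_o = np.trace(c) / total
    p_e = float((c.sum(axis=1) / total) @ (c.sum(axis=0) / total))
    if abs(1.0 - p_e) < 1e-15:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def confusion_from_matches(
    preds: list[Box],
    gts: list[Box],
    iou_threshold: float = 0.5,
    classes: tuple = DEFAULT_CLASSES,
) -> pd.DataFrame:
    """Item-level class-assignment confusion with a background row/column.

    Matching is class-agnostic: each matched pair contributes the cell
    (gt class, predicted class); unmatched ground truths count against the
    background column, unmatched predictions against the background row.
    """
    res = match_detections(preds, gts, iou_threshold, class_aware=False)
    labels = list(classes) + [BACKGROUND]
    mat = pd.DataFrame(0, index=labels, columns=labels)
    matched_preds = {pi for pi, _, _ in res.matches}
    matched_gts = {gj for _, gj, _ in res.matches}
    for pi, gj, _ in res.matches:
        mat.loc[gts[gj].class_label, preds[pi].class_label] += 1
    for j, g in enumerate(gts):
        if j not in matched_gts:
            mat.loc[g.class_label, BACKGROUND] += 1
    for i, p in enumerate(preds):
        if i not in matched_preds:
            mat.loc[BACKGROUND, p.class_label] += 1
    return mat


# ---------------------------------------------------------------------------
# report

@dataclass
class ModelReport:
    """Per-class metrics, macro means and kappa (one detector's scorecard)."""

    classes: tuple
    per_class: dict                # class -> ClassMetrics
    kappa: float
    ap_interpolation: str = "all_point"

    def macro_mean(self, name: str) -> float | None:
        """Unweighted mean of a per-class metric over defined classes,
        computed at full precision (rounding happens last, for display)."""
        vals = [getattr(self.per_class[c], name) for c in self.classes]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    def mean_pct(self, name: str) -> float | None:
        v = self.macro_mean(name)
        return None if v is None else round_half_up(100.0 * v, 1)

    def to_frame(self) -> pd.DataFrame:
        cols = ["accuracy", "precision", "sensitivity", "f1", "ap"]
        rows = {}
        for c in self.classes:
            rows[c] = [self.per_class[c].pct(n) for n in cols]
        rows["mean"] = [self.mean_pct(n) for n in cols]
        df = pd.DataFrame.from_dict(
            rows,
            orient="index",
            columns=["Accuracy (%)", "Precision (%)", "Sensitivity (%)",
                     "F1 Score (%)", "AP (%)"],
        )
        df["Kappa"] = [round(self.kappa, 3)] + [None] * (len(rows) - 1)
        return df

    def to_json_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "ap_interpolation": self.ap_interpolation,
            "kappa": self.kappa,
            "per_class": {
                c: {
                    "counts": {
                        "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
                    },
                    **{n: getattr(m, n) for n in
                       ("accuracy", "precision", "sensitivity", "f1", "ap")},
                }
                for c, m in self.per_class.items()
            },
            "macro_mean": {
                n: self.macro_mean(n)
                for n in ("accuracy", "precision", "sensitivity", "f1", "ap")
            },
        }

    def save(self, csv_path=None, json_path=None) -> None:
        if csv_path is not None:
            self.to_frame().to_csv(csv_path)
        if json_path is not None:
            Path(json_path).write_text(
                json.dumps(self.to_json_dict(), indent=2), encoding="utf-8"
            )


def build_report(
    counts: dict,
    rankings: dict,
    n_gt: dict,
    confusion: pd.DataFrame | np.ndarray,
    classes: tuple = DEFAULT_CLASSES,
    ap_interpolation: str = "all_point",
) -> ModelReport:
    """Assemble the scorecard from per-class counts, AP rankings and the
    item-level confusion matrix.

    Per-class accuracy is one-vs-rest over the item universe: all ground
    truths plus all false-positive detections.
    """
    universe = sum(n_gt.get(c, 0) for c in classes) + sum(
        counts.get(c, {}).get("fp", 0) for c in classes
    )
    per_class = {}
    for c in classes:
        cc = counts.get(c, {"tp": 0, "fp": 0, "fn": 0})
        tn = universe - cc["tp"] - cc["fp"] - cc["fn"]
        m = class_metrics(cc["tp"], cc["fp"], cc["fn"], tn)
        if n_gt.get(c, 0) >= 1:
            m.ap = average_precision(rankings.get(c, []), n_gt[c], ap_interpolation)
        per_class[c] = m
    conf = confusion.to_numpy() if isinstance(confusion, pd.DataFrame) else np.asarray(confusion)
    return ModelReport(classes, per_class, cohens_kappa(conf), ap_interpolation)


def evaluate_detections(
    dataset: dict,
    iou_threshold: float = 0.5,
    ap_interpolation: str = "all_point",
    classes: tuple = DEFAULT_CLASSES,
) -> ModelReport:
    """Full evaluation of a detection dataset (see :func:`read_detections_json`
    for the document layout).  Images are matched independently; counts,
    rankings and the confusion matrix are accumulated across images."""
    agg_counts = {c: {"tp": 0, "fp": 0, "fn": 0} for c in classes}
    agg_rank: dict = {c: [] for c in classes}
    agg_ngt = {c: 0 for c in classes}
    labels = list(classes) + [BACKGROUND]
    conf = pd.DataFrame(0, index=labels, columns=labels)
    for image in dataset["images"]:
        gts = image["ground_truth"]
        preds = image["predictions"]
        res = match_detections(preds, gts, iou_threshold, class_aware=True)
        for c in classes:
            if c in res.counts:
                for k in ("tp", "fp", "fn"):
                    agg_counts[c][k] += res.counts[c][k]
            agg_rank[c].extend(res.rankings.get(c, []))
            agg_ngt[c] += res.n_gt.get(c, 0)
        conf += confusion_from_matches(preds, gts, iou_threshold, classes)
    return build_report(agg_counts, agg_rank, agg_ngt, conf, classes, ap_interpolation)


# ---------------------------------------------------------------------------
# detection JSON I/O (COCO-style [x, y, w, h] boxes)

def _box_from_record(rec: dict, with_confidence: bool) -> Box:
    x, y, w, h = rec["bbox"]
    return Box(
        x, y, x + w, y + h,
        class_label=rec["class"],
        confidence=rec.get("confidence") if with_confidence else None,
    )


def read_detections_json(path) -> dict:
    """Read ``{"images": [{"id", "ground_truth": [...], "predictions": [...]}]}``
    with COCO-style ``bbox = [x, y, width, height]`` into Box objects."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    out = {"images": []}
    for image in doc["images"]:
        out["images"].append(
            {
                "id": image.get("id"),
                "ground_truth": [
                    _box_from_record(r, False) for r in image["ground_truth"]
                ],
                "predictions": [
                    _box_from_record(r, True) for r in image["predictions"]
                ],
            }
        )
    return out


def write_detections_json(dataset: dict, path) -> None:
    doc = {"images": []}
    for image in dataset["images"]:
        doc["images"].append(
            {
                "id": image.get("id"),
                "ground_truth": [
                    {
                        "bbox": [g.x_min, g.y_min, g.x_max - g.x_min, g.y_max - g.y_min],
                        "class": g.class_label,
                    }
                    for g in image["ground_truth"]
                ],
                "predictions": [
                    {
                        "bbox": [p.x_min, p.y_min, p.x_max - p.x_min, p.y_max - p.y_min],
                        "class": p.class_label,
                        "confidence": p.confidence,
                    }
                    for p in image["predictions"]
                ],
            }
        )
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def make_synthetic_detections(
    seed: int = 0,
    n_images: int = 20,
    classes: tuple = DEFAULT_CLASSES,
    image_size: int = 256,
    miss_rate: float = 0.2,
    fp_rate: float = 0.3,
    jitter: float = 6.0,
) -> dict:
    """Random ground-truth boxes with jittered, imperfect predictions.

    Emulates a mediocre detector: each ground truth is found with
    probability ``1 - miss_rate`` (box corners jittered by ``jitter`` px,
    class occasionally confused), and spurious detections appear at
    ``fp_rate`` per image.  For exercising the evaluation pipeline only.
    """
    rng = np.random.default_rng(seed)
    images = []
    for i in range(n_images):
        gts, preds = [], []
        for _ in range(int(rng.integers(1, 4))):
            w, h = rng.uniform(30, 80, size=2)
            x = rng.uniform(0, image_size - w)
            y = rng.uniform(0, image_size - h)
            cls = classes[int(rng.integers(len(classes)))]
            gts.append(Box(x, y, x + w, y + h, cls))
            if rng.random() > miss_rate:
                dx = rng.normal(0, jitter, size=4)
                pcls = cls if rng.random() > 0.1 else classes[int(rng.integers(len(classes)))]
                preds.append(
                    Box(
                        x + dx[0], y + dx[1],
                        max(x + w + dx[2], x + dx[0] + 5),
                        max(y + h + dx[3], y + dx[1] + 5),
                        pcls,
                        confidence=float(np.clip(rng.beta(4, 2), 0, 1)),
                    )
                )
        while rng.random() < fp_rate:
            w, h = rng.uniform(20, 60, size=2)
            x = rng.uniform(0, image_size - w)
            y = rng.uniform(0, image_size - h)
            preds.append(
                Box(x, y, x + w, y + h,
                    classes[int(rng.integers(len(classes)))],
                    confidence=float(np.clip(rng.beta(2, 4), 0, 1)))
            )
        images.append({"id": i, "ground_truth": gts, "predictions": preds})
    return {"images": images}
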