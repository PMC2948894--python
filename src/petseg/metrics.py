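"""Lesion quantification and classifier performance evaluation.

Quantification compares each lesion's computed volume CV (labelled cell
count x physical voxel volume, with the wavelet in-plane scale factor
applied squared) against the true volume TV, reporting the absolute
relative error ARE% = |TV - CV| / TV x 100 and the maximum caliper
diameter along an axis.  For wavelet-domain maps produced by an
occupancy-regression network, :func:`soft_volume` sums the clipped scores
instead of counting binary cells, which removes the half-cell dilation bias
of binary counting (partial-volume-aware CV).

Performance evaluation offers a 2x2 confusion matrix (rows = predicted
class, columns = actual class, with per-class and total accuracy
percentages) and ROC points (TPR vs FPR over score thresholds, perfect
point (0, 1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import LabelVolume

__all__ = [
    "LesionStats",
    "ConfusionMatrix",
    "ROCPoint",
    "find_lesions",
    "computed_volume",
    "soft_volume",
    "are_percent",
    "max_diameter",
    "lesion_table",
    "confusion_matrix",
    "roc_points",
    "roc_auc",
]


@dataclass
class LesionStats:
    lesion_id: int
    voxel_count: int
    cv_ml: float
    tv_ml: float | None = None
    are_percent: float | None = None
    max_diameter_mm: float | None = None


def _cell_volume_ml(voxel_size, scale_factor: int) -> float:
    dx, dy, dz = voxel_size
    return dx * scale_factor * dy * scale_factor * dz / 1000.0


def find_lesions(labels: LabelVolume, connectivity: int = 1) -> np.ndarray:
    """Instance map of the label volume's foreground.

    If the map already carries distinct positive instance ids they are kept;
    otherwise 6-connected (``connectivity=1``) components are labelled.
    """
    lab = labels.labels
    ids = np.unique(lab[lab > 0])
    if ids.size > 1:
        return lab.astype(np.int32)
    structure = ndimage.generate_binary_structure(3, connectivity)
    comp, _ = ndimage.label(lab > 0, structure=structure)
    return comp.astype(np.int32)


def computed_volume(labels: LabelVolume, voxel_size) -> dict[int, float]:
    """CV in ml per lesion: cell count x voxel volume x in-plane scale^2."""
    cell_ml = _cell_volume_ml(voxel_size, labels.scale_factor)
    comp = find_lesions(labels)
    ids, counts = np.unique(comp[comp > 0], return_counts=True)
    return {int(i): float(c * cell_ml) for i, c in zip(ids, counts)}


def soft_volume(scores: np.ndarray, region_mask: np.ndarray, voxel_size,
                scale_factor: int = 1, clip: bool = False) -> float:
    """Score-weighted volume in ml: sum of occupancy scores over a region.

    With an occupancy-regression score map (cell value ~ tumour fraction of
    the cell) this estimates the lesion's continuous volume without the
    binarisation bias.  By default raw scores are summed, so small
    symmetric regression errors in the region cancel; ``clip=True`` bounds
    each cell's contribution to [0, 1] instead.
    """
    if scores.shape != region_mask.shape:
        raise ValueError("scores and region mask shapes differ")
    cell_ml = _cell_volume_ml(voxel_size, scale_factor)
    vals = scores[region_mask]
    if clip:
        vals = np.clip(vals, 0.0, 1.0)
    return float(vals.sum() * cell_ml)


def are_percent(tv_ml: float, cv_ml: float) -> float:
    """Absolute relative error |TV - CV| / TV x 100 (scale-invariant)."""
    if tv_ml <= 0:
        raise ValueError("true volume must be positive")
    return abs(tv_ml - cv_ml) / tv_ml * 100.0


def max_diameter(labels: LabelVolume, axis: int, voxel_size) -> dict[int, float]:
    """Caliper extent per lesion along ``axis``: (max - min + 1) x spacing.

    In-plane axes (0, 1) include the wavelet scale factor; the slice axis
    is never down-sampled.
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    comp = find_lesions(labels)
    if comp.max() == 0:
        raise ValueError("no lesion voxels in the label volume")
    spacing = voxel_size[axis] * (labels.scale_factor if axis < 2 else 1)
    out: dict[int, float] = {}
    for i in np.unique(comp[comp > 0]):
        idx = np.nonzero(comp == i)[axis]
        out[int(i)] = float((idx.max() - idx.min() + 1) * spacing)
    return out


def lesion_table(labels: LabelVolume, voxel_size,
                 true_volumes_ml: dict[int, float] | None = None,
                 diameter_axis: int = 1) -> pd.DataFrame:
    """Per-lesion report: id, cell count, CV, TV, ARE%, max diameter."""
    comp = find_lesions(labels)
    cell_ml = _cell_volume_ml(voxel_size, labels.scale_factor)
    rows = []
    ids, counts = np.unique(comp[comp > 0], return_counts=True)
    diam = max_diameter(labels, diameter_axis, voxel_size) if ids.size else {}
    for i, c in zip(ids, counts):
        cv = float(c * cell_ml)
        tv = (true_volumes_ml or {}).get(int(i))
        rows.append({
            "lesion_id": int(i),
            "voxel_count": int(c),
            "cv_ml": round(cv, 4),
            "tv_ml": None if tv is None else round(tv, 4),
            "are_pct": None if tv is None else round(are_percent(tv, cv), 2),
            "max_diam_mm": round(diam[int(i)], 2),
        })
    return pd.DataFrame(rows, columns=["lesion_id", "voxel_count", "cv_ml",
                                       "tv_ml", "are_pct", "max_diam_mm"])


@dataclass
class ConfusionMatrix:
    """2x2 voxel-class cross-tabulation; rows predicted, columns actual.

    Layout::

                        actual tumour   actual background
        pred tumour          TP                FP
        pred background      FN                TN
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("confusion matrix must be 2x2")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def total_accuracy_percent(self) -> float:
        return float(np.trace(self.counts) / self.total * 100.0)

    @property
    def misclassified_percent(self) -> float:
        return 100.0 - self.total_accuracy_percent

    @property
    def predicted_class_accuracy_percent(self) -> np.ndarray:
        """Per predicted class (row): fraction of its predictions that are correct."""
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.diag(self.counts) / row * 100.0
        return np.where(row > 0, acc, np.nan)

    @property
    def actual_class_accuracy_percent(self) -> np.ndarray:
        """Per actual class (column): fraction of that class correctly predicted."""
        col = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.diag(self.counts) / col * 100.0
        return np.where(col > 0, acc, np.nan)

    def to_text(self) -> str:
        """Plain-text block with counts and the derived percentages."""
        tp, fp = self.counts[0]
        fn, tn = self.counts[1]
        pred = self.predicted_class_accuracy_percent
        act = self.actual_class_accuracy_percent
        lines = [
            "                   actual tumour   actual background",
            f"pred tumour       {tp:14d} {fp:19d}   ({pred[0]:.1f}% of row correct)",
            f"pred background   {fn:14d} {tn:19d}   ({pred[1]:.1f}% of row correct)",
            f"per-class recall     {act[0]:.1f}%            {act[1]:.1f}%",
            f"total accuracy    {self.total_accuracy_percent:.2f}%   "
            f"misclassified {self.misclassified_percent:.2f}%",
        ]
        return "\n".join(lines)


def confusion_matrix(predicted: LabelVolume | np.ndarray,
                     actual: LabelVolume | np.ndarray) -> ConfusionMatrix:
    """Exact 2x2 counts of predicted vs actual foreground voxels."""
    p = predicted.binary() if isinstance(predicted, LabelVolume) else np.asarray(predicted) > 0
    a = actual.binary() if isinstance(actual, LabelVolume) else np.asarray(actual) > 0
    if p.shape != a.shape:
        raise ValueError(f"shape mismatch: predicted {p.shape} vs actual {a.shape}")
    tp = int(np.sum(p & a))
    fp = int(np.sum(p & ~a))
    fn = int(np.sum(~p & a))
    tn = int(np.sum(~p & ~a))
    return ConfusionMatrix(np.array([[tp, fp], [fn, tn]]))


@dataclass
class ROCPoint:
    tpr: float
    fpr: float
    threshold: float


def roc_points(raw_scores: np.ndarray, actual: np.ndarray,
               thresholds: np.ndarray | None = None) -> list[ROCPoint]:
    """TPR/FPR over score thresholds (voxel labelled positive when
    score > threshold), sorted by increasing FPR; endpoints (0,0) and (1,1)
    are always included."""
    scores = np.asarray(raw_scores, dtype=np.float64).ravel()
    a = (np.asarray(actual).ravel() > 0)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if scores.size != a.size:
        raise ValueError("scores and actual labels differ in length")
    n_pos = int(a.sum())
    n_neg = a.size - n_pos
    if n_pos == 0:
        raise ValueError("TPR undefined: no positive voxels in the ground truth")
    if thresholds is None:
        thresholds = np.unique(scores)
    thresholds = np.concatenate([[-np.inf], np.asarray(thresholds, float), [np.inf]])
    points = []
    for t in sorted(thresholds, reverse=True):
        pred = scores > t
        tpr = float(np.sum(pred & a) / n_pos)
        fpr = float(np.sum(pred & ~a) / n_neg) if n_neg else 0.0
        points.append(ROCPoint(tpr, fpr, float(t)))
    return points


def roc_auc(points: list[ROCPoint]) -> float:
    """Trapezoidal area under a ROC point list."""
    fpr = np.array([p.fpr for p in points])
    tpr = np.array([p.tpr for p in points])
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))
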