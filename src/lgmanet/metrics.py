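"""Dice loss, overlap metrics and the paired-significance protocol.

The Dice loss is the smoothed squared-denominator form

    DL(p, g) = 1 - (2 * sum(p_i g_i) + eps) / (sum(p_i^2) + sum(g_i^2) + eps)

computed on soft (sigmoid) predictions against a binary mask. Evaluation
metrics are computed per image from the thresholded confusion counts and
averaged across images; model comparison uses a two-sided paired t-test on
per-image IoU vectors.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .nn import Tensor

METRIC_NAMES = ("dice", "iou", "recall", "precision")


def dice_loss(p, g, eps: float = 1e-5):
    """Smoothed Dice loss.

    Accepts NumPy arrays (returns a float) or autodiff tensors (returns a
    scalar Tensor, differentiable in ``p``). The smoothing term ``eps`` must
    lie in [0, 1]; it guards the empty-prediction/empty-mask limit and keeps
    gradients finite for negative samples.
    """
    if not (0.0 <= eps <= 1.0):
        raise ValueError(f"eps must lie in [0, 1], got {eps}")
    if isinstance(p, Tensor) or isinstance(g, Tensor):
        if p.shape != g.shape:
            raise ValueError(f"shape mismatch: prediction {p.shape} vs mask {g.shape}")
        num = 2.0 * (p * g).sum() + eps
        den = (p * p).sum() + (g * g).sum() + eps
        return 1.0 - num / den
    p = np.asarray(p, dtype=np.float64).ravel()
    g = np.asarray(g, dtype=np.float64).ravel()
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: prediction has {p.size} elements, mask {g.size}")
    num = 2.0 * float(p @ g) + eps
    den = float(p @ p) + float(g @ g) + eps
    if den == 0.0:
        return 0.0  # eps = 0 and both empty: perfect agreement
    return 1.0 - num / den


def segmentation_metrics(pred, g, threshold: float = 0.5) -> tuple[float, float, float, float]:
    """(dice, iou, recall, precision) of a soft prediction against a binary
    mask, after thresholding.

    The empty-vs-empty case (no foreground in either) scores 1.0 on all four
    metrics by convention; a metric whose denominator alone is zero scores 0.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    pred = np.asarray(pred, dtype=np.float64).ravel()
    g = np.asarray(g).ravel()
    if pred.shape != g.shape:
        raise ValueError(f"shape mismatch: prediction has {pred.size} elements, mask {g.size}")
    if not np.isin(g, (0, 1)).all():
        raise ValueError("ground-truth mask must be strictly binary (0/1)")
    g = g.astype(bool)
    pb = pred >= threshold
    tp = int(np.count_nonzero(pb & g))
    fp = int(np.count_nonzero(pb & ~g))
    fn = int(np.count_nonzero(~pb & g))
    if tp == 0 and fp == 0 and fn == 0:
        return (1.0, 1.0, 1.0, 1.0)
    dice = 2 * tp / (2 * tp + fp + fn)
    iou = tp / (tp + fp + fn)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    return (dice, iou, recall, precision)


@dataclass
class MetricsReport:
    """Per-image and aggregated segmentation metrics."""
    per_image: list[tuple] = field(default_factory=list)  # (id, dice, iou, recall, precision)
    threshold: float = 0.5

    @property
    def aggregate(self) -> dict[str, float]:
        if not self.per_image:
            return {m: float("nan") for m in METRIC_NAMES}
        arr = np.array([row[1:] for row in self.per_image], dtype=float)
        return dict(zip(METRIC_NAMES, arr.mean(axis=0)))

    def iou_vector(self) -> np.ndarray:
        return np.array([row[2] for row in self.per_image], dtype=float)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(("image_id",) + METRIC_NAMES)
            wr.writerows(self.per_image)

    def to_json(self, path) -> None:
        doc = {"threshold": self.threshold, "n_images": len(self.per_image),
               "aggregate": self.aggregate}
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_pairs(cls, ids, preds, masks, threshold: float = 0.5) -> "MetricsReport":
        rep = cls(threshold=threshold)
        for iid, p, m in zip(ids, preds, masks):
            rep.per_image.append((iid,) + segmentation_metrics(p, m, threshold))
        return rep


def paired_iou_ttest(iou_a, iou_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-image IoU vectors.

    Returns (t, p). Raises on unequal lengths, n < 2, or zero-variance
    differences (for which the statistic is undefined).
    """
    a = np.asarray(iou_a, dtype=np.float64)
    b = np.asarray(iou_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired t-test needs two equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise ValueError(f"paired t-test needs n >= 2 pairs, got {n}")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("all pairwise differences are identical; "
                         "t statistic is undefined (zero variance)")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return (float(t), float(p))


def significance_protocol(iou_a, iou_b, n: int = 30, seed: int = 0) -> tuple[float, float]:
    """The model-comparison protocol: draw ``n`` images (default 30) at
    random from the paired per-image IoU vectors and run the paired t-test
    on that subsample."""
    a = np.asarray(iou_a, dtype=np.float64)
    b = np.asarray(iou_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("IoU vectors must be paired (equal length)")
    if a.size < n:
        raise ValueError(f"need at least {n} paired images, got {a.size}")
    idx = np.random.default_rng(seed).choice(a.size, size=n, replace=False)
    return paired_iou_ttest(a[idx], b[idx])
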