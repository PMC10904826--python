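"""Macro-averaged classification metrics and attention-map localization.

Accuracy, sensitivity and specificity are computed per class under a
one-vs-rest reduction of the confusion matrix and then macro-averaged
(unweighted mean over classes); values are reported as percentages.
Localization quality is the exact binary IoU between a hard-thresholded,
normalised attention map and the ground-truth lesion mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np

from . import autodiff as ad
from .attention import LossConfig

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "LocalizationReport",
    "confusion_matrix",
    "macro_metrics",
    "binary_iou",
    "attention_binary_mask",
    "localization_iou",
    "export_overlay",
    "format_mean_sd",
]


@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion matrix entries must be >= 0")
        self.counts = c.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricReport:
    """Percent-scale macro metrics with per-class detail."""

    accuracy: float
    sensitivity: float
    specificity: float
    per_class: dict = field(default_factory=dict)
    multiclass_accuracy: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "multiclass_accuracy": self.multiclass_accuracy,
            "per_class": self.per_class,
        }


@dataclass
class LocalizationReport:
    ious: np.ndarray
    threshold: float
    n_skipped: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.ious)) if len(self.ious) else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.ious, ddof=1)) if len(self.ious) > 1 else 0.0


def confusion_matrix(true_labels: Sequence[int], predicted_labels: Sequence[int],
                     n_classes: int) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=np.intp)
    p = np.asarray(predicted_labels, dtype=np.intp)
    if t.shape != p.shape:
        raise ValueError("true and predicted label lists differ in length")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    if t.size:
        if t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes:
            raise ValueError("label outside [0, n_classes)")
        np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def macro_metrics(cm: ConfusionMatrix) -> MetricReport:
    """One-vs-rest accuracy/sensitivity/specificity per class, macro-averaged.

    Classes with a zero denominator for a metric are excluded from that
    macro mean with a warning.
    """
    c = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict = {}
    acc_list, sens_list, spec_list = [], [], []
    for k in range(c.shape[0]):
        tp = int(c[k, k])
        fn = int(c[k].sum() - tp)
        fp = int(c[:, k].sum() - tp)
        tn = total - tp - fn - fp
        entry: dict = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
        entry["accuracy"] = 100.0 * (tp + tn) / total
        acc_list.append(entry["accuracy"])
        if tp + fn > 0:
            entry["sensitivity"] = 100.0 * tp / (tp + fn)
            sens_list.append(entry["sensitivity"])
        else:
            entry["sensitivity"] = None
            warnings.warn(f"class {k}: sensitivity undefined (no positives)")
        if tn + fp > 0:
            entry["specificity"] = 100.0 * tn / (tn + fp)
            spec_list.append(entry["specificity"])
        else:
            entry["specificity"] = None
            warnings.warn(f"class {k}: specificity undefined (no negatives)")
        per_class[k] = entry
    return MetricReport(
        accuracy=float(np.mean(acc_list)),
        sensitivity=float(np.mean(sens_list)) if sens_list else float("nan"),
        specificity=float(np.mean(spec_list)) if spec_list else float("nan"),
        per_class=per_class,
        multiclass_accuracy=100.0 * float(np.trace(c)) / total,
    )


def binary_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Exact set IoU of two binary arrays."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def attention_binary_mask(attention: np.ndarray, out_shape: tuple[int, int],
                          threshold: float) -> np.ndarray:
    """Upsample, min-max normalise, and hard-threshold an attention map."""
    up = ad.bilinear_resize(np.asarray(attention, dtype=np.float64), out_shape)
    lo, hi = up.min(), up.max()
    norm = (up - lo) / (hi - lo + 1e-8)
    return norm >= threshold


def localization_iou(model, samples, bin_threshold: float = 0.5,
                     config: Optional[LossConfig] = None) -> LocalizationReport:
    """Per-sample IoU between the predicted-class attention map (binarized
    at ``bin_threshold``) and the ground-truth mask; mask-less samples are
    skipped and counted."""
    config = config or LossConfig()
    ious = []
    skipped = 0
    for s in samples:
        if s.attention_label is None:
            skipped += 1
            continue
        pred = int(model.predict(s.image[None])[0])
        amap = model.gradcam(s.image, pred, config)
        hard = attention_binary_mask(amap.values, s.image.shape, bin_threshold)
        ious.append(binary_iou(hard, s.attention_label > 0))
    return LocalizationReport(
        ious=np.asarray(ious), threshold=bin_threshold, n_skipped=skipped
    )


_JET_STOPS = np.array(
    [(0.0, 0.0, 0.5), (0.0, 0.0, 1.0), (0.0, 1.0, 1.0),
     (1.0, 1.0, 0.0), (1.0, 0.0, 0.0)]
)


def _heat_rgb(norm: np.ndarray) -> np.ndarray:
    """Small fixed blue->red colormap (no plotting dependency at runtime)."""
    pos = np.clip(norm, 0, 1) * (len(_JET_STOPS) - 1)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, len(_JET_STOPS) - 1)
    f = (pos - i0)[..., None]
    return _JET_STOPS[i0] * (1 - f) + _JET_STOPS[i1] * f


def export_overlay(sample, attention_map: np.ndarray, out_path,
                   predicted_class: Optional[str] = None) -> Path:
    """Write a heat overlay of the attention map on the radiograph.

    The heat layer's alpha scales with the normalised attention, so an
    all-zero map reproduces the base image; the ground-truth mask contour
    (when present) is drawn in green.  A JSON sidecar records the true and
    predicted classes.
    """
    out_path = Path(out_path)
    image = np.asarray(sample.image, dtype=np.float64)
    amap = np.asarray(attention_map, dtype=np.float64)
    if amap.shape != image.shape:
        amap = ad.bilinear_resize(amap, image.shape)
    peak = amap.max()
    norm = amap / peak if peak > 0 else np.zeros_like(amap)
    rgb = np.repeat(image[..., None], 3, axis=2)
    alpha = (0.5 * norm)[..., None]
    rgb = rgb * (1 - alpha) + _heat_rgb(norm) * alpha
    if sample.attention_label is not None:
        from skimage.segmentation import find_boundaries

        contour = find_boundaries(sample.attention_label > 0, mode="outer")
        rgb[contour] = (0.0, 1.0, 0.0)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_path, np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8))
    sidecar = {
        "sample_id": sample.sample_id,
        "true_class": sample.class_label,
        "predicted_class": predicted_class,
    }
    out_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return out_path


def format_mean_sd(values: Sequence[float]) -> str:
    """Format repeated-run results as 'xx.xx ± y.yy'."""
    v = np.asarray(values, dtype=np.float64)
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return f"{float(np.mean(v)):.2f} ± {sd:.2f}"
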