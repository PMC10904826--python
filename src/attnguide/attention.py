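"""Gradient-weighted class-activation attention and the guided loss.

This is the mathematical core of the package: extraction of a
class-activation attention map from last-layer feature maps, its
conversion to a differentiable near-binary soft mask (min-max
normalisation followed by a steep logistic threshold), the soft-IoU
attention loss computed only for location-labelled samples, softmax
cross-entropy for the class labels, and the weighted total objective.

All operations accept either plain ``numpy`` arrays or
:class:`attnguide.autodiff.Tensor` values; with tensors the whole chain is
differentiable end-to-end, which is what lets the attention loss steer the
feature extractor during training.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit, logsumexp

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "FeatureStack",
    "AttentionMap",
    "SoftMask",
    "ClassScores",
    "LossConfig",
    "compute_gradcam",
    "soft_mask",
    "soft_iou",
    "attention_loss",
    "classification_loss",
    "total_loss",
]


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _sigmoid(x):
    return ad.sigmoid(x) if _is_tensor(x) else expit(np.asarray(x, dtype=np.float64))


def _relu(x):
    return ad.relu(x) if _is_tensor(x) else np.maximum(np.asarray(x, dtype=np.float64), 0.0)


def _amin(x):
    return ad.amin(x) if _is_tensor(x) else float(np.min(x))


def _amax(x):
    return ad.amax(x) if _is_tensor(x) else float(np.max(x))


def _resize(x, shape):
    if _is_tensor(x):
        return ad.upsample_bilinear(x, shape)
    return ad.bilinear_resize(np.asarray(x, dtype=np.float64), shape)


def _sum(x):
    return ad.tsum(x) if _is_tensor(x) else float(np.sum(x))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LossConfig:
    """Hyper-parameters of the attention-guided objective.

    theta       soft-mask threshold in [0, 1]
    omega       logistic scale; large values sharpen the mask towards a
                hard threshold (default 100)
    alpha_cls   weight of the classification term (default 2)
    alpha_att   weight of the attention term (default 1)
    epsilon     guard added to the min-max denominator so constant
                attention maps stay defined
    gradcam_relu  apply ReLU to the weighted feature-map sum
    iou_mode    "product" for the probabilistic relaxation (exact on
                binary inputs) or "minmax" for the sum-min / sum-max form
    """

    theta: float = 0.5
    omega: float = 100.0
    alpha_cls: float = 2.0
    alpha_att: float = 1.0
    epsilon: float = 1e-8
    gradcam_relu: bool = True
    iou_mode: str = "product"

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.alpha_cls < 0 or self.alpha_att < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.iou_mode not in ("product", "minmax"):
            raise ValueError("iou_mode must be 'product' or 'minmax'")

    def replace(self, **kw) -> "LossConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class FeatureStack:
    """Last-layer feature maps and the matching score gradients.

    ``maps`` and ``gradients`` have shape (K, m, n); ``gradients[k]`` holds
    the partial derivatives of the target-class score with respect to
    ``maps[k]``.
    """

    maps: np.ndarray
    gradients: np.ndarray

    def __post_init__(self):
        m = self.maps.data if _is_tensor(self.maps) else np.asarray(self.maps)
        g = np.asarray(self.gradients)
        if m.shape != g.shape:
            raise ValueError(
                f"maps shape {m.shape} != gradients shape {g.shape}"
            )
        if m.ndim != 3:
            raise ValueError("expected (K, m, n) stacks")
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(g))):
            raise ValueError("feature stack contains non-finite values")


@dataclass
class AttentionMap:
    """Raw attention grid H on the last-conv spatial resolution."""

    values: np.ndarray
    target_class: Optional[int] = None


@dataclass
class SoftMask:
    """Near-binary relaxation of an attention map, at label resolution."""

    values: np.ndarray

    @property
    def array(self) -> np.ndarray:
        return self.values.data if _is_tensor(self.values) else self.values


@dataclass
class ClassScores:
    """Raw logits f_k(x) for one sample."""

    logits: np.ndarray
    n_classes: int = 0

    def __post_init__(self):
        self.logits = np.asarray(self.logits, dtype=np.float64)
        if self.logits.ndim != 1:
            raise ValueError("logits must be a vector")
        if self.n_classes == 0:
            self.n_classes = self.logits.shape[0]
        if self.logits.shape[0] != self.n_classes or self.n_classes < 2:
            raise ValueError("need at least two finite class logits")
        if not np.all(np.isfinite(self.logits)):
            raise ValueError("logits must be finite")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def compute_gradcam(features: FeatureStack, config: LossConfig | None = None,
                    target_class: Optional[int] = None) -> AttentionMap:
    """Weighted feature-map sum with gradient-derived channel weights.

    Each channel weight is the spatial mean (global average pooling) of the
    corresponding score gradient; the attention map is the weighted sum of
    the feature maps, optionally rectified.
    """
    config = config or LossConfig()
    grads = np.asarray(features.gradients, dtype=np.float64)
    weights = grads.mean(axis=(1, 2))  # (K,)
    maps = features.maps
    if _is_tensor(maps):
        h = ad.tsum(maps * weights[:, None, None], axis=0)
    else:
        h = np.tensordot(weights, np.asarray(maps, dtype=np.float64), axes=(0, 0))
    if config.gradcam_relu:
        h = _relu(h)
    return AttentionMap(values=h, target_class=target_class)


def soft_mask(attention: AttentionMap, label_shape: tuple[int, int],
              config: LossConfig | None = None) -> SoftMask:
    """Upsample, min-max normalise, and logistic-threshold an attention map.

    The map is first bilinearly resized to the label resolution, rescaled
    to [0, 1] with an epsilon-guarded min-max normalisation, then passed
    through ``s(omega * (hbar - theta))``.  Every step is differentiable.
    """
    config = config or LossConfig()
    h = attention.values
    if not _is_tensor(h):
        h = np.asarray(h, dtype=np.float64)
        if not np.all(np.isfinite(h)):
            raise ValueError("attention map contains non-finite values")
    up = _resize(h, tuple(label_shape))
    lo = _amin(up)
    hi = _amax(up)
    hbar = (up - lo) / (hi - lo + config.epsilon)
    return SoftMask(values=_sigmoid(config.omega * (hbar - config.theta)))


def soft_iou(mask: SoftMask | np.ndarray, label: np.ndarray,
             mode: str = "product"):
    """Differentiable intersection-over-union between a soft mask and a
    binary label.

    ``product`` uses sum(H*Y) / sum(H + Y - H*Y), which equals the exact
    set IoU whenever the mask is binary; ``minmax`` uses
    sum(min(H, Y)) / sum(max(H, Y)) (identical on binary inputs).
    """
    h = mask.values if isinstance(mask, SoftMask) else mask
    y = np.asarray(label, dtype=np.float64)
    hshape = h.data.shape if _is_tensor(h) else np.asarray(h).shape
    if hshape != y.shape:
        raise ValueError(f"shape mismatch: mask {hshape}, label {y.shape}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("label must be binary")
    if y.sum() == 0:
        raise ValueError("label has no foreground pixels; IoU undefined")
    if mode == "product":
        inter = _sum(h * y)
        union = _sum(h + y - h * y)
    elif mode == "minmax":
        if _is_tensor(h):
            # min(h, y) = h*y and max(h, y) = h + y - h*y only for binary y
            inter = _sum(h * y)
            union = _sum(h + y - h * y)
        else:
            inter = float(np.minimum(h, y).sum())
            union = float(np.maximum(h, y).sum())
    else:
        raise ValueError("mode must be 'product' or 'minmax'")
    return inter / union


def attention_loss(mask: Optional[SoftMask], label: Optional[np.ndarray],
                   mode: str = "product"):
    """1 - IoU(soft mask, label) when a location label exists, else 0."""
    if label is None:
        return 0.0
    if mask is None:
        raise ValueError("a soft mask is required for location-labelled samples")
    return 1.0 - soft_iou(mask, label, mode=mode)


def classification_loss(scores: ClassScores, true_class: int) -> float:
    """Softmax cross-entropy -log(e^{f_y} / sum_k e^{f_k}) for one sample."""
    y = int(true_class)
    if not 0 <= y < scores.n_classes:
        raise ValueError(
            f"class index {y} out of range for {scores.n_classes} classes"
        )
    z = scores.logits
    return float(logsumexp(z) - z[y])


def total_loss(l_cls, l_att, config: LossConfig | None = None):
    """Weighted sum alpha_cls * L_cls + alpha_att * L_att."""
    config = config or LossConfig()
    return config.alpha_cls * l_cls + config.alpha_att * l_att
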