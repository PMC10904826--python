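"""Radiograph preprocessing and augmentation.

Implements the augmentation stack applied during training: intensity
jitter (brightness then mean-anchored contrast), a joint horizontal flip,
a joint trapezoid projective warp that rescales the image's base width,
and a deterministic center crop.  Geometric operations are applied with
one shared random draw to the image and its location mask so that the two
stay aligned; the mask is resampled with nearest-neighbour interpolation
and therefore stays binary.

Coordinates are 0-based with (x=column, y=row); crop windows are
half-open.  Out-of-canvas pixels are filled with 0 (black).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from skimage.transform import warp

from .synthetic import RadiographSample

__all__ = [
    "AugmentationConfig",
    "Homography",
    "center_crop",
    "jitter_intensity",
    "horizontal_flip",
    "build_homography",
    "trapezoid_transform",
    "compose_augmentation",
    "imread_gray",
    "imwrite_gray",
]

_VALID_OPS = ("intensity", "flip", "trapezoid")


@dataclass
class AugmentationConfig:
    """On-the-fly augmentation parameters.

    Defaults follow the training recipe: brightness jitter +-5%, contrast
    jitter +-10%, flip probability 0.5, trapezoid base-width factor +-5%,
    and a 1280x720 -> 940x520 center crop.
    """

    brightness_factor: float = 0.05
    contrast_factor: float = 0.10
    flip_probability: float = 0.5
    trapezoid_factor: float = 0.05
    crop_size: tuple = (940, 520)  # (width, height)
    enabled_ops: tuple = _VALID_OPS
    trapezoid_anchor: str = "top"

    def __post_init__(self):
        if min(self.brightness_factor, self.contrast_factor, self.trapezoid_factor) < 0:
            raise ValueError("augmentation factors must be >= 0")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must lie in [0, 1]")
        for op in self.enabled_ops:
            if op not in _VALID_OPS:
                raise ValueError(f"unknown op {op!r}; valid: {_VALID_OPS}")
        if self.trapezoid_anchor not in ("top", "bottom"):
            raise ValueError("trapezoid_anchor must be 'top' or 'bottom'")

    def replace(self, **kw) -> "AugmentationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Homography:
    """3x3 projective matrix, normalised so the bottom-right entry is 1."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if abs(np.linalg.det(m)) <= 0:
            raise ValueError("homography must be invertible")
        self.matrix = m / m[2, 2]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) points given as (x, y) columns."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        homog = np.hstack([pts, np.ones((pts.shape[0], 1))])
        out = homog @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    @property
    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))


def center_crop(image: np.ndarray, mask: Optional[np.ndarray],
                crop_size: tuple[int, int]):
    """Centered (width, height) window; odd margins go right/bottom."""
    w, h = int(crop_size[0]), int(crop_size[1])
    ih, iw = image.shape
    if w > iw or h > ih:
        raise ValueError(
            f"crop {w}x{h} larger than image {iw}x{ih}"
        )
    if mask is not None and mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    ox = (iw - w) // 2
    oy = (ih - h) // 2
    out_img = image[oy : oy + h, ox : ox + w]
    out_mask = mask[oy : oy + h, ox : ox + w] if mask is not None else None
    return out_img, out_mask


def jitter_intensity(image: np.ndarray, brightness_factor: float,
                     contrast_factor: float, rng: np.random.Generator,
                     _forced: Optional[tuple] = None) -> np.ndarray:
    """Random brightness scaling followed by a contrast stretch about the
    image mean; output clipped to [0, 1].  The mask is never touched."""
    if brightness_factor < 0 or contrast_factor < 0:
        raise ValueError("intensity factors must be >= 0")
    if _forced is not None:
        b, c = _forced
    else:
        b = rng.uniform(1.0 - brightness_factor, 1.0 + brightness_factor)
        c = rng.uniform(1.0 - contrast_factor, 1.0 + contrast_factor)
    out = image * b
    m = out.mean()
    return np.clip((out - m) * c + m, 0.0, 1.0)


def horizontal_flip(image: np.ndarray, mask: Optional[np.ndarray],
                    flip_probability: float, rng: np.random.Generator,
                    _forced: Optional[bool] = None):
    """Mirror image (and mask) about the vertical axis with the given
    probability; one draw governs both arrays."""
    if mask is not None and mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    flipped = _forced if _forced is not None else bool(rng.random() < flip_probability)
    if not flipped:
        return image, mask, False
    return image[:, ::-1].copy(), (mask[:, ::-1].copy() if mask is not None else None), True


def build_homography(width: int, height: int, delta: float,
                     anchor: str = "top") -> Homography:
    """Projective matrix that rescales the base width by (1 + delta).

    With ``anchor='top'`` the top edge is fixed and the bottom corners move
    outward (delta > 0) or inward (delta < 0) by delta*(W-1)/2 each, so the
    bottom-edge width changes by the factor (1 + delta); ``anchor='bottom'``
    mirrors this.  Solved by the standard 8-DOF direct linear transform.
    """
    if abs(delta) > 0.5:
        raise ValueError("|delta| must be <= 0.5")
    if anchor not in ("top", "bottom"):
        raise ValueError("anchor must be 'top' or 'bottom'")
    w1 = float(width - 1)
    h1 = float(height - 1)
    shift = delta * w1 / 2.0
    src = np.array([[0, 0], [w1, 0], [0, h1], [w1, h1]], dtype=np.float64)
    if anchor == "top":
        dst = np.array(
            [[0, 0], [w1, 0], [-shift, h1], [w1 + shift, h1]], dtype=np.float64
        )
    else:
        dst = np.array(
            [[-shift, 0], [w1 + shift, 0], [0, h1], [w1, h1]], dtype=np.float64
        )
    # 8-DOF direct linear transform on the four corner correspondences
    a = np.zeros((8, 8))
    rhs = np.zeros(8)
    for i, ((x, y), (u, v)) in enumerate(zip(src, dst)):
        a[2 * i] = [x, y, 1, 0, 0, 0, -u * x, -u * y]
        a[2 * i + 1] = [0, 0, 0, x, y, 1, -v * x, -v * y]
        rhs[2 * i] = u
        rhs[2 * i + 1] = v
    sol = np.linalg.solve(a, rhs)
    matrix = np.append(sol, 1.0).reshape(3, 3)
    return Homography(matrix)


def _warp_pair(image: np.ndarray, mask: Optional[np.ndarray], hom: Homography):
    inv = np.linalg.inv(hom.matrix)
    out_img = warp(image, inverse_map=inv, order=1, cval=0.0, preserve_range=True)
    out_mask = None
    if mask is not None:
        out_mask = warp(
            mask.astype(np.float64), inverse_map=inv, order=0, cval=0.0,
            preserve_range=True,
        ).astype(mask.dtype)
    return out_img, out_mask


def trapezoid_transform(image: np.ndarray, mask: Optional[np.ndarray],
                        delta_range: float, rng: np.random.Generator,
                        anchor: str = "top",
                        _forced: Optional[float] = None):
    """Jointly warp image (bilinear) and mask (nearest) through a random
    trapezoid homography with delta ~ U(-delta_range, +delta_range)."""
    if mask is not None and mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    delta = _forced if _forced is not None else float(
        rng.uniform(-delta_range, delta_range)
    )
    if delta == 0.0:
        return image, mask
    h, w = image.shape
    hom = build_homography(w, h, delta, anchor=anchor)
    return _warp_pair(image, mask, hom)


def compose_augmentation(sample: RadiographSample, config: AugmentationConfig,
                         rng: np.random.Generator,
                         _forced: Optional[dict] = None) -> RadiographSample:
    """Apply the enabled ops in the fixed order
    intensity -> flip -> trapezoid, then center-crop.

    The mask (when present) passes through flip, trapezoid and crop only.
    Drawn parameters are recorded in the returned sample's ``meta``.
    The random stream is consumed identically whether or not a mask is
    present, so datasets generated at different attention rates see
    identical augmentations.
    """
    forced = _forced or {}
    image = sample.image
    mask = sample.attention_label
    log: dict = {}
    if "intensity" in config.enabled_ops:
        if "brightness" in forced:
            b, c = forced["brightness"], forced["contrast"]
        else:
            b = rng.uniform(1 - config.brightness_factor, 1 + config.brightness_factor)
            c = rng.uniform(1 - config.contrast_factor, 1 + config.contrast_factor)
        image = jitter_intensity(image, config.brightness_factor,
                                 config.contrast_factor, rng, _forced=(b, c))
        log["brightness"], log["contrast"] = b, c
    if "flip" in config.enabled_ops:
        do_flip = forced.get(
            "flip", bool(rng.random() < config.flip_probability)
        )
        image, mask, flipped = horizontal_flip(
            image, mask, config.flip_probability, rng, _forced=do_flip
        )
        log["flip"] = flipped
    if "trapezoid" in config.enabled_ops:
        delta = forced.get(
            "delta",
            float(rng.uniform(-config.trapezoid_factor, config.trapezoid_factor)),
        )
        image, mask = trapezoid_transform(
            image, mask, config.trapezoid_factor, rng,
            anchor=config.trapezoid_anchor, _forced=delta,
        )
        log["delta"] = delta
    image, mask = center_crop(image, mask, config.crop_size)
    if mask is not None and mask.sum() == 0:
        mask = None  # lesion fell outside the crop window
    meta = dict(sample.meta)
    meta["augment"] = log
    return RadiographSample(
        image=np.ascontiguousarray(image),
        class_label=sample.class_label,
        sample_id=sample.sample_id,
        attention_label=mask,
        use_attention=sample.use_attention and mask is not None,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# grayscale image I/O
# ---------------------------------------------------------------------------


def imread_gray(path) -> np.ndarray:
    """Read an 8/16-bit grayscale PNG/TIFF as float64 in [0, 1]."""
    raw = iio.imread(Path(path))
    if raw.ndim == 3:
        raw = raw[..., 0]
    if raw.dtype.kind == "u":
        return raw.astype(np.float64) / np.iinfo(raw.dtype).max
    return raw.astype(np.float64)


def imwrite_gray(path, image: np.ndarray, bit_depth: int = 8) -> None:
    """Write a float [0, 1] image as 8- or 16-bit grayscale."""
    if bit_depth == 8:
        iio.imwrite(Path(path), np.round(np.clip(image, 0, 1) * 255).astype(np.uint8))
    elif bit_depth == 16:
        iio.imwrite(Path(path), np.round(np.clip(image, 0, 1) * 65535).astype(np.uint16))
    else:
        raise ValueError("bit_depth must be 8 or 16")
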