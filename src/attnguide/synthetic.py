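"""Phantom radiograph generator with ground-truth lesion masks.

Produces grayscale phantoms that structurally resemble panoramic
radiographs: two smooth horizontal "jaw" bands over a noisy background,
with free-form lesion blobs (unions of overlapping ellipses) placed in the
lower band.  Three classes are emitted:

* ``Normal``    — no lesion, never carries a location mask;
* ``CystTumor`` — radiolucent (dark) blob with a sharp border, anywhere
  along the lower band;
* ``LMBD``      — darker-than-background blob with a soft border,
  restricted to the posterior (outer) thirds of the lower band, acting as
  the hard-negative mimic class.

Every lesion sample is generated together with the exact binary support
of its blob; a dataset-level attention rate then strips masks from all
but a seeded, exact-count subset so partial-label training can be
exercised end-to-end without any clinical data.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from math import ceil, pi
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "CLASSES",
    "LESION_CLASSES",
    "JawBandGeometry",
    "PhantomConfig",
    "RadiographSample",
    "generate_phantom",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]

CLASSES = ("Normal", "CystTumor", "LMBD")
LESION_CLASSES = ("CystTumor", "LMBD")


@dataclass(frozen=True)
class JawBandGeometry:
    """Vertical placement of the two anatomy bands (fractions of height)."""

    upper_center: float = 0.32
    lower_center: float = 0.68
    half_width: float = 0.10
    intensity: float = 0.35
    curvature: float = 0.04
    base_level: float = 0.45  # keeps lesion darkening away from the 0 clip


@dataclass
class PhantomConfig:
    image_width: int = 320
    image_height: int = 180
    n_per_class: dict = field(
        default_factory=lambda: {"Normal": 20, "CystTumor": 20, "LMBD": 20}
    )
    lesion_radius_range: tuple = (8, 16)
    lesion_contrast: dict = field(
        default_factory=lambda: {"CystTumor": -0.40, "LMBD": -0.40}
    )
    background_noise_sd: float = 0.02
    jaw_band_geometry: JawBandGeometry = field(default_factory=JawBandGeometry)
    seed: int = 0

    def __post_init__(self):
        if self.image_width < 64 or self.image_height < 64:
            raise ValueError("phantom images must be at least 64x64")
        for cls, n in self.n_per_class.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r}; valid: {CLASSES}")
            if n < 0:
                raise ValueError("per-class counts must be >= 0")
        rmin, rmax = self.lesion_radius_range
        if not 0 < rmin <= rmax:
            raise ValueError("lesion_radius_range must satisfy 0 < min <= max")
        band_half_px = self.jaw_band_geometry.half_width * self.image_height
        if rmax > band_half_px * 1.5:
            raise ValueError(
                f"lesion max radius {rmax} does not fit the lower jaw band "
                f"(half-width {band_half_px:.1f} px)"
            )
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")


@dataclass
class RadiographSample:
    """One grayscale image with a class label and optional location mask."""

    image: np.ndarray
    class_label: str
    sample_id: str
    attention_label: Optional[np.ndarray] = None
    use_attention: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}; valid: {CLASSES}")
        if self.attention_label is not None:
            if self.attention_label.shape != self.image.shape:
                raise ValueError("attention label shape must match image shape")
            if self.attention_label.sum() < 1:
                raise ValueError("attention label must have foreground pixels")
            if self.class_label == "Normal":
                raise ValueError("Normal samples never carry an attention label")


def _band_profile(config: PhantomConfig) -> np.ndarray:
    """Two smooth horizontal bands with a gentle arch."""
    h, w = config.image_height, config.image_width
    geom = config.jaw_band_geometry
    u = np.linspace(0.0, 1.0, w)[None, :]
    y = np.arange(h, dtype=np.float64)[:, None]
    arch = np.sin(pi * u)  # 0 at the edges, 1 mid-image
    sigma = geom.half_width * h / 2.0
    upper_c = (geom.upper_center - geom.curvature * arch) * h
    lower_c = (geom.lower_center + geom.curvature * arch) * h
    prof = np.exp(-((y - upper_c) ** 2) / (2 * sigma**2))
    prof += np.exp(-((y - lower_c) ** 2) / (2 * sigma**2))
    return geom.intensity * prof


def _lower_band_center(config: PhantomConfig, x: float) -> float:
    geom = config.jaw_band_geometry
    u = x / max(config.image_width - 1, 1)
    return (geom.lower_center + geom.curvature * np.sin(pi * u)) * config.image_height


def _blob_mask(config: PhantomConfig, class_name: str,
               rng: np.random.Generator) -> np.ndarray:
    """Union of 2-5 overlapping ellipses inside the lower band."""
    h, w = config.image_height, config.image_width
    rmin, rmax = config.lesion_radius_range
    if class_name == "LMBD":
        # posterior third, random side
        side = rng.integers(0, 2)
        lo, hi = (0.05 * w, w / 3.0) if side == 0 else (2 * w / 3.0, 0.95 * w)
    else:
        lo, hi = 0.08 * w, 0.92 * w
    cx = rng.uniform(lo, hi)
    cy = _lower_band_center(config, cx) + rng.uniform(-2.0, 2.0)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    mask = np.zeros((h, w), dtype=bool)
    n_ell = int(rng.integers(2, 6))
    for _ in range(n_ell):
        a = rng.uniform(rmin, rmax)
        b = rng.uniform(rmin, rmax)
        theta = rng.uniform(0.0, pi)
        ct, st = np.cos(theta), np.sin(theta)
        dx = xx - cx
        dy = yy - cy
        mask |= ((dx * ct + dy * st) / a) ** 2 + ((-dx * st + dy * ct) / b) ** 2 <= 1.0
        step = 0.6 * min(a, b)
        cx = np.clip(cx + rng.uniform(-step, step), 1, w - 2)
        cy = np.clip(cy + rng.uniform(-step, step), 1, h - 2)
    return mask


def generate_phantom(config: PhantomConfig, class_name: str,
                     rng: np.random.Generator,
                     sample_id: str | None = None) -> RadiographSample:
    """Generate one phantom radiograph of the given class.

    Lesion classes receive exactly one free-form blob with a class-specific
    intensity signature; the returned attention label is the exact binary
    support of that blob.  ``Normal`` samples have no blob and no mask.
    """
    if class_name not in CLASSES:
        raise ValueError(f"unknown class {class_name!r}; valid: {CLASSES}")
    h, w = config.image_height, config.image_width
    image = config.jaw_band_geometry.base_level + _band_profile(config)
    if config.background_noise_sd > 0:
        image = image + rng.normal(0.0, config.background_noise_sd, size=(h, w))
    else:
        rng.normal(0.0, 1.0, size=(h, w))  # keep the stream position fixed
    mask = None
    if class_name != "Normal":
        blob = _blob_mask(config, class_name, rng)
        contrast = config.lesion_contrast[class_name]
        if class_name == "CystTumor":
            image = image + contrast * blob
        else:
            # soft border: contrast fades towards the blob boundary
            dist = ndimage.distance_transform_edt(blob)
            if dist.max() > 0:
                dist = dist / dist.max()
            image = image + contrast * (0.7 + 0.3 * dist) * blob
        mask = blob.astype(np.uint8)
    image = np.clip(image, 0.0, 1.0)
    sid = sample_id or f"{class_name}-{rng.integers(0, 10**9):09d}"
    return RadiographSample(
        image=image,
        class_label=class_name,
        sample_id=sid,
        attention_label=mask,
    )


def _exact_count(rate: float, n: int) -> int:
    # guard against float artefacts such as 0.05 * 100 = 5.000000000000001
    return int(ceil(rate * n - 1e-9))


def generate_dataset(config: PhantomConfig, attention_rate: float = 1.0,
                     seed: int | None = None):
    """Generate a full phantom dataset and its manifest.

    Images depend only on (config, seed); ``attention_rate`` controls mask
    retention: exactly ``ceil(rate * n_lesion)`` lesion samples keep their
    masks, chosen by a seeded shuffle, so the retained set at a lower rate
    is always a subset of the set at a higher rate.
    """
    if not 0.0 <= attention_rate <= 1.0:
        raise ValueError("attention_rate must lie in [0, 1]")
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    n_total = sum(config.n_per_class.get(c, 0) for c in CLASSES)
    children = ss.spawn(n_total)
    samples: list[RadiographSample] = []
    idx = 0
    for cls in CLASSES:
        for i in range(config.n_per_class.get(cls, 0)):
            rng = np.random.Generator(np.random.PCG64(children[idx]))
            samples.append(
                generate_phantom(config, cls, rng, sample_id=f"{cls}-{i:04d}")
            )
            idx += 1
    lesion_idx = [i for i, s in enumerate(samples) if s.attention_label is not None]
    strip_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((seed, 0xA77E)))
    )
    perm = strip_rng.permutation(len(lesion_idx))
    keep = {lesion_idx[j] for j in perm[: _exact_count(attention_rate, len(lesion_idx))]}
    for i in lesion_idx:
        if i not in keep:
            samples[i].attention_label = None
    manifest = [
        {
            "sample_id": s.sample_id,
            "class": s.class_label,
            "mask_present": s.attention_label is not None,
        }
        for s in samples
    ]
    return samples, manifest


# ---------------------------------------------------------------------------
# on-disk layout: PNG images + masks, CSV manifest, JSON sidecar
# ---------------------------------------------------------------------------


def save_dataset(samples, config: PhantomConfig, out_dir, seed: int | None = None,
                 bit_depth: int = 16) -> Path:
    """Write images/masks as grayscale PNG plus a CSV manifest."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    scale = 255 if bit_depth == 8 else 65535
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    rows = []
    for s in samples:
        img_path = out / "images" / f"{s.sample_id}.png"
        iio.imwrite(img_path, np.round(s.image * scale).astype(dtype))
        mask_path = ""
        if s.attention_label is not None:
            mpath = out / "masks" / f"{s.sample_id}.png"
            iio.imwrite(mpath, (s.attention_label.astype(np.uint8) * 255))
            mask_path = str(mpath.relative_to(out))
        rows.append(
            {
                "sample_id": s.sample_id,
                "class": s.class_label,
                "image_path": str(img_path.relative_to(out)),
                "mask_path": mask_path,
            }
        )
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["sample_id", "class", "image_path", "mask_path"]
        )
        writer.writeheader()
        writer.writerows(rows)
    sidecar = asdict(config)
    sidecar["seed"] = config.seed if seed is None else seed
    sidecar["bit_depth"] = bit_depth
    with open(out / "phantom_config.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return out / "manifest.csv"


def load_dataset(manifest_path) -> list[RadiographSample]:
    """Read a dataset back from a manifest written by :func:`save_dataset`.

    Accepts the CSV layout (header ``sample_id,class,image_path,mask_path``)
    or a JSON list of records with the same keys; paths are resolved
    relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    if manifest_path.suffix.lower() == ".json":
        with open(manifest_path) as fh:
            rows = json.load(fh)
    else:
        with open(manifest_path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    samples = []
    for row in rows:
        raw = iio.imread(root / row["image_path"])
        info = np.iinfo(raw.dtype) if raw.dtype.kind == "u" else None
        image = raw.astype(np.float64) / (info.max if info else 1.0)
        mask = None
        if row.get("mask_path"):
            m = iio.imread(root / row["mask_path"])
            mask = (m > 0).astype(np.uint8)
        samples.append(
            RadiographSample(
                image=image,
                class_label=row["class"],
                sample_id=row["sample_id"],
                attention_label=mask,
            )
        )
    return samples
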