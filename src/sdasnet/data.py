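"""Dataset I/O and the offline augmentation pipeline.

Samples pair an RGB image with a binary mask (background 0, antler
foreground 255).  Masks come either as single-channel PNGs or as
Labelme-style JSON polygon annotations rasterised here.  The augmentation
scheme expands every original into exactly four samples: the original plus
one each from (i) a random affine transform applied identically to image
and mask, (ii) a brightness/contrast adjustment, and (iii) composite
gaussian + salt-and-pepper noise — photometric and noise edits leave the
mask untouched.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely
from PIL import Image
from scipy import ndimage

PROVENANCES = ("original", "affine", "photometric", "noise", "synthetic")


@dataclass
class Sample:
    image: np.ndarray          # (H, W, 3) uint8
    mask: np.ndarray           # (H, W) uint8 in {0, 255}
    id: str
    provenance: str = "original"

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.uint8)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be (H, W, 3), got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape} != image {self.image.shape[:2]}")
        bad = set(np.unique(self.mask)) - {0, 255}
        if bad:
            raise ValueError(f"mask has non-binary values {sorted(bad)}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class AugmentConfig:
    rotation_deg: tuple = (-15.0, 15.0)
    translate_frac: tuple = (-0.10, 0.10)
    scale: tuple = (0.9, 1.1)
    brightness_frac: tuple = (-0.2, 0.2)
    contrast_frac: tuple = (-0.2, 0.2)
    gaussian_sigma: tuple = (0.01, 0.05)       # fraction of the 0-255 range
    salt_pepper_density: tuple = (0.005, 0.02)
    seed: int = 0

    def __post_init__(self):
        for name in ("rotation_deg", "translate_frac", "scale",
                     "brightness_frac", "contrast_frac", "gaussian_sigma",
                     "salt_pepper_density"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} range must be non-degenerate")
        lo, hi = self.salt_pepper_density
        if not (0.0 < lo and hi < 0.5):
            raise ValueError("salt_pepper_density must lie in (0, 0.5)")


# -- Labelme ------------------------------------------------------------------

def labelme_to_mask(annotation, canvas) -> np.ndarray:
    """Rasterise Labelme polygon shapes onto a (H, W) binary mask.

    A pixel (row r, column c) is foreground when the point (x=c, y=r) lies
    inside or on the boundary of any polygon (boundary-inclusive rule);
    overlapping polygons union.  Vertices outside the canvas are clipped to
    its bounds with a warning.
    """
    if isinstance(annotation, (str, bytes)):
        annotation = json.loads(annotation)
    if not isinstance(annotation, dict) or "shapes" not in annotation:
        raise ValueError("malformed annotation: expected a dict with 'shapes'")
    h, w = canvas
    mask = np.zeros((h, w), dtype=np.uint8)
    cols, rows = np.meshgrid(np.arange(w, dtype=float),
                             np.arange(h, dtype=float))
    for shape in annotation["shapes"]:
        points = np.asarray(shape["points"], dtype=float)
        if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
            raise ValueError(f"polygon needs >= 3 (x, y) points, got {points.shape}")
        clipped = np.column_stack([np.clip(points[:, 0], 0, w - 1),
                                   np.clip(points[:, 1], 0, h - 1)])
        if not np.allclose(clipped, points):
            warnings.warn(f"polygon {shape.get('label', '?')!r} clipped to canvas")
        poly = shapely.Polygon(clipped)
        inside = shapely.covers(poly, shapely.points(cols.ravel(), rows.ravel()))
        mask[inside.reshape(h, w)] = 255
    return mask


# -- dataset loading ----------------------------------------------------------

def _resize(sample: Sample, size) -> Sample:
    h, w = size
    img = Image.fromarray(sample.image).resize((w, h), Image.BILINEAR)
    msk = Image.fromarray(sample.mask).resize((w, h), Image.NEAREST)
    return replace(sample, image=np.asarray(img), mask=np.asarray(msk))


def load_dataset(root, split: str = "train", image_size=None) -> list[Sample]:
    """Load paired image/mask files from ``root/split/{images,masks}``.

    Pairing is by shared stem.  Masks are binarised with the >127 threshold;
    images are resized bilinearly and masks with nearest-neighbour when
    ``image_size`` is given.  Unpaired files abort with an error report.
    """
    base = Path(root) / split
    img_dir, mask_dir = base / "images", base / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(f"expected {img_dir} and {mask_dir}")
    images = {p.stem: p for p in sorted(img_dir.iterdir())
              if p.suffix.lower() in (".png", ".jpg", ".jpeg")}
    masks = {p.stem: p for p in sorted(mask_dir.iterdir())
             if p.suffix.lower() == ".png"}
    unpaired = sorted(set(images) ^ set(masks))
    if unpaired:
        raise ValueError(f"unpaired stems (missing image or mask): {unpaired}")
    samples = []
    for stem in sorted(images):
        image = np.asarray(Image.open(images[stem]).convert("RGB"))
        mask = np.asarray(Image.open(masks[stem]).convert("L"))
        if mask.shape != image.shape[:2]:
            raise ValueError(f"{stem}: mask shape {mask.shape} != image "
                             f"{image.shape[:2]}")
        mask = np.where(mask > 127, 255, 0).astype(np.uint8)
        sample = Sample(image, mask, id=stem)
        if image_size is not None:
            sample = _resize(sample, image_size)
        samples.append(sample)
    return samples


def save_dataset(samples, root, split: str = "train") -> None:
    base = Path(root) / split
    (base / "images").mkdir(parents=True, exist_ok=True)
    (base / "masks").mkdir(parents=True, exist_ok=True)
    for s in samples:
        Image.fromarray(s.image).save(base / "images" / f"{s.id}.png")
        Image.fromarray(s.mask).save(base / "masks" / f"{s.id}.png")


# -- augmentation -------------------------------------------------------------

def _uniform(rng, bounds):
    return rng.uniform(bounds[0], bounds[1])


def _affine(sample: Sample, rng, cfg: AugmentConfig) -> Sample:
    h, w = sample.mask.shape
    angle = np.deg2rad(_uniform(rng, cfg.rotation_deg))
    scale = _uniform(rng, cfg.scale)
    tx = _uniform(rng, cfg.translate_frac) * w
    ty = _uniform(rng, cfg.translate_frac) * h
    # rotate+scale about the image centre, then translate (output->input map)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]]) * scale
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    inv = np.linalg.inv(rot)
    offset = centre - inv @ (centre + np.array([ty, tx]))
    img = np.stack([
        ndimage.affine_transform(sample.image[..., ch].astype(np.float32),
                                 inv, offset=offset, order=1, mode="constant")
        for ch in range(3)], axis=-1)
    msk = ndimage.affine_transform(sample.mask, inv, offset=offset, order=0,
                                   mode="constant")
    return replace(sample,
                   image=np.clip(np.round(img), 0, 255).astype(np.uint8),
                   mask=np.where(msk > 127, 255, 0).astype(np.uint8),
                   id=sample.id + "_affine", provenance="affine")


def _photometric(sample: Sample, rng, cfg: AugmentConfig) -> Sample:
    brightness = _uniform(rng, cfg.brightness_frac) * 255.0
    contrast = 1.0 + _uniform(rng, cfg.contrast_frac)
    img = sample.image.astype(np.float32)
    img = (img - 127.5) * contrast + 127.5 + brightness
    return replace(sample,
                   image=np.clip(np.round(img), 0, 255).astype(np.uint8),
                   id=sample.id + "_photo", provenance="photometric")


def _noise(sample: Sample, rng, cfg: AugmentConfig) -> Sample:
    sigma = _uniform(rng, cfg.gaussian_sigma) * 255.0
    density = _uniform(rng, cfg.salt_pepper_density)
    img = sample.image.astype(np.float32)
    img = img + rng.normal(0.0, sigma, size=img.shape)
    u = rng.random(sample.mask.shape)
    img[u < density / 2] = 0.0
    img[(u >= density / 2) & (u < density)] = 255.0
    return replace(sample,
                   image=np.clip(np.round(img), 0, 255).astype(np.uint8),
                   id=sample.id + "_noise", provenance="noise")


def augment_expand(samples, config: AugmentConfig | None = None) -> list[Sample]:
    """Expand each original into exactly 4 samples (x4 scheme), fully seeded."""
    if not samples:
        raise ValueError("no samples to augment")
    if config is None:
        config = AugmentConfig()
    out = []
    for i, sample in enumerate(samples):
        rng = np.random.default_rng((config.seed, i))
        out.append(sample)
        out.append(_affine(sample, rng, config))
        out.append(_photometric(sample, rng, config))
        out.append(_noise(sample, rng, config))
    return out
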