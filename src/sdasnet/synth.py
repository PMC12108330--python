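"""Seeded synthetic antler-image generator.

Emulates the statistical structure of farm photographs of adult sika deer
antlers: a bright, branched foreground (a random binary tree of thick,
gently curved strokes growing upward from a pedicle point, thinning toward
the tips), a textured background (low-pass filtered noise in muted
browns/greens), smooth lighting variation across the frame, sensor noise,
and optional ear-like elliptical distractors abutting the antler base whose
colour is close to the antler's — the classic confusion case.  The mask is
the exact support of the rendered foreground strokes, so labels are
pixel-perfect by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data import Sample


@dataclass
class SynthConfig:
    image_size: tuple = (64, 64)
    n_branches: tuple = (2, 5)            # splits beyond the main beam
    branch_thickness: tuple = (2, 5)      # trunk radius in pixels
    background_texture: str = "mottled"   # "mottled" | "flat"
    lighting: tuple = (0.75, 1.25)        # multiplicative gradient endpoints
    distractors: bool = True
    foreground_frac: tuple = (0.03, 0.40)
    seed: int = 0

    def __post_init__(self):
        if min(self.image_size) < 16:
            raise ValueError("image_size too small")
        if self.background_texture not in ("mottled", "flat"):
            raise ValueError(f"unknown texture {self.background_texture!r}")
        if self.branch_thickness[0] < 1:
            raise ValueError("branch_thickness must be positive")


def _stamp_disks(support: np.ndarray, rows, cols, radius: float) -> None:
    """Mark disks of ``radius`` at the given centres on a boolean canvas."""
    h, w = support.shape
    r = max(int(np.ceil(radius)), 1)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (yy * yy + xx * xx) <= radius * radius
    for cy, cx in zip(rows, cols):
        cy, cx = int(round(cy)), int(round(cx))
        y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
        x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
        if y0 >= y1 or x0 >= x1:
            continue
        support[y0:y1, x0:x1] |= disk[y0 - (cy - r):y1 - (cy - r),
                                      x0 - (cx - r):x1 - (cx - r)]


def _grow_branch(support, rng, start, angle, length, radius, depth, max_extra):
    """Recursively draw one gently curving stroke and its children."""
    h, w = support.shape
    n_steps = max(int(length), 4)
    pos = np.array(start, dtype=float)
    curve = rng.uniform(-0.04, 0.04)
    spawned = 0
    for step in range(n_steps):
        angle += curve + rng.normal(0.0, 0.02)
        pos += np.array([-np.cos(angle), np.sin(angle)])  # grow upward
        taper = radius * (1.0 - 0.6 * step / n_steps)
        _stamp_disks(support, [pos[0]], [pos[1]], max(taper, 1.0))
        if (max_extra > spawned and depth < 3 and step > n_steps // 3
                and rng.random() < 2.0 / n_steps):
            side = rng.choice((-1.0, 1.0))
            child_angle = angle + side * rng.uniform(0.4, 0.9)
            spawned += 1 + _grow_branch(
                support, rng, pos.copy(), child_angle,
                length * rng.uniform(0.4, 0.7), taper * 0.8,
                depth + 1, max_extra - spawned - 1)
    return spawned


def _render_antler_support(shape, rng, cfg: SynthConfig) -> np.ndarray:
    h, w = shape
    support = np.zeros(shape, dtype=bool)
    base = (h - 1 - rng.integers(0, h // 8),
            w // 2 + rng.integers(-w // 6, w // 6 + 1))
    n_extra = int(rng.integers(cfg.n_branches[0], cfg.n_branches[1] + 1))
    radius = rng.uniform(*cfg.branch_thickness)
    angle = rng.uniform(-0.35, 0.35)
    _grow_branch(support, rng, base, angle, length=0.65 * h, radius=radius,
                 depth=0, max_extra=n_extra)
    return support


def _background(shape, rng, cfg: SynthConfig) -> np.ndarray:
    h, w = shape
    base_colour = rng.uniform((60, 70, 50), (110, 110, 90))
    img = np.ones((h, w, 3), dtype=np.float64) * base_colour
    if cfg.background_texture == "mottled":
        noise = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=3.0)
        noise = noise / (np.abs(noise).max() + 1e-9)
        img += noise[..., None] * rng.uniform(15.0, 35.0)
    return img


def _apply_lighting(img, rng, cfg: SynthConfig):
    h, w = img.shape[:2]
    lo, hi = cfg.lighting
    a, b = rng.uniform(lo, hi), rng.uniform(lo, hi)
    direction = rng.random() < 0.5
    ramp = np.linspace(a, b, w)[None, :] if direction else np.linspace(a, b, h)[:, None]
    return img * ramp[..., None]


def _render_sample(rng, cfg: SynthConfig, sample_id: str) -> Sample:
    h, w = cfg.image_size
    lo_frac, hi_frac = cfg.foreground_frac
    for _ in range(50):  # rejection-sample until coverage is in range
        support = _render_antler_support((h, w), rng, cfg)
        frac = support.mean()
        if lo_frac <= frac <= hi_frac:
            break
    img = _background((h, w), rng, cfg)
    antler_colour = rng.uniform((150, 120, 90), (220, 200, 170))
    if cfg.distractors and rng.random() < 0.8:
        # ear-like ellipse abutting the antler base, antler-like colour
        rows, cols = np.nonzero(support)
        if rows.size:
            k = rng.integers(rows.size)
            cy, cx = rows[k], cols[k]
            ry, rx = rng.uniform(h / 14, h / 8), rng.uniform(w / 10, w / 6)
            th = rng.uniform(0, np.pi)
            yy, xx = np.mgrid[0:h, 0:w].astype(float)
            dy, dx = yy - cy, xx - (cx + rng.choice((-1, 1)) * rx)
            u = dy * np.cos(th) + dx * np.sin(th)
            v = -dy * np.sin(th) + dx * np.cos(th)
            ear = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
            ear &= ~support
            img[ear] = antler_colour * rng.uniform(0.8, 0.95)
    shade = 1.0 - 0.15 * ndimage.gaussian_filter(
        rng.normal(0, 1, (h, w)), sigma=2.0).clip(-1, 1)
    img[support] = (antler_colour * shade[..., None])[support]
    img = _apply_lighting(img, rng, cfg)
    img += rng.normal(0.0, 4.0, img.shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    mask = np.where(support, 255, 0).astype(np.uint8)
    return Sample(image, mask, id=sample_id, provenance="synthetic")


def generate_synthetic_dataset(config: SynthConfig | None = None,
                               n: int = 1) -> list[Sample]:
    """Produce ``n`` seeded image/mask pairs; the seed fully determines them."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if config is None:
        config = SynthConfig()
    samples = []
    for i in range(n):
        rng = np.random.default_rng((config.seed, i))
        samples.append(_render_sample(rng, config, sample_id=f"synth_{i:05d}"))
    return samples
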