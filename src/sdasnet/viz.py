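"""Feature-map and attention-heatmap dump utilities (grayscale PNG grids)."""

from __future__ import annotations

import numpy as np
from PIL import Image

from .nn import Tensor


def _to_array(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def feature_grid(fmap, max_channels: int = 16, pad: int = 1) -> np.ndarray:
    """Tile the first channels of a (C, H, W) or (N, C, H, W) feature map
    into one uint8 image, each channel min-max normalised independently."""
    arr = _to_array(fmap)
    if arr.ndim == 4:
        arr = arr[0]
    if arr.ndim != 3:
        raise ValueError(f"expected (C, H, W), got shape {arr.shape}")
    arr = arr[:max_channels].astype(np.float64)
    c, h, w = arr.shape
    cols = int(np.ceil(np.sqrt(c)))
    rows = int(np.ceil(c / cols))
    canvas = np.zeros((rows * (h + pad) - pad, cols * (w + pad) - pad))
    for i, ch in enumerate(arr):
        lo, hi = ch.min(), ch.max()
        norm = (ch - lo) / (hi - lo) if hi > lo else np.zeros_like(ch)
        r, q = divmod(i, cols)
        canvas[r * (h + pad):r * (h + pad) + h,
               q * (w + pad):q * (w + pad) + w] = norm
    return np.round(canvas * 255).astype(np.uint8)


def save_feature_maps(fmap, path, max_channels: int = 16) -> None:
    Image.fromarray(feature_grid(fmap, max_channels)).save(path)


def save_heatmap(weights, path) -> None:
    """Save a 2-D attention weight matrix as a min-max scaled PNG."""
    arr = _to_array(weights).astype(np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D weight matrix")
    lo, hi = arr.min(), arr.max()
    norm = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    Image.fromarray(np.round(norm * 255).astype(np.uint8)).save(path)
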