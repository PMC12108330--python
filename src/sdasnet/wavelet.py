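"""Single-level 2-D discrete wavelet transform.

The forward transform is the separable decimated form

    cA(x, y) = sum_m sum_n f(m, n) * lo(m - 2x) * lo(n - 2y)

and its three detail counterparts: low/high filtering along the row index
first, then along the column index, with stride-2 decimation and periodic
boundary extension.  Sub-band naming follows the low/high order of the two
axes: cA = low-low, cH = low-high, cV = high-low, cD = high-high.  For an
orthonormal family (default: Haar) the transform is orthogonal, so energy is
conserved and ``idwt2`` (the adjoint) is an exact inverse.

Filter coefficients are taken from PyWavelets' filter bank; the transform
itself is implemented here so the sign/orientation convention is fixed and
testable against a brute-force evaluation of the double sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt


@dataclass(frozen=True)
class WaveletFilters:
    """Analysis filter pair of a discrete wavelet family.

    ``scaling_lowpass`` holds the scale-function (phi) filter extracting the
    low-frequency content; ``wavelet_highpass`` holds the wavelet-function
    (psi) filter extracting the high-frequency content.
    """

    family_name: str
    scaling_lowpass: np.ndarray
    wavelet_highpass: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.scaling_lowpass, dtype=np.float64)
        hi = np.asarray(self.wavelet_highpass, dtype=np.float64)
        object.__setattr__(self, "scaling_lowpass", lo)
        object.__setattr__(self, "wavelet_highpass", hi)
        if lo.ndim != 1 or hi.ndim != 1:
            raise ValueError("filters must be 1-D")
        if lo.size != hi.size:
            raise ValueError("lowpass and highpass must have equal length")
        if lo.size % 2:
            raise ValueError("filter length must be even")

    @classmethod
    def from_family(cls, name: str = "haar") -> "WaveletFilters":
        w = pywt.Wavelet(name)
        return cls(name, np.asarray(w.dec_lo), np.asarray(w.dec_hi))

    @property
    def length(self) -> int:
        return self.scaling_lowpass.size

    def is_orthonormal(self, tol: float = 1e-12) -> bool:
        return (abs(np.sum(self.scaling_lowpass ** 2) - 1.0) < tol
                and abs(np.sum(self.wavelet_highpass ** 2) - 1.0) < tol)


@dataclass
class SubbandSet:
    """The four half-resolution sub-bands of one channel at one level."""

    cA: np.ndarray
    cH: np.ndarray
    cV: np.ndarray
    cD: np.ndarray

    def __post_init__(self):
        shapes = {np.shape(b) for b in (self.cA, self.cH, self.cV, self.cD)}
        if len(shapes) != 1:
            raise ValueError(f"sub-band shapes differ: {shapes}")

    @property
    def shape(self):
        return self.cA.shape

    def stack(self) -> np.ndarray:
        """(4, h, w) array in cA, cH, cV, cD order."""
        return np.stack([self.cA, self.cH, self.cV, self.cD])


def _analysis_1d(x: np.ndarray, filt: np.ndarray, axis: int) -> np.ndarray:
    """Periodic correlation with stride 2 along ``axis``: out[k] = sum_j x[2k+j] filt[j]."""
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(filt.size)[None, :]) % n
    out = np.einsum("...kj,j->...k", x[..., idx], filt)
    return np.moveaxis(out, -1, axis)


def _synthesis_1d(coef: np.ndarray, filt: np.ndarray, axis: int, n: int) -> np.ndarray:
    """Adjoint of ``_analysis_1d``: scatter coefficients back to length ``n``."""
    coef = np.moveaxis(coef, axis, -1)
    out = np.zeros(coef.shape[:-1] + (n,), dtype=np.result_type(coef, filt))
    for j, w in enumerate(filt):
        t = (2 * np.arange(n // 2) + j) % n
        np.add.at(out, (..., t), coef * w)
    return np.moveaxis(out, -1, axis)


def _validate_channel(channel: np.ndarray) -> np.ndarray:
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise ValueError(f"expected a 2-D channel, got ndim={channel.ndim}")
    if channel.shape[0] < 2 or channel.shape[1] < 2:
        raise ValueError(f"channel too small for decimation: {channel.shape}")
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite values")
    return channel


def dwt2(channel: np.ndarray, filters: WaveletFilters | None = None) -> SubbandSet:
    """Decompose one 2-D channel into approximation + three detail sub-bands.

    Odd-sized axes are symmetric-padded by one trailing row/column before the
    transform so each output dimension is ceil(input/2).
    """
    if filters is None:
        filters = WaveletFilters.from_family("haar")
    channel = _validate_channel(channel)
    pad_h = channel.shape[0] % 2
    pad_w = channel.shape[1] % 2
    if pad_h or pad_w:
        channel = np.pad(channel, ((0, pad_h), (0, pad_w)), mode="symmetric")
    lo, hi = filters.scaling_lowpass, filters.wavelet_highpass
    lo0 = _analysis_1d(channel, lo, axis=0)
    hi0 = _analysis_1d(channel, hi, axis=0)
    return SubbandSet(
        cA=_analysis_1d(lo0, lo, axis=1),
        cH=_analysis_1d(lo0, hi, axis=1),
        cV=_analysis_1d(hi0, lo, axis=1),
        cD=_analysis_1d(hi0, hi, axis=1),
    )


def idwt2(subbands: SubbandSet, filters: WaveletFilters | None = None) -> np.ndarray:
    """Reconstruct the channel from its four sub-bands (exact for orthonormal families)."""
    if filters is None:
        filters = WaveletFilters.from_family("haar")
    lo, hi = filters.scaling_lowpass, filters.wavelet_highpass
    h2, w2 = subbands.shape
    h, w = 2 * h2, 2 * w2
    lo0 = (_synthesis_1d(subbands.cA, lo, 1, w)
           + _synthesis_1d(subbands.cH, hi, 1, w))
    hi0 = (_synthesis_1d(subbands.cV, lo, 1, w)
           + _synthesis_1d(subbands.cD, hi, 1, w))
    return _synthesis_1d(lo0, lo, 0, h) + _synthesis_1d(hi0, hi, 0, h)


def dwt2_multichannel(image: np.ndarray, filters: WaveletFilters | None = None):
    """Per-channel transform of a (C, H, W) image.

    Returns ``(cA_stack, high_stack)`` where ``cA_stack`` is (C, H/2, W/2) and
    ``high_stack`` is (3C, H/2, W/2) holding each channel's cH, cV, cD grouped
    band-major (all cH first, then all cV, then all cD).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3:
        raise ValueError("expected (C, H, W) image")
    bands = [dwt2(ch, filters) for ch in image]
    cA = np.stack([b.cA for b in bands])
    high = np.concatenate([
        np.stack([b.cH for b in bands]),
        np.stack([b.cV for b in bands]),
        np.stack([b.cD for b in bands]),
    ])
    return cA, high
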