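"""Annotation-free IHC activation masks and the dynamic loss weights.

An IHC tile is thresholded in HSV space to isolate the chromogen-positive
("activated") pixels, giving a binary mask M with N activated and N-bar
background pixels.  The dynamic weights

    alpha = N-bar / (N + N-bar),    beta = N / (N + N-bar)

then rebalance the loss terms so that rare activated regions receive
large weight: alpha multiplies activated-region terms and grows as
activation becomes scarce.

The contract works in normalized HSV (hue in degrees 0-360, saturation
and value in [0, 1]); conversion from 8-bit RGB happens at the boundary.
Hue ranges may wrap around 0/360 (e.g. reds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

__all__ = [
    "HSVRange",
    "ActivationMask",
    "MaskWeights",
    "extract_activation_mask",
    "compute_weights",
    "degrade_mask",
    "resample_mask",
    "write_mask_png",
    "read_mask_png",
]


@dataclass(frozen=True)
class HSVRange:
    """Inclusive HSV thresholds; hue in degrees and allowed to wrap."""

    hue_lo: float
    hue_hi: float
    sat_lo: float = 0.0
    sat_hi: float = 1.0
    val_lo: float = 0.0
    val_hi: float = 1.0

    def __post_init__(self):
        for lo, hi, name in ((self.sat_lo, self.sat_hi, "sat"), (self.val_lo, self.val_hi, "val")):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} bounds must satisfy 0 <= lo <= hi <= 1")
        if not (0.0 <= self.hue_lo <= 360.0 and 0.0 <= self.hue_hi <= 360.0):
            raise ValueError("hue bounds must lie in [0, 360]")

    def contains(self, hue_deg, sat, val):
        """Vectorized membership test (hue tested with wraparound)."""
        hue_deg = np.asarray(hue_deg)
        if self.hue_lo <= self.hue_hi:
            hue_ok = (hue_deg >= self.hue_lo) & (hue_deg <= self.hue_hi)
        else:  # wrapping range, e.g. 350 -> 10
            hue_ok = (hue_deg >= self.hue_lo) | (hue_deg <= self.hue_hi)
        return (
            hue_ok
            & (sat >= self.sat_lo) & (sat <= self.sat_hi)
            & (val >= self.val_lo) & (val <= self.val_hi)
        )


#: Default band targeting DAB-brown-like chromogen.
DAB_BROWN = HSVRange(hue_lo=10, hue_hi=40, sat_lo=0.25, sat_hi=1.0, val_lo=0.0, val_hi=0.9)


@dataclass
class ActivationMask:
    """Binary activation mask with its pixel bookkeeping."""

    mask: np.ndarray  # bool H x W, True = IHC-activated

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.size == 0:
            raise ValueError("mask must be non-empty")
        self.mask = m.astype(bool)

    @property
    def n_activated(self) -> int:
        return int(self.mask.sum())

    @property
    def n_background(self) -> int:
        return int(self.mask.size - self.mask.sum())

    @property
    def complement(self) -> np.ndarray:
        return ~self.mask

    def as_float(self, dtype=np.float64) -> np.ndarray:
        return self.mask.astype(dtype)


@dataclass(frozen=True)
class MaskWeights:
    alpha: float
    beta: float

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("weights must lie in [0, 1]")
        if abs(self.alpha + self.beta - 1.0) > 1e-6:
            raise ValueError("alpha + beta must equal 1")


def extract_activation_mask(tile, hsv_range: HSVRange, median_filter: bool = False) -> ActivationMask:
    """Threshold an 8-bit RGB tile in HSV space.

    A pixel is activated iff its (hue, sat, val) triplet lies inside
    ``hsv_range``.  No morphological cleanup is applied by default;
    ``median_filter=True`` enables a 3x3 median pass.
    """
    pixels = getattr(tile, "pixels", tile)
    arr = np.asarray(pixels)
    if arr.size == 0:
        raise ValueError("empty tile")
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise ValueError("expected an 8-bit RGB tile")
    hsv = rgb2hsv(arr)
    mask = hsv_range.contains(hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2])
    if median_filter:
        from scipy.ndimage import median_filter as _median

        mask = _median(mask.astype(np.uint8), size=3).astype(bool)
    return ActivationMask(mask=mask)


def compute_weights(mask: ActivationMask) -> MaskWeights:
    """Dynamic weights alpha = N-bar/(N + N-bar), beta = N/(N + N-bar)."""
    n, nbar = mask.n_activated, mask.n_background
    total = n + nbar
    return MaskWeights(alpha=nbar / total, beta=n / total)


def degrade_mask(mask: ActivationMask) -> ActivationMask:
    """Low-resolution mask matching the image degradation operator.

    The binary mask is average-pooled with the same 3x3/stride-2 kernel
    used for images, then re-binarized at 0.5.
    """
    m = mask.as_float()
    if m.shape[0] < 3 or m.shape[1] < 3:
        raise ValueError("mask smaller than the 3x3 pooling kernel")
    pooled = _avg_pool_3s2(m)
    return ActivationMask(mask=pooled >= 0.5)


def _avg_pool_3s2(arr: np.ndarray) -> np.ndarray:
    win = np.lib.stride_tricks.sliding_window_view(arr, (3, 3))
    return win[::2, ::2].mean(axis=(2, 3))


def resample_mask(mask: ActivationMask, shape: tuple[int, int]) -> ActivationMask:
    """Area-resample a mask to an arbitrary grid and re-binarize at 0.5.

    Used to align image-resolution masks with discriminator patch grids
    and latent grids.
    """
    from skimage.transform import resize

    m = mask.as_float()
    if m.shape == tuple(shape):
        return ActivationMask(mask=mask.mask.copy())
    res = resize(m, shape, order=1, anti_aliasing=True, preserve_range=True)
    return ActivationMask(mask=res >= 0.5)


def write_mask_png(mask: ActivationMask, path) -> None:
    from PIL import Image

    Image.fromarray(mask.mask).save(path, bits=1)


def read_mask_png(path) -> ActivationMask:
    from PIL import Image

    arr = np.asarray(Image.open(path))
    return ActivationMask(mask=arr.astype(bool))
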