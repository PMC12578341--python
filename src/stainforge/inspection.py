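"""Discriminator self-inspection: confidence maps, QC gating, heatmaps.

The PatchGAN discriminator learned during training is reused at
deployment as an anomaly detector.  Its two head maps are clamped to
[-1, 1] (-1 anomaly, +1 authentic), bilinearly resized to the input
size, fused by a pixel-wise minimum and renormalized to [0, 1]:

    C_all = (min(C_lum, C_rgb) + 1) / 2

The population standard deviation of C_all (in percent) summarizes a
tile: very flat maps are typically background-only tiles, very spread
maps indicate artifacts.  An acceptance band for that std is calibrated
empirically from authentic tiles via quantiles, and tiles are gated
with a closed interval: accept iff lo <= std <= hi.

Heatmaps render C_all through the classic piecewise-linear Jet ramp;
by default the index is inverted so anomalies (low confidence) appear
red, matching how pathologists read the overlays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from ._autograd import Tensor
from .core_io import TileImage
from .networks import DualHeadDiscriminator, discriminate, image_to_net

__all__ = [
    "ConfidenceMap",
    "QCInterval",
    "confidence_map",
    "confidence_std",
    "calibrate_interval",
    "qc_gate",
    "heatmap",
    "jet_colormap",
    "inspect_virtual_stain",
]


@dataclass
class ConfidenceMap:
    """Clamped head maps and their fused, normalized combination."""

    c_lum: np.ndarray  # H x W in [-1, 1]
    c_rgb: np.ndarray  # H x W in [-1, 1]
    c_all: np.ndarray  # H x W in [0, 1]


@dataclass(frozen=True)
class QCInterval:
    """Acceptable band for the std of C_all, in percent."""

    lo_percent: float
    hi_percent: float

    def __post_init__(self):
        if not (0.0 <= self.lo_percent < self.hi_percent <= 100.0):
            raise ValueError("interval must satisfy 0 <= lo < hi <= 100")


def _fuse(lum: np.ndarray, rgb: np.ndarray, out_shape: tuple[int, int]) -> ConfidenceMap:
    c_lum = np.clip(lum, -1.0, 1.0)
    c_rgb = np.clip(rgb, -1.0, 1.0)
    if c_lum.shape != out_shape:
        c_lum = resize(c_lum, out_shape, order=1, anti_aliasing=False, preserve_range=True)
        c_rgb = resize(c_rgb, out_shape, order=1, anti_aliasing=False, preserve_range=True)
    c_all = (np.minimum(c_lum, c_rgb) + 1.0) / 2.0
    return ConfidenceMap(c_lum=c_lum, c_rgb=c_rgb, c_all=c_all)


def confidence_map(discriminator: DualHeadDiscriminator, tile) -> ConfidenceMap:
    """Run the discriminator on a tile and fuse its head maps."""
    pixels = getattr(tile, "pixels", tile)
    out = discriminate(discriminator, image_to_net(pixels))
    lum = out.lum_map.data[0, 0]
    rgb = out.rgb_map.data[0, 0]
    return _fuse(lum, rgb, np.asarray(pixels).shape[:2])


def confidence_std(cmap: ConfidenceMap | np.ndarray) -> float:
    """Population standard deviation of C_all, in percent."""
    c_all = cmap.c_all if isinstance(cmap, ConfidenceMap) else np.asarray(cmap)
    return float(c_all.std()) * 100.0


def calibrate_interval(std_values, lo_q: float = 0.025, hi_q: float = 0.975,
                       min_samples: int = 100) -> QCInterval:
    """Empirical quantile band of std values measured on authentic tiles."""
    values = np.asarray(list(std_values), dtype=np.float64)
    if values.size < min_samples:
        raise ValueError(f"need >= {min_samples} std values, got {values.size}")
    if not (0.0 <= lo_q < hi_q <= 1.0):
        raise ValueError("quantiles must satisfy 0 <= lo_q < hi_q <= 1")
    lo, hi = np.quantile(values, [lo_q, hi_q])
    if hi <= lo:  # degenerate (e.g. constant inputs): widen minimally
        hi = lo + 1e-9
    return QCInterval(lo_percent=float(lo), hi_percent=float(min(hi, 100.0)))


def qc_gate(tile, discriminator: DualHeadDiscriminator,
            interval: QCInterval) -> tuple[str, float]:
    """Gate a tile by its confidence-map std.

    Returns (verdict, std): ``accept`` iff lo <= std <= hi (closed
    interval), ``flag_low`` below (typically mostly-background tiles),
    ``flag_high`` above (typically artifacts).
    """
    std = confidence_std(confidence_map(discriminator, tile))
    return gate_verdict(std, interval), std


def gate_verdict(std: float, interval: QCInterval) -> str:
    """Pure closed-interval decision on a precomputed std."""
    if std < interval.lo_percent:
        return "flag_low"
    if std > interval.hi_percent:
        return "flag_high"
    return "accept"


def jet_colormap(values: np.ndarray) -> np.ndarray:
    """Classic piecewise-linear Jet ramp on values in [0, 1].

    0 maps to dark blue, 0.5 to green-ish, 1 to dark red:
    r = clip(min(4v - 1.5, -4v + 4.5)), g and b shifted accordingly.
    Returns float RGB in [0, 1] with trailing channel axis.
    """
    v = np.clip(np.asarray(values, dtype=np.float64), 0.0, 1.0)
    r = np.clip(np.minimum(4.0 * v - 1.5, -4.0 * v + 4.5), 0.0, 1.0)
    g = np.clip(np.minimum(4.0 * v - 0.5, -4.0 * v + 3.5), 0.0, 1.0)
    b = np.clip(np.minimum(4.0 * v + 0.5, -4.0 * v + 2.5), 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)


def heatmap(cmap: ConfidenceMap | np.ndarray, invert: bool = True) -> np.ndarray:
    """8-bit RGB rendering of C_all.

    With ``invert=True`` (default) low confidence is red: the Jet index
    is 1 - C_all.  ``invert=False`` uses the raw Jet orientation.
    """
    c_all = cmap.c_all if isinstance(cmap, ConfidenceMap) else np.asarray(cmap)
    idx = 1.0 - c_all if invert else c_all
    rgb = jet_colormap(idx)
    return np.floor(rgb * 255.0 + 0.5).astype(np.uint8)


def inspect_virtual_stain(virtual_tile, stain_discriminator: DualHeadDiscriminator,
                          invert: bool = True) -> tuple[ConfidenceMap, np.ndarray]:
    """Confidence map plus heatmap for a generated stain tile, using the
    matching stain discriminator; intended for overlay export."""
    cmap = confidence_map(stain_discriminator, virtual_tile)
    return cmap, heatmap(cmap, invert=invert)
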