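"""Tile and slide raster I/O plus the sliding-window tiling grid.

Coordinate conventions used across the package: 0-based, (column, row)
order with the origin at the slide's top-left corner; tile rectangles
are half-open, ``[x0, x0 + M) x [y0, y0 + M)``.  Boundary tiles are
clamped inward (shifted so they end exactly at the slide edge) rather
than zero-padded, so stitched output never contains padding halos.

Tile filenames encode position as ``{stain}_{x0}_{y0}.png``; paired
samples share the ``{x0}_{y0}`` grid key across stain directories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "TileImage",
    "TilePlan",
    "SlideRaster",
    "plan_tiles",
    "read_tile",
    "write_tile",
    "write_pyramidal_tiff",
    "read_pyramid_level",
    "tile_filename",
    "parse_tile_filename",
    "foreground_fraction",
]

MAGNIFICATIONS = ("x10", "x20", "x40")


@dataclass
class TileImage:
    """An 8-bit RGB tile with its slide-pixel position."""

    pixels: np.ndarray
    position: tuple[int, int] = (0, 0)
    magnification: str = "x10"
    stain_label: str = "HE"

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("expected 3 channels (H x W x 3)")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("tile must be non-empty")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.position[0] < 0 or self.position[1] < 0:
            raise ValueError("position components must be >= 0")
        if self.magnification not in MAGNIFICATIONS:
            raise ValueError(f"magnification must be one of {MAGNIFICATIONS}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class TilePlan:
    """Row-major grid of clamped tile offsets covering a slide."""

    tile_size: int
    overlap: float
    slide_extent: tuple[int, int]  # (width, height)
    positions: list[tuple[int, int]] = field(default_factory=list)

    @property
    def stride(self) -> int:
        return max(1, round(self.tile_size * (1.0 - self.overlap)))


@dataclass
class SlideRaster:
    """Full-resolution RGB raster with a pyramid-level count."""

    pixels: np.ndarray
    pyramid_levels: int = 1

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("expected an H x W x 3 raster")
        self.pixels = px


def _axis_offsets(extent: int, tile: int, stride: int) -> list[int]:
    offsets = list(range(0, extent - tile + 1, stride))
    last = extent - tile
    if offsets[-1] != last:
        offsets.append(last)  # clamp the final tile to the boundary
    return offsets


def plan_tiles(slide_extent: tuple[int, int], tile_size: int, overlap: float) -> TilePlan:
    """Plan a sliding-window grid covering every pixel of the slide.

    Parameters
    ----------
    slide_extent
        (width, height) of the slide in pixels.
    tile_size
        Square tile side M (>= 8).
    overlap
        Fractional overlap o in [0, 1); the stride is round(M * (1 - o)).
    """
    if tile_size < 8:
        raise ValueError("tile_size must be >= 8")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must lie in [0, 1)")
    width, height = slide_extent
    if width < tile_size or height < tile_size:
        raise ValueError(
            f"slide extent {width}x{height} is smaller than one {tile_size}px tile"
        )
    plan = TilePlan(tile_size=tile_size, overlap=overlap, slide_extent=(width, height))
    xs = _axis_offsets(width, tile_size, plan.stride)
    ys = _axis_offsets(height, tile_size, plan.stride)
    plan.positions = [(x, y) for y in ys for x in xs]  # row-major
    return plan


# ----------------------------------------------------------------------
# tile files
# ----------------------------------------------------------------------

def tile_filename(stain: str, position: tuple[int, int], suffix: str = ".png") -> str:
    return f"{stain}_{position[0]}_{position[1]}{suffix}"


def parse_tile_filename(name: str) -> tuple[str, tuple[int, int]]:
    stem = Path(name).stem
    stain, x0, y0 = stem.rsplit("_", 2)
    return stain, (int(x0), int(y0))


def read_tile(path) -> TileImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.dtype != np.uint8:
        raise ValueError(f"unsupported bit depth: {arr.dtype} (expected 8-bit)")
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected 3 channels")
    try:
        stain, position = parse_tile_filename(path.name)
    except (ValueError, IndexError):
        stain, position = "HE", (0, 0)
    return TileImage(pixels=arr, position=position, stain_label=stain)


def write_tile(tile: TileImage, path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, tile.pixels, photometric="rgb")
    else:
        Image.fromarray(tile.pixels).save(path)


# ----------------------------------------------------------------------
# pyramidal TIFF
# ----------------------------------------------------------------------

def _halve(level: np.ndarray) -> np.ndarray:
    """Downsample by 2 with 2x2 block means, rounding dimensions up."""
    h, w, _ = level.shape
    ph, pw = h % 2, w % 2
    if ph or pw:
        level = np.pad(level, ((0, ph), (0, pw), (0, 0)), mode="edge")
    acc = level.astype(np.float64)
    out = (acc[0::2, 0::2] + acc[1::2, 0::2] + acc[0::2, 1::2] + acc[1::2, 1::2]) / 4.0
    return np.floor(out + 0.5).astype(np.uint8)


def pyramid_levels(pixels: np.ndarray, min_size: int = 256) -> list[np.ndarray]:
    """Level 0 plus halved levels until both dimensions are <= min_size."""
    levels = [np.asarray(pixels)]
    while max(levels[-1].shape[:2]) > min_size:
        levels.append(_halve(levels[-1]))
    return levels


def write_pyramidal_tiff(raster: SlideRaster, path, tile_size_internal: int = 256) -> None:
    """Write a tiled multi-resolution TIFF readable by standard WSI viewers."""
    levels = pyramid_levels(raster.pixels)
    raster.pyramid_levels = len(levels)
    ts = tile_size_internal
    if ts % 16:
        raise ValueError("internal TIFF tile size must be a multiple of 16")
    with tifffile.TiffWriter(str(path)) as tif:
        tif.write(levels[0], subifds=len(levels) - 1, tile=(ts, ts), photometric="rgb")
        for level in levels[1:]:
            tif.write(level, subfiletype=1, tile=(ts, ts), photometric="rgb")


def read_pyramid_level(path, level: int = 0) -> np.ndarray:
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        return series.levels[level].asarray()


def foreground_fraction(pixels: np.ndarray, luminance_threshold: float = 0.9) -> float:
    """Fraction of pixels darker than a luminance threshold (tissue proxy).

    A configurable stand-in for slide-level tissue filtering; it makes no
    claim beyond "not near-white background".
    """
    arr = np.asarray(pixels, dtype=np.float64) / 255.0
    lum = arr @ np.array([0.299, 0.587, 0.114])
    return float((lum < luminance_threshold).mean())
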