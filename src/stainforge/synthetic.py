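"""Procedural histology-like fixtures with exact ground truth.

The generator emulates the statistical structure the mask-weighted
training assumes — shared tissue morphology across stains, with sparse
chromogen-activated regions — without attempting photorealism:

* H&E tiles are pink/purple pseudo-tissue: a smoothed-noise eosin
  background with elliptical hematoxylin "nuclei".
* Each synthetic stain is an invertible affine color transform of the
  H&E tile (so a small model can genuinely learn the mapping), with an
  activation color painted *hard* (no alpha blending) inside seeded
  blobs.  Hard replacement makes the activated pixel count exactly
  countable, and each profile's activation color sits strictly inside
  its configured HSV range while the color-transformed tissue stays
  outside it (low saturation), so mask extraction can be scored against
  ground truth.
* Three degradation modes mimic slide-level quality failures: a global
  channel gain/offset shift, opaque contamination blobs, and
  water-droplet-like local blur with a bright ring.

All generators are pure functions of (seed, parameters).
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_io import TileImage, tile_filename, write_tile
from .masks import ActivationMask, HSVRange, write_mask_png

__all__ = [
    "StainProfile",
    "SyntheticSample",
    "default_profiles",
    "generate_he_tile",
    "generate_stain_tile",
    "generate_sample",
    "degrade_fixture",
    "build_dataset",
    "DEGRADATION_MODES",
]

DEGRADATION_MODES = ("global_shift", "contamination", "droplet")


def _hsv_to_rgb8(h_deg: float, s: float, v: float) -> tuple[int, int, int]:
    from colorsys import hsv_to_rgb

    r, g, b = hsv_to_rgb(h_deg / 360.0, s, v)
    return (int(round(r * 255)), int(round(g * 255)), int(round(b * 255)))


@dataclass(frozen=True)
class StainProfile:
    """Parameters of one synthetic stain.

    ``matrix``/``offset`` define the invertible tissue color transform
    applied outside activated regions; ``activation_color`` is painted
    inside.  ``hsv_range`` is the extraction band the activation color
    is guaranteed to satisfy.
    """

    name: str
    activation_hue: float  # degrees
    activation_fraction: float = 0.1
    base_tint: tuple[float, float, float] = (150.0, 150.0, 150.0)
    activation_sat: float = 0.65
    activation_val: float = 0.70
    hue_halfwidth: float = 20.0
    contrast: float = 0.30
    max_blob_radius: int = 24

    def __post_init__(self):
        if not (0.0 <= self.activation_fraction <= 1.0):
            raise ValueError("activation_fraction must lie in [0, 1]")

    @property
    def activation_color(self) -> tuple[int, int, int]:
        return _hsv_to_rgb8(self.activation_hue, self.activation_sat, self.activation_val)

    @property
    def hsv_range(self) -> HSVRange:
        lo = (self.activation_hue - self.hue_halfwidth) % 360.0
        hi = (self.activation_hue + self.hue_halfwidth) % 360.0
        return HSVRange(hue_lo=lo, hue_hi=hi, sat_lo=0.25, sat_hi=1.0, val_lo=0.05, val_hi=0.9)

    @property
    def matrix(self) -> np.ndarray:
        """Invertible, diagonally dominant color matrix (low output
        saturation keeps transformed tissue outside the HSV band)."""
        c = self.contrast
        return np.array([
            [c, 0.02, 0.01],
            [0.01, c, 0.02],
            [0.02, 0.01, c],
        ])

    @property
    def offset(self) -> np.ndarray:
        return np.asarray(self.base_tint, dtype=np.float64)

    def transform(self, he_pixels: np.ndarray) -> np.ndarray:
        out = he_pixels.astype(np.float64) @ self.matrix.T + self.offset
        return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def default_profiles() -> dict[str, StainProfile]:
    """Eight stains with well-separated activation hues; the last one
    exercises a wrapping (red) hue range."""
    specs = [
        ("AE1AE3", 25.0), ("CD117", 65.0), ("CD15", 105.0), ("CD163", 145.0),
        ("CD3", 185.0), ("CD8", 225.0), ("D240", 265.0), ("GIEMSA", 355.0),
    ]
    profiles = {}
    for i, (name, hue) in enumerate(specs):
        tint = (148.0 + 6.0 * ((i * 2) % 3), 150.0, 152.0 - 4.0 * (i % 2))
        profiles[name] = StainProfile(name=name, activation_hue=hue, base_tint=tint)
    return profiles


@dataclass
class SyntheticSample:
    he_tile: TileImage
    stain_tiles: dict[str, TileImage]
    gt_masks: dict[str, ActivationMask]
    grid_key: tuple[int, int]


# ----------------------------------------------------------------------
# tile generators
# ----------------------------------------------------------------------

def generate_he_tile(size: int = 64, seed: int = 0, n_nuclei: int | None = None,
                     smoothing: float = 4.0) -> TileImage:
    """Seeded pink/purple pseudo-tissue with elliptical nuclei."""
    rng = np.random.default_rng(seed)
    noise = gaussian_filter(rng.normal(size=(size, size)), smoothing)
    span = noise.max() - noise.min()
    noise = (noise - noise.min()) / (span if span > 0 else 1.0)
    eosin = np.array([235.0, 175.0, 205.0])
    pale = np.array([250.0, 235.0, 242.0])
    img = pale[None, None] + (eosin - pale)[None, None] * noise[..., None]

    if n_nuclei is None:
        n_nuclei = max(4, (size * size) // 450)
    hema = np.array([120.0, 70.0, 150.0])
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, size, 2)
        ry = rng.uniform(size / 40 + 1.0, size / 16 + 2.0)
        rx = ry * rng.uniform(0.6, 1.4)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        inside = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
        depth = rng.uniform(0.65, 0.95)
        img[inside] = (1 - depth) * img[inside] + depth * hema[None]
    pixels = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return TileImage(pixels=pixels, stain_label="HE")


def _paint_blobs(shape: tuple[int, int], fraction: float, rng: np.random.Generator,
                 max_radius: int) -> np.ndarray:
    """Union of random discs covering ``fraction`` of the frame +-10%."""
    h, w = shape
    total = h * w
    target = fraction * total
    mask = np.zeros(shape, dtype=bool)
    if fraction >= 1.0:
        return np.ones(shape, dtype=bool)
    if target < 0.5:
        return mask
    yy, xx = np.mgrid[0:h, 0:w]
    count = 0
    # Each disc's area is capped by the remaining headroom, so the final
    # count lands in [0.95, 1.05] * target.
    for _ in range(100_000):
        if count >= 0.95 * target:
            break
        headroom = 1.05 * target - count
        r = min(max_radius, int(np.sqrt(headroom / np.pi)))
        if r >= 2:
            r = rng.integers(2, r + 1)
        else:
            r = 1
        cy = rng.integers(0, h)
        cx = rng.integers(0, w)
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        new = disc & ~mask
        if count + new.sum() > 1.05 * target:
            continue
        mask |= disc
        count = int(mask.sum())
    return mask


def generate_stain_tile(he_tile: TileImage, profile: StainProfile,
                        seed: int = 0) -> tuple[TileImage, ActivationMask]:
    """Color-transform an H&E tile and paint activation blobs on it."""
    rng = np.random.default_rng(seed)
    base = profile.transform(he_tile.pixels)
    h, w = base.shape[:2]
    blob = _paint_blobs((h, w), profile.activation_fraction, rng,
                        max_radius=min(profile.max_blob_radius, max(2, h // 8)))
    out = base.copy()
    out[blob] = np.asarray(profile.activation_color, dtype=np.uint8)
    tile = TileImage(pixels=out, position=he_tile.position,
                     magnification=he_tile.magnification, stain_label=profile.name)
    return tile, ActivationMask(mask=blob)


def generate_sample(profiles: dict[str, StainProfile], size: int, seed: int,
                    grid_key: tuple[int, int] = (0, 0)) -> SyntheticSample:
    he = generate_he_tile(size=size, seed=seed)
    he.position = grid_key
    stain_tiles: dict[str, TileImage] = {}
    gt_masks: dict[str, ActivationMask] = {}
    for j, (name, profile) in enumerate(profiles.items()):
        tile, gt = generate_stain_tile(he, profile, seed=seed * 9973 + j + 1)
        stain_tiles[name] = tile
        gt_masks[name] = gt
    return SyntheticSample(he_tile=he, stain_tiles=stain_tiles, gt_masks=gt_masks,
                           grid_key=grid_key)


# ----------------------------------------------------------------------
# degradations
# ----------------------------------------------------------------------

#: Global-shift direction: per-channel gain slope and additive offset at
#: severity 1.  Chosen to mimic over-concentrated eosin / scanner drift.
GLOBAL_SHIFT_GAIN = np.array([1.0, -0.45, -0.30])
GLOBAL_SHIFT_OFFSET = np.array([35.0, -20.0, -10.0])


def degrade_fixture(tile: TileImage, mode: str, severity: float,
                    seed: int = 0) -> tuple[TileImage, np.ndarray]:
    """Apply one quality-failure mode; returns (tile, corruption mask)."""
    if mode not in DEGRADATION_MODES:
        raise ValueError(f"unknown degradation mode {mode!r}")
    if not (0.0 <= severity <= 1.0):
        raise ValueError("severity must lie in [0, 1]")
    px = tile.pixels
    h, w = px.shape[:2]
    if severity == 0.0:
        return (
            TileImage(pixels=px.copy(), position=tile.position,
                      magnification=tile.magnification, stain_label=tile.stain_label),
            np.zeros((h, w), dtype=bool),
        )
    rng = np.random.default_rng(seed)
    out = px.astype(np.float64)
    if mode == "global_shift":
        gain = 1.0 + 0.5 * severity * (GLOBAL_SHIFT_GAIN - 1.0)
        offset = severity * GLOBAL_SHIFT_OFFSET
        out = out * gain[None, None] + offset[None, None]
        corrupt = np.ones((h, w), dtype=bool)
    elif mode == "contamination":
        k = max(1, int(round(severity * 5)))
        corrupt = np.zeros((h, w), dtype=bool)
        yy, xx = np.mgrid[0:h, 0:w]
        r = max(2, int(min(h, w) * 0.08))
        placed = 0
        for _ in range(10_000):
            if placed >= k:
                break
            cy = rng.integers(r + 1, h - r - 1)
            cx = rng.integers(r + 1, w - r - 1)
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            # keep blobs disconnected so each stays one component
            grown = (yy - cy) ** 2 + (xx - cx) ** 2 <= (r + 2) ** 2
            if (grown & corrupt).any():
                continue
            corrupt |= disc
            shade = rng.uniform(15, 60)
            out[disc] = shade
            placed += 1
    else:  # droplet
        r = max(4, int(min(h, w) * (0.15 + 0.2 * severity)))
        cy = rng.integers(r, h - r) if h > 2 * r else h // 2
        cx = rng.integers(r, w - r) if w > 2 * r else w // 2
        yy, xx = np.mgrid[0:h, 0:w]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disc = d2 <= r * r
        ring = (d2 <= (r + 2) ** 2) & (d2 >= (r - 2) ** 2)
        blurred = gaussian_filter(out, sigma=(1.0 + 3.0 * severity, 1.0 + 3.0 * severity, 0))
        out[disc] = blurred[disc]
        out[ring] = np.clip(out[ring] + 60.0 * severity, 0, 255)
        corrupt = disc | ring
    pixels = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return (
        TileImage(pixels=pixels, position=tile.position,
                  magnification=tile.magnification, stain_label=tile.stain_label),
        corrupt,
    )


# ----------------------------------------------------------------------
# dataset layout
# ----------------------------------------------------------------------

def build_dataset(profiles: dict[str, StainProfile], n_tiles: int, setting: str,
                  seed: int, out_dir, tile_size: int = 64, force: bool = False) -> dict:
    """Write an on-disk dataset in the directory-per-stain layout.

    Paired: every stain directory shares the H&E grid keys (tiles come
    from the same synthetic tissue).  Unpaired: each stain's tiles come
    from independent tissue and carry their own disjoint grid keys.
    Ground-truth masks are stored beside the tiles for evaluation only.
    """
    if setting not in ("paired", "unpaired"):
        raise ValueError("setting must be 'paired' or 'unpaired'")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not force:
            raise FileExistsError(f"{out_dir} is not empty (use force=True)")
        shutil.rmtree(out_dir)
    (out_dir / "HE").mkdir(parents=True, exist_ok=True)
    for name in profiles:
        (out_dir / name).mkdir(exist_ok=True)
        (out_dir / "gt_masks" / name).mkdir(parents=True, exist_ok=True)

    def key_for(index: int, block: int) -> tuple[int, int]:
        cols = 16
        return ((index % cols) * tile_size, (index // cols) * tile_size + block)

    n_written = 0
    if setting == "paired":
        for t in range(n_tiles):
            key = key_for(t, 0)
            sample = generate_sample(profiles, tile_size, seed * 100_003 + t, key)
            write_tile(sample.he_tile, out_dir / "HE" / tile_filename("HE", key))
            for name in profiles:
                write_tile(sample.stain_tiles[name], out_dir / name / tile_filename(name, key))
                write_mask_png(sample.gt_masks[name],
                               out_dir / "gt_masks" / name / tile_filename(name, key))
            n_written += 1 + len(profiles)
    else:
        for t in range(n_tiles):
            key = key_for(t, 0)
            he = generate_he_tile(size=tile_size, seed=seed * 100_003 + t)
            he.position = key
            write_tile(he, out_dir / "HE" / tile_filename("HE", key))
            n_written += 1
        for j, (name, profile) in enumerate(profiles.items()):
            block = (j + 1) * 1_000_000  # disjoint key block per stain
            for t in range(n_tiles):
                key = key_for(t, block)
                he = generate_he_tile(size=tile_size,
                                      seed=(seed + 7919 * (j + 1)) * 100_003 + t)
                he.position = key
                stain_tile, gt = generate_stain_tile(he, profile,
                                                     seed=seed * 9973 + 31 * (j + 1) + t)
                write_tile(stain_tile, out_dir / name / tile_filename(name, key))
                write_mask_png(gt, out_dir / "gt_masks" / name / tile_filename(name, key))
                n_written += 1

    manifest = {
        "setting": setting,
        "n_tiles": n_tiles,
        "tile_size": tile_size,
        "seed": seed,
        "n_files": n_written,
        "stains": list(profiles),
        "profiles": {name: asdict(p) for name, p in profiles.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
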