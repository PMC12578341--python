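"""Shared-H&E / per-stain encoder, generator and dual-head PatchGAN family.

One H&E triple (encoder ``E_HE``, generator ``G_HE``, discriminator
``D_HE``) is shared across all S stains; each stain *i* owns its triple
``(E_i, G_i, D_i)``.  The architecture follows the multi-domain
translation layout popularized by ComboGAN: the encoder holds the
downsampling convolutions plus the first half of the residual blocks,
the generator the remaining residual blocks plus the upsampling path.

The discriminator has two independent PatchGAN branches — one fed the
single-channel luminance of the input, one fed the RGB channels — whose
patch grids are fused downstream into confidence maps.

Images inside the networks live on a [-1, 1] scale; ``image_to_net`` /
``net_to_image`` convert at the module boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from . import nn

__all__ = [
    "NetworkConfig",
    "DualHeadOutput",
    "ComponentTriple",
    "ModelBundle",
    "Encoder",
    "Generator",
    "DualHeadDiscriminator",
    "encode",
    "generate",
    "discriminate",
    "count_trainable_components",
    "cyclegan_component_count",
    "luminance",
    "image_to_net",
    "net_to_image",
    "build_log",
    "reset_build_log",
    "load_for_inference",
]

#: BT.601 luminance weights; the paper family never defines "luminance",
#: this is the broadcast-video convention.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

# Registry of component constructions, so tests (and the modular-loading
# contract) can assert exactly which network parts were instantiated.
_BUILD_LOG: list[tuple[str, str]] = []


def reset_build_log() -> None:
    _BUILD_LOG.clear()


def build_log() -> list[tuple[str, str]]:
    return list(_BUILD_LOG)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters shared by every component of a bundle."""

    base_channels: int = 64
    n_downsamples: int = 2
    n_residual_blocks_encoder: int = 4
    n_residual_blocks_generator: int = 4
    disc_layers: int = 3
    stem_kernel: int = 7
    preset: str = "paper"

    def __post_init__(self):
        for f_ in ("base_channels", "n_downsamples", "n_residual_blocks_encoder",
                   "n_residual_blocks_generator", "disc_layers"):
            if getattr(self, f_) < 1:
                raise ValueError(f"{f_} must be >= 1")

    @classmethod
    def tiny(cls) -> "NetworkConfig":
        """Desk-scale preset: full forward/backward on CPU in well under 1 s."""
        return cls(base_channels=6, n_downsamples=2,
                   n_residual_blocks_encoder=1, n_residual_blocks_generator=1,
                   disc_layers=2, stem_kernel=3, preset="tiny")

    @classmethod
    def paper_scale(cls) -> "NetworkConfig":
        return cls()

    @classmethod
    def from_preset(cls, name: str) -> "NetworkConfig":
        if name == "tiny":
            return cls.tiny()
        if name == "paper":
            return cls.paper_scale()
        raise ValueError(f"unknown preset {name!r}")

    @property
    def latent_channels(self) -> int:
        return self.base_channels * 2**self.n_downsamples


@dataclass
class DualHeadOutput:
    """Patch grids from the luminance and RGB discriminator heads."""

    lum_map: Tensor
    rgb_map: Tensor

    def __post_init__(self):
        if self.lum_map.shape != self.rgb_map.shape:
            raise ValueError("head grids must share spatial extent")

    def stacked(self) -> Tensor:
        """Both heads as one (N, 2, h, w) tensor for loss evaluation."""
        return ag.concat([self.lum_map, self.rgb_map], axis=1)


class Encoder(nn.Module):
    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        c = config.base_channels
        k = config.stem_kernel
        layers: list[nn.Module] = [
            nn.Conv2d(3, c, k, padding=k // 2, rng=rng),
            nn.InstanceNorm2d(c),
            nn.ReLU(),
        ]
        for _ in range(config.n_downsamples):
            layers += [
                nn.Conv2d(c, 2 * c, 3, stride=2, padding=1, rng=rng),
                nn.InstanceNorm2d(2 * c),
                nn.ReLU(),
            ]
            c *= 2
        layers += [nn.ResidualBlock(c, rng=rng) for _ in range(config.n_residual_blocks_encoder)]
        self.net = nn.Sequential(*layers)
        self.config = config

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class Generator(nn.Module):
    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        c = config.latent_channels
        layers: list[nn.Module] = [
            nn.ResidualBlock(c, rng=rng) for _ in range(config.n_residual_blocks_generator)
        ]
        for _ in range(config.n_downsamples):
            layers += [
                _UpsampleConv(c, c // 2, rng=rng),
                nn.InstanceNorm2d(c // 2),
                nn.ReLU(),
            ]
            c //= 2
        k = config.stem_kernel
        layers += [nn.Conv2d(c, 3, k, padding=k // 2, rng=rng), nn.Tanh()]
        self.net = nn.Sequential(*layers)
        self.config = config

    def forward(self, z: Tensor) -> Tensor:
        return self.net(z)


class _UpsampleConv(nn.Module):
    """Nearest-neighbour x2 upsampling followed by a 3x3 convolution."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv = nn.Conv2d(cin, cout, 3, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(ag.upsample_nearest2d(x, 2))


class _PatchBranch(nn.Module):
    def __init__(self, in_channels: int, config: NetworkConfig, rng: np.random.Generator):
        c = config.base_channels
        layers: list[nn.Module] = [
            nn.Conv2d(in_channels, c, 4, stride=2, padding=1, rng=rng),
            nn.LeakyReLU(0.2),
        ]
        for _ in range(config.disc_layers - 1):
            layers += [
                nn.Conv2d(c, 2 * c, 4, stride=2, padding=1, rng=rng),
                nn.InstanceNorm2d(2 * c),
                nn.LeakyReLU(0.2),
            ]
            c *= 2
        layers += [nn.Conv2d(c, 1, 4, padding=1, rng=rng)]
        self.net = nn.Sequential(*layers)
        self.min_input = 2**config.disc_layers * 2  # kernel must fit after striding

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class DualHeadDiscriminator(nn.Module):
    """PatchGAN with independent luminance and RGB branches."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.lum_branch = _PatchBranch(1, config, rng=rng)
        self.rgb_branch = _PatchBranch(3, config, rng=rng)
        self.config = config

    def forward(self, x: Tensor) -> DualHeadOutput:
        h, w = x.shape[2], x.shape[3]
        m = self.lum_branch.min_input
        if h < m or w < m:
            raise ValueError(
                f"discriminator input {h}x{w} below the receptive-field minimum {m}"
            )
        return DualHeadOutput(self.lum_branch(luminance(x)), self.rgb_branch(x))


def luminance(x: Tensor) -> Tensor:
    """BT.601 luminance of an (N, 3, H, W) tensor as an (N, 1, H, W) tensor."""
    w = np.asarray(LUMA_WEIGHTS, dtype=np.float32).reshape(1, 3, 1, 1)
    return ag.conv2d(x, Tensor(w))


# ----------------------------------------------------------------------
# bundle
# ----------------------------------------------------------------------

@dataclass
class ComponentTriple:
    encoder: Encoder
    generator: Generator
    discriminator: DualHeadDiscriminator


class ModelBundle:
    """One shared H&E triple plus S per-stain triples, all on one config."""

    def __init__(self, config: NetworkConfig, he: ComponentTriple,
                 stains: dict[str, ComponentTriple]):
        if not stains:
            raise ValueError("a bundle needs at least one stain")
        self.config = config
        self.he = he
        self.stains = dict(stains)

    @property
    def n_stains(self) -> int:
        return len(self.stains)

    @property
    def stain_names(self) -> list[str]:
        return list(self.stains)

    @classmethod
    def build(cls, stain_names, config: NetworkConfig, seed: int = 0) -> "ModelBundle":
        rng = np.random.default_rng(seed)
        he = ComponentTriple(
            _build("enc", "HE", config, rng),
            _build("gen", "HE", config, rng),
            _build("disc", "HE", config, rng),
        )
        stains = {
            name: ComponentTriple(
                _build("enc", name, config, rng),
                _build("gen", name, config, rng),
                _build("disc", name, config, rng),
            )
            for name in stain_names
        }
        return cls(config, he, stains)

    def triples(self) -> dict[str, ComponentTriple]:
        return {"HE": self.he, **self.stains}

    # checkpoints ------------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, triple in self.triples().items():
            for kind, module in (("enc", triple.encoder), ("gen", triple.generator),
                                 ("disc", triple.discriminator)):
                save_component(module, directory / f"{name}_{kind}.ckpt")
        manifest = {"stains": self.stain_names, "config": asdict(self.config)}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        config = NetworkConfig(**manifest["config"])
        rng = np.random.default_rng(0)
        names = ["HE"] + list(manifest["stains"])
        triples = {}
        for name in names:
            triple = ComponentTriple(
                _build("enc", name, config, rng),
                _build("gen", name, config, rng),
                _build("disc", name, config, rng),
            )
            load_component(triple.encoder, directory / f"{name}_enc.ckpt")
            load_component(triple.generator, directory / f"{name}_gen.ckpt")
            load_component(triple.discriminator, directory / f"{name}_disc.ckpt")
            triples[name] = triple
        he = triples.pop("HE")
        return cls(config, he, triples)


def _build(kind: str, name: str, config: NetworkConfig, rng: np.random.Generator):
    _BUILD_LOG.append((kind, name))
    if kind == "enc":
        return Encoder(config, rng)
    if kind == "gen":
        return Generator(config, rng)
    if kind == "disc":
        return DualHeadDiscriminator(config, rng)
    raise ValueError(kind)


def save_component(module: nn.Module, path) -> None:
    with open(path, "wb") as fh:
        np.savez(fh, **module.state_dict())


def load_component(module: nn.Module, path) -> None:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing checkpoint: {path}")
    with np.load(path) as data:
        module.load_state_dict(dict(data))


def load_for_inference(directory, stain_names, with_discriminators: bool = False,
                       config: NetworkConfig | None = None) -> dict:
    """Load only the components a virtual-staining request needs.

    Per the modular-loading contract this constructs exactly one H&E
    encoder plus, per requested stain, one generator (and optionally one
    discriminator when confidence maps are requested) — nothing else.
    """
    directory = Path(directory)
    if config is None:
        manifest = json.loads((directory / "manifest.json").read_text())
        config = NetworkConfig(**manifest["config"])
    rng = np.random.default_rng(0)
    he_encoder = _build("enc", "HE", config, rng)
    load_component(he_encoder, directory / "HE_enc.ckpt")
    generators: dict[str, Generator] = {}
    discriminators: dict[str, DualHeadDiscriminator] = {}
    for name in stain_names:
        gen = _build("gen", name, config, rng)
        load_component(gen, directory / f"{name}_gen.ckpt")
        generators[name] = gen
        if with_discriminators:
            disc = _build("disc", name, config, rng)
            load_component(disc, directory / f"{name}_disc.ckpt")
            discriminators[name] = disc
    out = {"config": config, "he_encoder": he_encoder, "generators": generators}
    if with_discriminators:
        out["discriminators"] = discriminators
    return out


# ----------------------------------------------------------------------
# functional surface
# ----------------------------------------------------------------------

def encode(encoder: Encoder, tile: Tensor) -> Tensor:
    """Run an encoder on an (N, 3, H, W) tensor on the [-1, 1] scale."""
    h, w = tile.shape[2], tile.shape[3]
    d = 2**encoder.config.n_downsamples
    if h % d or w % d:
        raise ValueError(
            f"tile dims {h}x{w} must be divisible by {d}; "
            f"pad to {-(-h // d) * d}x{-(-w // d) * d}"
        )
    return encoder(tile)


def generate(generator: Generator, latent: Tensor) -> Tensor:
    if latent.shape[1] != generator.config.latent_channels:
        raise ValueError(
            f"latent has {latent.shape[1]} channels, "
            f"config requires {generator.config.latent_channels}"
        )
    return generator(latent)


def discriminate(discriminator: DualHeadDiscriminator, tile: Tensor) -> DualHeadOutput:
    return discriminator(tile)


def count_trainable_components(bundle: ModelBundle) -> tuple[int, int, int]:
    """Component triples of the unified model: (S+1, S+1, S+1)."""
    n = bundle.n_stains + 1
    return (n, n, n)


def cyclegan_component_count(n_stains: int) -> tuple[int, int, int]:
    """Component count of the pairwise CycleGAN baseline: one model per
    stain, each with two encoders, two generators and two discriminators."""
    return (2 * n_stains, 2 * n_stains, 2 * n_stains)


# ----------------------------------------------------------------------
# scale conversion
# ----------------------------------------------------------------------

def image_to_net(pixels: np.ndarray, dtype=np.float32) -> Tensor:
    """(H, W, 3) uint8 image -> (1, 3, H, W) tensor on the [-1, 1] scale."""
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) image")
    x = arr.astype(dtype) / 127.5 - 1.0
    return Tensor(x.transpose(2, 0, 1)[None])


def net_to_image(x) -> np.ndarray:
    """(1, 3, H, W) tensor on [-1, 1] -> (H, W, 3) uint8 image."""
    arr = x.data if isinstance(x, Tensor) else np.asarray(x)
    arr = (np.clip(arr[0].transpose(1, 2, 0), -1.0, 1.0) + 1.0) * 127.5
    return np.floor(arr + 0.5).clip(0, 255).astype(np.uint8)
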