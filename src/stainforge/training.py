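"""Dual-cycle optimization with the per-iteration stain sweep.

One training iteration visits every stain in a fresh random permutation.
For stain *i* it runs both cycles —

    H&E cycle:   X_HE -> E_HE -> G_i  -> Y^_i  -> E_i  -> G_HE -> X^_HE
    stain cycle: X_i  -> E_i  -> G_HE -> Y^_HE -> E_HE -> G_i  -> X^_i

— updates the stain components and the shared H&E components on the
synthesis loss, then updates the two discriminators.  After the sweep,
the mean of the per-stain synthesis losses is recomputed and
backpropagated once more, stepping *only* the shared H&E encoder and
generator: this is the balancing step that keeps the shared
representation from drifting toward whichever stain is easiest.

The schedule holds the learning rate at ``lr0`` for ``n_fixed_epochs``,
then decays it linearly to zero over ``n_decay_epochs``.  Augmentation
is limited to flips and quarter-turn rotations; in the paired setting
the H&E tile and its stain partner receive the identical transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autograd import Tensor
from . import losses as L
from .core_io import TileImage, parse_tile_filename, read_tile
from .masks import ActivationMask, compute_weights, extract_activation_mask, HSVRange
from .networks import (
    ComponentTriple,
    ModelBundle,
    NetworkConfig,
    image_to_net,
)
from . import nn

__all__ = [
    "TrainConfig",
    "IterationRecord",
    "TileDataset",
    "Trainer",
    "lr_at",
    "augment",
    "draw_stain_order",
    "held_out_cycle_error",
    "fit",
]


@dataclass
class TrainConfig:
    """Run configuration; defaults follow the published schedule where
    one exists (Adam betas, lr0, lambda_cyc) at desk-scale sizes."""

    n_fixed_epochs: int = 500
    n_decay_epochs: int = 500
    lr0: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    batch_size: int = 1
    setting: str = "unpaired"
    augment_flip: bool = True
    augment_rotate: bool = True
    seed: int = 0
    loss_weights: L.LossWeights = field(default_factory=L.LossWeights)
    distance_kind: str = "L1"
    iterations_per_epoch: int | None = None
    max_iterations: int | None = None
    use_regularizers: bool | None = None  # None: on iff unpaired
    checkpoint_every: int | None = None

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.setting not in ("paired", "unpaired"):
            raise ValueError("setting must be 'paired' or 'unpaired'")

    @property
    def regularizers_enabled(self) -> bool:
        if self.use_regularizers is None:
            return self.setting == "unpaired"
        return self.use_regularizers


@dataclass
class IterationRecord:
    epoch: int
    iteration: int
    stain_order: list[str]
    loss_ihc: dict[str, float]
    loss_he: float
    disc_losses: dict[str, float]
    lr: float
    loss_terms: list[str]
    n_generator_updates: int
    n_he_reg_updates: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Plateau then linear decay; the final decay epoch runs at
    lr0/n_decay and the (virtual) next epoch would be exactly 0."""
    n_total = config.n_fixed_epochs + config.n_decay_epochs
    if not (0 <= epoch < n_total):
        raise ValueError(f"epoch {epoch} outside [0, {n_total})")
    if epoch < config.n_fixed_epochs:
        return config.lr0
    return config.lr0 * (1.0 - (epoch - config.n_fixed_epochs) / config.n_decay_epochs)


def draw_stain_order(rng: np.random.Generator, stain_names) -> list[str]:
    names = list(stain_names)
    rng.shuffle(names)
    return names


def augment(tile_group, flip: bool = True, rotate: bool = True,
            rng: np.random.Generator | None = None) -> list[TileImage]:
    """Apply one shared flip/rotation draw to a group of tiles.

    The same transform hits every tile in the group, preserving
    per-pixel correspondence for paired batches.
    """
    rng = rng or np.random.default_rng()
    flip_mode = rng.integers(0, 3) if flip else 0  # 0 none, 1 horizontal, 2 vertical
    k = int(rng.integers(0, 4)) if rotate else 0
    out = []
    for tile in tile_group:
        px = tile.pixels
        if flip_mode == 1:
            px = px[:, ::-1]
        elif flip_mode == 2:
            px = px[::-1]
        if k:
            px = np.rot90(px, k)
        out.append(TileImage(pixels=np.ascontiguousarray(px), position=tile.position,
                             magnification=tile.magnification, stain_label=tile.stain_label))
    return out


# ----------------------------------------------------------------------
# dataset
# ----------------------------------------------------------------------

class TileDataset:
    """Directory-per-stain tile store with grid-key pairing.

    Layout: ``root/HE/HE_{x}_{y}.png`` plus ``root/{stain}/...``; in the
    paired setting every stain directory shares the H&E key set.
    """

    def __init__(self, root, hsv_ranges: dict[str, HSVRange] | None = None):
        self.root = Path(root)
        manifest_path = self.root / "manifest.json"
        self.manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
        self.stains = self.manifest.get("stains") or sorted(
            d.name for d in self.root.iterdir()
            if d.is_dir() and d.name not in ("HE", "gt_masks")
        )
        self.he_keys = self._keys("HE")
        self.stain_keys = {s: self._keys(s) for s in self.stains}
        if hsv_ranges is None and "profiles" in self.manifest:
            from .synthetic import StainProfile

            hsv_ranges = {
                name: StainProfile(**spec).hsv_range
                for name, spec in self.manifest["profiles"].items()
            }
        self.hsv_ranges = hsv_ranges or {}

    def _keys(self, stain: str) -> list[tuple[int, int]]:
        keys = []
        for path in sorted((self.root / stain).glob("*.png")):
            _, key = parse_tile_filename(path.name)
            keys.append(key)
        if not keys:
            raise FileNotFoundError(f"no tiles found under {self.root / stain}")
        return keys

    @property
    def smallest_stain_count(self) -> int:
        return min(len(k) for k in self.stain_keys.values())

    def load(self, stain: str, key: tuple[int, int]) -> TileImage:
        from .core_io import tile_filename

        return read_tile(self.root / stain / tile_filename(stain, key))

    def sample_pair(self, stain: str, rng: np.random.Generator,
                    paired: bool) -> tuple[TileImage, TileImage]:
        if paired:
            key = self.he_keys[rng.integers(0, len(self.he_keys))]
            if key not in self.stain_keys[stain]:
                raise KeyError(
                    f"paired dataset missing {stain} tile for grid key {key}"
                )
            return self.load("HE", key), self.load(stain, key)
        he_key = self.he_keys[rng.integers(0, len(self.he_keys))]
        st_keys = self.stain_keys[stain]
        st_key = st_keys[rng.integers(0, len(st_keys))]
        return self.load("HE", he_key), self.load(stain, st_key)


# ----------------------------------------------------------------------
# trainer
# ----------------------------------------------------------------------

class Trainer:
    def __init__(self, bundle: ModelBundle, config: TrainConfig,
                 hsv_ranges: dict[str, HSVRange]):
        missing = set(bundle.stain_names) - set(hsv_ranges)
        if missing:
            raise KeyError(f"no HSV range configured for stains: {sorted(missing)}")
        self.bundle = bundle
        self.config = config
        self.hsv_ranges = hsv_ranges
        self.rng = np.random.default_rng(config.seed)
        self.epoch = 0
        self.iteration = 0
        self.optimizers = {
            f"{name}_{kind}": nn.Adam(
                module.parameters(), lr=config.lr0,
                beta1=config.adam_beta1, beta2=config.adam_beta2,
            )
            for name, triple in bundle.triples().items()
            for kind, module in (("enc", triple.encoder), ("gen", triple.generator),
                                 ("disc", triple.discriminator))
        }

    # -- plumbing ------------------------------------------------------
    def _set_lr(self, lr: float) -> None:
        for opt in self.optimizers.values():
            opt.lr = lr

    def _zero_all(self) -> None:
        for name, triple in self.bundle.triples().items():
            triple.encoder.zero_grad()
            triple.generator.zero_grad()
            triple.discriminator.zero_grad()

    def _step(self, names) -> None:
        for n in names:
            self.optimizers[n].step()

    # -- forward / losses ---------------------------------------------
    def _forward_cycles(self, stain: str, x_he: Tensor, x_i: Tensor) -> L.CycleBatch:
        he, st = self.bundle.he, self.bundle.stains[stain]
        z_he = he.encoder(x_he)
        y_hat_i = st.generator(z_he)
        z_hat_he = st.encoder(y_hat_i)
        x_hat_he = he.generator(z_hat_he)
        z_i = st.encoder(x_i)
        y_hat_he = he.generator(z_i)
        z_hat_i = he.encoder(y_hat_he)
        x_hat_i = st.generator(z_hat_i)
        return L.CycleBatch(
            x_he=x_he, x_i=x_i, mask=None, weights=None,
            y_hat_i=y_hat_i, y_hat_he=y_hat_he,
            x_hat_i=x_hat_i, x_hat_he=x_hat_he,
            z_he=z_he, z_hat_he=z_hat_he, z_i=z_i, z_hat_i=z_hat_i,
        )

    def _prepare_items(self, stain: str, pairs) -> list[dict]:
        """Per-sample tensors and masks, computed once per iteration."""
        items = []
        for he_tile, stain_tile in pairs:
            mask = extract_activation_mask(stain_tile, self.hsv_ranges[stain])
            items.append({
                "mask": mask,
                "weights": compute_weights(mask),
                "x_he": image_to_net(he_tile.pixels),
                "x_i": image_to_net(stain_tile.pixels),
            })
        return items

    def _synthesis_loss(self, stain: str, items) -> tuple[Tensor, list[str]]:
        """Mean synthesis loss over the batch samples of one stain.

        Caches detached fakes on each item for the discriminator step.
        """
        cfg = self.config
        w = cfg.loss_weights
        kind = cfg.distance_kind
        he, st = self.bundle.he, self.bundle.stains[stain]
        paired = cfg.setting == "paired"
        terms_used: list[str] = []
        total = None
        for item in items:
            mask, weights = item["mask"], item["weights"]
            x_he, x_i = item["x_he"], item["x_i"]
            batch = self._forward_cycles(stain, x_he, x_i)
            batch.mask, batch.weights = mask, weights
            item["y_hat_i"] = batch.y_hat_i.detach()
            item["y_hat_he"] = batch.y_hat_he.detach()
            d_i_fake = st.discriminator(batch.y_hat_i)
            d_he_fake = he.discriminator(batch.y_hat_he)
            if paired:
                cyc = L.cycle_loss_paired(batch, kind)
                adv = L.adversarial_loss_paired(d_i_fake, d_he_fake, mask, weights)
                sup = L.supervised_loss(batch, kind)
                terms = ["cyc_paired", "adv_paired", "sup"]
            else:
                cyc = L.cycle_loss_unpaired(batch, kind)
                adv = L.adversarial_loss_unpaired(d_i_fake, d_he_fake, mask, weights)
                sup = None
                terms = ["cyc_unpaired", "adv_unpaired"]
            if cfg.regularizers_enabled:
                idt = (
                    L.identity_loss(x_i, lambda t: batch.z_i, st.generator,
                                    mask, weights, kind)
                    + L.identity_loss(x_he, lambda t: batch.z_he, he.generator,
                                      kind=kind)
                )
                lat = (
                    L.latent_loss(batch.z_i, batch.z_hat_i, mask, weights, kind)
                    + L.latent_loss(batch.z_he, batch.z_hat_he, kind=kind)
                )
                fwd = (
                    L.forward_loss(L.degrade(batch.y_hat_he), L.degrade(x_i),
                                   _degraded_mask(mask), weights, kind)
                    + L.forward_loss(L.degrade(batch.y_hat_i), L.degrade(x_he),
                                     kind=kind)
                )
                reg = L.regularization_loss(idt, lat, fwd, w)
                terms = terms + ["reg"]
            else:
                reg = Tensor(np.float32(0.0))
            loss = L.synthesis_loss(cyc, adv, reg, w, sup=sup)
            total = loss if total is None else total + loss
        terms_used = terms
        return total * (1.0 / len(items)), terms_used

    def _discriminator_losses(self, stain: str, items) -> dict[str, float]:
        """Update D_i and D_HE on real tiles vs the cached detached fakes."""
        w = self.config.loss_weights
        he, st = self.bundle.he, self.bundle.stains[stain]
        d_i_total = None
        d_he_total = None
        for item in items:
            d_i = L.discriminator_loss_stain(
                st.discriminator(item["x_i"]), st.discriminator(item["y_hat_i"]),
                item["mask"], item["weights"], lambda_d=w.lambda_D,
            )
            d_he = L.discriminator_loss_he(
                he.discriminator(item["x_he"]), he.discriminator(item["y_hat_he"]),
                lambda_d=w.lambda_D,
            )
            d_i_total = d_i if d_i_total is None else d_i_total + d_i
            d_he_total = d_he if d_he_total is None else d_he_total + d_he
        n = len(items)
        self._zero_all()
        (d_i_total * (1.0 / n)).backward()
        self._step([f"{stain}_disc"])
        self._zero_all()
        (d_he_total * (1.0 / n)).backward()
        self._step(["HE_disc"])
        return {stain: d_i_total.item() / n, "HE": d_he_total.item() / n}

    # -- public steps --------------------------------------------------
    def train_iteration(self, batch_per_stain: dict) -> IterationRecord:
        """One full sweep over all stains plus the shared-H&E balancing step.

        ``batch_per_stain`` maps stain name to a list of
        ``(he_tile, stain_tile)`` pairs (grid keys must match in the
        paired setting).
        """
        cfg = self.config
        paired = cfg.setting == "paired"
        for stain, pairs in batch_per_stain.items():
            for he_tile, stain_tile in pairs:
                if paired and he_tile.position != stain_tile.position:
                    raise ValueError(
                        f"paired batch for {stain} has mismatched grid keys "
                        f"{he_tile.position} vs {stain_tile.position}"
                    )
        order = draw_stain_order(self.rng, self.bundle.stain_names)
        loss_ihc: dict[str, float] = {}
        disc_losses: dict[str, float] = {}
        n_gen_updates = 0
        terms_used: list[str] = []
        he_params = (self.bundle.he.encoder.parameters()
                     + self.bundle.he.generator.parameters())
        he_grad_acc = [np.zeros_like(p.data) for p in he_params]
        s = len(order)
        for stain in order:
            items = self._prepare_items(stain, batch_per_stain[stain])
            self._zero_all()
            loss, terms_used = self._synthesis_loss(stain, items)
            loss.backward()
            # retain this stain's gradient on the shared components: the
            # balancing step below applies their mean to E_HE / G_HE only
            for acc, p in zip(he_grad_acc, he_params):
                if p.grad is not None:
                    acc += p.grad / s
            self._step([f"{stain}_enc", f"{stain}_gen", "HE_enc", "HE_gen"])
            n_gen_updates += 1
            loss_ihc[stain] = loss.item()
            d = self._discriminator_losses(stain, items)
            disc_losses[stain] = d[stain]
            disc_losses["HE"] = disc_losses.get("HE", 0.0) + d["HE"] / s
        # shared-H&E balancing step (mean of the retained per-stain
        # synthesis losses, backpropagated through E_HE / G_HE only)
        self._zero_all()
        for p, acc in zip(he_params, he_grad_acc):
            p.grad = acc
        loss_he = float(np.mean(list(loss_ihc.values())))
        self._step(["HE_enc", "HE_gen"])
        record = IterationRecord(
            epoch=self.epoch,
            iteration=self.iteration,
            stain_order=order,
            loss_ihc=loss_ihc,
            loss_he=loss_he,
            disc_losses=disc_losses,
            lr=self.optimizers["HE_enc"].lr,
            loss_terms=terms_used,
            n_generator_updates=n_gen_updates,
            n_he_reg_updates=1,
        )
        self.iteration += 1
        return record

    def fit(self, dataset: TileDataset, out_dir=None, log_path=None) -> list[IterationRecord]:
        """Run the configured schedule over a tile dataset.

        Checkpoints (when ``out_dir`` is given) are written at the
        configured cadence and at the end; records go to a JSONL log.
        """
        cfg = self.config
        paired = cfg.setting == "paired"
        iters_per_epoch = cfg.iterations_per_epoch or max(
            1, dataset.smallest_stain_count // cfg.batch_size
        )
        n_epochs = cfg.n_fixed_epochs + cfg.n_decay_epochs
        out_dir = Path(out_dir) if out_dir is not None else None
        log_fh = open(log_path, "a") if log_path is not None else None
        records: list[IterationRecord] = []
        total_iters = 0
        try:
            for epoch in range(self.epoch, n_epochs):
                self.epoch = epoch
                self._set_lr(lr_at(epoch, cfg))
                for _ in range(iters_per_epoch):
                    batch = {}
                    for stain in self.bundle.stain_names:
                        pairs = [dataset.sample_pair(stain, self.rng, paired)
                                 for _ in range(cfg.batch_size)]
                        pairs = [tuple(augment(p, cfg.augment_flip, cfg.augment_rotate,
                                               self.rng)) for p in pairs]
                        batch[stain] = pairs
                    record = self.train_iteration(batch)
                    if not np.isfinite(record.loss_he) or not all(
                        np.isfinite(v) for v in record.loss_ihc.values()
                    ):
                        raise RuntimeError(
                            f"non-finite loss at epoch {epoch}, iteration "
                            f"{record.iteration}: {record.loss_ihc}, {record.loss_he}"
                        )
                    records.append(record)
                    if log_fh is not None:
                        log_fh.write(record.to_json() + "\n")
                    total_iters += 1
                    if (out_dir is not None and cfg.checkpoint_every
                            and total_iters % cfg.checkpoint_every == 0):
                        self.save(out_dir)
                    if cfg.max_iterations and total_iters >= cfg.max_iterations:
                        raise StopIteration
        except StopIteration:
            pass
        finally:
            if log_fh is not None:
                log_fh.close()
        if out_dir is not None:
            self.save(out_dir)
        return records

    # -- state ---------------------------------------------------------
    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        self.bundle.save(out_dir)
        state = {
            "epoch": self.epoch,
            "iteration": self.iteration,
            "rng_state": self.rng.bit_generator.state,
            "optimizers": {k: _opt_state_jsonable(v) for k, v in self.optimizers.items()},
        }
        (out_dir / "trainer_state.json").write_text(json.dumps(state))

    def load(self, out_dir) -> None:
        out_dir = Path(out_dir)
        self.bundle = ModelBundle.load(out_dir)
        self.optimizers = {
            f"{name}_{kind}": nn.Adam(
                module.parameters(), lr=self.config.lr0,
                beta1=self.config.adam_beta1, beta2=self.config.adam_beta2,
            )
            for name, triple in self.bundle.triples().items()
            for kind, module in (("enc", triple.encoder), ("gen", triple.generator),
                                 ("disc", triple.discriminator))
        }
        state = json.loads((out_dir / "trainer_state.json").read_text())
        self.epoch = state["epoch"]
        self.iteration = state["iteration"]
        self.rng.bit_generator.state = state["rng_state"]
        for key, opt_state in state["optimizers"].items():
            self.optimizers[key].load_state_dict({
                "t": opt_state["t"],
                "m": [np.asarray(m, dtype=np.float32) for m in opt_state["m"]],
                "v": [np.asarray(v, dtype=np.float32) for v in opt_state["v"]],
            })


def _opt_state_jsonable(opt: nn.Adam) -> dict:
    return {
        "t": opt.t,
        "m": [m.tolist() for m in opt.m],
        "v": [v.tolist() for v in opt.v],
    }


def _degraded_mask(mask: ActivationMask) -> ActivationMask:
    from .masks import degrade_mask

    return degrade_mask(mask)


def held_out_cycle_error(bundle: ModelBundle, stain: str, pairs,
                         hsv_range: HSVRange, kind: str = "L1") -> float:
    """Masked cycle-reconstruction error of held-out (H&E, stain) pairs.

    For each pair the stain cycle is run (stain -> H&E -> stain) and the
    unpaired cycle loss's stain terms are evaluated:
    L(X^_i, X_i) + alpha*L(M (.) X^_i, ...) + beta*(...).
    """
    he, st = bundle.he, bundle.stains[stain]
    errs = []
    for he_tile, stain_tile in pairs:
        mask = extract_activation_mask(stain_tile, hsv_range)
        weights = compute_weights(mask)
        x_i = image_to_net(stain_tile.pixels)
        z_i = st.encoder(x_i)
        y_hat_he = he.generator(z_i)
        z_hat_i = he.encoder(y_hat_he)
        x_hat_i = st.generator(z_hat_i)
        err = (
            L.base_distance(x_hat_i, x_i, kind)
            + L.masked_triple(x_hat_i, x_i, mask, weights, kind)
        )
        errs.append(err.item())
    return float(np.mean(errs))


def fit(bundle: ModelBundle, dataset: TileDataset, config: TrainConfig,
        hsv_ranges: dict[str, HSVRange], out_dir=None, log_path=None):
    """Convenience wrapper: build a Trainer and run its schedule."""
    trainer = Trainer(bundle, config, hsv_ranges)
    records = trainer.fit(dataset, out_dir=out_dir, log_path=log_path)
    return trainer, records
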