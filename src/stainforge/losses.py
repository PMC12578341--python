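"""Mask-weighted loss functions for multi-stain virtual staining.

The synthesis objective for stain *i* is

    L_IHC,i = lambda_cyc * L_cyc,i + lambda_adv * L_adv,i + lambda_reg * L_reg,i

with, in the paired setting, an additional supervised term.  Every
reconstruction-style term carries the recurring mask-weighted pair

    alpha * L(M (.) a, M (.) b) + beta * L(M-bar (.) a, M-bar (.) b)

where M is the IHC activation mask of the real stain tile, (.) is the
elementwise product, and (alpha, beta) are the dynamic weights from the
activation pixel counts.  Masked means are taken over *all* pixels
(multiply by the mask, then global mean): alpha/beta already perform the
rebalancing and this keeps every masked term bounded by its unmasked
counterpart.

Base distances: L1 for image/latent reconstruction terms; least squares
against constant target maps of ones/zeros for adversarial and
discriminator terms (the conventions of the CycleGAN family).  Both are
switchable via ``kind``.

All functions accept autodiff tensors, so the same code path serves
training (gradients) and the brute-force oracle tests (float64 scalars).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor, as_tensor
from .masks import ActivationMask, MaskWeights, resample_mask
from .networks import DualHeadOutput

__all__ = [
    "LossWeights",
    "CycleBatch",
    "DegradedBatch",
    "base_distance",
    "masked_triple",
    "cycle_loss_unpaired",
    "cycle_loss_paired",
    "adversarial_loss_unpaired",
    "adversarial_loss_paired",
    "supervised_loss",
    "discriminator_loss_stain",
    "discriminator_loss_he",
    "identity_loss",
    "latent_loss",
    "forward_loss",
    "degrade",
    "regularization_loss",
    "synthesis_loss",
    "he_regularization_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Coefficients of the full objective.

    ``lambda_cyc=10`` and ``lambda_adv=1`` follow the published training
    configuration; ``lambda_D=0.5`` halves the discriminator loss (the
    convention of this architecture family).  The regularizer defaults
    enable the identity and forward terms and disable the latent term,
    the combination the ablation study found strongest; the supervised
    term enters with weight 1 in the paired setting.
    """

    lambda_cyc: float = 10.0
    lambda_adv: float = 1.0
    lambda_reg: float = 1.0
    lambda_D: float = 0.5
    lambda_idt: float = 1.0
    lambda_lat: float = 0.0
    lambda_fwd: float = 1.0
    lambda_sup: float = 1.0

    def __post_init__(self):
        for name, value in vars(self).items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CycleBatch:
    """Everything both training cycles of one stain produce.

    H&E cycle:   x_he -> y_hat_i -> x_hat_he  (latents z_he, z_hat_he)
    stain cycle: x_i  -> y_hat_he -> x_hat_i  (latents z_i, z_hat_i)

    ``mask``/``weights`` are derived from the real stain tile ``x_i``.
    """

    x_he: Tensor
    x_i: Tensor
    mask: ActivationMask
    weights: MaskWeights
    y_hat_i: Tensor | None = None
    y_hat_he: Tensor | None = None
    x_hat_i: Tensor | None = None
    x_hat_he: Tensor | None = None
    z_he: Tensor | None = None
    z_hat_he: Tensor | None = None
    z_i: Tensor | None = None
    z_hat_i: Tensor | None = None


@dataclass
class DegradedBatch:
    """3x3/stride-2 average-pooled tensors plus the matching degraded mask."""

    x_lo: Tensor
    y_hat_lo: Tensor
    m_lo: ActivationMask | None = None


# ----------------------------------------------------------------------
# base pieces
# ----------------------------------------------------------------------

def base_distance(a, b, kind: str = "L1") -> Tensor:
    """Mean absolute (L1) or mean squared (MSE) elementwise difference."""
    a, b = as_tensor(a), as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    diff = a - b
    if kind == "L1":
        return ag.mean_(ag.abs_(diff))
    if kind == "MSE":
        return ag.mean_(diff * diff)
    raise ValueError(f"unknown distance kind {kind!r}")


def _target_distance(d, target: float) -> Tensor:
    """Least-squares distance of a map to a constant target (1 real, 0 fake)."""
    d = _as_map(d)
    diff = d - target
    return ag.mean_(diff * diff)


def _masked_target_distance(d, mask_arr: np.ndarray, target: float) -> Tensor:
    d = _as_map(d)
    masked = d * mask_arr
    diff = masked - target
    return ag.mean_(diff * diff)


def _as_map(d) -> Tensor:
    if isinstance(d, DualHeadOutput):
        return d.stacked()
    return as_tensor(d)


def _mask_planes(mask: ActivationMask, like: Tensor) -> tuple[np.ndarray, np.ndarray]:
    """Mask and complement as broadcastable (1, 1, h, w) float arrays,
    resampled to the spatial grid of ``like`` when needed."""
    h, w = like.shape[-2], like.shape[-1]
    m = mask if mask.mask.shape == (h, w) else resample_mask(mask, (h, w))
    arr = m.as_float()[None, None]
    return arr, 1.0 - arr


def _check_weights(weights) -> MaskWeights:
    if isinstance(weights, MaskWeights):
        return weights
    alpha, beta = weights
    if abs(alpha + beta - 1.0) > 1e-6:
        raise ValueError("mask weights must sum to 1 within 1e-6")
    return MaskWeights(alpha=alpha, beta=beta)


def masked_triple(a, b, mask: ActivationMask, weights, kind: str = "L1") -> Tensor:
    """alpha * L(M (.) a, M (.) b) + beta * L(M-bar (.) a, M-bar (.) b)."""
    w = _check_weights(weights)
    a, b = as_tensor(a), as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    m, mbar = _mask_planes(mask, a)
    act = base_distance(a * m, b * m, kind)
    bg = base_distance(a * mbar, b * mbar, kind)
    return w.alpha * act + w.beta * bg


def _masked_pair_group(pairs, mask: ActivationMask, weights, kind: str) -> Tensor:
    """alpha * [sum of masked terms] + beta * [sum of complement terms],
    the grouped form the paired-setting losses print."""
    w = _check_weights(weights)
    m, mbar = _mask_planes(mask, as_tensor(pairs[0][0]))
    act = None
    bg = None
    for a, b in pairs:
        a, b = as_tensor(a), as_tensor(b)
        ta = base_distance(a * m, b * m, kind)
        tb = base_distance(a * mbar, b * mbar, kind)
        act = ta if act is None else act + ta
        bg = tb if bg is None else bg + tb
    return w.alpha * act + w.beta * bg


# ----------------------------------------------------------------------
# cycle losses
# ----------------------------------------------------------------------

def cycle_loss_unpaired(batch: CycleBatch, kind: str = "L1") -> Tensor:
    """Unpaired cycle loss: both plain reconstruction terms plus the
    mask-weighted pair on the stain reconstruction only."""
    return (
        base_distance(batch.x_hat_i, batch.x_i, kind)
        + base_distance(batch.x_hat_he, batch.x_he, kind)
        + masked_triple(batch.x_hat_i, batch.x_i, batch.mask, batch.weights, kind)
    )


def cycle_loss_paired(batch: CycleBatch, kind: str = "L1") -> Tensor:
    """Paired cycle loss: the shared mask additionally weights the H&E
    reconstruction, grouped as alpha*[stain + H&E] + beta*[stain + H&E]."""
    return (
        base_distance(batch.x_hat_i, batch.x_i, kind)
        + base_distance(batch.x_hat_he, batch.x_he, kind)
        + _masked_pair_group(
            [(batch.x_hat_i, batch.x_i), (batch.x_hat_he, batch.x_he)],
            batch.mask, batch.weights, kind,
        )
    )


# ----------------------------------------------------------------------
# adversarial losses (least squares against constant target maps)
# ----------------------------------------------------------------------

def adversarial_loss_unpaired(d_i_fake, d_he_fake, mask: ActivationMask, weights) -> Tensor:
    """L(D_i(Y^_i), 1) + alpha*L(M (.) D_HE(Y^_HE), 1) + beta*L(M-bar (.) D_HE(Y^_HE), 1).

    The first term carries no mask, exactly as the objective is printed.
    The mask is resampled to the discriminator patch grid.
    """
    w = _check_weights(weights)
    d_he = _as_map(d_he_fake)
    m, mbar = _mask_planes(mask, d_he)
    return (
        _target_distance(d_i_fake, 1.0)
        + w.alpha * _masked_target_distance(d_he, m, 1.0)
        + w.beta * _masked_target_distance(d_he, mbar, 1.0)
    )


def adversarial_loss_paired(d_i_fake, d_he_fake, mask: ActivationMask, weights) -> Tensor:
    """Paired adversarial loss: the plain term moves to D_HE and the
    masked pair applies to both discriminator responses."""
    w = _check_weights(weights)
    d_he = _as_map(d_he_fake)
    d_i = _as_map(d_i_fake)
    m, mbar = _mask_planes(mask, d_he)
    return (
        _target_distance(d_he, 1.0)
        + w.alpha * (_masked_target_distance(d_he, m, 1.0) + _masked_target_distance(d_i, m, 1.0))
        + w.beta * (_masked_target_distance(d_he, mbar, 1.0) + _masked_target_distance(d_i, mbar, 1.0))
    )


def supervised_loss(batch: CycleBatch, kind: str = "L1") -> Tensor:
    """Direct supervision (paired setting): the first-hop generations are
    compared with the real counterparts at the same grid position."""
    return (
        base_distance(batch.y_hat_i, batch.x_i, kind)
        + base_distance(batch.y_hat_he, batch.x_he, kind)
        + _masked_pair_group(
            [(batch.y_hat_i, batch.x_i), (batch.y_hat_he, batch.x_he)],
            batch.mask, batch.weights, kind,
        )
    )


# ----------------------------------------------------------------------
# discriminator losses
# ----------------------------------------------------------------------

def discriminator_loss_stain(d_real, d_fake, mask: ActivationMask, weights,
                             lambda_d: float = 0.5) -> Tensor:
    """lambda_D * (L_real,i + L_synthetic,i) for the stain discriminator;
    the real term carries the mask-weighted pair."""
    w = _check_weights(weights)
    d_r = _as_map(d_real)
    m, mbar = _mask_planes(mask, d_r)
    l_real = (
        _target_distance(d_r, 1.0)
        + w.alpha * _masked_target_distance(d_r, m, 1.0)
        + w.beta * _masked_target_distance(d_r, mbar, 1.0)
    )
    l_syn = _target_distance(d_fake, 0.0)
    return lambda_d * (l_real + l_syn)


def discriminator_loss_he(d_real, d_fake, lambda_d: float = 0.5) -> Tensor:
    """lambda_D * (L(D_HE(X_HE), 1) + L(D_HE(Y^_HE), 0)); no mask terms."""
    return lambda_d * (_target_distance(d_real, 1.0) + _target_distance(d_fake, 0.0))


# ----------------------------------------------------------------------
# regularizers
# ----------------------------------------------------------------------

def identity_loss(x, encoder, generator, mask: ActivationMask | None = None,
                  weights=None, kind: str = "L1") -> Tensor:
    """Autoencoding fidelity G(E(x)) vs x.

    Stain branch (mask given): plain term plus the mask-weighted pair.
    H&E branch (mask None): plain term only.
    """
    recon = generator(encoder(x))
    loss = base_distance(recon, x, kind)
    if mask is not None:
        loss = loss + masked_triple(recon, x, mask, _check_weights(weights), kind)
    return loss


def latent_loss(z, z_hat, mask: ActivationMask | None = None, weights=None,
                kind: str = "L1") -> Tensor:
    """Latent agreement L(Z^, Z); the stain branch adds the mask-weighted
    pair with the mask resampled to the latent grid."""
    loss = base_distance(z_hat, z, kind)
    if mask is not None:
        loss = loss + masked_triple(z_hat, z, mask, _check_weights(weights), kind)
    return loss


def forward_loss(y_hat_lo, x_lo, mask_lo: ActivationMask | None = None,
                 weights=None, kind: str = "L1") -> Tensor:
    """Cross-domain agreement of degraded tensors.

    Stain branch: degraded generated H&E vs degraded real stain tile,
    with mask terms on the degraded mask.  H&E branch: degraded
    generated stain vs degraded real H&E, plain.
    """
    loss = base_distance(y_hat_lo, x_lo, kind)
    if mask_lo is not None:
        loss = loss + masked_triple(y_hat_lo, x_lo, mask_lo, _check_weights(weights), kind)
    return loss


def degrade(image):
    """3x3/stride-2 average pooling, no padding: out = floor((in-3)/2)+1.

    Accepts an autodiff tensor in NCHW (differentiable) or a plain H x W
    / H x W x C array (returns an array).
    """
    if isinstance(image, Tensor):
        if image.shape[-2] < 3 or image.shape[-1] < 3:
            raise ValueError("input smaller than the 3x3 pooling kernel")
        return ag.avg_pool2d(image, 3, 2)
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None, None]
        squeeze = (0, 1)
    elif arr.ndim == 3:
        arr = arr.transpose(2, 0, 1)[None]
        squeeze = None
    else:
        raise ValueError("expected an H x W or H x W x C array")
    if arr.shape[-2] < 3 or arr.shape[-1] < 3:
        raise ValueError("input smaller than the 3x3 pooling kernel")
    out = ag.avg_pool2d(Tensor(arr), 3, 2).data
    if squeeze is not None:
        return out[0, 0]
    return out[0].transpose(1, 2, 0)


def regularization_loss(idt, lat, fwd, weights: LossWeights) -> Tensor:
    """lambda_idt * L_idt + lambda_lat * L_lat + lambda_fwd * L_fwd."""
    return (
        weights.lambda_idt * as_tensor(idt)
        + weights.lambda_lat * as_tensor(lat)
        + weights.lambda_fwd * as_tensor(fwd)
    )


def synthesis_loss(cyc, adv, reg, weights: LossWeights, sup=None) -> Tensor:
    """The per-stain objective; the supervised term (paired setting only)
    is added with weight ``lambda_sup``."""
    total = (
        weights.lambda_cyc * as_tensor(cyc)
        + weights.lambda_adv * as_tensor(adv)
        + weights.lambda_reg * as_tensor(reg)
    )
    if sup is not None:
        total = total + weights.lambda_sup * as_tensor(sup)
    return total


def he_regularization_loss(per_stain_losses) -> Tensor:
    """Arithmetic mean of the S per-stain synthesis losses."""
    losses = list(per_stain_losses)
    if not losses:
        raise ValueError("need at least one per-stain loss")
    total = as_tensor(losses[0])
    for loss in losses[1:]:
        total = total + as_tensor(loss)
    return total * (1.0 / len(losses))
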