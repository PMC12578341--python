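"""Every loss against an independent scalar-loop oracle, plus the
hand-derivable corner cases of the mask-weight extremes.

The oracles below use explicit Python loops over <=8x8 float64 arrays
and know nothing about the autodiff engine; the composite losses must
match them to 1e-9.
"""

import numpy as np
import pytest

from stainforge._autograd import Tensor
from stainforge.losses import (
    CycleBatch,
    LossWeights,
    adversarial_loss_paired,
    adversarial_loss_unpaired,
    base_distance,
    cycle_loss_paired,
    cycle_loss_unpaired,
    degrade,
    discriminator_loss_he,
    discriminator_loss_stain,
    forward_loss,
    he_regularization_loss,
    identity_loss,
    latent_loss,
    masked_triple,
    regularization_loss,
    supervised_loss,
    synthesis_loss,
)
from stainforge.masks import ActivationMask, MaskWeights

N_INSTANCES = 100
TOL = 1e-9


# ----------------------------------------------------------------------
# scalar-loop oracles
# ----------------------------------------------------------------------

def o_dist(a, b, kind):
    total = 0.0
    fa, fb = a.reshape(-1), b.reshape(-1)
    for x, y in zip(fa, fb):
        d = x - y
        total += abs(d) if kind == "L1" else d * d
    return total / fa.size


def o_apply_mask(arr, mask2d):
    out = np.empty_like(arr)
    n, c, h, w = arr.shape
    for ni in range(n):
        for ci in range(c):
            for i in range(h):
                for j in range(w):
                    out[ni, ci, i, j] = arr[ni, ci, i, j] * mask2d[i, j]
    return out


def o_masked_triple(a, b, mask2d, alpha, beta, kind):
    mbar = 1.0 - mask2d
    return alpha * o_dist(o_apply_mask(a, mask2d), o_apply_mask(b, mask2d), kind) + \
        beta * o_dist(o_apply_mask(a, mbar), o_apply_mask(b, mbar), kind)


def o_target(d, mask2d, target):
    if mask2d is not None:
        d = o_apply_mask(d, mask2d)
    return o_dist(d, np.full_like(d, target), "MSE")


def o_pool3s2(arr2d):
    h, w = arr2d.shape
    oh, ow = (h - 3) // 2 + 1, (w - 3) // 2 + 1
    out = np.zeros((oh, ow))
    for i in range(oh):
        for j in range(ow):
            s = 0.0
            for di in range(3):
                for dj in range(3):
                    s += arr2d[2 * i + di, 2 * j + dj]
            out[i, j] = s / 9.0
    return out


def rand_instance(rng, h=4, w=4, c=3):
    img = lambda: rng.normal(size=(1, c, h, w))
    mask2d = rng.random((h, w)) < rng.random()
    n = mask2d.sum()
    total = mask2d.size
    weights = MaskWeights(alpha=(total - n) / total, beta=n / total)
    return img, mask2d, weights


def weights_for(mask2d):
    n, total = mask2d.sum(), mask2d.size
    return MaskWeights(alpha=(total - n) / total, beta=n / total)


# ----------------------------------------------------------------------
# oracle-equivalence, quantified over random instances
# ----------------------------------------------------------------------

@pytest.mark.parametrize("kind", ["L1", "MSE"])
def test_base_distance_matches_loop_oracle(kind):
    rng = np.random.default_rng(10)
    for _ in range(N_INSTANCES):
        a, b = rng.normal(size=(4, 4, 3)), rng.normal(size=(4, 4, 3))
        got = base_distance(Tensor(a), Tensor(b), kind).item()
        assert got == pytest.approx(o_dist(a, b, kind), abs=TOL)


@pytest.mark.parametrize("kind", ["L1", "MSE"])
def test_masked_triple_matches_loop_oracle(kind):
    rng = np.random.default_rng(11)
    for _ in range(N_INSTANCES):
        img, mask2d, w = rand_instance(rng)
        a, b = img(), img()
        got = masked_triple(Tensor(a), Tensor(b), ActivationMask(mask2d), w, kind).item()
        assert got == pytest.approx(
            o_masked_triple(a, b, mask2d.astype(float), w.alpha, w.beta, kind), abs=TOL
        )


def _rand_batch(rng, h=4, w=4):
    img = lambda: Tensor(rng.normal(size=(1, 3, h, w)))
    mask2d = rng.random((h, w)) < rng.random()
    return CycleBatch(
        x_he=img(), x_i=img(),
        mask=ActivationMask(mask2d), weights=weights_for(mask2d),
        y_hat_i=img(), y_hat_he=img(), x_hat_i=img(), x_hat_he=img(),
    ), mask2d


def test_cycle_loss_unpaired_matches_term_oracle():
    rng = np.random.default_rng(12)
    for _ in range(N_INSTANCES):
        batch, mask2d = _rand_batch(rng)
        m = mask2d.astype(float)
        w = batch.weights
        expected = (
            o_dist(batch.x_hat_i.data, batch.x_i.data, "L1")
            + o_dist(batch.x_hat_he.data, batch.x_he.data, "L1")
            + o_masked_triple(batch.x_hat_i.data, batch.x_i.data, m, w.alpha, w.beta, "L1")
        )
        assert cycle_loss_unpaired(batch).item() == pytest.approx(expected, abs=TOL)


def test_cycle_loss_paired_matches_term_oracle():
    rng = np.random.default_rng(13)
    for _ in range(N_INSTANCES):
        batch, mask2d = _rand_batch(rng)
        m = mask2d.astype(float)
        mbar = 1.0 - m
        w = batch.weights
        xi, xhi = batch.x_i.data, batch.x_hat_i.data
        xh, xhh = batch.x_he.data, batch.x_hat_he.data
        expected = (
            o_dist(xhi, xi, "L1") + o_dist(xhh, xh, "L1")
            + w.alpha * (o_dist(o_apply_mask(xhi, m), o_apply_mask(xi, m), "L1")
                         + o_dist(o_apply_mask(xhh, m), o_apply_mask(xh, m), "L1"))
            + w.beta * (o_dist(o_apply_mask(xhi, mbar), o_apply_mask(xi, mbar), "L1")
                        + o_dist(o_apply_mask(xhh, mbar), o_apply_mask(xh, mbar), "L1"))
        )
        assert cycle_loss_paired(batch).item() == pytest.approx(expected, abs=TOL)


def test_supervised_loss_matches_term_oracle():
    rng = np.random.default_rng(14)
    for _ in range(N_INSTANCES):
        batch, mask2d = _rand_batch(rng)
        m = mask2d.astype(float)
        mbar = 1.0 - m
        w = batch.weights
        yi, xi = batch.y_hat_i.data, batch.x_i.data
        yh, xh = batch.y_hat_he.data, batch.x_he.data
        expected = (
            o_dist(yi, xi, "L1") + o_dist(yh, xh, "L1")
            + w.alpha * (o_dist(o_apply_mask(yi, m), o_apply_mask(xi, m), "L1")
                         + o_dist(o_apply_mask(yh, m), o_apply_mask(xh, m), "L1"))
            + w.beta * (o_dist(o_apply_mask(yi, mbar), o_apply_mask(xi, mbar), "L1")
                        + o_dist(o_apply_mask(yh, mbar), o_apply_mask(xh, mbar), "L1"))
        )
        assert supervised_loss(batch).item() == pytest.approx(expected, abs=TOL)


def test_adversarial_losses_match_oracle():
    rng = np.random.default_rng(15)
    for _ in range(N_INSTANCES):
        d_i = rng.normal(size=(1, 2, 4, 4))
        d_he = rng.normal(size=(1, 2, 4, 4))
        mask2d = rng.random((4, 4)) < rng.random()
        m = mask2d.astype(float)
        mbar = 1.0 - m
        w = weights_for(mask2d)
        amask = ActivationMask(mask2d)
        exp_u = (
            o_target(d_i, None, 1.0)
            + w.alpha * o_target(d_he, m, 1.0)
            + w.beta * o_target(d_he, mbar, 1.0)
        )
        got_u = adversarial_loss_unpaired(Tensor(d_i), Tensor(d_he), amask, w).item()
        assert got_u == pytest.approx(exp_u, abs=TOL)
        exp_p = (
            o_target(d_he, None, 1.0)
            + w.alpha * (o_target(d_he, m, 1.0) + o_target(d_i, m, 1.0))
            + w.beta * (o_target(d_he, mbar, 1.0) + o_target(d_i, mbar, 1.0))
        )
        got_p = adversarial_loss_paired(Tensor(d_i), Tensor(d_he), amask, w).item()
        assert got_p == pytest.approx(exp_p, abs=TOL)


def test_discriminator_losses_match_oracle():
    rng = np.random.default_rng(16)
    lam = 0.5
    for _ in range(N_INSTANCES):
        d_real = rng.normal(size=(1, 2, 4, 4))
        d_fake = rng.normal(size=(1, 2, 4, 4))
        mask2d = rng.random((4, 4)) < rng.random()
        m = mask2d.astype(float)
        w = weights_for(mask2d)
        exp = lam * (
            o_target(d_real, None, 1.0)
            + w.alpha * o_target(d_real, m, 1.0)
            + w.beta * o_target(d_real, 1.0 - m, 1.0)
            + o_target(d_fake, None, 0.0)
        )
        got = discriminator_loss_stain(Tensor(d_real), Tensor(d_fake),
                                       ActivationMask(mask2d), w, lambda_d=lam).item()
        assert got == pytest.approx(exp, abs=TOL)
        exp_he = lam * (o_target(d_real, None, 1.0) + o_target(d_fake, None, 0.0))
        got_he = discriminator_loss_he(Tensor(d_real), Tensor(d_fake), lambda_d=lam).item()
        assert got_he == pytest.approx(exp_he, abs=TOL)


def test_latent_and_forward_losses_match_oracle():
    rng = np.random.default_rng(17)
    for _ in range(N_INSTANCES):
        z = rng.normal(size=(1, 4, 4, 4))
        z_hat = rng.normal(size=(1, 4, 4, 4))
        mask2d = rng.random((4, 4)) < rng.random()
        m = mask2d.astype(float)
        w = weights_for(mask2d)
        exp = o_dist(z_hat, z, "L1") + o_masked_triple(z_hat, z, m, w.alpha, w.beta, "L1")
        got = latent_loss(Tensor(z), Tensor(z_hat), ActivationMask(mask2d), w).item()
        assert got == pytest.approx(exp, abs=TOL)
        # H&E branch ignores the mask entirely
        got_he = latent_loss(Tensor(z), Tensor(z_hat)).item()
        assert got_he == pytest.approx(o_dist(z_hat, z, "L1"), abs=TOL)
        # forward loss shares the masked-triple structure on degraded tensors
        got_f = forward_loss(Tensor(z_hat), Tensor(z), ActivationMask(mask2d), w).item()
        assert got_f == pytest.approx(exp, abs=TOL)


def test_identity_loss_with_random_network_matches_oracle():
    rng = np.random.default_rng(18)
    scale = Tensor(rng.normal(size=(1, 3, 1, 1)))
    encoder = lambda t: t * scale
    generator = lambda t: t + 0.25
    for _ in range(30):
        x = rng.normal(size=(1, 3, 4, 4))
        mask2d = rng.random((4, 4)) < 0.5
        w = weights_for(mask2d)
        recon = x * scale.data + 0.25
        exp = o_dist(recon, x, "L1") + o_masked_triple(
            recon, x, mask2d.astype(float), w.alpha, w.beta, "L1")
        got = identity_loss(Tensor(x), encoder, generator, ActivationMask(mask2d), w).item()
        assert got == pytest.approx(exp, abs=TOL)


def test_degrade_matches_loop_pooling_oracle():
    rng = np.random.default_rng(19)
    for _ in range(N_INSTANCES):
        arr = rng.normal(size=(7, 8))
        assert np.allclose(degrade(arr), o_pool3s2(arr), atol=TOL)


# ----------------------------------------------------------------------
# hand-derived corners and analytic examples
# ----------------------------------------------------------------------

class TestCorners:
    def test_identity_inputs_give_zero_everywhere(self):
        rng = np.random.default_rng(20)
        a = Tensor(rng.normal(size=(1, 3, 4, 4)))
        mask2d = rng.random((4, 4)) < 0.4
        w = weights_for(mask2d)
        assert base_distance(a, a).item() == 0.0
        assert masked_triple(a, a, ActivationMask(mask2d), w).item() == 0.0

    def test_l1_of_ones_vs_zeros_is_one(self):
        a = Tensor(np.ones((2, 5, 3)))
        b = Tensor(np.zeros((2, 5, 3)))
        assert base_distance(a, b, "L1").item() == 1.0

    def test_masked_triple_all_ones_mask_vanishes(self):
        # mask all ones forces alpha=0, beta=1 and M-bar zeroes both args
        rng = np.random.default_rng(21)
        a, b = Tensor(rng.normal(size=(1, 3, 4, 4))), Tensor(rng.normal(size=(1, 3, 4, 4)))
        mask = ActivationMask(np.ones((4, 4), dtype=bool))
        assert masked_triple(a, b, mask, MaskWeights(0.0, 1.0)).item() == 0.0

    def test_adv_unpaired_corner_mask_all_ones(self):
        # all disc outputs 1, mask all ones (alpha=0, beta=1):
        # L(1,1)=0; beta-term compares M-bar*1 = 0 against 1 -> 1
        ones = Tensor(np.ones((1, 2, 4, 4)))
        mask = ActivationMask(np.ones((4, 4), dtype=bool))
        got = adversarial_loss_unpaired(ones, ones, mask, MaskWeights(0.0, 1.0)).item()
        assert got == pytest.approx(1.0, abs=TOL)

    def test_adv_unpaired_corner_mask_all_zeros(self):
        ones = Tensor(np.ones((1, 2, 4, 4)))
        mask = ActivationMask(np.zeros((4, 4), dtype=bool))
        got = adversarial_loss_unpaired(ones, ones, mask, MaskWeights(1.0, 0.0)).item()
        assert got == pytest.approx(1.0, abs=TOL)

    def test_adv_paired_corner_mask_all_ones(self):
        # plain D_HE term 0; alpha-terms 0-weighted; beta * (two
        # complement-masked maps of zeros vs target 1) = 2
        ones = Tensor(np.ones((1, 2, 4, 4)))
        mask = ActivationMask(np.ones((4, 4), dtype=bool))
        got = adversarial_loss_paired(ones, ones, mask, MaskWeights(0.0, 1.0)).item()
        assert got == pytest.approx(2.0, abs=TOL)

    def test_disc_stain_corner_perfect_d_empty_mask(self):
        # D: 1 on real, 0 on fake; mask empty (alpha=1):
        # L_real = 0 + 1*L(0,1) + 0 = 1; L_syn = 0 -> lambda_D * 1
        ones, zeros = Tensor(np.ones((1, 2, 4, 4))), Tensor(np.zeros((1, 2, 4, 4)))
        mask = ActivationMask(np.zeros((4, 4), dtype=bool))
        got = discriminator_loss_stain(ones, zeros, mask, MaskWeights(1.0, 0.0),
                                       lambda_d=0.5).item()
        assert got == pytest.approx(0.5, abs=TOL)
        assert discriminator_loss_stain(ones, zeros, mask, MaskWeights(1.0, 0.0),
                                        lambda_d=0.0).item() == 0.0

    def test_disc_he_half_outputs(self):
        half = Tensor(np.full((1, 2, 4, 4), 0.5))
        got = discriminator_loss_he(half, half, lambda_d=0.5).item()
        assert got == pytest.approx(0.5 * (0.25 + 0.25), abs=TOL)

    def test_cycle_unpaired_uniform_offset_half_mask(self):
        # X^_i = X_i + 0.1, X^_HE = X_HE, half mask (alpha=beta=0.5):
        # 0.1 + alpha*0.1*f + beta*0.1*(1-f) with f=0.5 -> 0.15
        rng = np.random.default_rng(22)
        x_i = rng.normal(size=(1, 3, 4, 4))
        mask2d = np.zeros((4, 4), dtype=bool)
        mask2d[:2] = True
        batch = CycleBatch(
            x_he=Tensor(rng.normal(size=(1, 3, 4, 4))), x_i=Tensor(x_i),
            mask=ActivationMask(mask2d), weights=MaskWeights(0.5, 0.5),
            x_hat_i=Tensor(x_i + 0.1), x_hat_he=None,
        )
        batch.x_hat_he = batch.x_he
        assert cycle_loss_unpaired(batch).item() == pytest.approx(0.15, abs=TOL)

    def test_latent_constant_offset_half_mask(self):
        z = Tensor(np.zeros((1, 2, 4, 4)))
        z_hat = Tensor(np.full((1, 2, 4, 4), 0.3))
        mask2d = np.zeros((4, 4), dtype=bool)
        mask2d[:2] = True
        got = latent_loss(z, z_hat, ActivationMask(mask2d), MaskWeights(0.5, 0.5)).item()
        assert got == pytest.approx(0.3 + 0.5 * 0.15 + 0.5 * 0.15, abs=TOL)

    def test_identity_loss_stub_networks_zero(self):
        x = Tensor(np.random.default_rng(23).normal(size=(1, 3, 4, 4)))
        mask2d = np.zeros((4, 4), dtype=bool)
        got = identity_loss(x, lambda t: t, lambda t: t,
                            ActivationMask(mask2d), MaskWeights(1.0, 0.0)).item()
        assert got == 0.0

    def test_he_identity_branch_ignores_mask(self):
        rng = np.random.default_rng(24)
        x = Tensor(rng.normal(size=(1, 3, 4, 4)))
        got = identity_loss(x, lambda t: t * 0.9, lambda t: t)
        assert got.item() > 0.0  # plain branch, no mask argument at all


class TestComposition:
    def test_paired_cycle_dominates_unpaired(self):
        rng = np.random.default_rng(25)
        for _ in range(20):
            batch, _ = _rand_batch(rng)
            assert cycle_loss_paired(batch).item() >= cycle_loss_unpaired(batch).item() - TOL

    def test_regularization_weighted_sum(self):
        w = LossWeights(lambda_idt=1.0, lambda_lat=1.0, lambda_fwd=1.0)
        assert regularization_loss(0.1, 0.2, 0.3, w).item() == pytest.approx(0.6)
        w0 = LossWeights(lambda_idt=0.0, lambda_lat=0.0, lambda_fwd=0.0)
        assert regularization_loss(0.4, 0.5, 0.6, w0).item() == 0.0
        w1 = LossWeights(lambda_idt=1.0, lambda_lat=0.0, lambda_fwd=0.0)
        assert regularization_loss(0.3, 9.9, 9.9, w1).item() == pytest.approx(0.3)

    def test_synthesis_weighted_sum(self):
        w = LossWeights(lambda_cyc=10.0, lambda_adv=1.0, lambda_reg=0.0)
        assert synthesis_loss(0.5, 0.2, 7.0, w).item() == pytest.approx(5.2)
        assert synthesis_loss(0.0, 0.0, 0.0, w).item() == 0.0
        # supervised term enters with its own weight
        assert synthesis_loss(0.5, 0.2, 0.0, w, sup=0.3).item() == pytest.approx(5.5)

    def test_he_regularization_is_mean(self):
        assert he_regularization_loss([7.0]).item() == pytest.approx(7.0)
        assert he_regularization_loss([2.0, 4.0]).item() == pytest.approx(3.0)
        rng = np.random.default_rng(26)
        vals = rng.normal(size=8)
        assert he_regularization_loss(list(vals)).item() == pytest.approx(vals.mean(), abs=TOL)

    def test_weights_not_summing_to_one_rejected(self):
        a = Tensor(np.ones((1, 3, 4, 4)))
        with pytest.raises(ValueError):
            masked_triple(a, a, ActivationMask(np.ones((4, 4), dtype=bool)), (0.6, 0.6))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            base_distance(Tensor(np.ones((2, 2))), Tensor(np.ones((3, 2))))


class TestDegrade:
    def test_output_shape_512_to_255(self):
        out = degrade(np.zeros((512, 512)))
        assert out.shape == (255, 255)

    def test_constant_preserved(self):
        assert np.allclose(degrade(np.full((9, 9), 3.7)), 3.7)

    def test_5x5_ramp_hand_windows(self):
        ramp = np.arange(25, dtype=float).reshape(5, 5)
        # 3x3 window means centred at (1,1),(1,3),(3,1),(3,3): the mean of
        # a 3x3 patch of the ramp equals its central element
        expected = np.array([[6.0, 8.0], [16.0, 18.0]])
        assert np.allclose(degrade(ramp), expected)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            degrade(np.zeros((2, 5)))
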