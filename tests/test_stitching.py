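"""Hamming-window analytics and the stitch reconstruction identity."""

import numpy as np
import pytest

from stainforge.core_io import plan_tiles
from stainforge.networks import ModelBundle, NetworkConfig, build_log, load_for_inference, reset_build_log
from stainforge.stitching import (
    apply_window,
    hamming_window_2d,
    max_boundary_gradient,
    stitch,
    stain_wsi,
)
from stainforge.synthetic import generate_he_tile


class TestWindow:
    def test_center_value_one_for_odd_m(self):
        for m in (3, 65, 511):
            w = hamming_window_2d(m)
            assert w.weights[m // 2, m // 2] == pytest.approx(1.0, abs=1e-12)

    def test_corner_value(self):
        for m in (3, 64, 512):
            w = hamming_window_2d(m)
            assert w.weights[0, 0] == pytest.approx((0.54 - 0.46) ** 2, abs=1e-12)

    def test_m3_window_is_outer_product_of_1d(self):
        w = hamming_window_2d(3)
        h1d = np.array([0.08, 1.0, 0.08])
        assert np.allclose(np.diag(w.weights) ** 0.5, h1d)  # separable, symmetric
        assert np.allclose(w.weights, np.outer(h1d, h1d), atol=1e-12)

    def test_symmetry_and_positivity(self):
        w = hamming_window_2d(16).weights
        assert np.allclose(w, w[::-1])
        assert np.allclose(w, w[:, ::-1])
        assert (w > 0).all()

    def test_small_m_rejected(self):
        with pytest.raises(ValueError):
            hamming_window_2d(1)


class TestApplyWindow:
    def test_all_ones_patch_yields_window_per_channel(self):
        w = hamming_window_2d(8)
        out = apply_window(np.ones((8, 8, 3)), w)
        for c in range(3):
            assert np.allclose(out[..., c], w.weights)

    def test_zero_patch_stays_zero(self):
        w = hamming_window_2d(8)
        assert not apply_window(np.zeros((8, 8, 3)), w).any()

    def test_random_patch_matches_per_pixel_loop(self):
        rng = np.random.default_rng(0)
        w = hamming_window_2d(5)
        patch = rng.random((5, 5, 3))
        out = apply_window(patch, w)
        for i in range(5):
            for j in range(5):
                for c in range(3):
                    assert out[i, j, c] == pytest.approx(patch[i, j, c] * w.weights[i, j])

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_window(np.ones((6, 6, 3)), hamming_window_2d(8))


class TestStitch:
    def test_single_tile_recovered_exactly(self):
        rng = np.random.default_rng(1)
        tile = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        plan = plan_tiles((32, 32), 32, 0.6)
        out = stitch([(tile, (0, 0))], plan)
        assert np.array_equal(out.pixels, tile)

    @pytest.mark.parametrize("overlap", [0.0, 0.3, 0.6])
    def test_constant_tiles_give_constant_slide(self, overlap):
        plan = plan_tiles((100, 80), 32, overlap)
        tiles = [(np.full((32, 32, 3), 173, dtype=np.uint8), pos) for pos in plan.positions]
        out = stitch(tiles, plan)
        assert (out.pixels == 173).all()

    @pytest.mark.parametrize("overlap", [0.0, 0.3, 0.6])
    def test_roundtrip_through_crops_within_one_intensity_unit(self, overlap):
        rng = np.random.default_rng(2)
        src = rng.integers(0, 256, size=(300, 300, 3), dtype=np.uint8)
        plan = plan_tiles((300, 300), 64, overlap)
        tiles = [(src[y : y + 64, x : x + 64], (x, y)) for x, y in plan.positions]
        out = stitch(tiles, plan)
        err = np.abs(out.pixels.astype(int) - src.astype(int)).max()
        assert err <= 1

    def test_energy_bookkeeping(self):
        from stainforge.stitching import StitchAccumulator, hamming_window_2d

        rng = np.random.default_rng(3)
        plan = plan_tiles((96, 96), 32, 0.5)
        window = hamming_window_2d(32)
        acc = StitchAccumulator.for_extent(plan.slide_extent)
        total = 0.0
        for pos in plan.positions:
            patch = rng.random((32, 32, 3)) * 255
            acc.add(patch, pos, window)
            total += float(apply_window(patch, window).sum())
        assert acc.value_sum.sum() == pytest.approx(total, rel=1e-12)

    def test_boundary_jump_suppressed_by_overlap(self):
        # flat source, but tiles left of x=64 dimmed and tiles right of it
        # brightened: a deliberate per-tile color inconsistency of the kind
        # a context-sensitive generator produces at tile edges
        src = np.full((128, 128, 3), 128, dtype=np.uint8)

        def tiles_with_jump(plan):
            out = []
            for x, y in plan.positions:
                t = src[y : y + 64, x : x + 64].astype(int)
                t = t + (-20 if x < 64 else 20)
                out.append((np.clip(t, 0, 255).astype(np.uint8), (x, y)))
            return out

        plan0 = plan_tiles((128, 128), 64, 0.0)
        plan6 = plan_tiles((128, 128), 64, 0.6)
        hard = stitch(tiles_with_jump(plan0), plan0)
        soft = stitch(tiles_with_jump(plan6), plan6)
        g_hard = max_boundary_gradient(hard.pixels, [64])
        g_soft = max_boundary_gradient(soft.pixels, [64])
        assert g_hard == 40  # the raw seam survives hard stitching
        assert g_soft < g_hard

    def test_uncovered_pixels_rejected(self):
        plan = plan_tiles((64, 64), 32, 0.0)
        with pytest.raises(ValueError, match="coverage"):
            stitch([(np.zeros((32, 32, 3), dtype=np.uint8), (0, 0))], plan)

    def test_out_of_extent_tile_rejected(self):
        plan = plan_tiles((64, 64), 32, 0.0)
        with pytest.raises(ValueError, match="extent"):
            stitch([(np.zeros((32, 32, 3), dtype=np.uint8), (40, 0))], plan)


@pytest.fixture(scope="module")
def checkpoints(tmp_path_factory):
    path = tmp_path_factory.mktemp("ckpt")
    bundle = ModelBundle.build(["CD3", "CD8", "A", "B", "C", "D", "E", "F"],
                               NetworkConfig.tiny(), seed=0)
    bundle.save(path)
    return path


class TestStainWSI:

    def test_single_stain_request_builds_two_components(self, checkpoints):
        reset_build_log()
        components = load_for_inference(checkpoints, ["CD3"])
        assert len(build_log()) == 2
        slide = generate_he_tile(128, seed=30)
        from stainforge.core_io import SlideRaster

        rasters = stain_wsi(SlideRaster(pixels=slide.pixels), components, ["CD3"],
                            overlap=0.6, tile_size=64)
        assert rasters["CD3"].pixels.shape == (128, 128, 3)

    def test_identical_requests_bit_identical(self, checkpoints, tmp_path):
        from stainforge.core_io import SlideRaster

        slide = SlideRaster(pixels=generate_he_tile(128, seed=31).pixels)
        components = load_for_inference(checkpoints, ["CD8"])
        stain_wsi(slide, components, ["CD8"], overlap=0.3, tile_size=64,
                  out_dir=tmp_path / "a")
        stain_wsi(slide, components, ["CD8"], overlap=0.3, tile_size=64,
                  out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "CD8.tiff").read_bytes() == \
            (tmp_path / "b" / "CD8.tiff").read_bytes()

    def test_missing_generator_rejected_by_name(self, checkpoints):
        components = load_for_inference(checkpoints, ["CD3"])
        from stainforge.core_io import SlideRaster

        slide = SlideRaster(pixels=np.zeros((64, 64, 3), dtype=np.uint8))
        with pytest.raises(KeyError, match="CD8"):
            stain_wsi(slide, components, ["CD8"], tile_size=64)

    def test_smoke_runtime_256_fixture(self, checkpoints):
        import time

        from stainforge.core_io import SlideRaster

        slide = SlideRaster(pixels=generate_he_tile(256, seed=32).pixels)
        components = load_for_inference(checkpoints, ["CD3"])
        t0 = time.time()
        stain_wsi(slide, components, ["CD3"], overlap=0.6, tile_size=64)
        assert time.time() - t0 < 30
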