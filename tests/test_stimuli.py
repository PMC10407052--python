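"""Stimulus geometry: mosaics, ellipse clipping, area matching, variants."""

import numpy as np
import pytest
from scipy import ndimage

from numsense import (
    BBox, add_noise, apply_region_variant, clip_ellipse, compose_ellipse_scene,
    compose_mosaic, make_scene, phase_scramble, solve_scales,
)
from numsense.config import SceneLayoutConfig
from numsense.stimuli import _ellipse_mask, gaussian_kernel, soft_ellipse_weight

CFG = SceneLayoutConfig(canvas_size=240, target_total_area=30 * 30 * 7, seed=0)


def _blob(h, w, value=200, seed=0):
    rng = np.random.default_rng(seed)
    return rng.integers(50, value, size=(h, w, 3)).astype(np.uint8)


class TestMosaic:
    def test_single_block_is_identity(self):
        img = _blob(40, 40)
        stim = compose_mosaic([img])
        assert np.array_equal(stim.pixels, img)
        assert stim.item_count == 1

    def test_seven_blocks_appear_unmodified_in_their_slots(self):
        blocks = [_blob(50, 50, seed=k) for k in range(7)]
        stim = compose_mosaic(blocks)
        assert stim.item_count == 7
        for b, box in zip(blocks, stim.boxes):
            assert np.array_equal(box.crop(stim.pixels), b)

    def test_canvas_is_multiple_of_max_block(self):
        blocks = [_blob(30, 20), _blob(44, 36), _blob(10, 12)]
        stim = compose_mosaic(blocks)
        assert stim.pixels.shape[0] % 44 == 0
        assert stim.pixels.shape[1] % 36 == 0

    def test_noise_patch_variant(self):
        blocks = [_blob(30, 30, seed=k) for k in range(3)]
        stim = compose_mosaic(blocks, noise_patches=True, seed=5)
        assert stim.variant == "noise_patch"
        # no block content survives
        for b, box in zip(blocks, stim.boxes):
            assert not np.array_equal(box.crop(stim.pixels), b)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            compose_mosaic([])


class TestClipEllipse:
    def test_center_kept_corners_zeroed(self):
        white = np.full((100, 100, 3), 255, dtype=np.uint8)
        patch = clip_ellipse(white, BBox(0, 0, 100, 100), fade_kernel=15)
        assert np.all(patch[50, 50] == 255)
        for y, x in [(0, 0), (0, 99), (99, 0), (99, 99)]:
            assert np.all(patch[y, x] == 0)

    def test_mask_area_close_to_pi_over_4(self):
        mask = _ellipse_mask(100, 100)
        frac = mask.mean()
        rim_tolerance = 4 / 100  # one rim's worth of pixels
        assert abs(frac - np.pi / 4) < rim_tolerance

    def test_rim_profile_matches_direct_gaussian_convolution(self):
        """The soft edge equals convolving the binary mask with the kernel."""
        h = w = 60
        k = 11
        weight = soft_ellipse_weight(h, w, k)
        mask = _ellipse_mask(h, w)
        oracle = ndimage.convolve(mask.astype(float), gaussian_kernel(k),
                                  mode="constant", cval=0.0) * mask
        white = np.full((h, w), 255.0)
        patch = clip_ellipse(white[..., None].repeat(3, -1).astype(np.uint8),
                             BBox(0, 0, w, h), fade_kernel=k)
        assert np.all(np.abs(patch[..., 0].astype(float)
                             - np.round(255 * oracle)) <= 1)
        assert np.allclose(weight, oracle)

    def test_degenerate_box_errors(self):
        img = np.zeros((50, 50, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="degenerate"):
            clip_ellipse(img, BBox(0, 0, 10, 40), fade_kernel=15)


class TestSolveScales:
    def test_zero_jitter_exact_total(self):
        cfg = SceneLayoutConfig(canvas_size=240, target_total_area=6300,
                                scale_jitter=0.0, seed=0)
        sol = solve_scales(4, cfg)
        assert np.allclose(sol.factors, sol.factors[0])
        assert sol.achieved_total == pytest.approx(6300)

    def test_single_item_takes_mean_size(self):
        sol = solve_scales(1, CFG)
        assert sol.areas[0] == pytest.approx(CFG.target_total_area)

    def test_mean_item_size_is_total_over_count(self):
        for n in (2, 5, 7):
            sol = solve_scales(n, CFG, seed=n)
            # factors are centered on 1, so base (pre-jitter) area is total / n
            base = sol.areas / sol.factors
            assert np.allclose(base, CFG.target_total_area / n)

    def test_selected_combination_is_argmin_over_rescanned_candidates(self):
        """Exhaustive re-scan of the same seeded candidate set finds no better one."""
        n = 5
        sol = solve_scales(n, CFG, seed=42)
        rng = np.random.default_rng(42)
        j = CFG.scale_jitter
        cand = rng.uniform(1 - j, 1 + j, size=(CFG.n_candidates, n))
        base = CFG.target_total_area / n
        errors = np.abs(cand.sum(axis=1) * base - CFG.target_total_area)
        assert abs(sol.achieved_total - CFG.target_total_area) == pytest.approx(
            errors.min(), rel=1e-12)

    def test_factors_within_jitter_band(self):
        sol = solve_scales(6, CFG, seed=1)
        assert np.all(sol.factors >= 1 - CFG.scale_jitter)
        assert np.all(sol.factors <= 1 + CFG.scale_jitter)

    def test_infeasible_target_flagged_best_effort(self):
        sol = solve_scales(3, CFG, base_areas=np.array([10.0, 10.0, 10.0]), seed=0)
        assert not sol.feasible


class TestSceneComposition:
    def test_single_patch_pixel_count_preserved(self):
        patch = clip_ellipse(_blob(40, 40, seed=1), BBox(0, 0, 40, 40), 15)
        stim = compose_ellipse_scene([patch], CFG, seed=2)
        assert (stim.pixels.sum(-1) > 0).sum() == (patch.sum(-1) > 0).sum()

    def test_seven_patches_supports_disjoint(self, toy_images):
        images, _ = toy_images
        stim = make_scene(images[:7], CFG, seed=11)
        # item supports are pairwise disjoint iff their sizes sum to the union
        scene = (stim.pixels.sum(-1) > 0).sum()
        assert sum(stim.provenance["support_counts"]) == scene

    def test_total_area_within_10pct_of_target(self, toy_images):
        images, _ = toy_images
        for n in (2, 4, 7):
            stim = make_scene(images[:n], CFG, seed=n)
            area = (stim.pixels.sum(-1) > 0).sum()
            assert abs(area - CFG.target_total_area) / CFG.target_total_area < 0.10

    def test_cell_containment_when_items_fit(self, toy_images):
        """Items small enough for their cells stay inside them (density rule)."""
        images, _ = toy_images
        stim = make_scene(images[:6], CFG, seed=8)
        cell = CFG.canvas_size // CFG.grid_rows
        for box in stim.boxes:
            if box.w <= cell and box.h <= cell:
                # the box may straddle at most 2 cells worth of span
                assert box.w <= 2 * cell and box.h <= 2 * cell

    def test_reproducible_from_seed(self, toy_images):
        images, _ = toy_images
        a = make_scene(images[:3], CFG, seed=5)
        b = make_scene(images[:3], CFG, seed=5)
        assert np.array_equal(a.pixels, b.pixels)

    def test_unplaceable_scene_reports_item(self):
        big = np.full((230, 230, 3), 120, dtype=np.uint8)
        with pytest.raises(RuntimeError, match="item"):
            compose_ellipse_scene([big, big], CFG, seed=0)


class TestNoiseOverlay:
    def test_weight_zero_is_identity(self):
        img = _blob(30, 30, seed=9)
        assert np.array_equal(add_noise(img, 0.0, seed=1).pixels, img)

    def test_heavier_noise_moves_further_from_original(self):
        img = _blob(60, 60, seed=2)
        d05 = np.abs(add_noise(img, 0.5, seed=3).pixels.astype(float) - img).mean()
        d30 = np.abs(add_noise(img, 3.0, seed=3).pixels.astype(float) - img).mean()
        assert d30 > d05

    def test_standard_weights_accepted_and_tagged(self):
        img = _blob(20, 20)
        for w in (0.5, 1.0, 2.0, 3.0):
            stim = add_noise(img, w, seed=0)
            assert stim.variant == f"noise_overlay({w:g})"

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            add_noise(_blob(10, 10), -1.0)


class TestRegionVariants:
    def _image_with_boxes(self):
        img = _blob(120, 120, seed=4)
        boxes = [BBox(10, 10, 40, 40), BBox(60, 60, 50, 40)]
        return img, boxes

    def test_clip_then_cleared_is_black_up_to_rim(self):
        img, boxes = self._image_with_boxes()
        clipped = apply_region_variant(img, boxes, "clip")
        both = apply_region_variant(clipped, boxes, "bbox_cleared")
        # w * (1 - w) peaks at 1/4, so residual intensity is rim-limited
        assert both.pixels.max() <= np.ceil(0.25 * 255) + 1

    def test_noise_clip_retains_no_original_content(self):
        img, boxes = self._image_with_boxes()
        out = apply_region_variant(img, boxes, "noise_clip", seed=5)
        inside = out.pixels[np.asarray(_inside_mask(img, boxes))]
        orig = img[np.asarray(_inside_mask(img, boxes))]
        assert not np.array_equal(inside, orig)
        # outside the ellipses everything is black
        assert np.all(out.pixels[~_inside_mask(img, boxes)] == 0)

    def test_bbox_cleared_keeps_background_untouched(self):
        img, boxes = self._image_with_boxes()
        out = apply_region_variant(img, boxes, "bbox_cleared")
        outside = ~_inside_mask(img, boxes)
        assert np.array_equal(out.pixels[outside], img[outside])

    def test_no_boxes_errors(self):
        with pytest.raises(ValueError):
            apply_region_variant(_blob(20, 20), [], "clip")


def _inside_mask(img, boxes):
    from numsense.stimuli import soft_ellipse_weight
    H, W = img.shape[:2]
    m = np.zeros((H, W), dtype=bool)
    for b in boxes:
        m[b.y:b.y + b.h, b.x:b.x + b.w] |= soft_ellipse_weight(b.h, b.w, 15) > 0
    return m


class TestPhaseScramble:
    def test_amplitude_spectrum_preserved_before_clipping(self):
        img = _blob(64, 64, seed=6)
        out = phase_scramble(img, seed=1, clip=False)
        for ch in range(3):
            a_in = np.abs(np.fft.fft2(img[..., ch].astype(float)))
            a_out = np.abs(np.fft.fft2(out[..., ch]))
            rel = np.abs(a_out - a_in) / np.maximum(a_in, 1e-9)
            assert rel.max() < 1e-6

    def test_constant_image_is_fixed_point(self):
        img = np.full((32, 32, 3), 127, dtype=np.uint8)
        out = phase_scramble(img, seed=2)
        assert np.array_equal(out.pixels, img)

    def test_two_seeds_differ_in_pixels_not_amplitude(self):
        img = _blob(48, 48, seed=7)
        a = phase_scramble(img, seed=1, clip=False)
        b = phase_scramble(img, seed=2, clip=False)
        assert not np.allclose(a, b)
        for ch in range(3):
            assert np.allclose(np.abs(np.fft.fft2(a[..., ch])),
                               np.abs(np.fft.fft2(b[..., ch])), rtol=1e-9, atol=1e-6)
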