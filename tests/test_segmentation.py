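"""Segmentation chain: equalize, adaptive filter, binarize, Moore
tracing (vs the brute-force boundary oracle) and cloud assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemodyn import segmentation as sg
from hemodyn import synthetic as sy


class TestEqualize:
    def test_constant_image_unchanged(self):
        img = np.full((8, 8), 77, dtype=np.int64)
        np.testing.assert_array_equal(sg.equalize(img, 8), img)

    def test_two_level_hand_cdf(self):
        # 4x4 toy: 4 px of 50 (25%), 12 px of 200 (75%)
        img = np.full((4, 4), 200, dtype=np.int64)
        img[0, :] = 50
        out = sg.equalize(img, 8)
        # hand CDF: cdf(50)=0.25 (=cdf_min), cdf(200)=1.0
        # lut(v) = round((cdf - 0.25) / 0.75 * 255) -> 50 -> 0, 200 -> 255
        assert set(np.unique(out)) == {0, 255}
        np.testing.assert_array_equal(out == 255, img == 200)

    def test_full_range_occupied(self, rng):
        img = rng.integers(30, 200, size=(32, 32))
        out = sg.equalize(img, 8)
        assert out.min() == 0 and out.max() == 255

    def test_monotone_rank_preserving(self, rng):
        img = rng.integers(0, 256, size=(32, 32))
        out = sg.equalize(img, 8)
        a, b = img.ravel(), out.ravel()
        order = np.argsort(a)
        assert (np.diff(b[order]) >= 0).all()

    def test_ramp_idempotent_within_one_step(self):
        ramp = np.tile(np.arange(256, dtype=np.int64), (4, 1))
        once = sg.equalize(ramp, 8)
        twice = sg.equalize(once, 8)
        assert np.abs(twice.astype(int) - once.astype(int)).max() <= 1


class TestAdaptiveSmooth:
    def test_below_threshold_unchanged(self):
        img = np.full((5, 5), 10, dtype=np.int64)
        np.testing.assert_array_equal(sg.adaptive_smooth(img, 100, 30), img)

    def test_uniform_above_threshold_decremented(self):
        img = np.full((5, 5), 200, dtype=np.int64)
        np.testing.assert_array_equal(
            sg.adaptive_smooth(img, 100, 30), np.full((5, 5), 170)
        )

    def test_zero_decrement_is_identity(self, rng):
        img = rng.integers(0, 256, size=(16, 16))
        np.testing.assert_array_equal(sg.adaptive_smooth(img, 50, 0), img)

    def test_clipped_at_zero(self):
        img = np.full((5, 5), 20, dtype=np.int64)
        out = sg.adaptive_smooth(img, 10, 50)
        assert (out == 0).all()

    def test_plus_shaped_neighborhood_mean(self):
        # single bright pixel: its own mean (5-pixel plus, replicate pad)
        # is (200 + 4*0)/5 = 40; neighbors see (200 + 4*0)/5 = 40 too
        img = np.zeros((5, 5), dtype=np.int64)
        img[2, 2] = 200
        out = sg.adaptive_smooth(img, 39, 10)
        assert out[2, 2] == 190  # own mean 40 > 39
        assert out[2, 1] == 0 and out[1, 2] == 0  # clipped
        assert out[0, 0] == 0  # mean 0 < 39, untouched, already 0

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            sg.adaptive_smooth(np.zeros((3, 3), dtype=np.int64), -1, 5)


class TestBinarize:
    def test_threshold_zero_all_ones(self, rng):
        img = rng.integers(0, 256, size=(8, 8))
        assert (sg.binarize(img, 0) == 1).all()

    def test_threshold_above_max_all_zeros(self, rng):
        img = rng.integers(0, 256, size=(8, 8))
        assert (sg.binarize(img, 256) == 0).all()

    def test_center_pixel_only(self):
        img = np.full((3, 3), 50, dtype=np.int64)
        img[1, 1] = 200
        expected = np.zeros((3, 3), dtype=np.uint8)
        expected[1, 1] = 1
        np.testing.assert_array_equal(sg.binarize(img, 100), expected)


class TestTraceBoundary:
    def test_empty_mask(self):
        assert sg.trace_boundary(np.zeros((5, 5), dtype=np.uint8)) == []

    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 2] = 1
        contours = sg.trace_boundary(m, min_size=1)
        assert len(contours) == 1 and len(contours[0]) == 1
        assert tuple(contours[0].pixels[0]) == (2, 2)

    def test_3x3_square_hand_enumeration(self):
        m = np.pad(np.ones((3, 3), dtype=np.uint8), 1)
        (contour,) = sg.trace_boundary(m, min_size=1)
        # hand-traced clockwise Moore boundary from the top-left pixel
        expected = [
            (1, 1), (1, 2), (1, 3), (2, 3), (3, 3), (3, 2), (3, 1), (2, 1),
        ]
        assert [tuple(p) for p in contour.pixels] == expected

    def test_disk_contour_matches_oracle_and_length(self):
        rr, cc = np.mgrid[0:50, 0:50]
        m = ((rr - 25) ** 2 + (cc - 25) ** 2 <= 20**2).astype(np.uint8)
        (contour,) = sg.trace_boundary(m)
        oracle = {tuple(p) for p in sg.boundary_pixels(m)}
        assert contour.pixel_set() == oracle
        # digitized circle: ~4 sqrt(2) r boundary pixels (diagonal steps
        # cover sqrt(2) of arc length); within 10%
        assert len(contour) == pytest.approx(4 * np.sqrt(2) * 20, rel=0.10)
        # every contour pixel has a background 4-neighbor
        for r, c in contour.pixels:
            assert min(m[r - 1, c], m[r + 1, c], m[r, c - 1], m[r, c + 1]) == 0

    def test_consecutive_pixels_8_connected_and_closed(self):
        rr, cc = np.mgrid[0:40, 0:40]
        m = (((rr - 20) / 12) ** 2 + ((cc - 18) / 8) ** 2 <= 1).astype(np.uint8)
        (contour,) = sg.trace_boundary(m)
        loop = np.vstack([contour.pixels, contour.pixels[:1]])
        steps = np.abs(np.diff(loop, axis=0)).max(axis=1)
        assert (steps == 1).all()

    def test_min_size_filter(self):
        m = np.zeros((20, 20), dtype=np.uint8)
        m[2:4, 2:4] = 1  # 4 px, below default min of 8
        m[10:14, 10:14] = 1  # 16 px
        contours = sg.trace_boundary(m)
        assert len(contours) == 1
        assert tuple(contours[0].pixels[0]) == (10, 10)

    @settings(max_examples=60, deadline=None)
    @given(
        cy=st.floats(8, 24), cx=st.floats(8, 24),
        a=st.floats(2.0, 7.5), b=st.floats(2.0, 7.5),
        cy2=st.floats(8, 24), cx2=st.floats(8, 24),
        r2=st.floats(2.0, 6.0),
    )
    def test_property_trace_equals_oracle(self, cy, cx, a, b, cy2, cx2, r2):
        """Traced pixels == foreground pixels with a background
        4-neighbor, on random hole-free two-ellipse masks."""
        from scipy import ndimage

        rr, cc = np.mgrid[0:32, 0:32]
        m = (((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1) | (
            ((rr - cy2) / r2) ** 2 + ((cc - cx2) / r2) ** 2 <= 1
        )
        m = ndimage.binary_fill_holes(m).astype(np.uint8)
        contours = sg.trace_boundary(m, min_size=1)
        traced = set()
        for c in contours:
            traced |= c.pixel_set()
        oracle = {tuple(p) for p in sg.boundary_pixels(m)}
        assert traced == oracle

    def test_termination_bound(self, rng):
        # ragged random blob: tracing must stop within 4 x foreground
        m = (rng.random((30, 30)) < 0.4).astype(np.uint8)
        contours = sg.trace_boundary(m, min_size=1)
        for c in contours:
            assert len(c) <= 4 * int(m.sum()) + 4


class TestStackToCloud:
    def test_slice_zero(self):
        c = sg.Contour(np.array([[r, c] for r, c in zip(range(8), range(8))]))
        cloud = sg.stack_to_cloud({0: [c]}, pixel_spacing=1.0, slice_thickness=1.5)
        assert len(cloud) == 8
        assert (cloud.points[:, 2] == 0.0).all()

    def test_slice_three_thickness(self):
        # slice 3 at thickness 1.5 mm -> z = 4.5 mm
        c = sg.Contour(np.array([[0, 0], [0, 1]]))
        cloud = sg.stack_to_cloud({3: [c]}, pixel_spacing=0.9766, slice_thickness=1.5)
        np.testing.assert_allclose(cloud.points[:, 2], 4.5)
        np.testing.assert_allclose(cloud.points[1, 0], 0.9766)  # x = col*spacing

    def test_empty(self):
        assert len(sg.stack_to_cloud({}, 1.0, 1.0)) == 0

    def test_out_of_stack_rejected(self):
        c = sg.Contour(np.array([[0, 0]]))
        with pytest.raises(ValueError, match="outside"):
            sg.stack_to_cloud({5: [c]}, 1.0, 1.0, n_slices=3)


class TestSegmentPipeline:
    def test_noiseless_dice(self, two_lumen_phantom, tight_roi):
        _, masks = sg.segment_pipeline(two_lumen_phantom.stack, tight_roi)
        assert sg.dice(masks, two_lumen_phantom.truth_masks) >= 0.99

    def test_two_contours_per_slice(self, two_lumen_phantom, tight_roi):
        cloud, _ = sg.segment_pipeline(two_lumen_phantom.stack, tight_roi)
        for s in range(two_lumen_phantom.stack.n_slices):
            sel = cloud.provenance[:, 0] == s
            assert len(set(cloud.provenance[sel, 1])) == 2

    def test_noisy_with_adaptive_smoothing(self, two_lumen_spec, tight_roi):
        import dataclasses

        spec = dataclasses.replace(two_lumen_spec, noise_sd=5.0, seed=7)
        res = sy.gen_phantom_ct(spec)
        config = sg.SegmentationConfig(adaptive=True, decrement=0.05 * 255)
        _, masks = sg.segment_pipeline(res.stack, tight_roi, config)
        assert sg.dice(masks, res.truth_masks) >= 0.95

    def test_deterministic(self, two_lumen_phantom, tight_roi):
        a, _ = sg.segment_pipeline(two_lumen_phantom.stack, tight_roi)
        b, _ = sg.segment_pipeline(two_lumen_phantom.stack, tight_roi)
        np.testing.assert_array_equal(a.points, b.points)

    def test_invariant_under_monotone_rescaling(self, two_lumen_phantom, tight_roi):
        stack = two_lumen_phantom.stack
        rescaled = sg.ImageStack(
            intensities=stack.intensities // 2,  # distinct levels stay distinct
            pixel_spacing=stack.pixel_spacing,
            slice_thickness=stack.slice_thickness,
            bit_depth=stack.bit_depth,
        )
        a, _ = sg.segment_pipeline(stack, tight_roi)
        b, _ = sg.segment_pipeline(rescaled, tight_roi)
        np.testing.assert_array_equal(a.points, b.points)

    def test_cloud_in_physical_units(self, two_lumen_phantom, tight_roi):
        cloud, masks = sg.segment_pipeline(two_lumen_phantom.stack, tight_roi)
        stack = two_lumen_phantom.stack
        # z values are multiples of the slice thickness
        z = np.unique(cloud.points[:, 2])
        np.testing.assert_allclose(
            z, np.arange(stack.n_slices) * stack.slice_thickness
        )

    def test_bad_roi_rejected(self, two_lumen_phantom):
        roi = sg.RegionOfInterest(0, 200, 0, 50)
        with pytest.raises(ValueError, match="exceeds"):
            sg.segment_pipeline(two_lumen_phantom.stack, roi)


class TestDice:
    def test_identical(self):
        m = np.eye(5, dtype=np.uint8)
        assert sg.dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert sg.dice(a, b) == 0.0
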