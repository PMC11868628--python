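"""Mask codecs, fovea heatmap, geometric fits, and disc parameters."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aigs.morphometry import (NoDiscError, SegMask, assess_mask, compute_cdrs,
                              compute_disc_indices, compute_sector_rims,
                              decode_fovea_center, decode_mask, encode_mask,
                              fit_disc_circle, fit_ellipse, fovea_heatmap)
from aigs.phantom import PhantomSpec, generate_mask


def circle_mask(side=512, r_disc=100.0, r_cup=50.0, center=(256.0, 256.0),
                cup_offset=(0.0, 0.0), fovea=(470.0, 256.0)):
    spec = PhantomSpec(image_side=side, disc_center=center,
                       disc_semi_axes=(r_disc, r_disc), disc_rotation=0.0,
                       cup_semi_axes=(r_cup, r_cup),
                       cup_center_offset=cup_offset, fovea_center=fovea)
    return generate_mask(spec)


# ---------------------------------------------------------------------------
# fovea heatmap

class TestFoveaHeatmap:
    def test_peak_is_one_at_center(self):
        hm = fovea_heatmap((51.0, 51.0), sigma=10.0, image_side=512)
        assert hm.values[51, 51] == pytest.approx(1.0)
        assert hm.values.max() == pytest.approx(1.0)

    def test_value_at_one_sigma(self):
        hm = fovea_heatmap((51.0, 51.0), sigma=10.0, image_side=512)
        assert hm.values[51, 61] == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_grid_side_is_twenty_percent_of_image(self):
        assert fovea_heatmap((50, 50), 8.0, 512).grid_side == 102
        assert fovea_heatmap((30, 30), 8.0, 320).grid_side == 64

    def test_rejects_bad_sigma_and_center(self):
        with pytest.raises(ValueError, match="sigma"):
            fovea_heatmap((10, 10), 0.0, 512)
        with pytest.raises(ValueError, match="center"):
            fovea_heatmap((500, 10), 5.0, 512)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(ax=st.floats(20, 80), ay=st.floats(20, 80),
           sigma=st.floats(3, 20))
    def test_radial_symmetry(self, ax, ay, sigma):
        hm = fovea_heatmap((ax, ay), sigma, 512)
        yy, xx = np.mgrid[0:hm.grid_side, 0:hm.grid_side]
        d2 = (xx - ax) ** 2 + (yy - ay) ** 2
        np.testing.assert_allclose(hm.values,
                                   np.exp(-d2 / (2 * sigma ** 2)))


class TestDecodeFoveaCenter:
    def test_recovers_exact_heatmap_center(self):
        hm = fovea_heatmap((48.3, 55.7), sigma=8.0, image_side=512)
        cx, cy = decode_fovea_center(hm.values)
        assert math.hypot(cx - 48.3, cy - 55.7) < 0.5

    def test_absent_on_blank_plane(self):
        assert decode_fovea_center(np.zeros((64, 64))) is None
        assert decode_fovea_center(np.full((64, 64), 0.1)) is None

    def test_robust_to_additive_noise(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            hm = fovea_heatmap((48.0, 55.0), sigma=8.0, image_side=512)
            noisy = np.clip(hm.values + rng.uniform(0, 0.1,
                                                    hm.values.shape), 0, 1)
            cx, cy = decode_fovea_center(noisy)
            errs.append(math.hypot(cx - 48.0, cy - 55.0))
        assert max(errs) < 2.0


# ---------------------------------------------------------------------------
# fits

class TestFits:
    def test_circle_fit_recovers_radius_and_center(self):
        mask = circle_mask()
        (cx, cy), r = fit_disc_circle(mask.disc)
        assert abs(r - 100.0) < 1.0
        assert math.hypot(cx - 256, cy - 256) < 1.0

    def test_circle_fit_on_ellipse_bounded_by_axes(self):
        spec = PhantomSpec(image_side=512, disc_center=(256.0, 256.0),
                           disc_semi_axes=(120.0, 80.0), disc_rotation=20.0,
                           cup_semi_axes=(40.0, 30.0),
                           fovea_center=(450.0, 256.0))
        _, r = fit_disc_circle(generate_mask(spec).disc)
        assert 80.0 < r < 120.0

    def test_circle_fit_center_accuracy_across_axis_ratios(self):
        for ratio in (1.1, 1.3, 1.5):
            spec = PhantomSpec(image_side=512, disc_center=(250.0, 260.0),
                               disc_semi_axes=(100.0, 100.0 / ratio),
                               disc_rotation=35.0,
                               cup_semi_axes=(30.0, 25.0),
                               fovea_center=(470.0, 256.0))
            (cx, cy), _ = fit_disc_circle(generate_mask(spec).disc)
            assert math.hypot(cx - 250.0, cy - 260.0) < 1.0

    def test_empty_plane_signals_no_disc(self):
        with pytest.raises(NoDiscError):
            fit_disc_circle(np.zeros((64, 64)))
        with pytest.raises(NoDiscError):
            fit_ellipse(np.zeros((64, 64)))

    def test_ellipse_fit_circle_and_axis_ratio(self):
        a, b, _ = fit_ellipse(circle_mask().disc)
        assert a / b == pytest.approx(1.0, rel=0.01)
        spec = PhantomSpec(image_side=512, disc_center=(256.0, 256.0),
                           disc_semi_axes=(120.0, 80.0), disc_rotation=0.0,
                           cup_semi_axes=(40.0, 30.0),
                           fovea_center=(450.0, 256.0))
        a, b, _ = fit_ellipse(generate_mask(spec).disc)
        assert a / b == pytest.approx(1.5, rel=0.02)

    @pytest.mark.parametrize("rot", [-60.0, -25.0, 10.0, 45.0, 80.0])
    def test_ellipse_rotation_recovered(self, rot):
        spec = PhantomSpec(image_side=512, disc_center=(256.0, 256.0),
                           disc_semi_axes=(110.0, 80.0), disc_rotation=rot,
                           cup_semi_axes=(40.0, 30.0),
                           fovea_center=(450.0, 256.0))
        _, _, fitted = fit_ellipse(generate_mask(spec).disc)
        diff = abs(fitted - rot) % 180.0
        assert min(diff, 180.0 - diff) < 3.0


# ---------------------------------------------------------------------------
# disc parameters

class TestCdrsAndIndices:
    def test_concentric_circles(self):
        cdrs = compute_cdrs(circle_mask())
        cdr_major, vcdr, hcdr, acdr, pcdr = cdrs
        for v, ref in zip((cdr_major, vcdr, hcdr, pcdr), [0.5] * 4):
            assert v == pytest.approx(ref, rel=0.02)
        assert acdr == pytest.approx(0.25, rel=0.02)

    def test_cup_equals_disc_gives_unity(self):
        mask = circle_mask(r_cup=100.0)
        assert compute_cdrs(mask) == pytest.approx((1.0,) * 5)
        sectors = compute_sector_rims(mask, (470.0, 256.0))
        assert all(v == 0.0 for v in sectors.values())

    def test_empty_cup_and_empty_disc(self):
        mask = circle_mask()
        empty_cup = SegMask(mask.disc, np.zeros_like(mask.cup), mask.fovea)
        assert compute_cdrs(empty_cup) == (0.0,) * 5
        empty_disc = SegMask(np.zeros_like(mask.disc), mask.cup, mask.fovea)
        with pytest.raises(NoDiscError):
            compute_cdrs(empty_disc)

    def test_circularity_angle_and_index(self):
        mask = circle_mask()
        idx = compute_disc_indices(mask, (470.0, 256.0))
        assert idx["circularity_disc"] >= 0.95
        assert idx["disc_fovea_angle"] == pytest.approx(0.0, abs=0.5)
        # 214 px at diameter ~200 -> index ~1.07, classed large
        assert idx["disc_size_index"] == pytest.approx(214 / 200, rel=0.02)
        assert idx["disc_size_class"] == "large"

    def test_missing_fovea_flags_dependent_fields(self):
        mask = circle_mask()
        idx = compute_disc_indices(mask, None)
        assert math.isnan(idx["disc_size_index"])
        assert idx["disc_size_class"] == "unknown"
        a = assess_mask(SegMask(mask.disc, mask.cup,
                                np.zeros_like(mask.fovea)))
        assert a.fovea_center is None
        assert math.isnan(a.ratio_t)
        assert not math.isnan(a.acdr)


class TestSectors:
    def test_quadrants_partition_rim(self):
        mask = circle_mask()
        sectors = compute_sector_rims(mask, (470.0, 256.0))
        acdr = mask.cup_bin.sum() / mask.disc_bin.sum()
        total = sum(sectors[f"ratio_{k}"] for k in ("s", "i", "n", "t"))
        assert total == pytest.approx(1 - acdr, rel=0.01)
        for k in ("s", "i", "n", "t"):
            assert sectors[f"ratio_{k}"] == pytest.approx((1 - acdr) / 4,
                                                          rel=0.02)

    def test_nasally_shifted_cup_thins_nasal_rim(self):
        # fovea to the right -> nasal side is the left; shift cup left
        mask = circle_mask(cup_offset=(-30.0, 0.0))
        sectors = compute_sector_rims(mask, (470.0, 256.0))
        assert sectors["ratio_t"] > sectors["ratio_n"]

    def test_translation_and_rotation_invariance(self):
        base = circle_mask(center=(200.0, 200.0), cup_offset=(15.0, -10.0),
                           fovea=(420.0, 200.0))
        moved = circle_mask(center=(250.0, 260.0), cup_offset=(15.0, -10.0),
                            fovea=(470.0, 260.0))
        # fovea sits to the right of the disc: a left-eye geometry
        a1 = assess_mask(base, fovea_center=(420.0, 200.0),
                         laterality="left")
        a2 = assess_mask(moved, fovea_center=(470.0, 260.0),
                         laterality="left")
        # 90-degree rotation with the frame re-derived from the new fovea
        rot = SegMask(np.rot90(base.disc), np.rot90(base.cup),
                      np.rot90(base.fovea))
        # np.rot90 maps (x, y) -> (y, side-1-x)
        a3 = assess_mask(rot, fovea_center=(200.0, 512 - 1 - 420.0),
                         laterality="left")
        for f in ("vcdr", "hcdr", "acdr", "nrra_da", "ratio_s", "ratio_i",
                  "ratio_n", "ratio_t", "ratio_it", "ratio_st"):
            v1, v2, v3 = (getattr(a, f) for a in (a1, a2, a3))
            assert v2 == pytest.approx(v1, rel=0.01, abs=1e-3)
            if f in ("vcdr", "hcdr"):        # axes swap under rotation
                continue
            assert v3 == pytest.approx(v1, rel=0.01, abs=1e-3)


# ---------------------------------------------------------------------------
# PNG codec

class TestMaskCodec:
    def test_round_trip_both_dialects(self, phantom_scene):
        _, _, mask, _ = phantom_scene
        for dialect in ("training", "output"):
            rgb = encode_mask(mask, dialect)
            back = decode_mask(rgb)
            np.testing.assert_array_equal(back.disc_bin, mask.disc_bin)
            np.testing.assert_array_equal(back.cup_bin, mask.cup_bin)
            np.testing.assert_array_equal(back.fovea_bin, mask.fovea_bin)

    def test_dialects_decode_to_identical_masks(self, phantom_scene):
        _, _, mask, _ = phantom_scene
        a = decode_mask(encode_mask(mask, "training"))
        b = decode_mask(encode_mask(mask, "output"))
        np.testing.assert_array_equal(a.disc_bin, b.disc_bin)
        np.testing.assert_array_equal(a.cup_bin, b.cup_bin)

    def test_black_png_decodes_to_empty_planes(self):
        m = decode_mask(np.zeros((32, 32, 3), np.uint8))
        assert not m.disc_bin.any()
        with pytest.raises(NoDiscError):
            assess_mask(m)

    def test_unknown_colors_rejected_with_count(self):
        rgb = np.zeros((8, 8, 3), np.uint8)
        rgb[:2, :2] = (0, 0, 255)              # blue: not a mask color
        with pytest.raises(ValueError, match="4 pixels"):
            decode_mask(rgb)

    def test_unknown_dialect_rejected(self, phantom_scene):
        _, _, mask, _ = phantom_scene
        with pytest.raises(ValueError, match="dialect"):
            encode_mask(mask, "other")
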