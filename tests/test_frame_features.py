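"""Per-frame geometric features against analytic oracles."""

import numpy as np
import pytest

from stentexpand.frame_features import (
    CALC_FEATURE_NAMES,
    calc_arc_angle,
    calc_features_2d,
    calc_thickness_depth,
    compute_frame_features,
    lumen_features_2d,
)
from stentexpand.pullback import FrameMask, PullbackError

from conftest import make_sector_lesion


def disk_frame(radius_mm=2.0, pixel_spacing=0.02, grid=None):
    g = grid or int(2 * radius_mm / pixel_spacing) + 40
    c = (g - 1) / 2.0
    yy, xx = np.mgrid[0:g, 0:g]
    R = np.hypot(yy - c, xx - c) * pixel_spacing
    labels = (R <= radius_mm).astype(np.uint8)
    return FrameMask(labels, pixel_spacing)


def square_frame(side_mm=2.0, pixel_spacing=0.02):
    n = int(round(side_mm / pixel_spacing))
    g = n + 40
    labels = np.zeros((g, g), dtype=np.uint8)
    labels[20 : 20 + n, 20 : 20 + n] = 1
    return FrameMask(labels, pixel_spacing)


def annular_sector_frame(
    ang_lo, ang_hi, r_in, r_out, lumen_radius=1.0, pixel_spacing=0.02
):
    """Lumen disk + one annular sector deposit between polar angles
    [ang_lo, ang_hi] (deg, may wrap) and radii [r_in, r_out] (mm)."""
    g = int(2 * (r_out + 0.5) / pixel_spacing)
    c = (g - 1) / 2.0
    yy, xx = np.mgrid[0:g, 0:g]
    R = np.hypot(yy - c, xx - c) * pixel_spacing
    PHI = np.degrees(np.arctan2(yy - c, xx - c)) % 360.0
    labels = (R <= lumen_radius).astype(np.uint8)
    span = (ang_hi - ang_lo) % 360.0
    in_sector = ((PHI - ang_lo) % 360.0) <= span
    labels[in_sector & (R >= r_in) & (R <= r_out)] = 2
    return FrameMask(labels, pixel_spacing)


class TestLumenFeatures:
    def test_digitized_disk_matches_circle_identities(self):
        f = disk_frame(radius_mm=2.0)
        area_true = np.pi * 4.0
        out = lumen_features_2d(f, 2 * area_true, 2 * area_true)
        assert out["lumen_area"] == pytest.approx(area_true, rel=0.03)
        assert out["lumen_circularity"] == pytest.approx(1.0, abs=0.03)
        assert out["lumen_eccentricity"] == pytest.approx(0.0, abs=0.1)
        assert out["lumen_solidity"] == pytest.approx(1.0, abs=0.03)
        assert out["lumen_pct_area_stenosis"] == pytest.approx(50.0, rel=0.03)
        assert out["lumen_major_axis"] == pytest.approx(4.0, rel=0.03)

    def test_digitized_square_circularity_and_extent(self):
        f = square_frame(side_mm=2.0)
        out = lumen_features_2d(f, 8.0, 8.0)
        assert out["lumen_area"] == pytest.approx(4.0, rel=0.03)
        assert out["lumen_circularity"] == pytest.approx(np.pi / 4.0, rel=0.03)
        assert out["lumen_extent"] == pytest.approx(1.0, abs=0.02)

    def test_stenosis_percentage_and_threshold_indicators(self):
        f = disk_frame(radius_mm=1.0)
        area = lumen_features_2d(f, 1.0, 1.0)["lumen_area"]
        # choose references so that mean reference = 2 x lumen area exactly
        out = lumen_features_2d(f, 2 * area, 2 * area)
        assert out["lumen_pct_area_stenosis"] == pytest.approx(50.0, abs=1e-9)
        assert out["lumen_area_lt_0.5ref"] == 0.0  # not strictly below half
        assert out["lumen_area_lt_0.7ref"] == 1.0
        assert out["lumen_area_lt_0.9ref"] == 1.0

    def test_no_lumen_or_bad_refs_raise(self):
        empty = FrameMask(np.zeros((8, 8), dtype=np.uint8), 0.1)
        with pytest.raises(PullbackError):
            lumen_features_2d(empty, 4.0, 4.0)
        with pytest.raises(PullbackError):
            lumen_features_2d(disk_frame(1.0), -1.0, 4.0)

    def test_features_converge_with_resolution(self):
        errors = []
        for px in (0.04, 0.02):
            out = lumen_features_2d(disk_frame(2.0, pixel_spacing=px), 8.0, 8.0)
            errors.append(abs(out["lumen_area"] - 4 * np.pi))
        assert errors[1] < errors[0]


class TestCalcAngle:
    def test_sector_angle(self):
        f = annular_sector_frame(0, 90, 1.2, 1.7)
        out = calc_features_2d(f)
        assert out["calc_max_arc_angle"] == pytest.approx(90.0, abs=2.0)

    def test_full_ring_is_360(self):
        f = annular_sector_frame(0, 359.999, 1.2, 1.7)
        out = calc_features_2d(f)
        assert out["calc_max_arc_angle"] == pytest.approx(360.0, abs=2.0)

    def test_wraparound_sector_measures_small_span(self):
        f = annular_sector_frame(170 + 180, 190 + 180, 1.2, 1.7)  # 350..10 deg
        out = calc_features_2d(f)
        assert out["calc_max_arc_angle"] == pytest.approx(20.0, abs=2.0)

    def test_empty_region_raises(self):
        with pytest.raises(PullbackError):
            calc_arc_angle(np.empty((0, 2)), (0.0, 0.0))


class TestThicknessDepth:
    def test_sector_thickness_and_depth(self):
        f = annular_sector_frame(30, 120, r_in=1.1, r_out=1.6, lumen_radius=1.0)
        t, d = calc_thickness_depth(
            f.calc_mask, f.lumen_mask, ((f.labels.shape[0] - 1) / 2.0,) * 2, 0.02
        )
        assert t == pytest.approx(0.5, abs=0.03)
        assert d == pytest.approx(0.1, abs=0.03)

    def test_deposit_touching_lumen_has_zero_depth(self):
        f = annular_sector_frame(30, 120, r_in=1.0, r_out=1.5, lumen_radius=1.0)
        _, d = calc_thickness_depth(
            f.calc_mask, f.lumen_mask, ((f.labels.shape[0] - 1) / 2.0,) * 2, 0.02
        )
        assert d == pytest.approx(0.0, abs=0.03)

    def test_empty_deposit_raises(self):
        f = disk_frame(1.0)
        with pytest.raises(PullbackError):
            calc_thickness_depth(np.zeros_like(f.lumen_mask), f.lumen_mask, (5, 5), 0.02)


class TestCalcFeatures2D:
    def test_frame_without_calcification_is_all_zero(self):
        out = calc_features_2d(disk_frame(1.5))
        assert set(out) == set(CALC_FEATURE_NAMES)
        assert all(v == 0.0 for v in out.values())

    def test_circular_deposit_is_round(self):
        f = disk_frame(1.0, pixel_spacing=0.02, grid=240)
        labels = f.labels.copy()
        g = labels.shape[0]
        yy, xx = np.mgrid[0:g, 0:g]
        R = np.hypot(yy - (g - 1) / 2 - 60, xx - (g - 1) / 2) * 0.02
        labels[R <= 0.3] = 2
        out = calc_features_2d(FrameMask(labels, 0.02))
        assert out["calc_stretch_ratio"] == pytest.approx(1.0, abs=0.05)
        assert out["calc_eccentricity"] < 0.35

    def test_two_deposits_sum_area_and_max_angle(self):
        f = annular_sector_frame(0, 60, 1.2, 1.7)
        labels = f.labels.copy()
        g = labels.shape[0]
        c = (g - 1) / 2.0
        yy, xx = np.mgrid[0:g, 0:g]
        R = np.hypot(yy - c, xx - c) * 0.02
        PHI = np.degrees(np.arctan2(yy - c, xx - c)) % 360.0
        labels[(PHI >= 180) & (PHI <= 210) & (R >= 1.2) & (R <= 1.7)] = 2
        both = calc_features_2d(FrameMask(labels, 0.02))
        first = calc_features_2d(f)
        second_area = both["calc_area"] - first["calc_area"]
        assert second_area > 0
        assert both["calc_max_arc_angle"] == pytest.approx(60.0, abs=2.0)
        assert both["calc_area"] == pytest.approx(
            first["calc_area"] * 1.5, rel=0.05
        )  # 30 deg sector has half the area of the 60 deg one

    def test_rotation_invariance(self):
        _, _, lesion = make_sector_lesion(
            peak_angle=110, peak_thickness=0.6, depth=0.1, center_angle=30,
            pixel_spacing=0.04, grid_size=256, n_frames=7,
        )
        f = lesion.frames[3]
        rot = FrameMask(np.rot90(f.labels).copy(), f.pixel_spacing)
        a = compute_frame_features(f, 8.0, 8.0)
        b = compute_frame_features(rot, 8.0, 8.0)
        for key in (
            "lumen_area",
            "calc_area",
            "calc_max_arc_angle",
            "calc_max_thickness",
            "calc_max_depth",
            "lumen_circularity",
            "lumen_solidity",
        ):
            assert b[key] == pytest.approx(a[key], rel=0.02, abs=0.02), key

    def test_calc_features_zero_iff_no_calc_pixels(self, small_lesion):
        for f in small_lesion.frames[::7]:
            out = calc_features_2d(f)
            if f.calc_mask.any():
                assert out["calc_area"] > 0
            else:
                assert all(v == 0.0 for v in out.values())
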