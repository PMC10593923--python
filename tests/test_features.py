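"""Feature-matrix assembly, aggregation statistics, normalization, CLE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stentexpand.features import (
    CLE_COLUMNS,
    FeatureMatrix,
    WindowConfig,
    aggregate_stats,
    build_frame_matrix,
    build_lesion_matrix,
    build_segmental_matrix,
    compute_frame_table,
    normalize,
    select_cle,
    stack_matrices,
)
from stentexpand.frame_features import FRAME_FEATURE_NAMES
from stentexpand.pullback import PullbackError
from stentexpand.synth import DepositSpec, LesionGeometry, SyntheticConfig, render_lesion


class TestAggregateStats:
    def test_constant_sequence(self):
        out = aggregate_stats([2, 2, 2])
        assert out["min"] == out["max"] == out["mean"] == out["median"] == 2
        assert out["sd"] == out["skewness"] == out["kurtosis"] == 0.0

    def test_hand_computed_moments(self):
        out = aggregate_stats([1, 2, 3, 4])
        assert out["mean"] == pytest.approx(2.5)
        assert out["median"] == pytest.approx(2.5)
        assert out["sd"] == pytest.approx(1.2910, abs=1e-4)  # sample SD
        assert out["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_right_tail_has_positive_skew(self):
        assert aggregate_stats([0, 0, 0, 10])["skewness"] > 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_stats([])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=40))
    def test_order_statistics_bracket_the_mean(self, values):
        out = aggregate_stats(values)
        assert out["min"] - 1e-9 <= out["mean"] <= out["max"] + 1e-9
        assert out["sd"] >= 0


@pytest.fixture(scope="module")
def segment_lesion():
    """120-frame pullback whose stented segment spans 100 frames."""
    cfg = SyntheticConfig.fast()
    geom = LesionGeometry(
        baseline_radius_mm=1.6,
        stenosis_depth_frac=0.35,
        stenosis_center_frame=60,
        stenosis_sigma_mm=4.0,
        deposits=[
            DepositSpec(center_frame=55, length_mm=8.0, peak_angle_deg=200.0,
                        peak_thickness_mm=1.0, depth_mm=0.05, center_angle_deg=120.0)
        ],
        phenotype="protrusion",
        taper_ratio=1.2,
    )
    return render_lesion(cfg, geom, "seg", noise_rng=np.random.default_rng(3))


@pytest.fixture(scope="module")
def segment_table(segment_lesion):
    return compute_frame_table(segment_lesion)


class TestSegmentalMatrix:
    def test_row_count_and_centers_for_full_windows(self, segment_lesion, segment_table):
        m = build_segmental_matrix(segment_lesion, WindowConfig(31), segment_table)
        n = segment_lesion.n_stent_frames
        assert n == 100
        assert len(m) == n - 31 + 1 == 70
        centers = m.X.index.get_level_values("frame")
        lo, hi = segment_lesion.stent_segment
        assert centers[0] == lo + 15
        assert centers[-1] == hi - 15

    def test_168_aggregated_columns(self, segment_lesion, segment_table):
        for L in (3, 31):
            m = build_segmental_matrix(segment_lesion, WindowConfig(L), segment_table)
            agg = [c for c in m.X.columns if "__" in c]
            assert len(agg) == 24 * 7 == 168

    def test_constant_window_mean_equals_value_and_zero_sd(self, segment_lesion, segment_table):
        m = build_segmental_matrix(segment_lesion, WindowConfig(3), segment_table)
        # indicator columns are piecewise constant; wherever a window is
        # constant the SD must be exactly 0 and the mean the common value
        col = "lumen_area_lt_0.5ref"
        vals = segment_table[col].to_numpy()
        win = np.lib.stride_tricks.sliding_window_view(vals, 3)
        const = np.ptp(win, axis=1) == 0
        assert (m.X[f"{col}__sd"].to_numpy()[const] == 0).all()
        np.testing.assert_allclose(
            m.X[f"{col}__mean"].to_numpy()[const], win[const, 0]
        )

    def test_target_is_center_frame_post_area(self, segment_lesion, segment_table):
        m = build_segmental_matrix(segment_lesion, WindowConfig(31), segment_table)
        lo, _ = segment_lesion.stent_segment
        post = segment_lesion.post_stent_area
        centers = m.X.index.get_level_values("frame")
        np.testing.assert_allclose(m.y.to_numpy(), post[centers - lo])

    def test_window_longer_than_segment_warns_and_is_empty(self, segment_lesion, segment_table):
        with pytest.warns(UserWarning, match="shorter than"):
            m = build_segmental_matrix(segment_lesion, WindowConfig(101), segment_table)
        assert len(m) == 0

    def test_assembly_is_deterministic(self, segment_lesion, segment_table):
        a = build_segmental_matrix(segment_lesion, WindowConfig(15), segment_table)
        b = build_segmental_matrix(segment_lesion, WindowConfig(15), segment_table)
        pd.testing.assert_frame_equal(a.X, b.X)

    def test_window_config_validation(self):
        with pytest.raises(ValueError):
            WindowConfig(4)
        with pytest.raises(ValueError):
            WindowConfig(3, stride=0)


class TestFrameAndLesionMatrices:
    def test_frame_matrix_one_row_per_stented_frame(self, segment_lesion, segment_table):
        m = build_frame_matrix(segment_lesion, segment_table)
        assert len(m) == segment_lesion.n_stent_frames
        assert list(m.X.columns) == FRAME_FEATURE_NAMES

    def test_lesion_matrix_target_and_phenotype_onehot(self, segment_lesion):
        m = build_lesion_matrix([segment_lesion], include_phenotype=True)
        onehot = m.X[[f"phenotype_{k}" for k in ("nodule", "protrusion", "sheet")]]
        np.testing.assert_allclose(onehot.sum(axis=1), 1.0)
        assert m.X.loc["seg", "phenotype_protrusion"] == 1.0
        assert m.y.loc["seg"] == pytest.approx(segment_lesion.post_stent_area.min())

    def test_lesion_matrix_requires_phenotype_when_asked(self, segment_lesion):
        import dataclasses

        bare = dataclasses.replace(segment_lesion, phenotype=None)
        with pytest.raises(PullbackError):
            build_lesion_matrix([bare], include_phenotype=True)


class TestNormalize:
    def make_matrix(self):
        X = pd.DataFrame(
            {
                "lumen_extent__mean": [0.2, 0.5, 0.8, 0.9],
                "lumen_area__mean": [4.0, 5.0, 6.0, 7.0],
                "calc_max_arc_angle__mean": [0.0, 90.0, 180.0, 270.0],
                "flat__mean": [1.0, 1.0, 1.0, 1.0],
            },
            index=pd.MultiIndex.from_product(
                [["A"], [0, 1, 2, 3]], names=["lesion_id", "frame"]
            ),
        )
        return FeatureMatrix(X=X, groups=pd.Series("A", index=X.index))

    def test_minmax_on_training_rows_only(self):
        m = self.make_matrix()
        fit_rows = m.X.index[:3]
        with pytest.warns(UserWarning, match="zero range"):
            out = normalize(m, fit_rows)
        col = out.X["lumen_extent__mean"]
        assert col.iloc[0] == pytest.approx(0.0)
        assert col.iloc[2] == pytest.approx(1.0)
        # held-out row beyond the training range passes through unclipped
        assert col.iloc[3] > 1.0
        assert out.normalization["lumen_extent__mean"] == ("minmax", 0.2, 0.8)

    def test_absolute_columns_untouched(self):
        m = self.make_matrix()
        with pytest.warns(UserWarning):
            out = normalize(m)
        np.testing.assert_allclose(out.X["lumen_area__mean"], m.X["lumen_area__mean"])
        assert out.normalization["lumen_area__mean"] == "absolute"

    def test_zero_range_column_set_to_zero(self):
        m = self.make_matrix()
        with pytest.warns(UserWarning, match="zero range"):
            out = normalize(m)
        assert (out.X["flat__mean"] == 0.0).all()


class TestCLE:
    def test_segmental_matrix_yields_twenty_columns(self, segment_lesion, segment_table):
        m = build_segmental_matrix(segment_lesion, WindowConfig(31), segment_table)
        cle = select_cle(m)
        assert cle.columns == CLE_COLUMNS
        assert len(cle.columns) == 20

    def test_lesion_matrix_supports_cle(self, segment_lesion):
        m = build_lesion_matrix([segment_lesion])
        assert select_cle(m).columns == CLE_COLUMNS

    def test_idempotent(self, segment_lesion, segment_table):
        m = build_segmental_matrix(segment_lesion, WindowConfig(31), segment_table)
        once = select_cle(m)
        twice = select_cle(once)
        pd.testing.assert_frame_equal(once.X, twice.X)

    def test_frame_matrix_rejected_with_named_column(self, segment_lesion, segment_table):
        m = build_frame_matrix(segment_lesion, segment_table)
        with pytest.raises(KeyError, match="calc_max_arc_angle__mean"):
            select_cle(m)


def test_stack_matrices_concatenates_rows(segment_lesion, segment_table):
    a = build_frame_matrix(segment_lesion, segment_table)
    stacked = stack_matrices([a, a])
    assert len(stacked) == 2 * len(a)
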