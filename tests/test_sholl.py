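"""Grid-line placement, intersection counting and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mfcsholl import PipelineConfig
from mfcsholl.alignment import AlignmentResult
from mfcsholl.errors import NormalizationError, ValidationError
from mfcsholl.sholl import (ShollProfile, count_intersections, grid_columns,
                            normalize_profile, outermost_gridline)


def _alignment(exit_left=400, exit_right=1000, left0=0, right1=2000):
    return AlignmentResult(angle_deg=0.0,
                           left_zone=(left0, exit_left),
                           right_zone=(exit_right, right1),
                           groove_band=(exit_left, exit_right))


class TestGridColumns:
    def test_right_side_unit_pixels(self):
        cfg = PipelineConfig(pixel_size_um=1.0)
        cols, dists = grid_columns(_alignment(), "right", cfg)
        assert cols[0] == 1100 and dists[0] == 100.0
        assert list(cols[:3]) == [1100, 1150, 1200]
        assert cols[-1] == 1950  # the 2000-px line falls outside [1000, 2000)
        assert np.all(np.diff(dists) == 50.0)

    def test_left_side_mirrors_distance_axis(self):
        cfg = PipelineConfig(pixel_size_um=1.0)
        cols, dists = grid_columns(_alignment(), "left", cfg)
        assert list(cols[:3]) == [300, 250, 200]
        assert list(dists[:3]) == [100.0, 150.0, 200.0]
        assert cols[-1] == 0  # half-open zone keeps column 0

    def test_rounding_half_away_from_exit(self):
        # 100 um at 1.3 um/px = 76.92 px -> 77
        cfg = PipelineConfig(pixel_size_um=1.3)
        cols, _ = grid_columns(_alignment(), "right", cfg)
        assert cols[0] == 1000 + 77
        cols_l, _ = grid_columns(_alignment(), "left", cfg)
        assert cols_l[0] == 400 - 77

    def test_first_line_configurable_to_50um(self):
        cfg = PipelineConfig(pixel_size_um=1.0, first_line_um=50.0,
                             omit_debris_line=False)
        cols, dists = grid_columns(_alignment(), "right", cfg)
        assert cols[0] == 1050 and dists[0] == 50.0

    def test_too_narrow_zone_yields_empty_profile_with_warning(self):
        cfg = PipelineConfig(pixel_size_um=1.0)
        narrow = AlignmentResult(0.0, (960, 1000), (1000, 1040), (1000, 1000))
        with pytest.warns(UserWarning):
            cols, dists = grid_columns(narrow, "right", cfg)
        assert cols.size == 0 and dists.size == 0


class TestCountIntersections:
    def test_empty_skeleton_counts_zero(self):
        skel = np.zeros((50, 60), dtype=bool)
        assert list(count_intersections(skel, [10, 20], "runs")) == [0, 0]
        assert list(count_intersections(skel, [10, 20], "pixels")) == [0, 0]

    def test_three_transversal_chains(self):
        skel = np.zeros((60, 80), dtype=bool)
        for r in (10, 30, 50):
            skel[r, 5:75] = True
        for mode in ("runs", "pixels"):
            assert count_intersections(skel, [40], mode)[0] == 3

    def test_vertical_run_collapses_in_runs_mode(self):
        # one diagonal chain crossing through 1 px plus a 7-px vertical run
        skel = np.zeros((40, 40), dtype=bool)
        rr = np.arange(30, 36)
        skel[rr, rr - 10]  = True      # diagonal; crosses column 22 in one pixel
        skel[5:12, 22] = True          # vertical chain lying along the column
        counts_px = count_intersections(skel, [22], "pixels")[0]
        counts_runs = count_intersections(skel, [22], "runs")[0]
        assert counts_px == 8
        assert counts_runs == 2

    def test_column_outside_raster_rejected(self):
        with pytest.raises(ValidationError):
            count_intersections(np.zeros((10, 10), dtype=bool), [10], "runs")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(arrays(bool, (24, 17), elements=st.booleans()))
    def test_pixels_mode_dominates_runs_mode(self, skel):
        cols = np.arange(17)
        px = count_intersections(skel, cols, "pixels")
        runs = count_intersections(skel, cols, "runs")
        assert (px >= runs).all()


class TestNormalization:
    def test_division_by_soma_count(self):
        p = normalize_profile([100.0, 150.0, 200.0], [10, 5, 0], 100, "right")
        assert list(p.normalized) == [0.10, 0.05, 0.0]

    def test_soma_count_one_is_identity(self):
        p = normalize_profile([100.0, 150.0], [7, 3], 1, "left")
        np.testing.assert_array_equal(p.normalized, p.intersections)

    @pytest.mark.parametrize("bad", [0, -5, None])
    def test_nonpositive_soma_count_rejected(self, bad):
        with pytest.raises(NormalizationError):
            normalize_profile([100.0], [3], bad, "right")

    def test_normalized_recovers_counts_exactly(self):
        # normalized is the correctly rounded quotient, so rounding the
        # product recovers the integer counts without error
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(1, 500))
            counts = rng.integers(0, 60, size=6)
            p = normalize_profile(np.arange(100.0, 400.0, 50.0), counts, n, "right")
            np.testing.assert_array_equal(p.normalized,
                                          p.intersections / p.soma_count)
            recovered = np.round(p.normalized * p.soma_count).astype(int)
            np.testing.assert_array_equal(recovered, p.intersections)
            assert np.abs(p.normalized * p.soma_count
                          - p.intersections).max() <= 1e-9

    def test_doubling_soma_count_halves_normalized(self):
        counts = [12, 6, 4]
        a = normalize_profile([100.0, 150.0, 200.0], counts, 50, "right")
        b = normalize_profile([100.0, 150.0, 200.0], counts, 100, "right")
        np.testing.assert_allclose(b.normalized, a.normalized / 2)


class TestProfileInvariants:
    def test_irregular_spacing_rejected(self):
        with pytest.raises(ValidationError):
            ShollProfile(distances_um=[100.0, 150.0, 260.0],
                         intersections=[1, 1, 1], soma_count=10, side="right")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ShollProfile(distances_um=[100.0], intersections=[-1],
                         soma_count=10, side="right")


class TestOutermostGridline:
    @pytest.mark.parametrize("counts,dists,expected", [
        ([4, 2, 1, 0, 0], [100, 150, 200, 250, 300], 200.0),
        ([0, 0, 0], [100, 150, 200], None),
        ([0, 0, 3], [100, 150, 200], 200.0),
    ])
    def test_definition(self, counts, dists, expected):
        p = ShollProfile(distances_um=np.array(dists, float),
                         intersections=counts, soma_count=10, side="right")
        assert outermost_gridline(p) == expected
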