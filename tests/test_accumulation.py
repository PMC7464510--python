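"""Heat-map construction, edge correction, LUT rendering, ROI series."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casakit import (
    AccumulationParams,
    accumulation_map,
    apply_jet_lut,
    boundary_fraction,
    boundary_fraction_map,
    correct_counts,
    heatmap_video,
    jet_lut,
    local_counts,
    roi_timeseries,
    scale_to_display,
)

from conftest import particle_set


def brute_force_counts(points, width, height, R):
    """Per-pixel double loop: the independent counting oracle."""
    out = np.zeros((height, width), dtype=int)
    for y in range(height):
        for x in range(width):
            for px, py in points:
                if (px - x) ** 2 + (py - y) ** 2 <= R * R:
                    out[y, x] += 1
    return out


class TestLocalCounts:
    def test_empty_particleset_gives_zero_matrix(self):
        ps = particle_set([], 30, 20)
        assert not local_counts(ps, 5.0).any()

    def test_single_point_geometry(self):
        ps = particle_set([(50.0, 50.0)], 100, 100)
        m = local_counts(ps, 10.0)
        assert m[50, 50] == 1
        assert m[50, 58] == 1      # distance 8 ≤ 10
        assert m[50, 61] == 0      # distance 11 > 10
        assert m[50, 60] == 1      # boundary: distance exactly 10 counts

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        w, h, n = 48, 40, 25
        pts = np.column_stack([r.uniform(0, w - 1, n), r.uniform(0, h - 1, n)])
        ps = particle_set(pts, w, h)
        assert (local_counts(ps, 7.0) == brute_force_counts(pts, w, h, 7.0)).all()

    def test_count_conservation(self, rng):
        """Σ_pixels raw = Σ_particles (#pixels within R of that particle)."""
        w, h, R = 40, 32, 6.0
        pts = np.column_stack([rng.uniform(0, w - 1, 15), rng.uniform(0, h - 1, 15)])
        total = local_counts(particle_set(pts, w, h), R).sum()
        per_particle = 0
        ys, xs = np.mgrid[0:h, 0:w]
        for px, py in pts:
            per_particle += ((xs - px) ** 2 + (ys - py) ** 2 <= R * R).sum()
        assert total == per_particle


class TestBoundaryFraction:
    def test_interior_pixel_is_exactly_one(self):
        assert boundary_fraction((50, 50), (100, 100), 10.0) == 1.0

    @staticmethod
    def raster_tolerance(R):
        """One boundary row/column of the rasterized disk: the discretization
        error of quarter/half-disk fractions is bounded by its weight."""
        k = int(R)
        dy, dx = np.mgrid[-k : k + 1, -k : k + 1]
        n = (dy * dy + dx * dx <= R * R).sum()
        return (2 * R + 2) / n

    def test_corner_is_quarter_disk(self):
        f = boundary_fraction((0, 0), (100, 100), 10.0)
        assert f == pytest.approx(0.25, abs=self.raster_tolerance(10.0))

    def test_edge_midpoint_is_half_disk(self):
        f = boundary_fraction((50, 0), (100, 100), 10.0)
        assert f == pytest.approx(0.5, abs=self.raster_tolerance(10.0))

    def test_fraction_converges_to_geometry_with_radius(self):
        # rasterization error shrinks as R grows
        assert boundary_fraction((0, 0), (300, 300), 60.0) == pytest.approx(0.25, abs=0.01)

    def test_map_matches_per_pixel_oracle(self):
        shape, R = (14, 17), 5.0
        fmap = boundary_fraction_map(shape, R)
        for y in range(shape[0]):
            for x in range(shape[1]):
                assert fmap[y, x] == pytest.approx(
                    boundary_fraction((x, y), shape, R), abs=1e-9
                )

    def test_outside_pixel_rejected(self):
        with pytest.raises(ValueError):
            boundary_fraction((200, 0), (100, 100), 5.0)


class TestCorrectCounts:
    def test_examples(self):
        raw = np.array([[4.0, 2.0, 0.0]])
        frac = np.array([[1.0, 0.25, 0.5]])
        assert correct_counts(raw, frac).tolist() == [[4.0, 8.0, 0.0]]

    def test_all_zero_raw(self):
        out = correct_counts(np.zeros((3, 3)), np.full((3, 3), 0.7))
        assert not out.any()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            correct_counts(np.zeros((2, 2)), np.ones((3, 3)))


class TestScaleToDisplay:
    def test_extremes_and_half_up_rounding(self):
        m = np.array([[0.0, 5.0, 10.0]])
        s = scale_to_display(m)
        assert s.tolist() == [[0, 128, 255]]  # 127.5 rounds half-up to 128

    def test_constant_map_is_all_zero(self):
        assert not scale_to_display(np.full((4, 4), 3.7)).any()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16), h=st.integers(1, 12), w=st.integers(2, 12))
    def test_nonconstant_map_attains_both_ends(self, seed, h, w):
        r = np.random.default_rng(seed)
        m = r.normal(size=(h, w))
        if np.ptp(m) == 0:
            return
        s = scale_to_display(m)
        assert s.min() == 0 and s.max() == 255


class TestJetLut:
    def test_table_shape_and_identity_ramp(self):
        lut = jet_lut()
        assert lut.shape == (256, 3) and lut.dtype == np.uint8
        ramp = np.arange(256, dtype=np.uint8).reshape(16, 16)
        rendered = apply_jet_lut(ramp)
        assert (rendered.reshape(256, 3) == lut).all()

    def test_cold_is_blue_warm_is_red(self):
        lut = jet_lut()
        assert lut[0, 2] > lut[0, 0]       # index 0: blue dominates
        assert lut[255, 0] > lut[255, 2]   # index 255: red dominates
        assert (lut[128] == [255, 255, 255]).tolist().count(True) < 3  # mid ≠ white

    def test_uniform_maps(self):
        lut = jet_lut()
        cold = apply_jet_lut(np.zeros((3, 3), dtype=np.uint8))
        warm = apply_jet_lut(np.full((3, 3), 255, dtype=np.uint8))
        assert (cold == lut[0]).all() and (warm == lut[255]).all()


class TestHeatmapVideo:
    def make_frames(self, seed, n_frames, w=32, h=32, n=10):
        r = np.random.default_rng(seed)
        return [
            particle_set(
                np.column_stack([r.uniform(0, w - 1, n), r.uniform(0, h - 1, n)]),
                w, h, frame_index=i,
            )
            for i in range(n_frames)
        ]

    def test_f1_w1_equals_still_path(self):
        frames = self.make_frames(3, 4)
        params = AccumulationParams(radius_R=5.0)
        maps = heatmap_video(frames, params)
        for fr, m in zip(frames, maps):
            still = accumulation_map(fr, params)
            assert (m.corrected == still.corrected).all()
            assert (m.scaled == still.scaled).all()

    def test_sampling_interpolation_weights(self):
        frames = self.make_frames(7, 6)
        params = AccumulationParams(radius_R=5.0, sampling_factor_f=5)
        maps = heatmap_video(frames, params)
        A = accumulation_map(frames[0], params).corrected
        B = accumulation_map(frames[5], params).corrected
        assert np.allclose(maps[2].corrected, 0.6 * A + 0.4 * B)

    def test_window_blocks_share_center_value(self):
        frames = self.make_frames(11, 1, w=30, h=30)
        params = AccumulationParams(radius_R=5.0, window_W=3)
        m = heatmap_video(frames, params)[0]
        full = accumulation_map(frames[0], AccumulationParams(radius_R=5.0))
        for by in range(0, 30, 3):
            for bx in range(0, 30, 3):
                block = m.corrected[by : by + 3, bx : bx + 3]
                assert (block == block[0, 0]).all()
                assert block[0, 0] == full.corrected[by + 1, bx + 1]

    def test_raw_vs_corrected_inequality(self):
        frames = self.make_frames(5, 1)
        m = heatmap_video(frames, AccumulationParams(radius_R=8.0))[0]
        assert (m.corrected >= m.raw_counts - 1e-12).all()

    def test_param_validation(self):
        with pytest.raises(ValueError):
            AccumulationParams(radius_R=0.0)
        with pytest.raises(ValueError):
            AccumulationParams(radius_R=5.0, window_W=2)
        with pytest.raises(ValueError):
            AccumulationParams(radius_R=5.0, sampling_factor_f=0)


class TestRoiTimeseries:
    def test_all_inside(self):
        ps = particle_set([(50, 50), (52, 48), (49, 51)], 100, 100)
        s = roi_timeseries([ps], (50, 50), 10.0)
        row = s.table.iloc[0]
        assert (row.n_r, row.n_2r, row.n_3r, row.N) == (3, 3, 3, 3)
        assert row.pct_r == 100.0

    def test_boundary_particle_counts_inside(self):
        ps = particle_set([(60.0, 50.0)], 100, 100)  # distance exactly 10
        s = roi_timeseries([ps], (50, 50), 10.0)
        assert s.table.iloc[0].n_r == 1

    def test_nested_monotonicity_random(self, rng):
        frames = []
        for i in range(5):
            pts = np.column_stack([rng.uniform(0, 99, 40), rng.uniform(0, 99, 40)])
            frames.append(particle_set(pts, 100, 100, frame_index=i))
        t = roi_timeseries(frames, (30, 60), 12.0).table
        assert (t.n_r <= t.n_2r).all() and (t.n_2r <= t.n_3r).all() and (t.n_3r <= t.N).all()
        assert t.pct_3r.le(100).all()

    def test_zero_particle_frame_reports_missing(self):
        s = roi_timeseries([particle_set([], 50, 50)], (25, 25), 5.0)
        row = s.table.iloc[0]
        assert row.N == 0 and np.isnan(row.pct_r)

    def test_uniform_placement_matches_binomial_oracle(self, rng):
        w = h = 200
        n = 10_000
        pts = np.column_stack([rng.uniform(0, w - 1, n), rng.uniform(0, h - 1, n)])
        r = 30.0
        s = roi_timeseries([particle_set(pts, w, h)], (100, 100), r)
        p = np.pi * r * r / ((w - 1) * (h - 1))  # disk fully interior
        se = np.sqrt(p * (1 - p) / n)
        assert abs(s.table.iloc[0].pct_r / 100 - p) < 3 * se

    def test_radius_in_microns(self):
        ps = particle_set([(10, 10)], 50, 50, scale=0.5)
        s = roi_timeseries([ps], (25, 25), 10.0)
        assert s.radius_um == 5.0
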