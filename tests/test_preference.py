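"""ROI geometry, exclusion rules, the three dependent variables, binning, heatmaps."""

import math

import numpy as np
import pytest

from bmassay import (
    ArenaGeometry,
    CoverageError,
    GeometryError,
    PeriodDesign,
    QualifyCriteria,
    Trajectory,
    bin_series,
    define_rois,
    occupancy_heatmap,
    orientation_toward_pct,
    qualify_fish,
    rproj,
    summarize,
    time_in_roi_pct,
)


def make_traj(cent_cm, headings_deg=None, ok=None, arena=None, fps=2.0):
    """Trajectory from centroid positions (cm) and heading angles (deg)."""
    arena = arena or ArenaGeometry(px_per_cm=10.0)
    cent = np.asarray(cent_cm, dtype=float) * arena.px_per_cm
    n = len(cent)
    if headings_deg is None:
        headings_deg = np.zeros(n)
    ang = np.radians(np.asarray(headings_deg, dtype=float))
    u = np.column_stack([np.cos(ang), np.sin(ang)])
    head = cent + 10.0 * u
    tail = cent - 10.0 * u
    if ok is None:
        ok = np.ones(n, bool)
    ok = np.asarray(ok, bool)
    head = head.copy()
    head[~ok] = np.nan
    return Trajectory(head=head, centroid=cent, tail=tail, ok=ok, fps=fps, arena=arena)


class TestRois:
    def test_two_wall_geometry(self):
        arena = ArenaGeometry()  # 15 cm tank, 12 cm tracked, fraction 0.2
        rois = define_rois(arena)
        assert len(rois) == 2
        r1, r2 = rois
        assert r1.depth == pytest.approx(3.0)
        assert r1.rect == (0.0, 0.0, 12.0, 3.0)  # bottom band, 12 x 3 cm
        assert r2.rect == (0.0, 9.0, 12.0, 12.0)
        assert r1.inward_normal == (0.0, -1.0)

    def test_zero_fraction_degenerate(self):
        with pytest.raises(GeometryError):
            define_rois(ArenaGeometry(roi_fraction=0.0))

    def test_single_wall_gets_mirrored_control(self):
        arena = ArenaGeometry(stimulus_walls={"bottom": "upright BM"})
        rois = define_rois(arena)
        assert len(rois) == 2
        assert rois[0].label == "ROI 1" and not rois[0].is_control
        assert rois[1].label == "ROI 2" and rois[1].is_control
        assert rois[1].wall == "top"

    def test_overlapping_bands_rejected(self):
        with pytest.raises(GeometryError):
            define_rois(ArenaGeometry(roi_fraction=0.45))  # 6.75 cm bands in 12 cm


class TestQualify:
    def test_stationary_fish_excluded(self):
        traj = make_traj(np.full((120, 2), 6.0))
        res = qualify_fish(traj, baseline=range(120))
        assert res.excluded
        assert set(res.reasons) >= {"frozen", "restricted"}

    @pytest.mark.parametrize("n_still,excluded", [(9, True), (8, False), (7, False)])
    def test_freeze_boundary_at_2fps(self, n_still, excluded):
        # immobility must exceed 4 s strictly: 9 sub-threshold steps (4.5 s)
        # excluded, 8 (4.0 s) and 7 (3.5 s) kept
        rng = np.random.default_rng(0)
        n = 120
        cent = np.cumsum(rng.uniform(-1, 1, (n, 2)), axis=0) % 10 + 1.0
        start = 50
        for i in range(n_still):
            cent[start + 1 + i] = cent[start]  # zero displacement steps
        traj = make_traj(cent)
        res = qualify_fish(traj, QualifyCriteria(restricted_min_frac=0.0), baseline=range(n))
        assert ("frozen" in res.reasons) == excluded

    @pytest.mark.parametrize("n_missing,excluded", [(501, True), (500, False)])
    def test_missing_frame_boundary(self, n_missing, excluded):
        rng = np.random.default_rng(1)
        n = 1200
        cent = np.cumsum(rng.uniform(-1, 1, (n, 2)), axis=0) % 10 + 1.0
        ok = np.ones(n, bool)
        ok[:n_missing] = False
        traj = make_traj(cent, ok=ok)
        res = qualify_fish(traj, QualifyCriteria(restricted_min_frac=0.0), baseline=range(n))
        assert ("missing" in res.reasons) == excluded


class TestTimeInRoi:
    def test_saturation(self):
        arena = ArenaGeometry(px_per_cm=10.0)
        roi = define_rois(arena)[0]
        traj = make_traj(np.full((50, 2), 1.5), arena=arena)  # inside bottom band
        assert time_in_roi_pct(traj, roi) == 100.0

    def test_ratio(self):
        arena = ArenaGeometry(px_per_cm=10.0)
        roi = define_rois(arena)[0]
        cent = np.full((120, 2), 6.0)
        cent[:30, 1] = 1.0  # 30 of 120 frames inside the bottom band
        traj = make_traj(cent, arena=arena)
        assert time_in_roi_pct(traj, roi) == pytest.approx(25.0)

    def test_matches_brute_force_count(self, rng):
        arena = ArenaGeometry(px_per_cm=10.0)
        roi = define_rois(arena)[0]
        cent = rng.uniform(0, 12, (300, 2))
        ok = rng.random(300) > 0.1
        traj = make_traj(cent, ok=ok, arena=arena)
        x0, y0, x1, y1 = roi.rect
        inside = sum(
            1
            for i in range(300)
            if ok[i] and x0 <= cent[i, 0] <= x1 and y0 <= cent[i, 1] <= y1
        )
        expect = 100.0 * inside / ok.sum()
        assert time_in_roi_pct(traj, roi) == pytest.approx(expect)

    def test_opposite_rois_partition_their_union(self, rng):
        arena = ArenaGeometry(px_per_cm=10.0)
        r1, r2 = define_rois(arena)
        y = np.where(rng.random(200) < 0.4, rng.uniform(0, 2.9, 200), rng.uniform(9.1, 12, 200))
        cent = np.column_stack([rng.uniform(0, 12, 200), y])
        traj = make_traj(cent, arena=arena)
        assert time_in_roi_pct(traj, r1) + time_in_roi_pct(traj, r2) == pytest.approx(100.0)


class TestOrientation:
    def _traj_with_headings(self, headings_deg):
        arena = ArenaGeometry(px_per_cm=10.0)
        cent = np.full((len(headings_deg), 2), [6.0, 1.5])  # inside bottom band
        return make_traj(cent, headings_deg=headings_deg, arena=arena), define_rois(arena)[0]

    def test_all_toward_wall(self):
        traj, roi = self._traj_with_headings([-90.0] * 10)  # inward normal is -y
        assert orientation_toward_pct(traj, roi) == 100.0

    def test_tolerance_boundary(self):
        # headings 0, 89, 91 degrees away from the normal: the 91-degree one
        # falls outside the +-90 band under the strict positive-dot rule
        traj, roi = self._traj_with_headings([-90.0, -90.0 + 89.0, -90.0 + 91.0])
        assert orientation_toward_pct(traj, roi) == pytest.approx(200.0 / 3.0)

    def test_never_in_roi_is_missing(self):
        arena = ArenaGeometry(px_per_cm=10.0)
        roi = define_rois(arena)[0]
        traj = make_traj(np.full((20, 2), 6.0), arena=arena)  # central, never in band
        assert math.isnan(orientation_toward_pct(traj, roi))

    def test_reversed_normal_complements(self):
        traj, roi = self._traj_with_headings([-10.0, -170.0, 30.0, 100.0, -95.0])
        flipped = type(roi)(
            label=roi.label, wall=roi.wall, depth=roi.depth, rect=roi.rect,
            inward_normal=(-roi.inward_normal[0], -roi.inward_normal[1]),
        )
        a = orientation_toward_pct(traj, roi)
        b = orientation_toward_pct(traj, flipped)
        assert a + b == pytest.approx(100.0)


class TestRproj:
    def _setup(self, headings_deg):
        return TestOrientation()._traj_with_headings(headings_deg)

    def test_all_toward(self):
        traj, roi = self._setup([-90.0] * 8)
        assert rproj(traj, roi) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_split(self):
        traj, roi = self._setup([0.0, 180.0])  # +-90 from the -y normal
        assert abs(rproj(traj, roi)) <= 1e-12

    def test_45_degree_split(self):
        traj, roi = self._setup([-45.0, -135.0])
        assert rproj(traj, roi) == pytest.approx(math.sqrt(2) / 2, abs=1e-12)

    def test_reversed_normal_negates(self):
        traj, roi = self._setup([-30.0, -120.0, 40.0])
        flipped = type(roi)(
            label=roi.label, wall=roi.wall, depth=roi.depth, rect=roi.rect,
            inward_normal=(-roi.inward_normal[0], -roi.inward_normal[1]),
        )
        assert rproj(traj, flipped) == pytest.approx(-rproj(traj, roi), abs=1e-12)

    def test_bounded_by_resultant_length(self, rng):
        arena = ArenaGeometry(px_per_cm=10.0)
        roi = define_rois(arena)[0]
        traj = make_traj(
            rng.uniform(0, 12, (100, 2)), headings_deg=rng.uniform(-180, 180, 100), arena=arena
        )
        r = rproj(traj, roi)
        if not math.isnan(r):
            assert -1.0 <= r <= 1.0


class TestTranslationInvariance:
    def test_metrics_unchanged_under_rigid_shift(self, rng):
        # shifting trajectory and ROI band by the same offset leaves all
        # three metrics unchanged
        arena = ArenaGeometry(px_per_cm=10.0)
        roi = define_rois(arena)[0]
        cent = rng.uniform(0, 12, (150, 2))
        hd = rng.uniform(-180, 180, 150)
        traj = make_traj(cent, headings_deg=hd, arena=arena)
        shift = np.array([2.5, -1.75])
        shifted = make_traj(cent + shift, headings_deg=hd, arena=arena)
        x0, y0, x1, y1 = roi.rect
        roi_shifted = type(roi)(
            label=roi.label, wall=roi.wall, depth=roi.depth,
            rect=(x0 + shift[0], y0 + shift[1], x1 + shift[0], y1 + shift[1]),
            inward_normal=roi.inward_normal,
        )
        assert time_in_roi_pct(shifted, roi_shifted) == pytest.approx(
            time_in_roi_pct(traj, roi)
        )
        a, b = orientation_toward_pct(shifted, roi_shifted), orientation_toward_pct(traj, roi)
        assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)
        a, b = rproj(shifted, roi_shifted), rproj(traj, roi)
        assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)


class TestBinning:
    def test_default_layout_at_2fps(self):
        traj = make_traj(np.full((600, 2), 6.0))
        ranges = bin_series(traj)
        assert ranges["baseline"] == range(0, 120)
        assert ranges["test"] == range(120, 600)
        assert ranges["bin1"] == range(120, 240)
        assert ranges["bin4"] == range(480, 600)

    def test_short_trajectory_rejected(self):
        traj = make_traj(np.full((599, 2), 6.0))
        with pytest.raises(CoverageError):
            bin_series(traj)

    def test_rate_scaling(self):
        traj = make_traj(np.full((1200, 2), 6.0), fps=4.0)
        ranges = bin_series(traj)
        assert len(ranges["bin1"]) == 240


class TestSummarize:
    def test_delta_is_test_minus_baseline(self):
        arena = ArenaGeometry(px_per_cm=10.0)
        rois = define_rois(arena)
        cent = np.full((600, 2), 6.0)
        base_in = round(0.1686 * 120)   # ~16.86% of baseline inside ROI 1
        test_in = round(0.2507 * 480)   # ~25.07% of test inside ROI 1
        cent[:base_in, 1] = 1.0
        cent[120 : 120 + test_in, 1] = 1.0
        traj = make_traj(cent, arena=arena)
        s = summarize(traj, rois)
        b = s.value("ROI 1", "baseline", "time_pct")
        t = s.value("ROI 1", "test", "time_pct")
        assert s.value("ROI 1", "test", "d_time_pct") == pytest.approx(t - b)
        assert t - b == pytest.approx(8.21, abs=0.25)

    def test_missing_propagates_into_deltas(self):
        arena = ArenaGeometry(px_per_cm=10.0)
        rois = define_rois(arena)
        cent = np.full((600, 2), 6.0)
        cent[150:200, 1] = 11.0  # enters ROI 2 only during the test period
        traj = make_traj(cent, arena=arena)
        s = summarize(traj, rois)
        assert math.isnan(s.value("ROI 2", "baseline", "orient_pct"))
        assert math.isnan(s.value("ROI 2", "test", "d_orient_pct"))
        assert math.isnan(s.value("ROI 2", "test", "d_rproj"))
        assert not math.isnan(s.value("ROI 2", "test", "d_time_pct"))


class TestHeatmap:
    def test_single_cell_saturation(self):
        traj = make_traj(np.full((50, 2), 0.2))
        h = occupancy_heatmap(traj, grid=(24, 24))
        assert h[0, 0] == 1.0
        assert h.sum() == 1.0

    def test_ratio_then_max_scaling(self):
        cent = np.concatenate([np.full((90, 2), 0.2), np.full((30, 2), 11.8)])
        traj = make_traj(cent)
        h = occupancy_heatmap(traj, grid=(24, 24))
        assert h[0, 0] == 1.0
        assert h[23, 23] == pytest.approx(1.0 / 3.0)

    def test_matches_manual_histogram(self, rng):
        cent = rng.uniform(0, 12, (200, 2))
        traj = make_traj(cent)
        h = occupancy_heatmap(traj, grid=(24, 24))
        manual, _, _ = np.histogram2d(
            cent[:, 1], cent[:, 0], bins=(24, 24), range=[[0, 12], [0, 12]]
        )
        manual /= 200.0
        assert manual.sum() == pytest.approx(1.0)  # pre-scaling fractions
        np.testing.assert_allclose(h, manual / manual.max())

    def test_no_ok_frames_all_zero(self):
        traj = make_traj(np.full((10, 2), 6.0), ok=np.zeros(10, bool))
        assert not occupancy_heatmap(traj).any()
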