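"""Stream fusion, cyclopean gaze, labelling, dwell and time courses."""

import math

import numpy as np
import pytest

from ymaze.gaze import (
    REGIONS, cyclopean, dwell_summary, fuse_streams, heatmap, label_stream,
    label_trial, mean_orientation_altitude,
)
from ymaze.metrics import segment_trial
from ymaze.simulate import TrialRecord


def _pose(t, x=0.0, y=0.0, z=1.6, yaw=0.0):
    t = np.asarray(t, dtype=float)
    cols = [np.full(len(t), v) if np.isscalar(v) else np.asarray(v)
            for v in (x, y, z, yaw)]
    return np.column_stack([t, *cols])


def _gaze(t, direction, lvalid=1.0, rvalid=1.0):
    t = np.asarray(t, dtype=float)
    d = np.tile(np.asarray(direction, dtype=float), (len(t), 1)) \
        if np.ndim(direction) == 1 else np.asarray(direction)
    lv = np.full(len(t), lvalid) if np.isscalar(lvalid) else lvalid
    rv = np.full(len(t), rvalid) if np.isscalar(rvalid) else rvalid
    return np.column_stack([t, d, d, lv, rv])


class TestCyclopean:
    def test_identical_eyes_unchanged(self):
        d = np.array([[0.0, 1.0, 0.0]])
        out, missing = cyclopean(d, [1], d, [1])
        assert np.allclose(out, d)
        assert not missing[0]

    def test_single_valid_eye_used(self):
        l = np.array([[1.0, 0.0, 0.0]])
        r = np.array([[0.0, 1.0, 0.0]])
        out, _ = cyclopean(l, [0], r, [1])
        assert np.allclose(out, r)
        out, _ = cyclopean(l, [1], r, [0])
        assert np.allclose(out, l)

    def test_both_invalid_is_missing(self):
        d = np.array([[0.0, 1.0, 0.0]])
        out, missing = cyclopean(d, [0], d, [0])
        assert missing[0]
        assert np.isnan(out[0]).all()

    def test_mean_is_renormalized(self):
        l = np.array([[1.0, 0.0, 0.0]])
        r = np.array([[0.0, 1.0, 0.0]])
        out, _ = cyclopean(l, [1], r, [1])
        assert np.linalg.norm(out[0]) == pytest.approx(1.0)
        assert out[0, 0] == pytest.approx(out[0, 1])


class TestFuseStreams:
    def test_static_head_passes_directions_through(self):
        pose = _pose(np.arange(0, 1, 1 / 30))
        gaze = _gaze(np.arange(0, 0.97, 1 / 120), [0, 1, 0])
        f = fuse_streams(pose, gaze)
        assert np.allclose(f.left, [[0, 1, 0]] * len(f.t))
        assert np.allclose(f.origin[:, 2], 1.6)

    def test_yawed_head_rotates_gaze_azimuth(self):
        pose = _pose([0.0, 1.0], yaw=[math.pi / 2, math.pi / 2])
        gaze = _gaze([0.5], [1, 0, 0])       # straight ahead in head frame
        f = fuse_streams(pose, gaze)
        assert np.allclose(f.left[0], [0, 1, 0], atol=1e-12)

    def test_interpolation_identity_at_pose_timestamps(self):
        t = np.arange(0, 1, 1 / 30)
        x = np.sin(t * 3)
        pose = _pose(t, x=x)
        gaze = _gaze(t, [0, 1, 0])           # sample exactly at pose times
        f = fuse_streams(pose, gaze)
        assert np.allclose(f.origin[:, 0], x)

    def test_samples_outside_pose_range_dropped(self):
        pose = _pose([0.0, 1.0])
        gaze = _gaze([-0.5, 0.5, 1.5], [0, 1, 0])
        f = fuse_streams(pose, gaze)
        assert len(f.t) == 1 and f.t[0] == 0.5

    def test_bad_streams_rejected(self):
        with pytest.raises(ValueError):
            fuse_streams(np.empty((0, 5)), _gaze([0.0], [0, 1, 0]))
        pose = _pose([0.0, 1.0, 0.5])
        with pytest.raises(ValueError):
            fuse_streams(pose, _gaze([0.0], [0, 1, 0]))


class TestLabelStream:
    def test_downward_gaze_is_floor(self, landmark_spec):
        pose = _pose(np.arange(0, 1, 1 / 30))
        gaze = _gaze(np.arange(0, 0.9, 1 / 120), [0, 0, -1])
        lab = label_stream(fuse_streams(pose, gaze), landmark_spec)
        assert all(s == "floor" for s in lab.surface)
        assert np.allclose(lab.elevation, -90)

    def test_landmark_azimuth_above_walls_is_its_sky_sector(self,
                                                            landmark_spec):
        spec = landmark_spec
        star = next(l for l in spec.landmarks if l.label == "star")
        a = math.radians(star.azimuth_deg)
        d = np.array([math.cos(a) * math.cos(0.5), math.sin(a) * math.cos(0.5),
                      math.sin(0.5)])   # ~29 deg elevation
        pose = _pose([0.0, 1.0])
        gaze = _gaze([0.5], d)
        lab = label_stream(fuse_streams(pose, gaze), spec)
        assert lab.surface[0] == "sky"
        assert lab.sector[0] == "star"

    def test_missing_samples_stay_missing(self, landmark_spec):
        pose = _pose(np.arange(0, 1, 1 / 30))
        tg = np.arange(0, 0.9, 1 / 120)
        valid = (np.arange(len(tg)) % 2).astype(float)
        gaze = _gaze(tg, [0, 0, -1], lvalid=valid, rvalid=valid)
        lab = label_stream(fuse_streams(pose, gaze), landmark_spec)
        assert np.array_equal(lab.missing, valid < 0.5)
        assert all(s is None for s in lab.surface[lab.missing])


class TestDwellSummary:
    def _lab(self, spec, dirs, t=None):
        t = np.arange(0, 10, 1 / 120) if t is None else t
        pose = _pose(np.arange(0, 10.01, 1 / 30))
        gaze = np.column_stack([t, dirs, dirs,
                                np.ones(len(t)), np.ones(len(t))])
        return label_stream(fuse_streams(pose, gaze), spec)

    def test_all_floor_gives_unit_proportion(self, landmark_spec):
        t = np.arange(0, 10, 1 / 120)
        lab = self._lab(landmark_spec, np.tile([0, 0, -1.0], (len(t), 1)), t)
        d = dwell_summary(lab, (0, 3), (3, 10))
        assert d.proportions["floor"] == pytest.approx(1.0)
        assert d.missing_fraction == pytest.approx(0.0)

    def test_missing_excluded_from_denominator(self, landmark_spec):
        t = np.arange(0, 10, 1 / 120)
        pose = _pose(np.arange(0, 10.01, 1 / 30))
        valid = (np.arange(len(t)) % 2).astype(float)
        horiz = np.tile([0, 1.0, 0], (len(t), 1))   # wall-level gaze
        gaze = np.column_stack([t, horiz, horiz, valid, valid])
        lab = label_stream(fuse_streams(pose, gaze), landmark_spec)
        d = dwell_summary(lab, (0, 3), (3, 10))
        assert d.missing_fraction == pytest.approx(0.5, abs=0.01)
        assert d.proportions["wall"] == pytest.approx(1.0)

    def test_alternating_regions_split_evenly(self, landmark_spec):
        t = np.arange(0, 10, 1 / 120)
        dirs = np.tile([0, 0, -1.0], (len(t), 1))
        dirs[::2] = [0, 0, 1.0]                     # alternate sky/floor
        lab = self._lab(landmark_spec, dirs, t)
        d = dwell_summary(lab, (0, 3), (3, 10))
        assert d.proportions["sky"] == pytest.approx(0.5, abs=1 / len(t))
        assert d.proportions["floor"] == pytest.approx(0.5, abs=1 / len(t))

    def test_proportions_sum_to_one_and_sectors_to_sky(self, small_cohort):
        from ymaze.gaze import trial_dwell
        sim, specs = small_cohort
        checked = 0
        for tr in sim.trials[:60]:
            if not len(tr.gaze):
                continue
            d = trial_dwell(tr, specs[tr.subject_id])
            if not d.valid:
                continue
            total = sum(d.proportions[r] for r in REGIONS)
            assert total == pytest.approx(1.0, abs=1e-12)
            if tr.condition == "landmark":
                assert sum(d.sector_proportions.values()) == pytest.approx(
                    d.proportions["sky"], abs=1e-12)
            checked += 1
        assert checked > 20

    def test_timecourse_has_fifteen_plus_thirtyfive_bins(self, landmark_spec):
        t = np.arange(0, 10, 1 / 120)
        lab = self._lab(landmark_spec, np.tile([0, 0, -1.0], (len(t), 1)), t)
        d = dwell_summary(lab, (0, 3), (3, 10))
        tc = d.timecourse
        assert len(tc) == 50 * len(REGIONS)
        assert (tc[tc.period == "orientation"].bin.nunique(),
                tc[tc.period == "navigation"].bin.nunique()) == (15, 35)

    def test_timecourse_consistent_with_overall_proportion(self,
                                                           landmark_spec):
        """Duration-weighted mean of binned floor fractions matches the
        overall floor proportion within window-edge tolerance."""
        rng = np.random.default_rng(0)
        t = np.arange(0, 10, 1 / 120)
        dirs = np.where(rng.random((len(t), 1)) < 0.3,
                        [0, 0, -1.0], [0, 1.0, 0.0])
        lab = self._lab(landmark_spec, dirs, t)
        d = dwell_summary(lab, (0, 3), (3, 10))
        tc = d.timecourse
        fl = tc[tc.region == "floor"]
        w = np.where(fl.period == "orientation", 3 / 15, 7 / 35)
        est = float((fl.fraction * w).sum() / w.sum())
        assert est == pytest.approx(d.proportions["floor"], abs=0.05)

    def test_all_missing_is_flagged(self, landmark_spec):
        t = np.arange(0, 2, 1 / 120)
        pose = _pose(np.arange(0, 2.01, 1 / 30))
        d0 = np.tile([0, 0, -1.0], (len(t), 1))
        gaze = np.column_stack([t, d0, d0, np.zeros(len(t)),
                                np.zeros(len(t))])
        lab = label_stream(fuse_streams(pose, gaze), landmark_spec)
        d = dwell_summary(lab, (0, 1), (1, 2))
        assert not d.valid
        assert np.isnan(d.proportions["wall"])


class TestAltitude:
    def test_constant_and_balanced_means(self, landmark_spec):
        t = np.arange(0, 4, 1 / 120)
        pose = _pose(np.arange(0, 4.01, 1 / 30))
        el = np.full(len(t), 20.0)
        d = np.column_stack([np.zeros(len(t)),
                             np.cos(np.radians(el)), np.sin(np.radians(el))])
        gaze = np.column_stack([t, d, d, np.ones(len(t)), np.ones(len(t))])
        lab = label_stream(fuse_streams(pose, gaze), landmark_spec)
        assert mean_orientation_altitude(lab, (0, 4)) == pytest.approx(20.0)
        el = np.where(np.arange(len(t)) % 2, 10.0, -10.0)
        d = np.column_stack([np.zeros(len(t)),
                             np.cos(np.radians(el)), np.sin(np.radians(el))])
        gaze = np.column_stack([t, d, d, np.ones(len(t)), np.ones(len(t))])
        lab = label_stream(fuse_streams(pose, gaze), landmark_spec)
        assert mean_orientation_altitude(lab, (0, 4)) == pytest.approx(
            0.0, abs=0.1)

    def test_gaussian_profile_mean_recovered(self, landmark_spec, rng):
        """CLT oracle: n = 1000 samples at N(25, 5) recover 25 +- 0.5."""
        n = 1000
        t = np.arange(n) / 120
        pose = _pose(np.array([0.0, t[-1] + 0.1]))
        el = rng.normal(25.0, 5.0, size=n)
        d = np.column_stack([np.zeros(n), np.cos(np.radians(el)),
                             np.sin(np.radians(el))])
        gaze = np.column_stack([t, d, d, np.ones(n), np.ones(n)])
        lab = label_stream(fuse_streams(pose, gaze), landmark_spec)
        assert mean_orientation_altitude(lab, (0, t[-1] + 0.1)) \
            == pytest.approx(25.0, abs=0.5)

    def test_no_usable_samples_raises(self, landmark_spec):
        t = np.arange(0, 1, 1 / 120)
        pose = _pose(np.arange(0, 1.01, 1 / 30))
        d = np.tile([0, 1.0, 0], (len(t), 1))
        gaze = np.column_stack([t, d, d, np.zeros(len(t)), np.zeros(len(t))])
        lab = label_stream(fuse_streams(pose, gaze), landmark_spec)
        with pytest.raises(ValueError):
            mean_orientation_altitude(lab, (0, 1))


class TestHeatmap:
    def test_single_cell_peaks_at_one(self):
        pts = np.tile([0.5, 0.5, 0.0], (20, 1))
        grid, _, _ = heatmap(pts, "floor")
        assert grid.max() == 1.0
        assert (grid > 0).sum() == 1

    def test_two_equal_cells_both_one(self):
        pts = np.vstack([np.tile([0.55, 0.55, 0], (10, 1)),
                         np.tile([-1.55, -1.55, 0], (10, 1))])
        grid, _, _ = heatmap(pts, "floor")
        assert (grid == 1.0).sum() == 2

    def test_uniform_sky_scatter_is_flat(self, rng):
        """Multinomial oracle: a uniform azimuth scatter at one elevation
        fills its row with counts whose spread matches sampling noise."""
        n = 100000
        az = np.radians(rng.uniform(0, 360, n))
        el = np.radians(np.full(n, 45.0))
        pts = 6.0 * np.column_stack([np.cos(el) * np.cos(az),
                                     np.cos(el) * np.sin(az), np.sin(el)])
        grid, xe, ye = heatmap(pts, "sky", resolution=10.0)
        row = grid[:, int(np.searchsorted(ye, 45.0)) - 1]
        expect = n / 36
        raw = row / row.mean() * expect
        assert np.all(np.abs(raw - expect) < 5 * math.sqrt(expect))

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            heatmap(np.empty((0, 3)), "sky")
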