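"""Unit-level tracker operations: peak detection, triangulation,
prediction, shaking and track fitting, each against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.spatial import cKDTree

from lv4dflow.imaging import default_camera_model, render_particle_image
from lv4dflow.tracking import (Tracker, TrackerConfig, detect_peaks, fit_tracks,
                               match_tracks_to_truth, predict_positions,
                               shake_refine, triangulate)
from lv4dflow.tracks import TrackSet


@pytest.fixture(scope="module")
def cam():
    return default_camera_model(image_shape=(128, 128), mm_per_px=0.2)


@pytest.fixture(scope="module")
def cfg():
    return TrackerConfig()


def _spot(cam, pos_mm, view=0):
    return np.rint(render_particle_image(np.atleast_2d(pos_mm), cam, view))


class TestDetectPeaks:
    def test_blank_image_returns_nothing(self):
        pos, inten, plat = detect_peaks(np.zeros((32, 32)), 5.0)
        assert len(pos) == 0

    def test_subpixel_position_against_dense_grid_search(self, cam):
        """One rendered spot at a known sub-pixel position: the 3-point
        refinement must agree with an exhaustive correlation search of the
        known OTF on a 0.005 px grid."""
        pos_mm = np.array([2.06, -1.46, 0.8])
        img = _spot(cam, pos_mm)
        (p, i, _) = detect_peaks(img, 5.0)
        assert len(p) == 1

        # brute-force oracle: maximise correlation with the OTF template
        # over a dense sub-pixel grid (local window around the peak)
        cx, cy = np.rint(p[0]).astype(int)
        win = img[cy - 7:cy + 8, cx - 7:cx + 8]
        yy, xx = np.mgrid[cy - 7:cy + 8, cx - 7:cx + 8]
        offs = np.arange(-1, 1, 0.005)
        best, best_score = None, -np.inf
        for ox in offs:
            gx = np.exp(-((xx[0] - cx - ox) ** 2) / (2 * cam.otf_sigma**2))
            for oy in offs:
                gy = np.exp(-((yy[:, 0] - cy - oy) ** 2) / (2 * cam.otf_sigma**2))
                g = gy[:, None] * gx[None, :]
                score = (win * g).sum() / np.sqrt((g * g).sum())
                if score > best_score:
                    best_score, best = score, (cx + ox, cy + oy)
        assert abs(p[0][0] - best[0]) < 0.02
        assert abs(p[0][1] - best[1]) < 0.02
        true_px = cam.project(pos_mm[None], 0)[0]
        assert np.abs(p[0] - true_px).max() < 0.02

    def test_close_spots_follow_documented_merge_rule(self, cam):
        """Two spots 1.5 otf_sigma apart merge into one local maximum of
        the summed profile, or appear as two peaks farther than 1 px;
        either way every reported peak is a true local maximum and no
        duplicates within 1 px survive."""
        d_px = 1.5 * cam.otf_sigma
        base = np.array([0.0, 0.0, 0.0])
        other = base + np.array([d_px * cam.mm_per_px, 0, 0])
        img = np.rint(render_particle_image(np.stack([base, other]), cam, 0))
        p, inten, _ = detect_peaks(img, 5.0)
        assert 1 <= len(p) <= 2
        if len(p) == 2:
            assert np.linalg.norm(p[0] - p[1]) > 1.0

    def test_saturated_plateau_flagged_with_centroid(self):
        img = np.zeros((32, 32))
        img[10:13, 10:13] = 100.0  # flat-topped blob
        p, inten, plat = detect_peaks(img, 5.0)
        assert plat.any()
        k = np.flatnonzero(plat)[0]
        assert p[k] == pytest.approx([11.0, 11.0], abs=1e-9)


class TestTriangulate:
    def test_single_particle_four_views(self, cam, cfg):
        pos_mm = np.array([1.2, -0.7, 2.3])
        peaks = [detect_peaks(_spot(cam, pos_mm, v), 5.0) for v in range(4)]
        cands = triangulate(peaks, cam, cfg.triangulation_tol)
        assert len(cands) == 1
        assert np.linalg.norm(cands[0].position_mm - pos_mm) < 0.2 * cam.mm_per_px
        assert cands[0].n_supporting_views == 4

    def test_large_reprojection_error_rejected(self, cam, cfg):
        """Peaks displaced by 1.5 voxels in every view admit no candidate
        at the 1-voxel triangulation tolerance."""
        pos_mm = np.array([0.5, 0.5, 0.5])
        rng = np.random.default_rng(3)
        peaks = []
        for v in range(4):
            px = cam.project(pos_mm[None], v)
            off = rng.standard_normal(2)
            px = px + 1.5 * off / np.linalg.norm(off)
            peaks.append((px, np.array([1000.0]), np.array([False])))
        cands = triangulate(peaks, cam, 1.0)
        for c in cands:
            # any accepted candidate must genuinely reproject within tol
            for v, k in c.support:
                err = np.linalg.norm(cam.project(c.position_mm[None], v)[0]
                                     - peaks[v][0][k])
                assert err <= 1.0

    def test_ghosts_bounded_by_brute_force_oracle(self, cam, cfg, rng):
        """Several particles with shared epipolar geometry: the iterative
        claiming returns at most as many candidates as the brute-force
        all-combination oracle admits, and includes every true particle."""
        true = rng.uniform(-6, 6, (12, 3))
        peaks = [detect_peaks(np.rint(render_particle_image(true, cam, v)), 5.0)
                 for v in range(4)]
        cands = triangulate(peaks, cam, cfg.triangulation_tol)

        # oracle: every pair-view peak combination whose LSQ point
        # reprojects within tol in >= 3 views
        from lv4dflow.tracking import _solve_views
        oracle = []
        p0, p1 = peaks[0][0], peaks[1][0]
        for i in range(len(p0)):
            for j in range(len(p1)):
                X = _solve_views(cam, (0, 1), (p0[i:i + 1], p1[j:j + 1]))[0]
                n_sup = 0
                for v in range(4):
                    pv = peaks[v][0]
                    if len(pv) and cKDTree(pv).query(cam.project(X[None], v))[0][0] <= 1.0:
                        n_sup += 1
                if n_sup >= 3:
                    oracle.append(X)
        assert len(cands) <= len(oracle)
        got = np.array([c.position_mm for c in cands])
        d, _ = cKDTree(got).query(true)
        assert (d < 2 * cam.mm_per_px).all()  # every true particle found


class TestPrediction:
    def test_constant_history(self):
        h = np.tile([1.0, 2.0, 3.0], (3, 1))
        assert np.allclose(predict_positions(h), [1, 2, 3])

    def test_linear_sequence(self):
        h = np.array([[1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        assert np.allclose(predict_positions(h), [4, 0, 0])

    def test_quadratic_sequence_exact(self):
        h = np.array([[0, 0, 0], [1, 0, 0], [4, 0, 0]], dtype=float)  # t^2
        assert np.allclose(predict_positions(h), [9, 0, 0])

    def test_two_point_history_is_linear(self):
        h = np.array([[1, 1, 1], [3, 2, 1]], dtype=float)
        assert np.allclose(predict_positions(h), [5, 3, 1])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(coef=hnp.arrays(np.float64, (3, 3),
                           elements=st.floats(-100, 100, allow_nan=False)))
    def test_prediction_exact_on_any_quadratic(self, coef):
        """Quadratic extrapolation reproduces any quadratic trajectory."""
        t = np.arange(4.0)[:, None]
        traj = coef[0] + coef[1] * t + coef[2] * t**2
        pred = predict_positions(traj[:3])
        assert np.allclose(pred, traj[3], rtol=1e-9, atol=1e-6)


class TestShake:
    def test_particle_at_truth_is_a_fixed_point(self, cam, cfg):
        pos = np.array([[1.0, 1.0, 1.0]])
        images = [np.rint(render_particle_image(pos, cam, v)) for v in range(4)]
        sr = shake_refine(pos, images, cam, cfg)
        disp = np.linalg.norm(sr.positions - pos) / cam.mm_per_px
        assert disp < cfg.shake_step

    def test_half_voxel_perturbation_recovered(self, cam, cfg):
        """Isolated particle 0.5 voxel off: the shake reaches the global
        optimum found by an exhaustive 0.01-voxel grid search."""
        pos = np.array([[0.8, -0.4, 1.6]])
        images = [np.rint(render_particle_image(pos, cam, v)) for v in range(4)]
        start = pos + 0.5 * cam.mm_per_px / np.sqrt(3)
        sr = shake_refine(start, images, cam, cfg)
        err = np.linalg.norm(sr.positions - pos) / cam.mm_per_px
        assert err < 0.05

        # oracle: exhaustive search of the same residual objective on a
        # 0.01-voxel grid along each axis around the truth
        from lv4dflow.tracking import _ShakeWorkspace
        ws = _ShakeWorkspace([im.astype(float) for im in images], sr.positions,
                             sr.intensities, cam)
        E_final = ws.objective(np.array([0]), sr.positions)[0]
        best = E_final
        for ax in range(3):
            for off in np.arange(-0.05, 0.05, 0.01):
                q = sr.positions.copy()
                q[0, ax] += off * cam.mm_per_px
                best = min(best, ws.objective(np.array([0]), q)[0])
        assert E_final <= best * 1.05 + 1e-9

    def test_global_objective_non_increasing(self, cam, cfg, rng):
        positions = rng.uniform(-8, 8, (25, 3))
        images = [np.rint(render_particle_image(positions, cam, v)) for v in range(4)]
        start = positions + rng.uniform(-0.4, 0.4, positions.shape) * cam.mm_per_px
        sr = shake_refine(start, images, cam, cfg)
        assert np.all(np.diff(sr.global_objective) <= 1e-6 * sr.global_objective[0])

    def test_per_particle_objective_monotone_for_isolated_particles(self, cam, cfg):
        positions = np.array([[-8.0, -8.0, -8.0], [8.0, 8.0, 8.0]])
        images = [np.rint(render_particle_image(positions, cam, v)) for v in range(4)]
        start = positions + np.array([[0.3, -0.3, 0.2], [-0.2, 0.1, 0.3]]) * cam.mm_per_px
        sr = shake_refine(start, images, cam, cfg)
        assert np.all(np.diff(sr.objectives, axis=0) <= 1e-9 * sr.objectives[0].max())

    def test_overlapping_pair_joint_residual_non_increasing(self, cam, cfg):
        d = cam.otf_sigma * cam.mm_per_px  # 1 otf_sigma apart
        positions = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        images = [np.rint(render_particle_image(positions, cam, v)) for v in range(4)]
        start = positions + 0.3 * cam.mm_per_px * np.array([[1, -1, 1], [-1, 1, -1]])
        sr = shake_refine(start, images, cam, cfg)
        assert sr.global_objective[-1] <= sr.global_objective[0] * (1 + 1e-12)

    def test_unsupported_particle_marked_lost(self, cam, cfg):
        images = [np.zeros((128, 128)) for _ in range(4)]
        sr = shake_refine(np.array([[0.0, 0.0, 0.0]]), images, cam, cfg)
        assert sr.lost[0]


class TestTrackerBehaviour:
    @staticmethod
    def _uniform_motion_images(cam, n=25, frames=8, step_vox=2.0, seed=4):
        rng_l = np.random.default_rng(seed)
        pos = np.empty((n, frames, 3))
        pos[:, 0] = rng_l.uniform(-8, 8, (n, 3))
        drift = np.array([step_vox * cam.mm_per_px, 0.0, 0.0])
        for f in range(1, frames):
            pos[:, f] = pos[:, f - 1] + drift
        truth = TrackSet(pos, np.ones((n, frames), bool), 5e-4)
        from lv4dflow.imaging import render_images
        return truth, render_images(truth, cam)

    def test_uniform_motion_linked_like_optimal_assignment(self, cam):
        """2 voxels/frame uniform drift, search radius 4: every particle
        is linked with no spurious chains — matching the globally optimal
        assignment between consecutive frames (Hungarian oracle)."""
        from scipy.optimize import linear_sum_assignment
        from lv4dflow.tracking import Tracker

        truth, images = self._uniform_motion_images(cam)
        cfg = TrackerConfig()
        tr = Tracker(cfg, cam)
        tr.initialize(images.frames[:4])
        for f in range(4, images.n_steps):
            tr.advance(images.frames[f])
        ts = tr.to_trackset(images.n_steps, 2000.0)
        # oracle: optimal one-to-one matching frame 0 -> 1 of the truth
        d = np.linalg.norm(truth.positions[:, 0][:, None]
                           - truth.positions[:, 1][None], axis=-1)
        rows, cols = linear_sum_assignment(d)
        assert (rows == cols).all()  # drift below any inter-particle spacing
        assert ts.n_tracks == truth.n_tracks
        rep = match_tracks_to_truth(ts, truth, cam)
        assert rep["n_ghost"] == 0

    def test_search_radius_below_displacement_yields_no_tracks(self, cam):
        """Documented failure mode: a linking radius smaller than the
        per-frame displacement cannot form initialization chains."""
        from lv4dflow.tracking import Tracker

        truth, images = self._uniform_motion_images(cam, step_vox=2.0)
        cfg = TrackerConfig(search_radius=1.0)  # < 2-voxel displacement
        tr = Tracker(cfg, cam)
        tr.initialize(images.frames[:4])
        assert len(tr.tracks) == 0

    def test_all_particles_vanishing_terminates_every_track(self, cam):
        """Blank frames from frame n on: every track is lost within the
        miss allowance and no new tracks appear."""
        from lv4dflow.tracking import ACTIVE, INITIALIZING, PROBATION, Tracker

        truth, images = self._uniform_motion_images(cam, frames=10)
        frames = images.frames.copy()
        frames[6:] = 0
        cfg = TrackerConfig()
        tr = Tracker(cfg, cam)
        tr.initialize(frames[:4])
        n_started = len(tr.tracks)
        assert n_started > 0
        for f in range(4, 10):
            diag = tr.advance(frames[f])
        assert diag["n_new"] == 0
        live = [t for t in tr.tracks if t.status in (ACTIVE, PROBATION, INITIALIZING)]
        assert len(live) == 0


class TestDeterminism:
    def test_identical_inputs_give_bit_identical_tracks(self, rng):
        """Same images and config twice: the reconstructed TrackSet is
        bit-identical (no hidden randomness in the tracker)."""
        from lv4dflow.imaging import render_images
        from lv4dflow.tracking import Tracker

        cam = default_camera_model(image_shape=(128, 128), mm_per_px=0.4)
        n, frames = 30, 8
        pos = np.empty((n, frames, 3))
        pos[:, 0] = rng.uniform(-10, 10, (n, 3))
        drift = rng.uniform(-0.15, 0.15, (n, 3))
        for f in range(1, frames):
            pos[:, f] = pos[:, f - 1] + drift
        truth = TrackSet(pos, np.ones((n, frames), bool), 5e-4)
        images = render_images(truth, cam)

        def run():
            cfg = TrackerConfig()
            tr = Tracker(cfg, cam)
            tr.initialize(images.frames[:cfg.init_frames])
            for f in range(cfg.init_frames, frames):
                tr.advance(images.frames[f])
            return tr.to_trackset(frames, 2000.0)

        a, b = run(), run()
        assert np.array_equal(a.positions, b.positions, equal_nan=True)
        assert np.array_equal(a.active, b.active)
        assert np.array_equal(a.ids, b.ids)


class TestFitTracks:
    def test_constant_track_zero_kinematics(self):
        pos = np.tile([2.0, 3.0, 4.0], (1, 10, 1))
        ts = fit_tracks(TrackSet(pos, np.ones((1, 10), bool), 5e-4))
        assert np.allclose(ts.velocity[0, :], 0.0, atol=1e-12)
        assert np.allclose(ts.acceleration[0, :], 0.0, atol=1e-9)

    def test_quadratic_track_acceleration_exact(self):
        a = np.array([2.0, -1.0, 0.5])  # m/s^2
        dt = 5e-4
        t = (np.arange(12) * dt)[:, None]
        pos = (0.5 * a[None] * t**2) * 1e3  # mm
        ts = fit_tracks(TrackSet(pos[None], np.ones((1, 12), bool), dt))
        assert np.allclose(ts.acceleration[0], a[None], rtol=1e-7)
        want_v = (a[None] * t)  # m/s
        assert np.allclose(ts.velocity[0], want_v, rtol=1e-7, atol=1e-12)

    def test_sinusoid_velocity_error_within_truncation_bound(self):
        """x = sin(2 pi f t) at f dt = 0.01: the centered 3-point window's
        velocity error is bounded by the cubic truncation term
        h^2/6 |x'''|."""
        f = 20.0
        dt = 0.01 / f
        t = np.arange(60) * dt
        x_m = np.sin(2 * np.pi * f * t)
        pos = np.zeros((1, 60, 3))
        pos[0, :, 0] = x_m * 1e3
        ts = fit_tracks(TrackSet(pos, np.ones((1, 60), bool), dt))
        v_true = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        bound = dt**2 / 6 * (2 * np.pi * f) ** 3  # max |x'''| h^2 / 6
        err = np.abs(ts.velocity[0, 1:-1, 0] - v_true[1:-1])
        assert err.max() <= bound * 1.01

    def test_short_track_velocity_only(self):
        pos = np.zeros((1, 2, 3))
        pos[0, 1, 0] = 1.0
        ts = fit_tracks(TrackSet(pos, np.ones((1, 2), bool), 5e-4))
        assert np.isfinite(ts.velocity[0]).all()
        assert np.isnan(ts.acceleration[0]).all()  # undefined, flagged
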