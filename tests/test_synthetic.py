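"""Ground-truth generators: LV-like flow, Taylor-Green oracle, mode
superpositions, tracer advection and image rendering."""

import numpy as np
import pytest

from lv4dflow.grid import FlowField4D, GridSpec
from lv4dflow.imaging import default_camera_model, render_images
from lv4dflow.synthetic import (LVAnalyticFlow, LVFlowParams, MITRAL_AXIS,
                                MITRAL_POINT, advect_particles, make_lv_flow,
                                make_mode_superposition, make_taylor_green,
                                taylor_green_fields)
from lv4dflow.tracks import TrackSet


def _max_interior_divergence(flow):
    sp = [s * 1e-3 for s in flow.grid.spacing]
    worst = 0.0
    for t in range(flow.n_steps):
        v = flow.velocity[t]
        div = sum(np.gradient(v[..., c], sp[c], axis=c) for c in range(3))
        interior = flow.mask[t][2:-2, 2:-2, 2:-2]
        if interior.any():
            worst = max(worst, np.abs(div[2:-2, 2:-2, 2:-2])[interior].max())
    return worst


class TestLVFlow:
    def test_zero_jet_speed_gives_zero_velocity_but_moving_wall(self, lv_grid):
        params = LVFlowParams(peak_jet_speed=0.0)
        flow = make_lv_flow(params, lv_grid)
        assert np.all(flow.velocity == 0.0)
        vols = flow.mask_volumes_ml()
        assert vols.max() - vols.min() > 0.5 * params.stroke_volume

    def test_diastolic_mitral_inflow_equals_stroke_volume(self, lv_params):
        """Numerical flux integration through the mitral plane over
        diastole recovers the 50 ml stroke volume within 2%."""
        fn = LVAnalyticFlow(lv_params)
        r = np.linspace(0.0, 30.0, 500)
        phi = np.linspace(0.0, 2 * np.pi, 128, endpoint=False)
        R, PHI = np.meshgrid(r, phi, indexing="ij")
        e1 = np.cross(MITRAL_AXIS, [0.0, 0.0, 1.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(MITRAL_AXIS, e1)
        pts = (MITRAL_POINT + 2.0 * MITRAL_AXIS
               + R.ravel()[:, None] * (np.cos(PHI.ravel())[:, None] * e1
                                       + np.sin(PHI.ravel())[:, None] * e2))
        ts = np.linspace(lv_params.systole_duration, lv_params.cycle_period, 200)
        dA = (r[1] - r[0]) * (phi[1] - phi[0])
        flux = np.array([(fn.velocity(pts, t) @ MITRAL_AXIS * R.ravel() * dA).sum()
                         for t in ts])  # mm^2 * m/s
        volume_ml = np.trapezoid(flux, ts) * 1e-6 * 1e6  # -> litres*... -> ml
        assert volume_ml == pytest.approx(lv_params.stroke_volume, rel=0.02)

    def test_divergence_vanishes_under_grid_refinement(self, lv_params):
        """Sampled central-difference divergence is discretisation-only:
        refining the grid 2x drops it by about the 2nd-order factor."""
        coarse = GridSpec((-33, -48, -30), (2.75, 2.75, 2.75), (24, 34, 22), 0.107, 8)
        fine = GridSpec((-33, -48, -30), (1.375, 1.375, 1.375), (48, 68, 44), 0.107, 8)
        d_c = _max_interior_divergence(make_lv_flow(lv_params, coarse))
        d_f = _max_interior_divergence(make_lv_flow(lv_params, fine))
        assert d_f < d_c  # converging
        assert d_c / d_f > 2.0  # roughly 2nd order (4x in the clean limit)

    def test_mask_volume_waveform_is_cycle_periodic(self, lv_params):
        fn = LVAnalyticFlow(lv_params)
        assert abs(fn.volume_ml(0.0) - fn.volume_ml(lv_params.cycle_period)) \
            <= 1e-9 * fn.volume_ml(0.0)
        # extrema at end-diastole (t = 0) and end-systole
        span = fn.volume_ml(0.0) - fn.volume_ml(lv_params.systole_duration)
        assert span == pytest.approx(lv_params.stroke_volume, rel=1e-9)
        t = np.linspace(0, 5 * lv_params.cycle_period, 400)
        assert np.all(np.abs(fn.volume_ml(t) - fn.volume_ml(t + lv_params.cycle_period)) < 1e-9)

    def test_too_coarse_grid_rejected(self, lv_params):
        grid = GridSpec((-33, -52, -30), (8.0, 8.0, 8.0), (8, 12, 8), 0.107, 4)
        with pytest.raises(ValueError, match="too coarse"):
            make_lv_flow(lv_params, grid)


class TestTaylorGreen:
    def test_velocity_decays_to_zero(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), (16, 16, 16), 30.0, 12)
        flow, _ = make_taylor_green(grid, amplitude=0.5)
        assert np.abs(flow.velocity[-1]).max() < 1e-6 * 0.5

    def test_sampled_divergence_at_machine_level(self):
        """The analytic field is solenoidal, and for this trigonometric
        mode the central-difference contributions cancel identically, so
        the sampled divergence sits at round-off for any resolution."""
        for n in (16, 32):
            grid = GridSpec((0, 0, 0), (32.0 / n,) * 3, (n, n, n), 0.01, 1)
            flow, _ = make_taylor_green(grid, amplitude=0.5)
            sp = [s * 1e-3 for s in grid.spacing]
            v = flow.velocity[0]
            div = sum(np.gradient(v[..., c], sp[c], axis=c) for c in range(3))
            scale = 0.5 * 2 * np.pi / (n * sp[0])  # A * k
            assert np.abs(div[2:-2, 2:-2, 2:-2]).max() < 1e-10 * scale

    def test_pressure_difference_quarter_period_points(self):
        """p(0,0) - p(L/4, L/4) = -rho A^2 at t=0 (closed form)."""
        grid = GridSpec((0, 0, 0), (1, 1, 1), (32, 32, 32), 0.01, 1)
        rho, amp = 1160.0, 0.5
        _, p_fn, _ = taylor_green_fields(grid, rho, 0.0177, amp)
        L = 32.0
        dp = p_fn(np.array([[0.0, 0.0, 0.0]]), 0.0) \
            - p_fn(np.array([[L / 4, L / 4, 0.0]]), 0.0)
        assert dp[0] == pytest.approx(-rho * amp**2, rel=1e-12)


class TestModeSuperposition:
    @staticmethod
    def _pod_fractions(flow):
        n = flow.n_steps
        S = flow.velocity.reshape(n, -1).T
        dv = flow.grid.voxel_volume_mm3 * 1e-9
        lam = np.linalg.eigvalsh((dv / n) * (S.T @ S))[::-1]
        lam = np.maximum(lam, 0)
        return lam / lam.sum()

    def test_single_mode_spectrum(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), (8, 8, 8), 0.01, 20)
        flow = make_mode_superposition([1.0], 20, grid, rng_seed=0)
        f = self._pod_fractions(flow)
        assert f[0] == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_pair_spectrum(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), (8, 8, 8), 0.01, 30)
        flow = make_mode_superposition([0.5, 0.5], 30, grid, rng_seed=1)
        f = self._pod_fractions(flow)
        assert f[0] == pytest.approx(0.5, abs=1e-9)
        assert f[1] == pytest.approx(0.5, abs=1e-9)

    def test_reconstruction_from_stored_modes_is_exact(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), (8, 10, 8), 0.01, 25)
        flow = make_mode_superposition([0.6, 0.2], 25, grid, rng_seed=3)
        md = flow.metadata
        rec = md["modes"] @ md["coefficients"].T
        S = flow.velocity.reshape(25, -1).T
        assert np.abs(rec - S).max() <= 1e-12 * np.abs(S).max()

    def test_too_few_snapshots_rejected(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), (8, 8, 8), 0.01, 4)
        with pytest.raises(ValueError, match="exceed"):
            make_mode_superposition([0.3, 0.3, 0.2, 0.1], 4, grid, rng_seed=0)


class TestAdvection:
    def test_zero_flow_keeps_particles_static(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), (8, 8, 8), 0.01, 10)
        vel = np.zeros((10, 8, 8, 8, 3))
        mask = np.ones((10, 8, 8, 8), dtype=bool)
        flow = FlowField4D(grid, vel, mask)
        tracks = advect_particles(flow, 20, rng_seed=0)
        assert np.allclose(tracks.positions, tracks.positions[:, :1], equal_nan=True)
        assert tracks.active.all()

    @staticmethod
    def _solid_body_flow(omega, n_steps, dt):
        grid = GridSpec((-16, -16, -16), (0.5, 0.5, 0.5), (64, 64, 64), dt, n_steps)
        X, Y, _ = grid.meshgrid()
        vel = np.zeros((n_steps, *grid.shape, 3))
        vel[..., 0] = -omega * Y * 1e-3
        vel[..., 1] = omega * X * 1e-3
        mask = np.ones((n_steps, *grid.shape), dtype=bool)
        return FlowField4D(grid, vel, mask)

    def test_solid_body_rotation_period_and_richardson_ratio(self):
        """A particle returns to its start after 2 pi / omega; halving the
        step shrinks the closure error by roughly the 4th-order factor.

        The step-halved run inherits the truncation of trilinear sampling,
        so the ratio is tested loosely above the asymptotic 16.
        """
        omega = 2 * np.pi  # 1 s period
        n, dt = 101, 0.01
        flow = self._solid_body_flow(omega, n, dt)
        flow2 = self._solid_body_flow(omega, 2 * n - 1, dt / 2)
        start = np.array([[5.0, 0.0, 0.0]])

        def closure(flow):
            ts = TrackSet(np.tile(start, (1, 1, 1)), np.ones((1, 1), bool), flow.grid.time_step)
            x = start.copy()
            mm = 1e3
            for i in range(flow.n_steps - 1):
                t = i * flow.grid.time_step
                k1 = flow.sample_velocity(x, t)
                k2 = flow.sample_velocity(x + 0.5 * flow.grid.time_step * mm * k1, t)
                k3 = flow.sample_velocity(x + 0.5 * flow.grid.time_step * mm * k2, t)
                k4 = flow.sample_velocity(x + flow.grid.time_step * mm * k3, t)
                x = x + flow.grid.time_step * mm / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            return np.linalg.norm(x - start)

        e1, e2 = closure(flow), closure(flow2)
        assert e1 < 0.05  # closes within 1% of the radius
        assert e1 / max(e2, 1e-15) > 4.0

    def test_taylor_green_richardson_against_integrator(self):
        grid = GridSpec((0, 0, 0), (0.5, 0.5, 0.5), (64, 64, 64), 0.005, 41)
        flow, _ = make_taylor_green(grid, amplitude=0.3)
        grid2 = GridSpec((0, 0, 0), (0.5, 0.5, 0.5), (64, 64, 64), 0.0025, 81)
        flow2, _ = make_taylor_green(grid2, amplitude=0.3)
        t1 = advect_particles(flow, 50, rng_seed=5)
        t2 = advect_particles(flow2, 50, rng_seed=5)
        # identical seeding; compare final positions of surviving tracks
        both = t1.active[:, -1] & t2.active[:, -1]
        assert both.sum() > 5
        d = np.linalg.norm(t1.positions[both, -1] - t2.positions[both, -1], axis=1)
        disp = np.linalg.norm(t1.positions[both, -1] - t1.positions[both, 0], axis=1)
        # halving the step changes trajectories only at the numerical floor
        # (well below 0.1% of the travelled distance)
        assert np.median(d) < 1e-3 * np.median(disp)

    def test_particles_leaving_mask_terminate(self, lv_flow):
        tracks = advect_particles(lv_flow, 300, rng_seed=0)
        # systole shrinks the wall: some near-wall particles must terminate
        assert tracks.terminated.sum() > 0
        for k in np.flatnonzero(tracks.terminated)[:10]:
            act = tracks.active[k]
            last = np.flatnonzero(act)[-1]
            assert not act[last + 1:].any()  # terminated tracks never reappear

    def test_track_ids_unique(self, lv_flow):
        tracks = advect_particles(lv_flow, 50, rng_seed=0)
        assert len(np.unique(tracks.ids)) == tracks.n_tracks


class TestRendering:
    def test_zero_particles_renders_background(self):
        cam = default_camera_model(image_shape=(64, 64))
        ts = TrackSet(np.full((1, 3, 3), np.nan), np.zeros((1, 3), bool), 5e-4)
        imgs = render_images(ts, cam)
        assert imgs.frames.sum() == 0

    def test_ppp_arithmetic_and_energy_proportionality(self, rng):
        """512 x 512 at 0.04 ppp corresponds to ~10,486 particles; image
        energy grows linearly with the in-frustum particle count."""
        assert round(512 * 512 * 0.04) == 10486
        cam = default_camera_model(image_shape=(128, 128), mm_per_px=0.5)
        energies = []
        for n in (50, 100):
            pos = rng.uniform(-15, 15, (n, 1, 3))
            ts = TrackSet(pos, np.ones((n, 1), bool), 5e-4)
            imgs = render_images(ts, cam)
            energies.append(imgs.frames[0, 0].astype(float).sum())
        assert energies[1] / energies[0] == pytest.approx(2.0, rel=0.01)

    def test_single_particle_centroid_matches_projection(self):
        cam = default_camera_model(image_shape=(64, 64), mm_per_px=0.5)
        pos = np.array([[[1.23, -0.87, 0.54]]])
        ts = TrackSet(pos, np.ones((1, 1), bool), 5e-4)
        imgs = render_images(ts, cam)
        for v in range(4):
            img = imgs.frames[0, v].astype(float)
            yy, xx = np.mgrid[:64, :64]
            cx = (img * xx).sum() / img.sum()
            cy = (img * yy).sum() / img.sum()
            px = cam.project(pos[0], v)[0]
            assert abs(cx - px[0]) < 0.01
            assert abs(cy - px[1]) < 0.01

    def test_rendering_is_deterministic_and_warns_on_ppp_mismatch(self, rng):
        cam = default_camera_model(image_shape=(64, 64), mm_per_px=0.5)
        pos = rng.uniform(-10, 10, (1, 20, 3)).transpose(1, 0, 2)
        ts = TrackSet(pos, np.ones((20, 1), bool), 5e-4)
        a = render_images(ts, cam, noise_sigma=2.0, rng_seed=9)
        b = render_images(ts, cam, noise_sigma=2.0, rng_seed=9)
        assert np.array_equal(a.frames, b.frames)
        with pytest.warns(UserWarning, match="ppp"):
            render_images(ts, cam, ppp_target=0.04)
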