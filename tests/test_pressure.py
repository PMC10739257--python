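"""Material derivative, momentum balance, pressure-Poisson solves and probes."""

import numpy as np
import pytest

from lv4dflow.binning import BinningConfig
from lv4dflow.grid import FlowField4D, GridSpec, PressureField4D, PA_PER_MMHG
from lv4dflow.pressure import (FluidProperties, PPEConfig,
                               estimate_convective_velocity,
                               material_derivative_eulerian,
                               material_derivative_lagrangian,
                               pressure_gradient, probe_pressure_difference,
                               solve_ppe, solve_pressure_series)
from lv4dflow.synthetic import (advect_particles, make_taylor_green,
                                taylor_green_fields)
from lv4dflow.tracking import TrackerConfig, fit_tracks
from lv4dflow.tracks import TrackSet


def _uniform_flow(n=8, value=(0.2, 0.0, -0.1), n_steps=3):
    grid = GridSpec((0, 0, 0), (1, 1, 1), (n, n, n), 0.002, n_steps)
    vel = np.tile(np.asarray(value), (n_steps, n, n, n, 1))
    return FlowField4D(grid, vel, np.ones((n_steps, n, n, n), bool))


class TestMaterialDerivative:
    def test_steady_uniform_flow_gives_zero(self):
        md = material_derivative_eulerian(_uniform_flow())
        assert np.abs(md.du_dt).max() < 1e-12

    def test_rigid_translation_gives_dU_dt(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), (8, 8, 8), 0.002, 5)
        rates = np.linspace(0.1, 0.5, 5)
        vel = np.zeros((5, 8, 8, 8, 3))
        vel[..., 0] = rates[:, None, None, None]
        flow = FlowField4D(grid, vel, np.ones((5, 8, 8, 8), bool))
        md = material_derivative_eulerian(flow)
        expected = np.gradient(rates, 0.002)
        got = md.du_dt[:, 4, 4, 4, 0]
        assert np.allclose(got, expected, rtol=1e-9)

    def test_eulerian_taylor_green_second_order(self):
        errs = []
        for n in (24, 48):
            grid = GridSpec((0, 0, 0), (48.0 / n,) * 3, (n, n, n), 0.002, 3)
            flow, _ = make_taylor_green(grid, amplitude=0.5)
            md = material_derivative_eulerian(flow)
            _, _, md_fn = taylor_green_fields(grid, 1160.0, 0.0177, 0.5)
            ana = md_fn(grid.centers(), grid.time_step).reshape(*grid.shape, 3)
            errs.append(np.linalg.norm(md.du_dt[1] - ana) / np.linalg.norm(ana))
        assert errs[1] < errs[0] / 3.0  # 2nd-order in h

    def test_ballistic_track_acceleration_recovered_exactly(self):
        """x = 0.5 a t^2 sampled at frame times: the quadratic track fit
        returns the acceleration exactly, and Lagrangian binning grids it."""
        a = np.array([1.2, -0.4, 0.8])  # m/s^2
        dt = 5e-4
        t = np.arange(20) * dt
        pos = 0.5 * a[None] * t[:, None]**2 * 1e3 + np.array([4.0, 4.0, 4.0])
        tracks = TrackSet(np.tile(pos[None], (30, 1, 1))
                          + np.random.default_rng(0).uniform(-2, 2, (30, 1, 3)),
                          np.ones((30, 20), bool), dt)
        tracks = fit_tracks(tracks, TrackerConfig())
        assert np.allclose(tracks.acceleration[:, 5], a, rtol=1e-6)
        grid = GridSpec((0, 0, 0), (1, 1, 1), (8, 8, 8), dt, 4)
        md = material_derivative_lagrangian(
            tracks, grid, BinningConfig(initial_subvolume=8, final_subvolume=8,
                                        mm_per_voxel=1.0))
        assert md.source == "lagrangian_tracks"
        assert np.allclose(md.du_dt[1][md.mask[1]], a, rtol=1e-6)

    def test_lagrangian_taylor_green_matches_analytic(self):
        """A dense tracer lattice advected through the decaying vortex:
        quadratic pathline fits binned with the Gaussian scheme agree with
        the closed-form du/dt + (u.grad)u within 2% (L2, valid voxels).

        Lattice seeding keeps the sampling symmetric so the comparison
        probes the scheme's bias, not Monte-Carlo noise; the tracers are
        integrated with the closed-form velocity (independent of the
        gridded advection code under test elsewhere).
        """
        n = 64
        grid = GridSpec((0, 0, 0), (1, 1, 1), (n, n, n), 0.002, 7)
        vel_fn, _, md_fn = taylor_green_fields(grid, 1160.0, 0.0177, 0.5)
        ax = np.arange(0.0, n, 1.0)
        lattice = np.stack(np.meshgrid(ax, ax, ax[::4], indexing="ij"),
                           axis=-1).reshape(-1, 3)  # thinned in z only (w = 0)
        dt, mm = grid.time_step, 1e3
        step = 3  # lattice instant: sampling is exactly symmetric here
        positions = np.empty((len(lattice), 7, 3))
        positions[:, step] = lattice

        def rk4(x, t, h):
            k1 = vel_fn(x, t)
            k2 = vel_fn(x + 0.5 * h * mm * k1, t + h / 2)
            k3 = vel_fn(x + 0.5 * h * mm * k2, t + h / 2)
            k4 = vel_fn(x + h * mm * k3, t + h)
            return x + h * mm / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

        x = lattice
        for i in range(step, 6):
            x = rk4(x, i * dt, dt)
            positions[:, i + 1] = x
        x = lattice
        for i in range(step, 0, -1):
            x = rk4(x, i * dt, -dt)
            positions[:, i - 1] = x
        tracks = TrackSet(positions, np.ones(positions.shape[:2], bool), dt)
        tracks = fit_tracks(tracks, TrackerConfig())
        cfg = BinningConfig(initial_subvolume=4, final_subvolume=2, mm_per_voxel=1.0,
                            min_samples=1)
        md = material_derivative_lagrangian(tracks, grid, cfg)
        ana = md_fn(grid.centers(), step * dt).reshape(*grid.shape, 3)
        m = md.mask[step]
        assert m.sum() > 0.4 * m.size
        err = np.linalg.norm(md.du_dt[step][m] - ana[m]) / np.linalg.norm(ana[m])
        assert err < 0.02


class TestPressureGradient:
    def test_zero_flow_zero_gradient(self):
        flow = _uniform_flow(value=(0.0, 0.0, 0.0))
        md = material_derivative_eulerian(flow)
        g = pressure_gradient(md, flow)
        assert np.abs(g).max() == 0.0

    def test_taylor_green_gradient_matches_closed_form(self):
        n = 48
        grid = GridSpec((0, 0, 0), (1, 1, 1), (n, n, n), 0.002, 3)
        flow, pres = make_taylor_green(grid, amplitude=0.5)
        md = material_derivative_eulerian(flow)
        g = pressure_gradient(md, flow)
        # analytic grad p from the closed-form pressure
        k = 2 * np.pi / (n * 1e-3)
        X, Y, _ = grid.meshgrid()
        F = np.exp(-2 * (0.0177 / 1160) * k**2 * grid.time_step)
        amp2 = 1160 * 0.5**2 / 2 * k
        ana = np.zeros((*grid.shape, 3))
        ana[..., 0] = amp2 * np.sin(2 * k * X * 1e-3) * F**2
        ana[..., 1] = amp2 * np.sin(2 * k * Y * 1e-3) * F**2
        err = np.linalg.norm(g[1] - ana) / np.linalg.norm(ana)
        assert err < 0.02

    def test_viscous_term_vanishes_for_linear_shear(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), (10, 10, 10), 0.002, 3)
        Y = grid.meshgrid()[1]
        vel = np.zeros((3, 10, 10, 10, 3))
        vel[..., 0] = 20.0 * Y[None] * 1e-3
        flow = FlowField4D(grid, vel, np.ones((3, 10, 10, 10), bool))
        zero_md = material_derivative_eulerian(_uniform_flow(n=10, value=(0, 0, 0)))
        g = pressure_gradient(zero_md, flow, FluidProperties())
        # Laplacian of a linear profile is identically zero
        assert np.abs(g).max() < 1e-9


class TestPoissonSolve:
    def test_zero_gradient_gives_zero_pressure(self):
        mask = np.ones((8, 8, 8), bool)
        grid = GridSpec((0, 0, 0), (1, 1, 1), (8, 8, 8), 0.002, 1)
        p, _ = solve_ppe(np.zeros((8, 8, 8, 3)), mask, grid, PPEConfig(xi=0))
        assert np.abs(p[mask]).max() < 1e-12

    def test_taylor_green_chain_under_one_percent_on_64_cube(self):
        """Material derivative -> momentum balance -> Poisson solve on the
        decaying vortex recovers the analytic pressure to < 1% relative L2
        on a 64^3 box."""
        n = 64
        grid = GridSpec((0, 0, 0), (1, 1, 1), (n, n, n), 0.002, 3)
        flow, pres = make_taylor_green(grid, amplitude=0.5)
        md = material_derivative_eulerian(flow)
        g = pressure_gradient(md, flow)
        p, _ = solve_ppe(g[1], flow.mask[1], grid, PPEConfig(xi=0))
        pa = pres.pressure[1]
        err = np.linalg.norm((p - p.mean()) - (pa - pa.mean())) \
            / np.linalg.norm(pa - pa.mean())
        assert err < 0.01

    def test_xi_coupled_series_tracks_analytic_decay(self):
        """xi = 1 with zero convective velocity (standing decaying
        pattern): the pointwise pressure series follows the analytic
        exponential within 2%."""
        n = 48
        grid = GridSpec((0, 0, 0), (1, 1, 1), (n, n, n), 0.02, 10)
        flow, pres = make_taylor_green(grid, amplitude=0.5)
        md = material_derivative_eulerian(flow)
        p4 = solve_pressure_series(flow, md,
                                   cfg=PPEConfig(xi=1.0, convective_velocity=np.zeros(3)))
        means = p4.pressure.reshape(10, -1).mean(axis=1)
        got = p4.pressure[:, n // 4, n // 4, n // 4] - means
        ana = pres.pressure[:, n // 4, n // 4, n // 4] \
            - pres.pressure.reshape(10, -1).mean(axis=1)
        assert np.abs(got - ana).max() <= 0.02 * np.abs(ana).max()

    def test_linearity_for_xi_zero(self, rng):
        mask = np.ones((10, 10, 10), bool)
        grid = GridSpec((0, 0, 0), (1, 1, 1), (10, 10, 10), 0.002, 1)
        g = rng.standard_normal((10, 10, 10, 3))
        p1, _ = solve_ppe(g, mask, grid, PPEConfig(xi=0))
        p3, _ = solve_ppe(3.0 * g, mask, grid, PPEConfig(xi=0))
        assert np.allclose(p3[mask], 3.0 * p1[mask], rtol=1e-6, atol=1e-8)

    def test_disconnected_probes_invariant_to_constant_offset(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), (12, 12, 12), 0.002, 2)
        mask = np.ones((2, 12, 12, 12), bool)
        Y = grid.meshgrid()[1]
        pres = np.tile(50.0 * Y, (2, 1, 1, 1))
        a = PressureField4D(grid, pres, mask)
        b = PressureField4D(grid, pres + 123.4, mask)
        pa = probe_pressure_difference(a, (6, 2, 6), (6, 10, 6))
        pb = probe_pressure_difference(b, (6, 2, 6), (6, 10, 6))
        assert np.allclose(pa["dp_mmhg"], pb["dp_mmhg"], atol=1e-12)


class TestConvectiveVelocity:
    def test_frozen_translation_recovered(self, rng):
        n = 24
        grid = GridSpec((0, 0, 0), (1, 1, 1), (n, n, n), 0.01, 2)
        base = rng.standard_normal((n, n, n, 3))
        from scipy.ndimage import gaussian_filter
        base = gaussian_filter(base, sigma=(2, 2, 2, 0), mode="wrap")
        vel = np.stack([base, np.roll(base, (2, 1, 0), axis=(0, 1, 2))])
        flow = FlowField4D(grid, vel, np.ones((2, n, n, n), bool))
        uc = estimate_convective_velocity(flow)
        want = np.array([2.0, 1.0, 0.0]) * 1e-3 / 0.01
        assert np.allclose(uc[0], want, atol=0.1 * 1e-3 / 0.01)

    def test_steady_field_gives_zero(self):
        flow = _uniform_flow(n=12, n_steps=2)
        uc = estimate_convective_velocity(flow)
        assert np.allclose(uc, 0.0, atol=1e-9)

    def test_pure_decay_gives_zero(self):
        grid = GridSpec((0, 0, 0), (2, 2, 2), (16, 16, 16), 0.05, 2)
        flow, _ = make_taylor_green(grid, amplitude=0.5)
        uc = estimate_convective_velocity(flow)
        assert np.linalg.norm(uc[0]) < 0.05 * 2e-3 / 0.05


class TestProbes:
    def test_uniform_pressure_gives_zero_difference(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), (10, 10, 10), 0.002, 3)
        mask = np.ones((3, 10, 10, 10), bool)
        p = PressureField4D(grid, np.full((3, 10, 10, 10), 7.0), mask)
        out = probe_pressure_difference(p, (3, 3, 5), (7, 7, 5))
        assert np.allclose(out["dp_mmhg"], 0.0, atol=1e-14)

    def test_linear_pressure_box_average_equals_center_value(self):
        grid = GridSpec((0, 0, 0), (0.5, 0.5, 0.5), (20, 20, 20), 0.002, 1)
        alpha = 40.0  # Pa / mm
        Y = grid.meshgrid()[1]
        p = PressureField4D(grid, alpha * Y[None], np.ones((1, 20, 20, 20), bool))
        la, lb = (5.0, 2.0, 5.0), (5.0, 8.0, 5.0)
        out = probe_pressure_difference(p, la, lb, box_mm=2.0)
        want = alpha * (lb[1] - la[1]) / PA_PER_MMHG
        assert out["dp_mmhg"][0] == pytest.approx(want, rel=1e-12)

    def test_probe_box_exiting_mask_is_flagged(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), (10, 10, 10), 0.002, 1)
        mask = np.ones((1, 10, 10, 10), bool)
        mask[0, :, :3] = False
        pres = np.where(mask[0], 5.0, np.nan)[None]
        p = PressureField4D(grid, pres, mask)
        out = probe_pressure_difference(p, (5, 3, 5), (5, 7, 5), box_mm=3.0)
        assert out["flagged"][0]
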