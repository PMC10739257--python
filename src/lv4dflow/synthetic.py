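"""Synthetic ground-truth flows standing in for the in-vitro experiment.

Three generators are provided:

* :func:`make_lv_flow` — a pulsatile left-ventricle-like flow (diastolic
  trans-mitral jet with a translating vortex ring, late-diastolic apical
  swirl) inside a contracting truncated-ellipsoid domain,
* :func:`make_taylor_green` — the decaying 2D Taylor-Green vortex embedded
  in 3D, with closed-form pressure (analytic oracle for the pressure chain),
* :func:`make_mode_superposition` — snapshots assembled from orthonormal
  random modes with a prescribed modal energy spectrum (oracle for POD).

All velocity components of the LV flow derive from axisymmetric Stokes
stream functions or azimuthal swirl fields, so the continuum field is
divergence-free by construction; only the sampling onto the grid
introduces discretisation-level divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import FlowField4D, GridSpec, PressureField4D
from .tracks import TrackSet

__all__ = [
    "LVFlowParams",
    "LVAnalyticFlow",
    "make_lv_flow",
    "make_taylor_green",
    "taylor_green_fields",
    "make_mode_superposition",
    "advect_particles",
]


@dataclass(frozen=True)
class LVFlowParams:
    """Physical parameters of the pulsatile LV-like flow.

    The defaults reproduce the study conditions: a 857 ms cardiac cycle
    (70 bpm) with a 300 ms systole, 50 ml stroke volume, and the
    blood-mimicking fluid (rho = 1160 kg/m^3, mu = 0.0177 Pa s).

    ``peak_jet_speed`` of ``None`` means "derive the jet amplitude from the
    stroke volume", which makes the diastolic trans-mitral flux integrate
    to ``stroke_volume`` by construction. An explicit value rescales the
    entire velocity field relative to that calibration (0 gives an
    identically zero velocity field while the wall keeps moving).
    """

    cycle_period: float = 0.857       # s
    systole_duration: float = 0.300   # s
    stroke_volume: float = 50.0       # ml
    peak_jet_speed: float | None = None  # m/s; None -> derived from stroke volume
    jet_radius: float = 7.5           # mm, Gaussian e-folding radius of the jet
    ring_translation_speed: float = 0.06  # m/s, apex-ward vortex-ring drift
    apical_vortex_strength: float = 30.0  # 1/s, swirl rate of the apical vortex
    density: float = 1160.0           # kg/m^3
    dynamic_viscosity: float = 0.0177  # Pa s
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cycle_period", "systole_duration", "stroke_volume", "jet_radius",
                     "ring_translation_speed", "apical_vortex_strength", "density",
                     "dynamic_viscosity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.systole_duration >= self.cycle_period:
            raise ValueError("systole_duration must be shorter than cycle_period")
        if self.peak_jet_speed is not None and self.peak_jet_speed < 0:
            raise ValueError("peak_jet_speed must be >= 0")

    @property
    def diastole_duration(self) -> float:
        return self.cycle_period - self.systole_duration


# Geometry of the parameterised ventricle (mm). A truncated prolate
# ellipsoid stands in for the CT-averaged phantom shape: semi-axes below,
# base plane at y = +BASE_Y, apex at y = -SEMI_B; mitral and aortic orifice
# axes pierce the base plane with a 40 degree separation.
SEMI_A = 24.0
SEMI_B = 45.0
SEMI_C = 24.0
BASE_Y = 27.0
ORIFICE_TILT_DEG = 20.0
MITRAL_POINT = np.array([-8.0, BASE_Y, 0.0])
AORTIC_POINT = np.array([8.0, BASE_Y, 0.0])
_s, _c = math.sin(math.radians(ORIFICE_TILT_DEG)), math.cos(math.radians(ORIFICE_TILT_DEG))
MITRAL_AXIS = np.array([_s, -_c, 0.0])   # unit, pointing into the ventricle
AORTIC_AXIS = np.array([-_s, -_c, 0.0])
JET_LENGTH = 40.0       # mm, axial e-folding length of the jets
RING_SIGMA = 6.0        # mm, vortex-ring core width
RING_START_ZETA = 8.0   # mm, ring stand-off from the base plane at onset
APEX_SWIRL_CENTER_Y = -28.0
APEX_SWIRL_RADIUS = 10.0  # mm
APEX_SWIRL_HEIGHT = 13.0  # mm
APEX_SWIRL_TAU = 0.12     # s, temporal width of the apical-vortex envelope
RING_SPEED_FRACTION = 0.4  # ring swirl speed relative to the jet peak


def _truncated_ellipsoid_volume_ml(a: float, b: float, c: float, y_cut: float) -> float:
    """Analytic volume (ml) of x^2/a^2+y^2/b^2+z^2/c^2<=1 cut at y <= y_cut."""
    integral = (y_cut - y_cut**3 / (3 * b**2)) - (-b + b**3 / (3 * b**2))
    return math.pi * a * c * integral / 1000.0


class LVAnalyticFlow:
    """Closed-form evaluator behind :func:`make_lv_flow`.

    Provides pointwise velocity (m/s), the time-varying domain mask, and the
    analytic volume waveform. Exposed separately so tests and analyses can
    integrate fluxes on arbitrarily fine quadrature grids.
    """

    def __init__(self, params: LVFlowParams):
        self.params = params
        self.edv_ml = _truncated_ellipsoid_volume_ml(SEMI_A, SEMI_B, SEMI_C, BASE_Y)
        p = params
        # Half-sine flow-rate waveforms, each integrating to the stroke volume.
        self._q_sys = p.stroke_volume * 1e-6 * math.pi / (2 * p.systole_duration)   # m^3/s
        self._q_dia = p.stroke_volume * 1e-6 * math.pi / (2 * p.diastole_duration)  # m^3/s
        r_m = p.jet_radius * 1e-3
        self._u_jet_default = self._q_dia / (math.pi * r_m**2)  # centreline peak, m/s
        if p.peak_jet_speed is None:
            self.scale = 1.0
        else:
            self.scale = p.peak_jet_speed / self._u_jet_default
        self.peak_jet_speed = self._u_jet_default * self.scale

    # -- waveforms --------------------------------------------------------
    def _tc(self, t):
        return np.asarray(t, dtype=float) % self.params.cycle_period

    def inflow_rate(self, t):
        """Diastolic volumetric inflow rate (m^3/s), zero during systole."""
        p, tc = self.params, self._tc(t)
        dia = tc >= p.systole_duration
        return np.where(dia, self._q_dia * np.sin(np.pi * (tc - p.systole_duration)
                                                  / p.diastole_duration), 0.0) * self.scale

    def outflow_rate(self, t):
        p, tc = self.params, self._tc(t)
        sys_ = tc < p.systole_duration
        return np.where(sys_, self._q_sys * np.sin(np.pi * tc / p.systole_duration), 0.0) * self.scale

    def volume_ml(self, t):
        """Cavity volume waveform (ml); periodic, range = stroke_volume."""
        p, tc = self.params, self._tc(t)
        w = np.where(tc < p.systole_duration,
                     0.5 * (1 - np.cos(np.pi * tc / p.systole_duration)),
                     0.5 * (1 + np.cos(np.pi * (tc - p.systole_duration) / p.diastole_duration)))
        return self.edv_ml - p.stroke_volume * w

    def _gamma(self, t):
        # lateral scale factor of the wall; volume ~ gamma^2
        return np.sqrt(self.volume_ml(t) / self.edv_ml)

    # -- geometry ---------------------------------------------------------
    def mask_at(self, points_mm: np.ndarray, t: float) -> np.ndarray:
        g = float(self._gamma(t))
        x, y, z = points_mm[:, 0], points_mm[:, 1], points_mm[:, 2]
        r2 = (x / (SEMI_A * g))**2 + (y / SEMI_B)**2 + (z / (SEMI_C * g))**2
        return (r2 <= 1.0) & (y <= BASE_Y)

    # -- velocity components ---------------------------------------------
    @staticmethod
    def _axis_coords(points, origin, axis):
        rel = points - origin
        zeta = rel @ axis
        perp = rel - np.outer(zeta, axis)
        r = np.linalg.norm(perp, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rhat = np.where(r[:, None] > 1e-12, perp / np.maximum(r, 1e-12)[:, None], 0.0)
        return zeta, r, rhat

    def _jet(self, points, origin, axis, q_m3s, sign):
        """Axisymmetric jet from the stream function
        psi = (Q/2pi) (1 - exp(-(r/R)^2)) exp(-(zeta/L)^2); exactly solenoidal."""
        p = self.params
        zeta, r, rhat = self._axis_coords(points, origin, axis)
        R, L = p.jet_radius, JET_LENGTH
        zc = np.maximum(zeta, 0.0)
        g = np.exp(-((zc / L)**2))
        dg = -2.0 * zc / L**2 * g
        q_mm = q_m3s * 1e9  # mm^3/s
        u_zeta = q_mm / (math.pi * R**2) * np.exp(-((r / R)**2)) * g
        with np.errstate(invalid="ignore", divide="ignore"):
            u_r = np.where(r > 1e-9,
                           -q_mm / (2 * math.pi) * (1 - np.exp(-((r / R)**2))) / np.maximum(r, 1e-9) * dg,
                           0.0)
        v_mm = sign * (u_zeta[:, None] * axis + u_r[:, None] * rhat)
        return v_mm * 1e-3  # m/s

    def _ring(self, points, t):
        """Translating vortex ring about the mitral axis,
        psi = A r^2 exp(-((r-r0)^2 + (zeta-zeta_c)^2)/sigma^2)."""
        p = self.params
        tc = float(self._tc(t))
        if tc < p.systole_duration:
            return np.zeros_like(points, dtype=float)
        env = math.sin(math.pi * (tc - p.systole_duration) / p.diastole_duration)
        zeta, r, rhat = self._axis_coords(points, MITRAL_POINT, MITRAL_AXIS)
        r0 = 1.2 * p.jet_radius
        zc = RING_START_ZETA + p.ring_translation_speed * 1e3 * (tc - p.systole_duration)
        # A in mm/s: swirl speed around the core is ~2A
        A = 0.5 * RING_SPEED_FRACTION * self.peak_jet_speed * 1e3 * env
        q = ((r - r0)**2 + (zeta - zc)**2) / RING_SIGMA**2
        e = np.exp(-q)
        u_zeta = A * e * (2.0 - 2.0 * r * (r - r0) / RING_SIGMA**2)
        u_r = A * e * r * 2.0 * (zeta - zc) / RING_SIGMA**2
        v_mm = u_zeta[:, None] * MITRAL_AXIS + u_r[:, None] * rhat
        return v_mm * 1e-3  # mm/s -> m/s

    def _apical_swirl(self, points, t):
        """Azimuthal swirl about the long axis near the apex (divergence-free)."""
        p = self.params
        tc = float(self._tc(t))
        d = min(tc, p.cycle_period - tc)  # circular distance to end-diastole (t = 0)
        env = math.exp(-((d / APEX_SWIRL_TAU)**2))
        x, y, z = points[:, 0], points[:, 1], points[:, 2]
        r = np.sqrt(x**2 + z**2)
        amp = p.apical_vortex_strength * self.scale * env
        f = np.exp(-((r / APEX_SWIRL_RADIUS)**2) - (((y - APEX_SWIRL_CENTER_Y) / APEX_SWIRL_HEIGHT)**2))
        # u_phi * phi_hat about +y axis: phi_hat = (-z, 0, x)/r; u_phi = amp * r * f
        v = np.zeros_like(points, dtype=float)
        v[:, 0] = -amp * z * f
        v[:, 2] = amp * x * f
        return v * 1e-3  # mm/s -> m/s

    def velocity(self, points_mm: np.ndarray, t: float) -> np.ndarray:
        """Velocity (m/s) at mm positions; defined on all of space."""
        points = np.atleast_2d(np.asarray(points_mm, dtype=float))
        tc = float(self._tc(t))
        v = self._apical_swirl(points, t)
        q_in = float(self.inflow_rate(tc))
        if q_in != 0.0:
            v = v + self._jet(points, MITRAL_POINT, MITRAL_AXIS, q_in, sign=1.0)
            v = v + self._ring(points, t)
        q_out = float(self.outflow_rate(tc))
        if q_out != 0.0:
            # converging flow toward the aortic orifice: reversed jet
            v = v + self._jet(points, AORTIC_POINT, AORTIC_AXIS, q_out, sign=-1.0)
        return v


def make_lv_flow(params: LVFlowParams, grid: GridSpec) -> FlowField4D:
    """Sample the analytic LV-like flow onto a grid.

    The grid must resolve the jet: fewer than 3 voxels across the jet
    diameter is rejected. Velocity is stored on the full grid (the analytic
    field is defined everywhere), the mask marks the cavity.
    """
    coarsest = max(grid.spacing)
    if 2.0 * params.jet_radius / coarsest < 3.0:
        raise ValueError(
            f"grid too coarse to resolve the jet: {2 * params.jet_radius:.1f} mm jet diameter "
            f"spans {2 * params.jet_radius / coarsest:.2f} voxels (< 3) at "
            f"{coarsest:.2f} mm spacing")
    flow_fn = LVAnalyticFlow(params)
    pts = grid.centers()
    vel = np.empty((grid.n_steps, *grid.shape, 3))
    mask = np.empty((grid.n_steps, *grid.shape), dtype=bool)
    for i, t in enumerate(grid.times()):
        vel[i] = flow_fn.velocity(pts, t).reshape(*grid.shape, 3)
        mask[i] = flow_fn.mask_at(pts, t).reshape(grid.shape)
    return FlowField4D(grid, vel, mask, cycle_period=params.cycle_period,
                       metadata={"generator": "lv_flow", "params": params,
                                 "rng_seed": params.rng_seed})


# ---------------------------------------------------------------------------
# Taylor-Green oracle
# ---------------------------------------------------------------------------

def taylor_green_fields(grid: GridSpec, density: float, viscosity: float,
                        amplitude: float):
    """Closed-form Taylor-Green velocity/pressure evaluators.

    The 2D decaying vortex lattice embedded in 3D (w = 0) on the periodic
    box spanned by the grid's x extent::

        u =  A cos(kx) sin(ky) F(t),   v = -A sin(kx) cos(ky) F(t)
        p = -(rho A^2 / 4)(cos 2kx + cos 2ky) F(t)^2,  F = exp(-2 nu k^2 t)

    Returns ``(velocity_fn, pressure_fn, dudt_fn)`` taking (points_mm, t).
    """
    L_m = grid.shape[0] * grid.spacing[0] * 1e-3
    k = 2.0 * math.pi / L_m
    nu = viscosity / density

    def _xy(points_mm):
        p = np.atleast_2d(np.asarray(points_mm, dtype=float)) * 1e-3
        o = np.asarray(grid.origin) * 1e-3
        return k * (p[:, 0] - o[0]), k * (p[:, 1] - o[1])

    def velocity(points_mm, t):
        kx, ky = _xy(points_mm)
        F = math.exp(-2.0 * nu * k**2 * t)
        v = np.zeros((len(kx), 3))
        v[:, 0] = amplitude * np.cos(kx) * np.sin(ky) * F
        v[:, 1] = -amplitude * np.sin(kx) * np.cos(ky) * F
        return v

    def pressure(points_mm, t):
        kx, ky = _xy(points_mm)
        F = math.exp(-2.0 * nu * k**2 * t)
        return -(density * amplitude**2 / 4.0) * (np.cos(2 * kx) + np.cos(2 * ky)) * F**2

    def material_derivative(points_mm, t):
        """Du/Dt = du/dt + (u . grad) u, closed form (m/s^2)."""
        kx, ky = _xy(points_mm)
        F = math.exp(-2.0 * nu * k**2 * t)
        dudt = np.zeros((len(kx), 3))
        dudt[:, 0] = -2.0 * nu * k**2 * amplitude * np.cos(kx) * np.sin(ky) * F
        dudt[:, 1] = 2.0 * nu * k**2 * amplitude * np.sin(kx) * np.cos(ky) * F
        conv = np.zeros_like(dudt)
        A2kF2 = amplitude**2 * k * F**2
        conv[:, 0] = -0.5 * A2kF2 * np.sin(2 * kx)
        conv[:, 1] = -0.5 * A2kF2 * np.sin(2 * ky)
        return dudt + conv

    return velocity, pressure, material_derivative


def make_taylor_green(grid: GridSpec, density: float = 1160.0,
                      viscosity: float = 0.0177, amplitude: float = 0.5
                      ) -> tuple[FlowField4D, PressureField4D]:
    """Sample the decaying Taylor-Green field and its analytic pressure."""
    vel_fn, p_fn, _ = taylor_green_fields(grid, density, viscosity, amplitude)
    pts = grid.centers()
    vel = np.empty((grid.n_steps, *grid.shape, 3))
    prs = np.empty((grid.n_steps, *grid.shape))
    for i, t in enumerate(grid.times()):
        vel[i] = vel_fn(pts, t).reshape(*grid.shape, 3)
        prs[i] = p_fn(pts, t).reshape(grid.shape)
    mask = np.ones((grid.n_steps, *grid.shape), dtype=bool)
    meta = {"generator": "taylor_green", "density": density,
            "viscosity": viscosity, "amplitude": amplitude}
    return (FlowField4D(grid, vel, mask, metadata=dict(meta)),
            PressureField4D(grid, prs, mask.copy(), reference_note="analytic (zero mean)",
                            metadata=dict(meta)))


# ---------------------------------------------------------------------------
# Prescribed-spectrum mode superposition
# ---------------------------------------------------------------------------

def make_mode_superposition(spectrum, n_snapshots: int, grid: GridSpec,
                            rng_seed: int = 0) -> FlowField4D:
    """Snapshots with an exactly prescribed modal energy spectrum.

    Random smooth fields are orthonormalised into spatial modes; seeded
    Gaussian coefficient series are orthogonalised over time and rescaled
    so each mode's empirical energy share equals the prescribed fraction
    exactly. Any remainder (1 - sum(spectrum)) is spread geometrically over
    additional low-energy modes. Snapshot POD of the output therefore
    recovers ``spectrum`` to machine precision.
    """
    fracs = np.asarray(spectrum, dtype=float)
    if fracs.ndim != 1 or len(fracs) == 0 or (fracs <= 0).any():
        raise ValueError("spectrum must be a non-empty list of positive fractions")
    if fracs.sum() > 1.0 + 1e-9:
        raise ValueError(f"energy fractions sum to {fracs.sum():.4f} > 1")
    remainder = max(0.0, 1.0 - fracs.sum())
    if remainder > 1e-12:
        n_extra = min(6, n_snapshots - len(fracs) - 1)
        if n_extra > 0:
            w = 0.5 ** np.arange(n_extra)
            fracs = np.concatenate([fracs, remainder * w / w.sum()])
    n_modes = len(fracs)
    if n_snapshots <= n_modes:
        raise ValueError(
            f"n_snapshots={n_snapshots} must exceed the number of modes ({n_modes}); "
            "the spectrum is not recoverable otherwise")
    if grid.n_steps != n_snapshots:
        grid = GridSpec(grid.origin, grid.spacing, grid.shape, grid.time_step, n_snapshots)

    rng = np.random.default_rng(rng_seed)
    n_dof = 3 * grid.n_voxels
    raw = rng.standard_normal((*grid.shape, 3, n_modes))
    raw = ndimage.gaussian_filter(raw, sigma=(1.5, 1.5, 1.5, 0, 0))
    phi, _ = np.linalg.qr(raw.reshape(n_dof, n_modes))  # orthonormal, plain l2

    coeffs_raw = rng.standard_normal((n_snapshots, n_modes))
    q, _ = np.linalg.qr(coeffs_raw)  # orthogonal coefficient series
    dv = grid.voxel_volume_mm3 * 1e-9  # m^3
    total_energy = 0.25 * grid.n_voxels * dv  # ~ (0.5 m/s)^2 average speed scale
    # ||a_k||^2 = N * lambda_k with <phi, phi>_dv = 1
    lam = fracs * total_energy
    coeffs = q * np.sqrt(n_snapshots * lam)
    modes = phi / math.sqrt(dv)  # unit norm under the dv-weighted inner product

    snaps = modes @ coeffs.T  # (n_dof, N)
    vel = np.ascontiguousarray(snaps.T).reshape(n_snapshots, *grid.shape, 3)
    mask = np.ones((n_snapshots, *grid.shape), dtype=bool)
    return FlowField4D(grid, vel, mask,
                       metadata={"generator": "mode_superposition", "rng_seed": rng_seed,
                                 "fractions": fracs, "modes": modes,
                                 "coefficients": coeffs, "total_energy": total_energy})


# ---------------------------------------------------------------------------
# Particle advection
# ---------------------------------------------------------------------------

def advect_particles(flow: FlowField4D, n_particles: int, rng_seed: int = 0) -> TrackSet:
    """Advect tracers through a gridded flow: ground truth for the tracker.

    Particles are seeded uniformly inside the initial mask and integrated
    with classical RK4 at the flow's stored time step (trilinear in space,
    linear in time). A particle leaving the mask is terminated and flagged;
    its positions stay NaN afterwards.
    """
    if n_particles <= 0:
        raise ValueError("n_particles must be positive")
    if not flow.mask[0].any():
        raise ValueError("empty mask at seeding time")
    rng = np.random.default_rng(rng_seed)
    grid = flow.grid

    vox = np.argwhere(flow.mask[0])
    pick = rng.integers(0, len(vox), size=n_particles)
    offs = rng.random((n_particles, 3)) - 0.5
    pos0 = (vox[pick] + 0.5 + offs) * np.asarray(grid.spacing) + np.asarray(grid.origin)

    n_steps = grid.n_steps
    dt = grid.time_step
    positions = np.full((n_particles, n_steps, 3), np.nan)
    active = np.zeros((n_particles, n_steps), dtype=bool)
    terminated = np.zeros(n_particles, dtype=bool)

    positions[:, 0] = pos0
    active[:, 0] = True
    x = pos0.copy()
    alive = np.ones(n_particles, dtype=bool)
    mm = 1e3  # m/s * s -> mm
    for i in range(n_steps - 1):
        t = i * dt
        idx = np.flatnonzero(alive)
        if len(idx) == 0:
            break
        xi = x[idx]
        k1 = flow.sample_velocity(xi, t)
        k2 = flow.sample_velocity(xi + 0.5 * dt * mm * k1, t + 0.5 * dt)
        k3 = flow.sample_velocity(xi + 0.5 * dt * mm * k2, t + 0.5 * dt)
        k4 = flow.sample_velocity(xi + dt * mm * k3, t + dt)
        xn = xi + (dt * mm / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        inside = flow.inside_mask(xn, i + 1)
        x[idx] = xn
        still = idx[inside]
        gone = idx[~inside]
        positions[still, i + 1] = xn[inside]
        active[still, i + 1] = True
        alive[gone] = False
        terminated[gone] = True
    return TrackSet(positions, active, time_step=dt, terminated=terminated,
                    metadata={"rng_seed": rng_seed, "n_seeded": n_particles})
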