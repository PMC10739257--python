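"""Relative pressure from 4D velocity via the pressure-Poisson equation.

The chain implemented here mirrors the measurement pipeline: the material
derivative Du/Dt is evaluated either along particle pathlines (quadratic
least-squares track fits, binned to the grid) or from the gridded field
(du/dt + (u . grad) u); the momentum balance of an incompressible fluid,

    grad p = -rho Du/Dt + mu laplacian(u),

provides the pressure gradient; taking its divergence yields a Poisson
equation solved on the masked domain with Neumann data from the same
gradient. A weighting factor xi couples consecutive time steps through
the convective pressure time-derivative (a line integral of grad p along
the convective displacement), so a Dirichlet anchor (zero domain mean) is
needed only at the first step and the result is a *relative* pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg

from .binning import BinningConfig, bin_velocity
from .grid import (FlowField4D, GridSpec, PressureField4D, nearest_fill,
                   trilinear_sample, MMHG_PER_PA)
from .tracks import TrackSet

__all__ = [
    "FluidProperties", "PPEConfig", "MaterialDerivativeField",
    "material_derivative_lagrangian", "material_derivative_eulerian",
    "pressure_gradient", "solve_ppe", "solve_pressure_series",
    "estimate_convective_velocity", "probe_pressure_difference",
]


@dataclass(frozen=True)
class FluidProperties:
    """Working-fluid constants (defaults: the blood-mimicking
    water-glycerol mixture, rho = 1160 kg/m^3, mu = 0.0177 Pa s)."""

    density: float = 1160.0
    dynamic_viscosity: float = 0.0177

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("fluid properties must be positive")


@dataclass(frozen=True)
class PPEConfig:
    """Pressure-Poisson solver settings.

    ``xi`` weights the temporal-coupling term (0 = independent per-step
    solves); ``convective_velocity`` is either a per-step (3,) vector
    array, a single vector, or ``"estimated"`` (least-squares bulk shift
    between consecutive fields).
    """

    xi: float = 1.0
    convective_velocity: object = "estimated"
    solver_tolerance: float = 1e-8
    quadrature_points: int = 4  # line-integral samples for the xi term

    def __post_init__(self) -> None:
        if self.xi < 0:
            raise ValueError("xi must be >= 0")
        if self.solver_tolerance <= 0:
            raise ValueError("solver_tolerance must be positive")


@dataclass
class MaterialDerivativeField:
    """Du/Dt (m/s^2) on the grid; ``source`` records the evaluation route."""

    grid: GridSpec
    du_dt: np.ndarray          # (n_steps, nx, ny, nz, 3)
    mask: np.ndarray
    source: str = "eulerian_field"
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Material derivative
# ---------------------------------------------------------------------------

def material_derivative_lagrangian(tracks: TrackSet, grid: GridSpec,
                                   cfg: BinningConfig | None = None
                                   ) -> MaterialDerivativeField:
    """Du/Dt from particle pathlines.

    Per-track accelerations (second-order least-squares fits along the
    pathline, produced by the track fitter) are binned onto the grid with
    the same Gaussian scheme as the velocity.
    """
    if tracks.acceleration is None:
        raise ValueError("tracks carry no fitted accelerations; run fit_tracks first")
    binned = bin_velocity(tracks, grid, cfg, which="acceleration")
    return MaterialDerivativeField(binned.grid, binned.velocity, binned.mask,
                                   source="lagrangian_tracks",
                                   metadata=dict(binned.metadata))


def material_derivative_eulerian(flow: FlowField4D) -> MaterialDerivativeField:
    """Du/Dt = du/dt + (u . grad) u from the gridded field.

    Central differences in time and space; one-sided (and flagged) at the
    first/last step when fewer than 3 steps are available.
    """
    from .fields import velocity_gradient

    v = flow.velocity
    dt = flow.grid.time_step
    dudt = np.gradient(v, dt, axis=0) if flow.n_steps >= 2 else np.zeros_like(v)
    out = np.empty_like(v)
    for t in range(flow.n_steps):
        G = velocity_gradient(flow, t)  # G[i, j] = du_i/dx_j
        conv = np.einsum("...ij,...j->...i", G, v[t])
        out[t] = dudt[t] + conv
    meta = {"one_sided_time": flow.n_steps < 3}
    return MaterialDerivativeField(flow.grid, out, flow.mask.copy(),
                                   source="eulerian_field", metadata=meta)


# ---------------------------------------------------------------------------
# Pressure gradient (momentum balance)
# ---------------------------------------------------------------------------

def _masked_laplacian_field(u: np.ndarray, mask: np.ndarray, spacing_m) -> np.ndarray:
    """7-point Laplacian of each velocity component, nearest-filled at the wall."""
    uf = nearest_fill(u, mask)
    out = np.zeros_like(uf)
    for ax, h in enumerate(spacing_m):
        d2 = (np.roll(uf, -1, axis=ax) - 2 * uf + np.roll(uf, +1, axis=ax)) / h**2
        # one-sided second differences at the grid edges (exact for
        # quadratics; zero for linear profiles)
        lo = [slice(None)] * uf.ndim
        hi = [slice(None)] * uf.ndim
        lo[ax], hi[ax] = 0, -1
        lo1 = list(lo); lo1[ax] = 1
        hi1 = list(hi); hi1[ax] = -2
        d2[tuple(lo)] = d2[tuple(lo1)]
        d2[tuple(hi)] = d2[tuple(hi1)]
        out += d2
    return out


def pressure_gradient(md: MaterialDerivativeField, flow: FlowField4D,
                      fluid: FluidProperties | None = None) -> np.ndarray:
    """grad p = -rho Du/Dt + mu laplacian(u), per voxel per step (Pa/m)."""
    fluid = fluid or FluidProperties()
    if md.grid.shape != flow.grid.shape:
        raise ValueError("material derivative and flow live on different grids")
    spacing_m = [s * 1e-3 for s in flow.grid.spacing]
    out = np.empty_like(md.du_dt)
    for t in range(flow.n_steps):
        visc = _masked_laplacian_field(flow.velocity[t], flow.mask[t], spacing_m)
        out[t] = -fluid.density * md.du_dt[t] + fluid.dynamic_viscosity * visc
    return out


# ---------------------------------------------------------------------------
# Poisson solve
# ---------------------------------------------------------------------------

class _PoissonWorkspace:
    """Finite-volume Neumann Laplacian on the masked voxels.

    For each masked voxel, interior faces carry fluxes (p_nb - p_c)/h^2;
    faces on the wall carry the prescribed Neumann flux g . n taken from
    the pressure gradient, which moves to the right-hand side. The
    operator A = -L is symmetric positive semi-definite with the constant
    null space of the pure Neumann problem.
    """

    def __init__(self, mask: np.ndarray, spacing_mm):
        from scipy import ndimage as ndi
        _, n_comp = ndi.label(mask)
        if n_comp != 1:
            raise ValueError(
                f"masked domain is disconnected ({n_comp} components); the "
                "Neumann problem is singular per component — restrict the mask "
                "(e.g. to its largest connected component) first")
        self.mask = mask
        self.spacing_m = [s * 1e-3 for s in spacing_mm]
        self.n = int(mask.sum())
        idx = -np.ones(mask.shape, dtype=np.int64)
        idx[mask] = np.arange(self.n)
        self.idx = idx
        rows, cols, vals = [], [], []
        diag = np.zeros(self.n)
        self.boundary = []  # per axis/sign: (voxel ids, h, sign)
        where = np.argwhere(mask)
        for ax in range(3):
            h = self.spacing_m[ax]
            for sgn in (+1, -1):
                nb = where.copy()
                nb[:, ax] += sgn
                ok = (nb[:, ax] >= 0) & (nb[:, ax] < mask.shape[ax])
                inside = np.zeros(len(where), dtype=bool)
                inside[ok] = mask[nb[ok][:, 0], nb[ok][:, 1], nb[ok][:, 2]]
                src = idx[where[inside][:, 0], where[inside][:, 1], where[inside][:, 2]]
                dst = idx[nb[inside][:, 0], nb[inside][:, 1], nb[inside][:, 2]]
                rows.append(src)
                cols.append(dst)
                vals.append(np.full(len(src), -1.0 / h**2))
                np.add.at(diag, src, 1.0 / h**2)
                bnd = idx[where[~inside][:, 0], where[~inside][:, 1], where[~inside][:, 2]]
                self.boundary.append((ax, sgn, bnd, h))
        rows.append(np.arange(self.n))
        cols.append(np.arange(self.n))
        vals.append(diag)
        self.A = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n)).tocsr()

    def rhs(self, grad_p: np.ndarray) -> np.ndarray:
        """-div(g) with Neumann closure, such that A p = rhs."""
        g = [grad_p[..., c] for c in range(3)]
        mask = self.mask
        rhs = np.zeros(self.n)
        where = np.argwhere(mask)
        gm = [nearest_fill(gc, mask) for gc in g]
        for ax in range(3):
            h = self.spacing_m[ax]
            gc = gm[ax]
            for sgn in (+1, -1):
                nb = where.copy()
                nb[:, ax] += sgn
                ok = (nb[:, ax] >= 0) & (nb[:, ax] < mask.shape[ax])
                inside = np.zeros(len(where), dtype=bool)
                inside[ok] = mask[nb[ok][:, 0], nb[ok][:, 1], nb[ok][:, 2]]
                src = self.idx[where[:, 0], where[:, 1], where[:, 2]]
                gc_c = gc[where[:, 0], where[:, 1], where[:, 2]]
                # face-averaged flux for interior faces
                gi = np.zeros(len(where))
                gi[inside] = 0.5 * (gc_c[inside]
                                    + gc[nb[inside][:, 0], nb[inside][:, 1], nb[inside][:, 2]])
                # wall faces: Neumann data, linearly extrapolated to the
                # face (second order) when an inner neighbour exists
                wall = ~inside
                inner = where[wall].copy()
                inner[:, ax] -= sgn
                ok_in = (inner[:, ax] >= 0) & (inner[:, ax] < mask.shape[ax])
                has_in = np.zeros(wall.sum(), dtype=bool)
                has_in[ok_in] = mask[inner[ok_in][:, 0], inner[ok_in][:, 1], inner[ok_in][:, 2]]
                g_wall = gc_c[wall].copy()
                g_wall[has_in] = (1.5 * gc_c[wall][has_in]
                                  - 0.5 * gc[inner[has_in][:, 0], inner[has_in][:, 1],
                                             inner[has_in][:, 2]])
                gi[wall] = g_wall
                np.add.at(rhs, src, -sgn * gi / h)
        return rhs

    def solve(self, rhs: np.ndarray, xi_dt2: float, rtol: float,
              anchor_mean: bool) -> np.ndarray:
        n = self.n
        if xi_dt2 > 0:
            A = self.A + sparse.identity(n) * xi_dt2
            op = A
        else:
            # pure Neumann: regularise the constant null space by pinning
            # the domain mean (relative pressure only)
            ones = np.ones(n) / n
            rhs = rhs - ones * (rhs.sum())
            op = LinearOperator((n, n), matvec=lambda x: self.A @ x + ones * x.sum())
        scale = np.linalg.norm(rhs)
        if scale == 0:
            return np.zeros(n)
        p, info = cg(op, rhs, rtol=rtol, maxiter=10 * n)
        res = np.linalg.norm(op @ p - rhs) / scale
        if info != 0 and res > 100 * rtol:
            raise RuntimeError(f"PPE solver did not converge: relative residual {res:.2e}")
        if anchor_mean:
            p = p - p.mean()
        return p


def estimate_convective_velocity(flows: FlowField4D, max_shift_vox: float = 3.0
                                 ) -> np.ndarray:
    """Bulk convective velocity u_c per step pair (m/s).

    A single best-fit displacement d minimising
    sum |u(x, t+dt) - u(x - d, t)|^2 over an integer-shift search with
    parabolic sub-voxel refinement per axis (a surrogate for the full
    least-squares flow-tracking estimator). Steps marked ``flagged`` hit
    the search bound.
    """
    g = flows.grid
    n = flows.n_steps
    if n < 2:
        raise ValueError("need at least two consecutive steps")
    m = int(np.ceil(max_shift_vox))
    out = np.zeros((n - 1, 3))
    for t in range(n - 1):
        a = flows.velocity[t]
        b = flows.velocity[t + 1]
        mask = flows.mask[t] & flows.mask[t + 1]
        core = mask.copy()
        best = None
        # integer search, smallest displacement first so exact ties
        # (uniform or shift-invariant fields) resolve to zero drift
        shifts = sorted(((dx, dy, dz)
                         for dx in range(-m, m + 1)
                         for dy in range(-m, m + 1)
                         for dz in range(-m, m + 1)),
                        key=lambda s: (s[0]**2 + s[1]**2 + s[2]**2, s))
        for dx, dy, dz in shifts:
            shifted = np.roll(a, (dx, dy, dz), axis=(0, 1, 2))
            err = ((b - shifted) ** 2).sum(axis=-1)[core].sum()
            if best is None or err < best[0] * (1 - 1e-12):
                best = (err, dx, dy, dz)
        _, dx, dy, dz = best
        d = np.array([dx, dy, dz], dtype=float)
        # parabolic refinement per axis from +/- 1 neighbours
        for ax in range(3):
            errs = []
            for o in (-1, 0, 1):
                dd = d.copy()
                dd[ax] = round(d[ax]) + o
                shifted = np.roll(a, tuple(int(x) for x in np.rint(dd)), axis=(0, 1, 2))
                errs.append(((b - shifted) ** 2).sum(axis=-1)[core].sum())
            den = errs[0] - 2 * errs[1] + errs[2]
            if den > 0:
                d[ax] = round(d[ax]) + 0.5 * (errs[0] - errs[2]) / den
        out[t] = d * np.asarray(g.spacing) * 1e-3 / g.time_step
    return out


def solve_ppe(grad_p: np.ndarray, mask: np.ndarray, grid: GridSpec,
              cfg: PPEConfig | None = None, previous: dict | None = None,
              u_c: np.ndarray | None = None) -> tuple[np.ndarray, dict]:
    """Solve one pressure step from its gradient field.

    ``previous`` carries ``{"pressure": (nx,ny,nz), "dpdt": ...}`` from the
    preceding step (or None: the step is anchored to zero domain mean and,
    for xi > 0, the coupling falls back to xi = 0). Returns the masked
    pressure field (Pa, NaN outside) and the state dict for the next step.
    """
    cfg = cfg or PPEConfig()
    ws = _PoissonWorkspace(mask, grid.spacing)
    rhs = ws.rhs(grad_p)
    dt = grid.time_step
    xi_eff = cfg.xi if (previous is not None and cfg.xi > 0) else 0.0
    if xi_eff > 0:
        p_prev = previous["pressure"]
        dpdt_prev = previous.get("dpdt")
        uc = np.zeros(3) if u_c is None else np.asarray(u_c, dtype=float)
        p_tilde = _semi_lagrangian_pressure(p_prev, mask, grid, uc, dt,
                                            cfg.quadrature_points)
        target = p_tilde[mask]
        if dpdt_prev is not None:
            target = target + dt * dpdt_prev[mask]
        rhs = rhs + (xi_eff / dt**2) * target
        p_flat = ws.solve(rhs, xi_eff / dt**2, cfg.solver_tolerance, anchor_mean=False)
    else:
        p_flat = ws.solve(rhs, 0.0, cfg.solver_tolerance, anchor_mean=True)
    p = np.full(mask.shape, np.nan)
    p[mask] = p_flat
    state = {"pressure": p.copy()}
    if previous is not None:
        prev_p = previous["pressure"]
        both = mask & np.isfinite(prev_p)
        dpdt = np.zeros(mask.shape)
        dpdt[both] = (p[both] - prev_p[both]) / dt
        state["dpdt"] = dpdt
    return p, state


def _semi_lagrangian_pressure(p_prev, mask, grid, u_c, dt, nq):
    """p_{n-1}(x - u_c dt) via the line integral of grad p_{n-1} sampled
    trilinearly at ``nq`` quadrature points along the convective path."""
    if not np.any(u_c):
        return nearest_fill(p_prev, mask & np.isfinite(p_prev))
    pm = nearest_fill(p_prev, mask & np.isfinite(p_prev))
    spacing_m = [s * 1e-3 for s in grid.spacing]
    grads = np.gradient(pm, *spacing_m)
    disp_m = -np.asarray(u_c) * dt  # backtracked displacement (m)
    centers = grid.centers()
    acc = np.zeros(grid.n_voxels)
    # int_{x-d}^{x} grad p . dl  ~ sum_q grad p(x - s_q d) . (d / nq)
    for q in range(nq):
        s = (q + 0.5) / nq
        pts = centers + disp_m[None, :] * s * 1e3  # mm
        for c in range(3):
            acc += trilinear_sample(grads[c], grid, pts) * disp_m[c] / nq
    # p(x - d) = p(x) - int
    return pm - acc.reshape(grid.shape)


def solve_pressure_series(flow: FlowField4D, md: MaterialDerivativeField,
                          fluid: FluidProperties | None = None,
                          cfg: PPEConfig | None = None,
                          restrict_to_largest_component: bool = True) -> PressureField4D:
    """Full 4D relative-pressure reconstruction.

    Applies the momentum balance per step, then marches the xi-coupled
    Poisson solves through the series (first step anchored to zero domain
    mean). Binned measurement masks can carry stray disconnected voxel
    islands; by default each step's mask is restricted to its largest
    connected component (pressure elsewhere stays NaN).
    """
    from scipy import ndimage as ndi

    fluid = fluid or FluidProperties()
    cfg = cfg or PPEConfig()
    if restrict_to_largest_component:
        mask = np.empty_like(flow.mask)
        for t in range(flow.n_steps):
            lab, n_comp = ndi.label(flow.mask[t])
            if n_comp > 1:
                sizes = np.bincount(lab.ravel())[1:]
                mask[t] = lab == (1 + sizes.argmax())
            else:
                mask[t] = flow.mask[t]
        flow = FlowField4D(flow.grid, flow.velocity, mask, flow.cycle_period,
                           dict(flow.metadata, pressure_mask="largest component"))
    grad = pressure_gradient(md, flow, fluid)
    if isinstance(cfg.convective_velocity, str) and cfg.convective_velocity == "estimated":
        ucs = estimate_convective_velocity(flow) if flow.n_steps >= 2 and cfg.xi > 0 \
            else np.zeros((max(flow.n_steps - 1, 1), 3))
    else:
        ucs = np.broadcast_to(np.asarray(cfg.convective_velocity, dtype=float),
                              (max(flow.n_steps - 1, 1), 3))
    pressure = np.full((flow.n_steps, *flow.grid.shape), np.nan)
    state = None
    residuals = []
    for t in range(flow.n_steps):
        uc = ucs[t - 1] if t > 0 else None
        p, state = solve_ppe(grad[t], flow.mask[t], flow.grid, cfg, state, uc)
        pressure[t] = p
    note = ("zero domain mean at first time step; later steps coupled through "
            f"the xi={cfg.xi:g} convective time-derivative term")
    return PressureField4D(flow.grid, pressure, flow.mask.copy(), reference_note=note,
                           metadata={"xi": cfg.xi, "fluid": fluid})


# ---------------------------------------------------------------------------
# Probes
# ---------------------------------------------------------------------------

def probe_pressure_difference(p4d: PressureField4D, loc_a, loc_b,
                              box_mm: float = 2.0) -> dict:
    """Delta p(t) between two box-averaged probes (mmHg).

    Pressure is averaged over voxels whose centers fall inside a
    ``box_mm`` x ``box_mm`` square around each location in the x-y plane,
    on the z-plane closest to the probe (the center-plane convention of
    jet-axis probing). Samples where a box exits the mask are flagged.
    """
    g = p4d.grid
    out = {"t": g.times(), "p_a": [], "p_b": [], "dp_mmhg": [], "flagged": []}
    sel = []
    for loc in (np.asarray(loc_a, float), np.asarray(loc_b, float)):
        zi = int(np.clip(round((loc[2] - g.origin[2]) / g.spacing[2] - 0.5),
                         0, g.shape[2] - 1))
        X, Y, _ = g.meshgrid()
        # on grids coarser than the probe box, widen to one voxel so the
        # probe always averages at least the nearest cell
        hx = max(box_mm / 2, 0.5001 * g.spacing[0])
        hy = max(box_mm / 2, 0.5001 * g.spacing[1])
        box = ((np.abs(X[..., zi] - loc[0]) <= hx)
               & (np.abs(Y[..., zi] - loc[1]) <= hy))
        if not box.any():
            raise ValueError(f"probe box at {loc} contains no voxel centers")
        sel.append((zi, box))
    for t in range(g.n_steps):
        vals = []
        flag = False
        for zi, box in sel:
            sl = p4d.pressure[t][..., zi]
            mk = p4d.mask[t][..., zi]
            inside = box & mk & np.isfinite(sl)
            if inside.sum() < box.sum():
                flag = True
            vals.append(np.nan if not inside.any() else float(sl[inside].mean()))
        out["p_a"].append(vals[0])
        out["p_b"].append(vals[1])
        out["dp_mmhg"].append((vals[1] - vals[0]) * MMHG_PER_PA)
        out["flagged"].append(flag)
    for k in ("p_a", "p_b", "dp_mmhg"):
        out[k] = np.asarray(out[k])
    out["flagged"] = np.asarray(out["flagged"], dtype=bool)
    return out
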