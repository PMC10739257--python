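"""Eulerian field operations: incompressibility projection, phase
averaging, velocity gradients and the lambda2 vortex criterion."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg

from .grid import FlowField4D, GridSpec, nearest_fill

__all__ = [
    "divergence_free_filter", "phase_average", "convergence_metric",
    "velocity_gradient", "lambda2", "VortexField", "LAMBDA2_ISO_DEFAULT",
]

#: default iso-surface level for vortex visualisation (1/s^2)
LAMBDA2_ISO_DEFAULT = -150.0


# ---------------------------------------------------------------------------
# Divergence-free projection
# ---------------------------------------------------------------------------

def _divergence_matrix(mask: np.ndarray, spacing_m) -> sparse.csr_matrix:
    """Sparse central-difference divergence operator on the masked voxels.

    Maps the 3 * n_masked velocity DOFs to n_masked divergence values;
    one-sided differences where a neighbour leaves the mask.
    """
    idx = -np.ones(mask.shape, dtype=np.int64)
    n = int(mask.sum())
    idx[mask] = np.arange(n)
    rows, cols, vals = [], [], []
    where = np.argwhere(mask)
    for ax in range(3):
        h = spacing_m[ax]
        for sgn in (+1, -1):
            nb = where.copy()
            nb[:, ax] += sgn
            ok = (nb[:, ax] >= 0) & (nb[:, ax] < mask.shape[ax])
            nb_ok = nb[ok]
            inside = mask[nb_ok[:, 0], nb_ok[:, 1], nb_ok[:, 2]]
            has = np.zeros(n, dtype=bool)
            has[idx[where[ok][inside][:, 0], where[ok][inside][:, 1],
                    where[ok][inside][:, 2]]] = True
            # store neighbour ids per voxel for this direction
            nb_id = -np.ones(n, dtype=np.int64)
            src = idx[where[ok][inside][:, 0], where[ok][inside][:, 1], where[ok][inside][:, 2]]
            nb_id[src] = idx[nb_ok[inside][:, 0], nb_ok[inside][:, 1], nb_ok[inside][:, 2]]
            if sgn == +1:
                plus_id = nb_id
            else:
                minus_id = nb_id
        both = (plus_id >= 0) & (minus_id >= 0)
        only_p = (plus_id >= 0) & ~both
        only_m = (minus_id >= 0) & ~both
        i = np.arange(n)
        # central difference where both neighbours exist
        rows += [i[both], i[both]]
        cols += [ax * n + plus_id[both], ax * n + minus_id[both]]
        vals += [np.full(both.sum(), 1.0 / (2 * h)), np.full(both.sum(), -1.0 / (2 * h))]
        # one-sided at the mask boundary
        rows += [i[only_p], i[only_p]]
        cols += [ax * n + plus_id[only_p], ax * n + i[only_p]]
        vals += [np.full(only_p.sum(), 1.0 / h), np.full(only_p.sum(), -1.0 / h)]
        rows += [i[only_m], i[only_m]]
        cols += [ax * n + i[only_m], ax * n + minus_id[only_m]]
        vals += [np.full(only_m.sum(), 1.0 / h), np.full(only_m.sum(), -1.0 / h)]
    D = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, 3 * n)).tocsr()
    return D


def discrete_divergence(velocity: np.ndarray, mask: np.ndarray, spacing_mm) -> np.ndarray:
    """Central-difference divergence (1/s) on masked voxels (same stencil
    as the projection operator)."""
    spacing_m = [s * 1e-3 for s in spacing_mm]
    D = _divergence_matrix(mask, spacing_m)
    u = np.stack([velocity[..., c][mask] for c in range(3)]).ravel()
    return D @ u


def divergence_free_filter(flow: FlowField4D, rtol: float = 1e-10,
                           periodic: bool | None = None) -> FlowField4D:
    """Project each time step onto a (discretely) divergence-free field.

    Two paths:

    * fully periodic, unmasked grids (``periodic=True``, or auto-detected
      when every voxel is inside the mask and the metadata says so):
      exact spectral Helmholtz projection per Fourier mode — solenoidal
      fields are fixed points to machine precision;
    * masked domains: minimum-norm correction ``u - D^T lambda`` with
      ``D D^T lambda = D u`` solved by conjugate gradients, where ``D`` is
      the central-difference divergence on the masked voxels (one-sided at
      the wall, equivalent to a homogeneous-Neumann potential solve).
      The returned field's discrete divergence, measured with the same
      stencil, is reduced to ``rtol`` of the input's.

    Both are orthogonal projections: kinetic energy never increases, and
    applying the filter twice equals applying it once.
    """
    if periodic is None:
        periodic = bool(flow.mask.all()) and flow.metadata.get("periodic", False)
    out = np.empty_like(flow.velocity)
    if periodic:
        for t in range(flow.n_steps):
            out[t] = _spectral_projection(flow.velocity[t])
    else:
        for t in range(flow.n_steps):
            out[t] = _masked_projection(flow.velocity[t], flow.mask[t],
                                        flow.grid.spacing, rtol)
    meta = dict(flow.metadata)
    meta["divergence_free"] = "spectral" if periodic else "masked_projection"
    return FlowField4D(flow.grid, out, flow.mask.copy(), flow.cycle_period, meta)


def _spectral_projection(u: np.ndarray) -> np.ndarray:
    shape = u.shape[:3]
    ks = [np.fft.fftfreq(n) * n for n in shape]  # integer wavenumbers
    KX, KY, KZ = np.meshgrid(*ks, indexing="ij")
    K = np.stack([KX, KY, KZ])
    K2 = (K**2).sum(axis=0)
    K2[0, 0, 0] = 1.0
    uh = np.stack([np.fft.fftn(u[..., c]) for c in range(3)])
    proj = (K * uh).sum(axis=0) / K2
    uh -= K * proj[None]
    return np.stack([np.fft.ifftn(uh[c]).real for c in range(3)], axis=-1)


def _masked_projection(u: np.ndarray, mask: np.ndarray, spacing_mm, rtol) -> np.ndarray:
    spacing_m = [s * 1e-3 for s in spacing_mm]
    D = _divergence_matrix(mask, spacing_m)
    n = D.shape[0]
    uv = np.stack([u[..., c][mask] for c in range(3)]).ravel()
    b = D @ uv
    bnorm = np.linalg.norm(b)
    # divergence already at the numerical floor (e.g. re-applying the
    # filter): nothing to project out
    floor = 1e-13 * np.linalg.norm(uv) / min(spacing_m)
    if bnorm <= max(floor, 1e-300):
        return u.copy()
    A = LinearOperator((n, n), matvec=lambda x: D @ (D.T @ x))
    lam, info = cg(A, b, rtol=rtol, atol=floor, maxiter=20 * n)
    if info > 0:
        res = np.linalg.norm(b - A @ lam) / bnorm
        if res > 1e-6:
            raise RuntimeError(
                f"divergence-free projection did not converge: relative residual {res:.2e}")
    corr = D.T @ lam
    out = u.copy()
    flat = corr.reshape(3, n)
    for c in range(3):
        comp = out[..., c]
        vals = comp[mask] - flat[c]
        comp[mask] = vals
        out[..., c] = comp
    return out


# ---------------------------------------------------------------------------
# Phase averaging and cycle-convergence metric
# ---------------------------------------------------------------------------

def phase_average(flows: list[FlowField4D]) -> FlowField4D:
    """Voxel-wise mean over phase-aligned cardiac cycles.

    All cycles must share the grid; the output mask is the intersection of
    the per-cycle masks at each phase.
    """
    if not flows:
        raise ValueError("no cycles to average")
    g0 = flows[0].grid
    for f in flows[1:]:
        if f.grid != g0:
            raise ValueError("cycles live on different grids; cannot phase-average")
    vel = np.mean([f.velocity for f in flows], axis=0)
    mask = np.logical_and.reduce([f.mask for f in flows])
    meta = dict(flows[0].metadata)
    meta["phase_average_cycles"] = len(flows)
    return FlowField4D(g0, vel, mask, flows[0].cycle_period, meta)


def convergence_metric(a: FlowField4D, b: FlowField4D) -> float:
    """Cycle-convergence measure between two phase-averaged fields, in %.

    The median over valid voxels and phases of |a - b| normalised by the
    spatial peak speed of ``a`` at that phase. (The normalisation is a
    disclosed choice; peak-speed scaling keeps the measure meaningful in
    near-stagnant phases.)
    """
    if a.grid != b.grid:
        raise ValueError("fields live on different grids")
    vals = []
    for t in range(a.n_steps):
        m = a.mask[t] & b.mask[t]
        if not m.any():
            continue
        diff = np.linalg.norm(a.velocity[t] - b.velocity[t], axis=-1)[m]
        peak = np.linalg.norm(a.velocity[t], axis=-1)[m].max()
        if peak <= 0:
            continue
        vals.append(diff / peak)
    if not vals:
        return 0.0
    return 100.0 * float(np.median(np.concatenate(vals)))


# ---------------------------------------------------------------------------
# Velocity gradients and lambda2
# ---------------------------------------------------------------------------

@dataclass
class VortexField:
    """lambda2 (1/s^2) per voxel with on-demand strain/rotation tensors."""

    grid: GridSpec
    lambda2: np.ndarray           # (n_steps, nx, ny, nz)
    mask: np.ndarray
    iso_default: float = LAMBDA2_ISO_DEFAULT
    metadata: dict = field(default_factory=dict)


def velocity_gradient(flow: FlowField4D, step: int) -> np.ndarray:
    """Central-difference velocity-gradient tensor G_ij = du_i/dx_j (1/s).

    Outside-mask voxels are filled with the nearest inside value before
    differencing so that near-wall stencils stay usable; gradients are
    only meaningful inside the mask.
    """
    spacing_m = [s * 1e-3 for s in flow.grid.spacing]
    u = nearest_fill(flow.velocity[step], flow.mask[step])
    G = np.empty((*flow.grid.shape, 3, 3))
    for i in range(3):
        grads = np.gradient(u[..., i], *spacing_m, axis=(0, 1, 2), edge_order=2)
        for j in range(3):
            G[..., i, j] = grads[j]
    return G


def lambda2(flow: FlowField4D) -> VortexField:
    """Vortex identification by the lambda2 criterion.

    lambda2 is the middle eigenvalue of S^2 + Omega^2, where S and Omega
    are the symmetric and antisymmetric parts of the velocity gradient;
    negative values mark vortex cores. The conventional display threshold
    is exposed as ``LAMBDA2_ISO_DEFAULT``.
    """
    lam = np.empty((flow.n_steps, *flow.grid.shape))
    for t in range(flow.n_steps):
        G = velocity_gradient(flow, t)
        S = 0.5 * (G + np.swapaxes(G, -1, -2))
        O = 0.5 * (G - np.swapaxes(G, -1, -2))
        M = S @ S + O @ O
        lam[t] = np.linalg.eigvalsh(M)[..., 1]  # ascending; middle eigenvalue
    return VortexField(flow.grid, lam, flow.mask.copy(),
                       metadata={"definition": "middle eigenvalue of S^2 + Omega^2"})


def strain_rotation(flow: FlowField4D, step: int) -> tuple[np.ndarray, np.ndarray]:
    """(S, Omega) tensors at one time step (1/s)."""
    G = velocity_gradient(flow, step)
    return 0.5 * (G + np.swapaxes(G, -1, -2)), 0.5 * (G - np.swapaxes(G, -1, -2))
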