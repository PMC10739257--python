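"""Snapshot proper orthogonal decomposition of 4D velocity fields.

The moving ventricle wall means each stored step has its own mask; all
snapshots are first interpolated onto a fixed reference mesh (the
end-systole mask, the smallest domain) before the snapshot correlation
matrix is formed. Eigenvalues are reported as kinetic-energy
contributions; no mean-flow subtraction is performed by default (the
leading mode then captures the jet-dominated mean structure), switchable
with ``subtract_mean``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import FlowField4D, GridSpec, nearest_fill

__all__ = [
    "SnapshotMatrix", "PODResult", "interpolate_to_reference",
    "snapshot_pod", "energy_fractions", "reconstruct",
    "phase_portrait", "subphase_pod",
]


@dataclass
class SnapshotMatrix:
    """Velocity snapshots flattened over a fixed reference mask.

    ``data`` has shape ``(3 * n_masked_voxels, n_snapshots)``; the column
    order follows ``snapshot_times``.
    """

    reference_grid: GridSpec
    reference_mask: np.ndarray            # (nx, ny, nz)
    data: np.ndarray
    snapshot_times: np.ndarray
    subsample_factor: int = 1
    filled_fraction: float = 0.0          # snapshots' voxels filled from outside source masks
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape[0] != 3 * int(self.reference_mask.sum()):
            raise ValueError("column length must be 3 x n_masked_voxels")
        if not np.isfinite(self.data).all():
            raise ValueError("snapshot matrix contains non-finite values")

    @property
    def n_snapshots(self) -> int:
        return self.data.shape[1]

    @property
    def voxel_volume_m3(self) -> float:
        return self.reference_grid.voxel_volume_mm3 * 1e-9


@dataclass
class PODResult:
    """Spatial modes, time coefficients and the energy spectrum.

    Modes are orthonormal under the voxel-volume-weighted inner product;
    coefficients satisfy ``sum_t a_i(t) a_j(t) = N lambda_i delta_ij`` and
    ``sum_k lambda_k`` equals the mean snapshot energy.
    """

    modes: np.ndarray          # (3 * n_masked, n_modes)
    coefficients: np.ndarray   # (n_snapshots, n_modes)
    eigenvalues: np.ndarray    # descending
    reference_grid: GridSpec
    reference_mask: np.ndarray
    snapshot_times: np.ndarray
    n_truncated: int = 0
    subtract_mean: bool = False
    mean_field: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def energy_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def cumulative_fractions(self) -> np.ndarray:
        return np.cumsum(self.energy_fractions())

    def mode_field(self, k: int) -> np.ndarray:
        """Mode k as a (nx, ny, nz, 3) array (NaN outside the mask)."""
        out = np.full((*self.reference_grid.shape, 3), np.nan)
        out[self.reference_mask] = self.modes[:, k].reshape(3, -1).T
        return out


# ---------------------------------------------------------------------------
# Reference-mesh interpolation
# ---------------------------------------------------------------------------

def interpolate_to_reference(flow: FlowField4D, reference_step: int | None = None,
                             subsample_factor: int = 5, order: int = 3,
                             strict: bool = True) -> SnapshotMatrix:
    """Sample every (subsampled) snapshot on the reference-mask voxels.

    ``reference_step`` defaults to the end-systole step (smallest mask).
    Interpolation is tri-polynomial (tricubic by default) with a trilinear
    fallback within 2 voxels of the grid edge; reference voxels outside a
    snapshot's own mask take the nearest inside value and are counted in
    ``filled_fraction``. By default a reference voxel with no source data
    within 2 voxels is an error; ``strict=False`` (for patchy binned
    measurement masks) fills it anyway and only reports the fraction.
    Identical grids and masks short-circuit to an exact copy.
    """
    grid = flow.grid
    if reference_step is None:
        reference_step = int(np.argmin(flow.mask.sum(axis=(1, 2, 3))))
    ref_mask = flow.mask[reference_step]
    steps = np.arange(0, flow.n_steps, subsample_factor)
    n_masked = int(ref_mask.sum())
    data = np.empty((3 * n_masked, len(steps)))
    filled = 0
    for col, s in enumerate(steps):
        if flow.mask[s].shape == ref_mask.shape and bool((flow.mask[s] == ref_mask).all()):
            vals = flow.velocity[s][ref_mask]  # identical sampling: exact copy
        else:
            src_mask = flow.mask[s]
            outside = ref_mask & ~src_mask
            # reference voxels far from any source data are a hard error
            if outside.any():
                dist = ndimage.distance_transform_edt(
                    ~src_mask, sampling=grid.spacing)
                too_far = outside & (dist > 2.0 * max(grid.spacing))
                if strict and too_far.any():
                    locs = np.argwhere(too_far)[:5]
                    raise ValueError(
                        f"{int(too_far.sum())} reference voxels have no source data "
                        f"within 2 voxels at step {s}; first offenders (ijk): "
                        f"{locs.tolist()}")
                filled += int(outside.sum())
            u = nearest_fill(flow.velocity[s], src_mask)
            vals = np.empty((n_masked, 3))
            idx = np.argwhere(ref_mask).T.astype(float)
            for c in range(3):
                vals[:, c] = ndimage.map_coordinates(u[..., c], idx, order=order,
                                                     mode="nearest")
        data[:, col] = vals.T.ravel()
    return SnapshotMatrix(
        grid, ref_mask, data, steps * grid.time_step, subsample_factor,
        filled_fraction=filled / max(n_masked * len(steps), 1),
        metadata={"reference_step": int(reference_step),
                  "interpolation_order": order})


# ---------------------------------------------------------------------------
# POD core
# ---------------------------------------------------------------------------

def snapshot_pod(S: SnapshotMatrix, subtract_mean: bool = False,
                 truncate_rel: float = 1e-12) -> PODResult:
    """Snapshot-method POD.

    Builds the N x N correlation matrix with the voxel-volume-weighted
    inner product, eigendecomposes, and forms orthonormal spatial modes
    and time coefficients. Trailing eigenvalues below
    ``truncate_rel * lambda_1`` are truncated (reported via
    ``n_truncated``). Mode signs are fixed so each mode's
    largest-magnitude entry is positive.
    """
    X = S.data
    n = S.n_snapshots
    if n < 2:
        raise ValueError("need at least 2 snapshots")
    mean = None
    if subtract_mean:
        mean = X.mean(axis=1, keepdims=True)
        X = X - mean
    dv = S.voxel_volume_m3
    C = (dv / n) * (X.T @ X)
    w, V = np.linalg.eigh(C)
    w, V = w[::-1], V[:, ::-1]
    w = np.maximum(w, 0.0)
    keep = w > truncate_rel * (w[0] if w[0] > 0 else 1.0)
    n_trunc = int((~keep).sum())
    w, V = w[keep], V[:, keep]
    # modes: phi_k = X v_k / sqrt(N lambda_k); <phi, phi>_dv = 1
    scale = 1.0 / np.sqrt(n * np.maximum(w, 1e-300))
    modes = (X @ V) * scale
    coeffs = dv * (X.T @ modes)
    # deterministic sign convention
    peak = np.abs(modes).argmax(axis=0)
    signs = np.sign(modes[peak, np.arange(modes.shape[1])])
    signs[signs == 0] = 1.0
    modes *= signs
    coeffs *= signs
    return PODResult(modes, coeffs, w, S.reference_grid, S.reference_mask,
                     S.snapshot_times, n_truncated=n_trunc,
                     subtract_mean=subtract_mean,
                     mean_field=None if mean is None else mean.ravel(),
                     metadata=dict(S.metadata))


def energy_fractions(r: PODResult) -> tuple[np.ndarray, np.ndarray]:
    """(fractions, cumulative fractions) of the modal kinetic energy."""
    f = r.energy_fractions()
    return f, np.cumsum(f)


def reconstruct(r: PODResult, k: int) -> np.ndarray:
    """Rank-k reconstruction sum_{j<=k} a_j(t) phi_j as a snapshot matrix
    (same layout as the input data)."""
    if k < 1 or k > r.n_modes:
        raise ValueError(f"k must be in [1, {r.n_modes}]")
    out = r.modes[:, :k] @ r.coefficients[:, :k].T
    if r.subtract_mean and r.mean_field is not None:
        out = out + r.mean_field[:, None]
    return out


# ---------------------------------------------------------------------------
# Phase portraits
# ---------------------------------------------------------------------------

@dataclass
class EllipseFit:
    residual: float
    eccentricity: float
    degenerate: bool


def phase_portrait(r: PODResult, i: int, j: int) -> tuple[np.ndarray, np.ndarray, EllipseFit]:
    """Coefficient pair (a_i(t), a_j(t)) with an algebraic ellipse fit.

    The conic fit residual (smallest singular value of the normalised
    design matrix) quantifies how closely the trajectory traces an
    ellipse; a zero-variance coefficient flags a degenerate portrait.
    """
    a, b = r.coefficients[:, i], r.coefficients[:, j]
    sa, sb = a.std(), b.std()
    if sa < 1e-14 * max(np.abs(a).max(), 1.0) or sb < 1e-14 * max(np.abs(b).max(), 1.0):
        return a, b, EllipseFit(np.nan, np.nan, True)
    x = (a - a.mean()) / sa
    y = (b - b.mean()) / sb
    D = np.stack([x * x, x * y, y * y, x, y, np.ones_like(x)], axis=1)
    _, s, vt = np.linalg.svd(D, full_matrices=False)
    resid = s[-1] / np.sqrt(len(x))
    A, B, C = vt[-1, 0], vt[-1, 1], vt[-1, 2]
    # eccentricity of the fitted conic (meaningful when elliptic)
    disc = B * B - 4 * A * C
    if disc < 0:
        lam = np.linalg.eigvalsh(np.array([[A, B / 2], [B / 2, C]]))
        lo, hi = np.abs(lam).min(), np.abs(lam).max()
        ecc = float(np.sqrt(max(1 - lo / hi, 0.0))) if hi > 0 else np.nan
    else:
        ecc = np.nan
    return a, b, EllipseFit(float(resid), ecc, False)


# ---------------------------------------------------------------------------
# Sub-phase analysis
# ---------------------------------------------------------------------------

def subphase_pod(flow: FlowField4D, phase_windows: dict | None = None,
                 subsample_factor: int = 1, reference_step: int | None = None,
                 subtract_mean: bool = False) -> dict:
    """Independent POD of the systole and diastole snapshot subsets.

    ``phase_windows`` maps names to (t_start, t_end) in seconds; the
    default splits the cycle into a 300 ms systole starting at t = 0 and
    the remaining diastole. Windows must be disjoint and each must retain
    at least 2 snapshots.
    """
    if phase_windows is None:
        T = flow.cycle_period or flow.grid.time_step * flow.n_steps
        phase_windows = {"systole": (0.0, 0.300), "diastole": (0.300, T)}
    items = sorted(phase_windows.items(), key=lambda kv: kv[1][0])
    for (na, (a0, a1)), (nb, (b0, b1)) in zip(items, items[1:]):
        if b0 < a1:
            raise ValueError(f"phase windows {na} and {nb} overlap")
    S = interpolate_to_reference(flow, reference_step, subsample_factor)
    out = {}
    for name, (t0, t1) in phase_windows.items():
        sel = (S.snapshot_times >= t0) & (S.snapshot_times < t1)
        if sel.sum() < 2:
            raise ValueError(f"phase window '{name}' contains {int(sel.sum())} snapshots (< 2)")
        sub = SnapshotMatrix(S.reference_grid, S.reference_mask, S.data[:, sel],
                             S.snapshot_times[sel], S.subsample_factor,
                             S.filled_fraction, dict(S.metadata))
        out[name] = snapshot_pod(sub, subtract_mean=subtract_mean)
    return out
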