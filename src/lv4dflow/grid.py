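"""Eulerian grid and 4D field containers.

Conventions used throughout the package:

* grids are uniform and voxel-centered: the center of voxel ``(i, j, k)``
  sits at ``origin + (index + 0.5) * spacing`` (0-based indices),
* spatial coordinates and grid spacing are in millimetres, time in
  seconds, velocity in m/s, pressure in Pa (mmHg only on export),
* field arrays are indexed ``[t, ix, iy, iz (, component)]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["GridSpec", "FlowField4D", "PressureField4D"]

MMHG_PER_PA = 1.0 / 133.322
PA_PER_MMHG = 133.322


@dataclass(frozen=True)
class GridSpec:
    """Geometry and time sampling of a regular 4D grid.

    Parameters
    ----------
    origin
        Position (mm) of the *corner* of the grid; the first voxel center
        is at ``origin + 0.5 * spacing``.
    spacing
        Voxel edge lengths (mm), strictly positive.
    shape
        Number of voxels per axis, at least 2 per axis.
    time_step
        Interval between stored time steps (s).
    n_steps
        Number of stored time steps.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    time_step: float
    n_steps: int

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 2 for n in self.shape):
            raise ValueError(f"grid shape must have >= 2 voxels per axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if self.time_step <= 0 or self.n_steps < 1:
            raise ValueError("time_step must be > 0 and n_steps >= 1")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))

    # -- geometry helpers -------------------------------------------------
    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """X, Y, Z voxel-center coordinate arrays of shape ``self.shape`` (mm)."""
        return np.meshgrid(*(self.axis_centers(a) for a in range(3)), indexing="ij")

    def centers(self) -> np.ndarray:
        """All voxel centers as an ``(n_voxels, 3)`` array (mm), C order."""
        X, Y, Z = self.meshgrid()
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.time_step

    def to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Convert mm positions to fractional voxel indices (voxel-centered)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing) - 0.5

    def extent(self) -> np.ndarray:
        """Physical box covered by the grid: ``[[x0, x1], [y0, y1], [z0, z1]]`` mm."""
        o = np.asarray(self.origin)
        return np.stack([o, o + np.asarray(self.spacing) * np.asarray(self.shape)], axis=1)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


def trilinear_sample(values: np.ndarray, grid: GridSpec, points_mm: np.ndarray) -> np.ndarray:
    """Sample a static (possibly multi-component) voxel field at mm positions.

    Uses trilinear interpolation with edge clamping (``mode='nearest'``).
    ``values`` is indexed ``[ix, iy, iz]`` or ``[ix, iy, iz, c]``.
    """
    idx = grid.to_index(points_mm).T  # (3, n)
    if values.ndim == 3:
        return ndimage.map_coordinates(values, idx, order=1, mode="nearest")
    out = np.empty((idx.shape[1], values.shape[-1]))
    for c in range(values.shape[-1]):
        out[:, c] = ndimage.map_coordinates(values[..., c], idx, order=1, mode="nearest")
    return out


def nearest_fill(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace values outside ``mask`` with the nearest inside-mask value.

    Keeps finite-difference stencils near the moving wall from picking up
    garbage; the filled voxels remain flagged invalid through the mask.
    """
    if mask.all():
        return values
    if not mask.any():
        raise ValueError("mask is empty; nothing to fill from")
    _, idx = ndimage.distance_transform_edt(~mask, return_indices=True)
    filled = values[tuple(idx)] if values.ndim == mask.ndim else values[tuple(idx) + (slice(None),)]
    return filled


@dataclass
class FlowField4D:
    """Time series of a 3-component velocity field with a per-step domain mask.

    ``velocity`` has shape ``(n_steps, nx, ny, nz, 3)`` in m/s and
    ``mask`` has shape ``(n_steps, nx, ny, nz)`` (True inside the fluid
    domain). ``cycle_period`` is the cardiac cycle duration in seconds
    (0 for aperiodic fields).
    """

    grid: GridSpec
    velocity: np.ndarray
    mask: np.ndarray
    cycle_period: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected_v = (self.grid.n_steps, *self.grid.shape, 3)
        expected_m = (self.grid.n_steps, *self.grid.shape)
        if self.velocity.shape != expected_v:
            raise ValueError(f"velocity shape {self.velocity.shape} != {expected_v}")
        if self.mask.shape != expected_m:
            raise ValueError(f"mask shape {self.mask.shape} != {expected_m}")
        if not self.mask.any(axis=(1, 2, 3)).all():
            raise ValueError("mask is empty at one or more time steps")
        inside = self.velocity[self.mask]
        if not np.isfinite(inside).all():
            raise ValueError("non-finite velocity inside the mask")

    @property
    def n_steps(self) -> int:
        return self.grid.n_steps

    def sample_velocity(self, points_mm: np.ndarray, t: float) -> np.ndarray:
        """Velocity (m/s) at arbitrary positions and time.

        Trilinear in space, linear in time between stored steps; clamps at
        the first/last step.
        """
        s = t / self.grid.time_step
        i0 = int(np.clip(np.floor(s), 0, self.n_steps - 1))
        i1 = min(i0 + 1, self.n_steps - 1)
        f = float(np.clip(s - i0, 0.0, 1.0))
        v0 = trilinear_sample(self.velocity[i0], self.grid, points_mm)
        if i1 == i0 or f == 0.0:
            return v0
        v1 = trilinear_sample(self.velocity[i1], self.grid, points_mm)
        return (1.0 - f) * v0 + f * v1

    def inside_mask(self, points_mm: np.ndarray, step: int) -> np.ndarray:
        """Nearest-voxel mask lookup for mm positions at a stored step."""
        idx = np.rint(self.grid.to_index(points_mm)).astype(int)
        shape = np.asarray(self.grid.shape)
        in_grid = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.zeros(len(idx), dtype=bool)
        ii = idx[in_grid]
        out[in_grid] = self.mask[step][ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def mask_volumes_ml(self) -> np.ndarray:
        """Masked domain volume per time step in millilitres."""
        return self.mask.sum(axis=(1, 2, 3)) * self.grid.voxel_volume_mm3 / 1000.0


@dataclass
class PressureField4D:
    """Relative pressure on the same grid/mask layout as :class:`FlowField4D`.

    Stored in Pa; converted with 1 mmHg = 133.322 Pa on export. The field
    is defined up to a constant; ``reference_note`` records the anchoring.
    """

    grid: GridSpec
    pressure: np.ndarray  # (n_steps, nx, ny, nz), Pa
    mask: np.ndarray
    reference_note: str = "zero domain mean at first time step"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (self.grid.n_steps, *self.grid.shape)
        if self.pressure.shape != expected:
            raise ValueError(f"pressure shape {self.pressure.shape} != {expected}")
        if self.mask.shape != expected:
            raise ValueError(f"mask shape {self.mask.shape} != {expected}")
        if not np.isfinite(self.pressure[self.mask]).all():
            raise ValueError("non-finite pressure inside the mask")

    def pressure_mmhg(self) -> np.ndarray:
        return self.pressure * MMHG_PER_PA
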