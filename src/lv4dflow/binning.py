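"""Track-to-grid velocity reconstruction by multi-pass Gaussian binning.

Scattered Lagrangian samples (track positions with fitted velocities or
accelerations) are averaged onto the Eulerian grid in overlapping cubic
sub-volumes with Gaussian distance weights. The pass sequence halves the
sub-volume edge (72 -> 36 -> 18 -> 9 reconstruction voxels by default),
each pass using the previous one as a predictor for outlier rejection
(> 3 median absolute deviations from the local predictor are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .grid import FlowField4D, GridSpec, nearest_fill, trilinear_sample
from .tracks import TrackSet

__all__ = ["BinningConfig", "bin_velocity", "bin_vector_samples"]

#: reconstruction-voxel pitch of the reference experiment (9 voxels = 0.735 mm)
DEFAULT_MM_PER_VOXEL = 0.0817


@dataclass(frozen=True)
class BinningConfig:
    """Multi-pass binning parameters (sub-volume sizes in reconstruction
    voxels; the Gaussian weight sigma is ``subvolume / 4``)."""

    initial_subvolume: float = 72.0
    overlap_fraction: float = 0.875
    final_subvolume: float = 9.0
    mm_per_voxel: float = DEFAULT_MM_PER_VOXEL
    outlier_mad: float = 3.0
    min_samples: int = 2

    def __post_init__(self) -> None:
        if self.final_subvolume > self.initial_subvolume:
            raise ValueError("final_subvolume must not exceed initial_subvolume")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.mm_per_voxel <= 0:
            raise ValueError("mm_per_voxel must be positive")

    def pass_sizes_mm(self) -> list[float]:
        """Sub-volume edge lengths (mm) of the halving pass sequence."""
        sizes = [self.initial_subvolume]
        while sizes[-1] / 2.0 >= self.final_subvolume - 1e-9:
            sizes.append(sizes[-1] / 2.0)
        if abs(sizes[-1] - self.final_subvolume) > 1e-9:
            sizes.append(self.final_subvolume)
        return [s * self.mm_per_voxel for s in sizes]

    @property
    def resolution_report(self) -> str:
        return (f"{self.final_subvolume:g} voxels "
                f"({self.final_subvolume * self.mm_per_voxel:.3f} mm)")


def _segment_median(values: np.ndarray, seg_ids: np.ndarray, n_segments: int) -> np.ndarray:
    """Median of ``values`` grouped by segment id (vectorised)."""
    out = np.full(n_segments, np.nan)
    if len(values) == 0:
        return out
    order = np.lexsort((values, seg_ids))
    v = values[order]
    s = seg_ids[order]
    starts = np.flatnonzero(np.r_[True, s[1:] != s[:-1]])
    counts = np.diff(np.r_[starts, len(s)])
    for st, ct in zip(starts, counts):
        out[s[st]] = v[st + (ct - 1) // 2] if ct % 2 else 0.5 * (v[st + ct // 2 - 1] + v[st + ct // 2])
    return out


def bin_vector_samples(positions_mm: np.ndarray, values: np.ndarray, grid: GridSpec,
                       cfg: BinningConfig) -> tuple[np.ndarray, np.ndarray]:
    """One time step of multi-pass Gaussian binning.

    Returns ``(field (nx, ny, nz, 3), valid (nx, ny, nz))``; voxels with
    fewer than ``cfg.min_samples`` contributing samples are invalid (NaN).
    """
    if len(positions_mm) == 0:
        raise ValueError("no samples to bin")
    centers = grid.centers()
    tree = cKDTree(positions_mm)
    predictor: np.ndarray | None = None
    field = np.full((grid.n_voxels, 3), np.nan)
    valid = np.zeros(grid.n_voxels, dtype=bool)
    for size_mm in cfg.pass_sizes_mm():
        radius = 0.5 * size_mm
        sigma = size_mm / 4.0
        pairs = tree.query_ball_point(centers, radius)
        counts = np.fromiter((len(p) for p in pairs), dtype=np.int64, count=len(pairs))
        if counts.sum() == 0:
            continue
        vox_id = np.repeat(np.arange(len(pairs)), counts)
        samp_id = np.fromiter((j for p in pairs for j in p), dtype=np.int64,
                              count=counts.sum())
        d2 = ((positions_mm[samp_id] - centers[vox_id]) ** 2).sum(axis=1)
        w = np.exp(-0.5 * d2 / sigma**2)
        vals = values[samp_id]
        if predictor is not None:
            pred = trilinear_sample(predictor, grid, positions_mm[samp_id])
            resid = np.linalg.norm(vals - pred, axis=1)
            mad = _segment_median(
                np.abs(resid - _segment_median(resid, vox_id, len(pairs))[vox_id]),
                vox_id, len(pairs))
            keep = resid <= (_segment_median(resid, vox_id, len(pairs))[vox_id]
                             + cfg.outlier_mad * np.maximum(mad[vox_id], 1e-12))
            vox_id, samp_id, w, vals = vox_id[keep], samp_id[keep], w[keep], vals[keep]
        wsum = np.bincount(vox_id, weights=w, minlength=grid.n_voxels)
        nsamp = np.bincount(vox_id, minlength=grid.n_voxels)
        fld = np.stack([np.bincount(vox_id, weights=w * vals[:, c],
                                    minlength=grid.n_voxels) for c in range(3)], axis=1)
        ok = nsamp >= cfg.min_samples
        field = np.full((grid.n_voxels, 3), np.nan)
        field[ok] = fld[ok] / wsum[ok, None]
        valid = ok
        # predictor for the next (smaller) pass: invalid voxels filled from
        # the nearest valid ones
        predictor = nearest_fill(field.reshape(*grid.shape, 3),
                                 valid.reshape(grid.shape)) if ok.any() else None
        if predictor is None:
            break
    return field.reshape(*grid.shape, 3), valid.reshape(grid.shape)


def bin_velocity(tracks: TrackSet, grid: GridSpec, cfg: BinningConfig | None = None,
                 which: str = "velocity") -> FlowField4D:
    """Bin fitted track velocities onto an Eulerian grid, per time step.

    ``which`` may be ``"acceleration"`` to grid the Lagrangian material
    derivative with the same scheme. The output mask marks voxels with at
    least ``cfg.min_samples`` contributing samples.
    """
    cfg = cfg or BinningConfig()
    n_steps = min(tracks.n_steps, grid.n_steps)
    if grid.n_steps != n_steps:
        grid = GridSpec(grid.origin, grid.spacing, grid.shape, grid.time_step, n_steps)
    vel = np.zeros((n_steps, *grid.shape, 3))
    mask = np.zeros((n_steps, *grid.shape), dtype=bool)
    for t in range(n_steps):
        pos, val = tracks.samples(t, which=which)
        if len(pos) == 0:
            raise ValueError(f"no {which} samples at time step {t}")
        field, valid = bin_vector_samples(pos, val, grid, cfg)
        field[~valid] = 0.0
        vel[t] = field
        mask[t] = valid
    return FlowField4D(grid, vel, mask, metadata={
        "source": f"binned_{which}", "resolution": cfg.resolution_report,
        "binning": cfg})
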