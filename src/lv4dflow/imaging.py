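"""Ideal multi-view camera model and particle-image rendering.

The cameras are exactly known affine (scaled-orthographic) projections:
view ``v`` maps a world point X (mm) to pixels via a rotation ``R_v``,

    y = R_v @ (X - origin);  px = y[:2] / mm_per_px + center_px

so one image pixel corresponds to one reconstruction voxel of edge
``mm_per_px`` (the camera magnification). Particles are rendered as
isotropic Gaussian spots (the optical transfer function) sampled at pixel
centers, which is also the model the tracker matches against.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .tracks import TrackSet

__all__ = ["CameraModel", "ImageSequence", "render_images", "default_camera_model"]


def _rot_y(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


@dataclass
class CameraModel:
    """Projection geometry plus the synthetic OTF parameters.

    ``rotations`` has shape (n_views, 3, 3); ``otf_sigma`` is the Gaussian
    spot width in px and ``peak_intensity`` the noise-free peak counts of a
    unit-brightness particle.
    """

    rotations: np.ndarray
    mm_per_px: float
    image_shape: tuple[int, int]  # (height, width)
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center_px: np.ndarray | None = None
    otf_sigma: float = 1.2
    peak_intensity: float = 1000.0

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.rotations.ndim != 3 or self.rotations.shape[1:] != (3, 3):
            raise ValueError("rotations must have shape (n_views, 3, 3)")
        for R in self.rotations:
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
                raise ValueError("camera rotation is not orthonormal (degenerate geometry)")
        if self.otf_sigma <= 0:
            raise ValueError("otf_sigma must be positive")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.center_px is None:
            h, w = self.image_shape
            self.center_px = np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    @property
    def n_views(self) -> int:
        return self.rotations.shape[0]

    def project(self, points_mm: np.ndarray, view: int) -> np.ndarray:
        """World mm -> pixel coordinates (x_px, y_px) in one view."""
        X = np.atleast_2d(points_mm) - self.origin_mm
        y = X @ self.rotations[view].T
        return y[:, :2] / self.mm_per_px + self.center_px

    def ray(self, px: np.ndarray, view: int) -> tuple[np.ndarray, np.ndarray]:
        """Line of sight of a pixel: returns (point_mm, unit direction)."""
        px = np.atleast_2d(px)
        uv = (px - self.center_px) * self.mm_per_px
        y = np.concatenate([uv, np.zeros((len(uv), 1))], axis=1)
        p0 = y @ self.rotations[view] + self.origin_mm
        d = self.rotations[view].T @ np.array([0.0, 0.0, 1.0])
        return p0, d

    def in_frame(self, px: np.ndarray, margin: float = 0.0) -> np.ndarray:
        h, w = self.image_shape
        return ((px[:, 0] >= -margin) & (px[:, 0] <= w - 1 + margin)
                & (px[:, 1] >= -margin) & (px[:, 1] <= h - 1 + margin))

    def mm_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Reconstruction-voxel coordinates (1 voxel = 1 px via magnification)."""
        return (np.atleast_2d(points_mm) - self.origin_mm) / self.mm_per_px


def default_camera_model(image_shape=(512, 512), mm_per_px=0.2, otf_sigma=1.2,
                         peak_intensity=1000.0, origin_mm=(0.0, 0.0, 0.0)) -> CameraModel:
    """Four views in a +/-30, +/-10 degree fan with alternating elevation.

    Emulates the four-view splitter arrangement with exactly known synthetic
    calibration.
    """
    angles = [(-30.0, -6.0), (-10.0, 6.0), (10.0, -6.0), (30.0, 6.0)]
    rots = np.stack([_rot_x(el) @ _rot_y(az) for az, el in angles])
    return CameraModel(rotations=rots, mm_per_px=mm_per_px, image_shape=tuple(image_shape),
                       origin_mm=np.asarray(origin_mm, dtype=float),
                       otf_sigma=otf_sigma, peak_intensity=peak_intensity)


@dataclass
class ImageSequence:
    """Multi-view count-image time series at a fixed frame rate.

    ``frames`` has shape (n_steps, n_views, height, width), dtype uint16.
    """

    frames: np.ndarray
    frame_rate: float = 2000.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.ndim != 4:
            raise ValueError("frames must be (n_steps, n_views, H, W)")
        if np.issubdtype(self.frames.dtype, np.signedinteger) and (self.frames < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_steps(self) -> int:
        return self.frames.shape[0]

    @property
    def n_views(self) -> int:
        return self.frames.shape[1]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[2:]


def gaussian_patches(px: np.ndarray, sigma: float, radius: int):
    """Unit-peak Gaussian spots around sub-pixel centers, as patches.

    Returns (corner (n, 2) int, patch (n, P, P)) where patch[i, dy, dx]
    is the spot value at pixel (corner + (dy, dx)); P = 2*radius + 1.
    Separable evaluation keeps the exp count linear in patch size.
    """
    px = np.atleast_2d(px)
    cx = np.rint(px[:, 0]).astype(np.int64)
    cy = np.rint(px[:, 1]).astype(np.int64)
    offs = np.arange(-radius, radius + 1)
    dx = cx[:, None] + offs[None, :] - px[:, 0:1]
    dy = cy[:, None] + offs[None, :] - px[:, 1:2]
    gx = np.exp(-0.5 * (dx / sigma) ** 2)
    gy = np.exp(-0.5 * (dy / sigma) ** 2)
    patch = gy[:, :, None] * gx[:, None, :]
    corner = np.stack([cy - radius, cx - radius], axis=1)
    return corner, patch


def scatter_add_patches(image: np.ndarray, corner: np.ndarray, patch: np.ndarray) -> None:
    """Accumulate patches into an image in place, clipping at the borders."""
    if len(corner) == 0:
        return
    h, w = image.shape
    P = patch.shape[1]
    offs = np.arange(P)
    rows = corner[:, 0:1, None] + offs[None, :, None]
    cols = corner[:, 1:2, None] + offs[None, None, :]
    rows = np.broadcast_to(rows, patch.shape)
    cols = np.broadcast_to(cols, patch.shape)
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    np.add.at(image, (rows[ok], cols[ok]), patch[ok])


def render_particle_image(positions_mm: np.ndarray, cam: CameraModel, view: int,
                          intensities: np.ndarray | None = None,
                          out: np.ndarray | None = None) -> np.ndarray:
    """Noise-free float image of a particle set in one view."""
    h, w = cam.image_shape
    img = out if out is not None else np.zeros((h, w))
    if len(positions_mm) == 0:
        return img
    px = cam.project(positions_mm, view)
    radius = int(math.ceil(4.0 * cam.otf_sigma))
    keep = cam.in_frame(px, margin=radius)
    px = px[keep]
    corner, patch = gaussian_patches(px, cam.otf_sigma, radius)
    amp = np.full(len(px), cam.peak_intensity) if intensities is None \
        else np.asarray(intensities, dtype=float)[keep]
    scatter_add_patches(img, corner, patch * amp[:, None, None])
    return img


def render_images(tracks: TrackSet, cam: CameraModel, ppp_target: float | None = None,
                  noise_sigma: float = 0.0, rng_seed: int = 0) -> ImageSequence:
    """Render a track set into multi-view Gaussian-spot count images.

    Each active particle appears in every view as a spot of width
    ``cam.otf_sigma`` and peak ``cam.peak_intensity`` at its projected
    sub-pixel position. Optional additive Gaussian noise (``noise_sigma``
    counts, seeded) is applied before clipping at zero and quantising to
    integer counts. If ``ppp_target`` is given the rendered particle count
    is checked against ``H * W * ppp_target`` (a >10% mismatch warns).
    """
    rng = np.random.default_rng(rng_seed)
    h, w = cam.image_shape
    frames = np.zeros((tracks.n_steps, cam.n_views, h, w), dtype=np.uint16)
    counts = []
    for t in range(tracks.n_steps):
        _, pos = tracks.active_positions(t)
        counts.append(len(pos))
        for v in range(cam.n_views):
            img = render_particle_image(pos, cam, v)
            if noise_sigma > 0:
                img = img + rng.normal(0.0, noise_sigma, size=img.shape)
            np.clip(np.rint(img), 0, np.iinfo(np.uint16).max, out=img)
            frames[t, v] = img.astype(np.uint16)
    meta = {"rng_seed": rng_seed, "noise_sigma": noise_sigma,
            "mean_particles_per_frame": float(np.mean(counts)),
            "ppp_actual": float(np.mean(counts)) / (h * w)}
    if ppp_target is not None:
        expected = h * w * ppp_target
        meta["ppp_target"] = ppp_target
        if expected > 0 and abs(np.mean(counts) - expected) > 0.1 * expected:
            warnings.warn(
                f"rendered particle count {np.mean(counts):.0f} deviates >10% from "
                f"ppp target ({expected:.0f})", stacklevel=2)
    return ImageSequence(frames, frame_rate=tracks.frame_rate, metadata=meta)
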