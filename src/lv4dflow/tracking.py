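"""Time-resolved 3D particle tracking from multi-view images.

The pipeline follows the predict/shake/extend scheme of Lagrangian
particle tracking: particles are identified in the first frames by
iterative triangulation (peak detection, epipolar matching, greedy
claiming), linked into tracks, and then propagated frame to frame by
extrapolating each track and refining the predicted 3D position against
the raw images ("shaking"). Triangulation of the residual images spawns
candidate tracks that become active only after ``min_track_len``
consecutive confirmations, which is the main ghost-suppression mechanism.

Positions are handled in world mm; "voxel" tolerances are converted
through the camera magnification (1 voxel = 1 px = ``cam.mm_per_px`` mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .imaging import CameraModel, ImageSequence
from .tracks import TrackSet

__all__ = [
    "TrackerConfig", "ParticleCandidate", "detect_peaks", "triangulate",
    "predict_positions", "shake_refine", "ShakeResult", "Tracker",
    "initialize_tracks", "track_frame_advance", "track_sequence",
    "fit_tracks", "match_tracks_to_truth",
]


@dataclass(frozen=True)
class TrackerConfig:
    """Tracker tuning; defaults follow the reference operating point
    (5-count detection threshold, 1-voxel triangulation tolerance,
    0.1-voxel shake step over eight iterations, 4-frame track acceptance,
    3-step quadratic track fit)."""

    intensity_threshold: float = 5.0   # counts
    triangulation_tol: float = 1.0     # voxel
    shake_step: float = 0.1            # voxel
    n_shake_iterations: int = 8
    min_track_len: int = 4             # consecutive frames before a track is accepted
    init_frames: int = 4
    spline_window: int = 3             # frames per quadratic fit window
    search_radius: float = 4.0         # voxel, frame-to-frame linking radius
    ipr_sweeps: int = 3                # triangulation sweeps during initialization
    max_missed: int = 2                # consecutive misses before termination
    # image-match quality gate: a tracked particle whose window residual
    # exceeds this fraction of its model energy counts as missed (tuned
    # for noise-free synthetic images; raise for noisy recordings)
    max_misfit: float = 0.02

    def __post_init__(self) -> None:
        for name in ("intensity_threshold", "triangulation_tol", "shake_step",
                     "n_shake_iterations", "min_track_len", "init_frames",
                     "spline_window", "search_radius", "ipr_sweeps", "max_missed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.shake_step >= self.triangulation_tol:
            raise ValueError("shake_step must be smaller than triangulation_tol")


@dataclass
class ParticleCandidate:
    """A triangulated 3D particle: position (mm), supporting-view count,
    worst reprojection error (px) and mean supporting peak intensity."""

    position_mm: np.ndarray
    intensity: float
    reprojection_error: float
    n_supporting_views: int
    support: tuple = ()  # ((view, peak_index), ...)

    def position_vox(self, cam: CameraModel) -> np.ndarray:
        return cam.mm_to_voxel(self.position_mm)[0]


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def _subpixel_refine(img: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """3-point Gaussian (log-parabolic) refinement per axis; exact for a
    point-sampled Gaussian spot. Falls back to a parabolic fit when a
    neighbour is non-positive; offsets are clamped to half a pixel."""
    out = np.stack([cols, rows], axis=1).astype(float)
    h, w = img.shape
    interior = (rows > 0) & (rows < h - 1) & (cols > 0) & (cols < w - 1)
    r, c = rows[interior], cols[interior]
    center = img[r, c].astype(float)
    for axis in range(2):
        if axis == 0:  # x (columns)
            lo, hi = img[r, c - 1].astype(float), img[r, c + 1].astype(float)
        else:          # y (rows)
            lo, hi = img[r - 1, c].astype(float), img[r + 1, c].astype(float)
        ok = (lo > 0) & (hi > 0) & (center > 0)
        delta = np.zeros(len(r))
        with np.errstate(divide="ignore", invalid="ignore"):
            llo, lc, lhi = np.log(lo[ok]), np.log(center[ok]), np.log(hi[ok])
            den = llo - 2 * lc + lhi
            d = np.where(den < 0, 0.5 * (llo - lhi) / den, 0.0)
            delta[ok] = d
            nok = ~ok
            den2 = lo[nok] - 2 * center[nok] + hi[nok]
            delta[nok] = np.where(den2 < 0, 0.5 * (lo[nok] - hi[nok]) / den2, 0.0)
        out[interior, axis] += np.clip(delta, -0.5, 0.5)
    return out


def detect_peaks(image: np.ndarray, threshold: float):
    """Sub-pixel local maxima of a count image.

    Returns ``(positions (n, 2) px, intensities (n,), plateau_flags (n,))``,
    brightest first. Local maxima at or above ``threshold`` are refined to
    sub-pixel by a 3-point Gaussian fit per axis; saturated plateaus are
    replaced by their centroid and flagged; duplicates within 1 px are
    merged keeping the brightest.
    """
    img = np.asarray(image, dtype=float)
    if (img < 0).any():
        raise ValueError("image must be non-negative")
    maxf = ndimage.maximum_filter(img, size=3, mode="constant", cval=-1.0)
    cand = (img >= threshold) & (img == maxf)
    if not cand.any():
        return np.empty((0, 2)), np.empty(0), np.empty(0, dtype=bool)

    labels, n_lab = ndimage.label(cand)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n_lab + 1))
    positions, intensities, plateau = [], [], []

    single = sizes == 1
    if single.any():
        idx = np.argwhere(cand & np.isin(labels, np.flatnonzero(single) + 1))
        rows, cols = idx[:, 0], idx[:, 1]
        pos = _subpixel_refine(img, rows, cols)
        positions.append(pos)
        intensities.append(img[rows, cols].astype(float))
        plateau.append(np.zeros(len(rows), dtype=bool))
    for lab in np.flatnonzero(~single) + 1:
        com = ndimage.center_of_mass(img, labels, lab)
        positions.append(np.array([[com[1], com[0]]]))
        intensities.append(np.array([ndimage.maximum(img, labels, lab)]))
        plateau.append(np.array([True]))

    pos = np.concatenate(positions)
    inten = np.concatenate(intensities)
    plat = np.concatenate(plateau)
    order = np.argsort(-inten, kind="stable")
    pos, inten, plat = pos[order], inten[order], plat[order]

    # merge duplicates within 1 px, brightest kept
    keep = np.ones(len(pos), dtype=bool)
    tree = cKDTree(pos)
    for i in range(len(pos)):
        if not keep[i]:
            continue
        for j in tree.query_ball_point(pos[i], 1.0):
            if j != i and inten[j] <= inten[i]:
                keep[j] = False
    return pos[keep], inten[keep], plat[keep]


# ---------------------------------------------------------------------------
# Triangulation (iterative particle reconstruction core)
# ---------------------------------------------------------------------------

def _solve_views(cam: CameraModel, views, px_list) -> np.ndarray:
    """Batch least-squares 3D point from fixed supporting views.

    ``px_list``: per-view (n, 2) pixel arrays, consistent ordering.
    """
    A = np.concatenate([cam.rotations[v][:2] for v in views], axis=0)  # (2k, 3)
    pinv = np.linalg.pinv(A)
    b = np.concatenate(
        [(px - cam.center_px) * cam.mm_per_px for px in px_list], axis=1)  # (n, 2k)
    return b @ pinv.T + cam.origin_mm


def triangulate(view_peaks, cam: CameraModel, tol: float = 1.0,
                min_views: int = 3) -> list[ParticleCandidate]:
    """3D particle candidates from per-view peak lists.

    A candidate must reproject within ``tol`` voxels of a detected peak in
    at least 3 supporting views. Candidates are generated from epipolar
    pair matching over consecutive view pairs, refined with all supporting
    views, de-duplicated, and finally accepted brightest-first with each
    peak claimable once (iterative claiming suppresses ghosts).

    ``view_peaks`` is a sequence of ``(positions (n, 2), intensities (n,))``
    per view (extra tuple entries are ignored).
    """
    nv = cam.n_views
    min_views = max(3, min_views)
    peaks = [(np.asarray(vp[0], dtype=float), np.asarray(vp[1], dtype=float))
             for vp in view_peaks]
    if sum(1 for p, _ in peaks if len(p)) < min_views:
        return []
    tol_mm = tol * cam.mm_per_px

    raw: list[ParticleCandidate] = []
    for i, j in [(k, k + 1) for k in range(nv - 1)]:
        pi, ii = peaks[i]
        pj, ij = peaks[j]
        if len(pi) == 0 or len(pj) == 0:
            continue
        p0, d = cam.ray(pi, i)
        a = cam.project(p0, j)                      # epipolar line anchors in view j
        bdir = (cam.rotations[j] @ d)[:2]
        nb = np.linalg.norm(bdir)
        if nb < 1e-9:
            continue  # parallel geometry: no depth from this pair
        bhat = bdir / nb
        rel = pj[None, :, :] - a[:, None, :]        # (ni, nj, 2)
        dist = np.abs(rel[..., 0] * bhat[1] - rel[..., 1] * bhat[0])
        ci, cj = np.nonzero(dist <= 1.6 * tol + 0.5)
        if len(ci) == 0:
            continue
        X = _solve_views(cam, (i, j), (pi[ci], pj[cj]))
        # gather supports in every view
        support_px = [None] * nv
        support_idx = np.full((len(X), nv), -1, dtype=np.int64)
        err = np.zeros((len(X), nv))
        for v in range(nv):
            pv, _ = peaks[v]
            proj = cam.project(X, v)
            if len(pv) == 0:
                err[:, v] = np.inf
                continue
            tv = cKDTree(pv)
            dd, kk = tv.query(proj, k=1)
            hit = dd <= tol * 1.5  # generous before joint refinement
            support_idx[hit, v] = kk[hit]
            err[:, v] = np.where(hit, dd, np.inf)
        n_sup = (support_idx >= 0).sum(axis=1)
        ok = n_sup >= min_views
        if not ok.any():
            continue
        # refine with all supporting views, grouped by support pattern;
        # a supporting view whose peak is biased (e.g. two particles merged
        # into one spot) can push the joint reprojection error over
        # tolerance, so the worst view is dropped while >= 3 remain
        for pattern in np.unique(support_idx[ok] >= 0, axis=0):
            sel = ok & (np.all((support_idx >= 0) == pattern[None, :], axis=1))
            if not sel.any():
                continue
            views = list(np.flatnonzero(pattern))
            rows = np.flatnonzero(sel)
            pending = [(views, rows)]
            while pending:
                vws, rws = pending.pop()
                px_list = [peaks[v][0][support_idx[rws, v]] for v in vws]
                Xr = _solve_views(cam, tuple(vws), px_list)
                errs = np.stack([np.linalg.norm(cam.project(Xr, v) - px_list[n_v], axis=1)
                                 for n_v, v in enumerate(vws)])  # (n_views, n)
                werr = errs.max(axis=0)
                good = werr <= tol
                for x, e, si in zip(Xr[good], werr[good], rws[good]):
                    sup = tuple((int(v), int(support_idx[si, v])) for v in vws)
                    inten = float(np.mean([peaks[v][1][k] for v, k in sup]))
                    raw.append(ParticleCandidate(x, inten, float(e), len(vws), sup))
                if len(vws) > min_views and (~good).any():
                    bad = rws[~good]
                    worst = errs[:, ~good].argmax(axis=0)
                    for w in np.unique(worst):
                        keep_views = [v for n_v, v in enumerate(vws) if n_v != w]
                        pending.append((keep_views, bad[worst == w]))

    if not raw:
        return []
    # de-duplicate in 3D (same physical particle found from several pairs)
    raw.sort(key=lambda c: (-c.n_supporting_views, -c.intensity, c.reprojection_error))
    pos = np.array([c.position_mm for c in raw])
    tree = cKDTree(pos)
    taken = np.zeros(len(raw), dtype=bool)
    unique: list[ParticleCandidate] = []
    for i, c in enumerate(raw):
        if taken[i]:
            continue
        for j in tree.query_ball_point(pos[i], 0.75 * tol_mm):
            taken[j] = True
        unique.append(c)

    # Greedy claiming of peaks, two passes: fully supported candidates
    # (seen in every view) claim first, brightest first; 3-view candidates
    # may only use peaks left over. Ghosts assembled from epipolar
    # coincidences rarely find a consistent fourth view, so this ordering
    # suppresses them without losing genuinely occluded particles.
    unique.sort(key=lambda c: (-c.n_supporting_views, -c.intensity))
    claimed = [np.zeros(len(p), dtype=bool) for p, _ in peaks]
    accepted: list[ParticleCandidate] = []
    for c in unique:
        free = tuple((v, k) for v, k in c.support if not claimed[v][k])
        if len(free) < min_views:
            continue
        for v, k in free:
            claimed[v][k] = True
        accepted.append(ParticleCandidate(c.position_mm, c.intensity,
                                          c.reprojection_error, len(free), free))
    return accepted


# ---------------------------------------------------------------------------
# Prediction and shaking
# ---------------------------------------------------------------------------

def predict_positions(history: np.ndarray) -> np.ndarray:
    """Extrapolate the next position from the last <=3 positions.

    ``history`` is ``(n_frames, 3)`` (or ``(n_tracks, n_frames, 3)``), most
    recent last. Quadratic extrapolation from 3 frames, linear from 2,
    constant from 1.
    """
    h = np.asarray(history, dtype=float)
    single = h.ndim == 2
    if single:
        h = h[None]
    n = h.shape[1]
    if n >= 3:
        pred = 3 * h[:, -1] - 3 * h[:, -2] + h[:, -3]
    elif n == 2:
        pred = 2 * h[:, -1] - h[:, -2]
    elif n == 1:
        pred = h[:, -1].copy()
    else:
        raise ValueError("history must contain at least one position")
    return pred[0] if single else pred


def _patches_fixed_corner(corner: np.ndarray, px: np.ndarray, sigma: float, P: int):
    """Unit-peak Gaussians at sub-pixel centers ``px`` sampled on windows
    anchored at ``corner`` (rows, cols), window size P x P."""
    offs = np.arange(P)
    dx = corner[:, 1:2] + offs[None, :] - px[:, 0:1]
    dy = corner[:, 0:1] + offs[None, :] - px[:, 1:2]
    gx = np.exp(-0.5 * (dx / sigma) ** 2)
    gy = np.exp(-0.5 * (dy / sigma) ** 2)
    return gy[:, :, None] * gx[:, None, :]


def _gather_patches(img: np.ndarray, corner: np.ndarray, P: int) -> np.ndarray:
    h, w = img.shape
    offs = np.arange(P)
    rows = np.clip(corner[:, 0:1, None] + offs[None, :, None], 0, h - 1)
    cols = np.clip(corner[:, 1:2, None] + offs[None, None, :], 0, w - 1)
    ok_r = (corner[:, 0:1, None] + offs[None, :, None] == rows)
    ok_c = (corner[:, 1:2, None] + offs[None, None, :] == cols)
    vals = img[rows, cols] * (ok_r & ok_c)
    return vals


def _scatter_patches(img: np.ndarray, corner: np.ndarray, patch: np.ndarray) -> None:
    h, w = img.shape
    P = patch.shape[1]
    offs = np.arange(P)
    rows = np.broadcast_to(corner[:, 0:1, None] + offs[None, :, None], patch.shape)
    cols = np.broadcast_to(corner[:, 1:2, None] + offs[None, None, :], patch.shape)
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    np.add.at(img, (rows[ok], cols[ok]), patch[ok])


@dataclass
class ShakeResult:
    positions: np.ndarray       # refined (n, 3) mm
    intensities: np.ndarray     # re-estimated particle brightness (counts)
    lost: np.ndarray            # particles whose intensity fell below threshold
    residual_images: np.ndarray  # (n_views, H, W), images minus rendered particles, >= 0
    objectives: np.ndarray      # (n_iterations + 1, n) summed squared residual per particle
    global_objective: np.ndarray | None = None  # (n_iterations + 1,) whole-image residual norm^2
    misfit: np.ndarray | None = None  # window residual energy / particle model energy


class _ShakeWorkspace:
    """Residual-image bookkeeping for the shake optimisation.

    Maintains ``R_v = I_v - sum_j A_j G(p_j)`` per view; every accepted move
    updates R incrementally so objective evaluations stay consistent with
    the current particle ensemble.
    """

    def __init__(self, images, positions, intensities, cam: CameraModel):
        self.cam = cam
        self.sigma = cam.otf_sigma
        self.P = 2 * (int(math.ceil(4.0 * self.sigma)) + 1) + 1
        self.images = [np.asarray(im, dtype=float) for im in images]
        self.pos = positions.copy()
        self.amp = intensities.copy()
        self.R = [im.copy() for im in self.images]
        self._apply_render(np.arange(len(positions)), sign=-1.0)

    def _proj(self, idx, positions=None):
        pos = self.pos[idx] if positions is None else positions
        return [self.cam.project(pos, v) for v in range(self.cam.n_views)]

    def _corner(self, px):
        half = (self.P - 1) // 2
        return np.stack([np.rint(px[:, 1]).astype(np.int64) - half,
                         np.rint(px[:, 0]).astype(np.int64) - half], axis=1)

    def _apply_render(self, idx, sign, positions=None, amps=None):
        if len(idx) == 0:
            return
        amp = (self.amp[idx] if amps is None else amps)
        for v, px in enumerate(self._proj(idx, positions)):
            corner = self._corner(px)
            g = _patches_fixed_corner(corner, px, self.sigma, self.P)
            _scatter_patches(self.R[v], corner, sign * amp[:, None, None] * g)

    def objective(self, idx, trial_positions) -> np.ndarray:
        """Summed squared residual over all views in the particle windows,
        as if particles ``idx`` moved to ``trial_positions`` (others fixed)."""
        E = np.zeros(len(idx))
        cur_px = self._proj(idx)
        new_px = self._proj(idx, trial_positions)
        amp = self.amp[idx]
        for v in range(self.cam.n_views):
            corner = self._corner(cur_px[v])
            Rp = _gather_patches(self.R[v], corner, self.P)
            g_cur = _patches_fixed_corner(corner, cur_px[v], self.sigma, self.P)
            g_new = _patches_fixed_corner(corner, new_px[v], self.sigma, self.P)
            diff = Rp + amp[:, None, None] * (g_cur - g_new)
            E += (diff * diff).sum(axis=(1, 2))
        return E

    def move(self, idx, new_positions):
        self._apply_render(idx, sign=+1.0)   # put old spots back
        self.pos[idx] = new_positions
        self._apply_render(idx, sign=-1.0)   # subtract at new location

    def reestimate_intensities(self, threshold, passes: int = 8):
        """Iterated per-particle least-squares intensity estimation.

        Each pass re-fits every particle's brightness against the residual
        (coordinate descent on the joint linear least-squares problem).
        Particles that explain no image signal of their own — ghosts whose
        every spot is also claimed by true particles — have no unique
        support and their intensity contracts geometrically to zero, while
        genuine particles stay anchored by their unshared views.
        """
        idx = np.arange(len(self.pos))
        for _ in range(passes):
            num = np.zeros(len(idx))
            den = np.zeros(len(idx))
            for v, px in enumerate(self._proj(idx)):
                corner = self._corner(px)
                Rp = _gather_patches(self.R[v], corner, self.P)
                g = _patches_fixed_corner(corner, px, self.sigma, self.P)
                num += ((Rp + self.amp[:, None, None] * g) * g).sum(axis=(1, 2))
                den += (g * g).sum(axis=(1, 2))
            new_amp = np.where(den > 0, np.maximum(num / np.maximum(den, 1e-30), 0.0), 0.0)
            converged = np.allclose(new_amp, self.amp, rtol=1e-3, atol=1e-2)
            self._rebuild(idx, new_amp)
            if converged:
                break
        return self.amp < threshold

    def _rebuild(self, idx, new_amp):
        self._apply_render(idx, sign=+1.0)
        self.amp = new_amp
        self._apply_render(idx, sign=-1.0)

    def misfit(self) -> np.ndarray:
        """Core-weighted residual energy over the particle's own model
        energy: sums are weighted by the particle's unit-peak footprint so
        the measure probes the fit *at the spot*, not leftover signal of
        distant neighbours. Near zero for a well-fit particle on
        noise-free images; order 0.01+ when the particle sits off its spot
        or stitches together spots of different physical particles."""
        idx = np.arange(len(self.pos))
        E = np.zeros(len(idx))
        model = np.zeros(len(idx))
        for v, px in enumerate(self._proj(idx)):
            corner = self._corner(px)
            Rp = _gather_patches(self.R[v], corner, self.P)
            gu = _patches_fixed_corner(corner, px, self.sigma, self.P)
            g = self.amp[:, None, None] * gu
            E += (Rp * Rp * gu).sum(axis=(1, 2))
            model += (g * g * gu).sum(axis=(1, 2))
        return E / np.maximum(model, 1e-30)


def _overlap_coloring(ws: _ShakeWorkspace) -> list[np.ndarray]:
    """Greedy coloring of the window-overlap graph.

    Two particles conflict when their image windows could overlap in any
    view (projected distance below ~1.5 window sizes, with margin for the
    drift accumulated while shaking). Particles of one color have disjoint
    windows everywhere, so their probes and moves are independent: batched
    updates per color keep every accepted move an exact non-increase of the
    global image-match residual."""
    n = len(ws.pos)
    radius = float(math.hypot(ws.P, ws.P) + 4)
    neighbors: list[set] = [set() for _ in range(n)]
    for v in range(ws.cam.n_views):
        px = ws.cam.project(ws.pos, v)
        tree = cKDTree(px)
        pairs = tree.query_pairs(radius, output_type="ndarray")
        for i, j in pairs:
            neighbors[i].add(j)
            neighbors[j].add(i)
    colors = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        used = {colors[j] for j in neighbors[i] if colors[j] >= 0}
        c = 0
        while c in used:
            c += 1
        colors[i] = c
    return [np.flatnonzero(colors == c) for c in range(colors.max() + 1)] if n else []


def depth_scan(positions, intensities, images, cam: CameraModel,
               span_vox: float = 2.5, steps: int = 21) -> np.ndarray:
    """Line search along the mean viewing direction for fresh candidates.

    Triangulated positions of particles found in residual images are least
    certain along the depth axis (small angular aperture); a coarse
    render-match scan over +/- ``span_vox`` voxels before shaking avoids
    locking a newcomer into a displaced local minimum.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(positions) == 0:
        return positions
    amps = np.asarray(intensities, dtype=float)
    d = np.array([cam.rotations[v].T @ [0.0, 0.0, 1.0] for v in range(cam.n_views)]).mean(0)
    d /= np.linalg.norm(d)
    sigma = cam.otf_sigma
    P = 2 * (int(math.ceil(4.0 * sigma)) + 1) + 1
    half = (P - 1) // 2
    offsets = np.linspace(-span_vox, span_vox, steps) * cam.mm_per_px
    best_E = np.full(len(positions), np.inf)
    best_q = positions.copy()
    imgs = [np.asarray(im, dtype=float) for im in images]
    for off in offsets:
        q = positions + off * d
        E = np.zeros(len(q))
        for v in range(cam.n_views):
            px = cam.project(q, v)
            corner = np.stack([np.rint(px[:, 1]).astype(np.int64) - half,
                               np.rint(px[:, 0]).astype(np.int64) - half], axis=1)
            Rp = _gather_patches(imgs[v], corner, P)
            g = _patches_fixed_corner(corner, px, sigma, P)
            diff = Rp - amps[:, None, None] * g
            E += np.einsum("npq,npq->n", diff, diff)
        better = E < best_E
        best_E[better] = E[better]
        best_q[better] = q[better]
    return best_q


def shake_refine(positions, images, cam: CameraModel, cfg: TrackerConfig,
                 intensities=None, refine_pairs: bool = True) -> ShakeResult:
    """Refine predicted 3D particle positions against the current images.

    Coordinate descent: per iteration and axis every particle probes
    displacements of +/- ``shake_step`` voxels; a guarded 3-point parabolic
    interpolation of the residual then proposes a sub-step position, which
    is accepted only if it lowers the residual (otherwise the best probe
    wins). After the iterations particle intensities are re-estimated by
    least squares; particles falling below ``intensity_threshold`` are
    flagged lost. With ``refine_pairs`` (the default), closely projecting
    particle pairs whose joint windows still carry residual energy get an
    extra antisymmetric joint refinement after the coordinate descent.
    Returns refined positions, intensities, the residual images
    (non-negative) and the per-iteration objective history.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    if intensities is None:
        intensities = np.full(n, cam.peak_intensity)
    else:
        intensities = np.asarray(intensities, dtype=float).copy()
    if n == 0:
        R = np.clip([np.asarray(im, float) for im in images], 0, None)
        return ShakeResult(positions, intensities, np.zeros(0, bool), R,
                           np.zeros((cfg.n_shake_iterations + 1, 0)),
                           np.zeros(cfg.n_shake_iterations + 1))

    ws = _ShakeWorkspace(images, positions, intensities, cam)
    h = cfg.shake_step * cam.mm_per_px  # mm
    color_batches = _overlap_coloring(ws)

    obj = np.zeros((cfg.n_shake_iterations + 1, n))
    obj[0] = ws.objective(np.arange(n), ws.pos)
    gobj = np.zeros(cfg.n_shake_iterations + 1)
    gobj[0] = sum(float((r * r).sum()) for r in ws.R)

    nv = cam.n_views
    # affine cameras: a world displacement along an axis shifts every
    # projection by a constant pixel vector
    axis_shift_px = np.stack([cam.rotations[v][:2] / cam.mm_per_px
                              for v in range(nv)])  # (views, 2 px, 3 axes)

    def axis_update(idx):
        if len(idx) == 0:
            return
        for axis in range(3):
            amp = ws.amp[idx][:, None, None]
            cache = []  # per view: (corner, Rp + amp*g_cur, px_cur)
            for v in range(nv):
                px_cur = cam.project(ws.pos[idx], v)
                corner = ws._corner(px_cur)
                Rp = _gather_patches(ws.R[v], corner, ws.P)
                g_cur = _patches_fixed_corner(corner, px_cur, ws.sigma, ws.P)
                cache.append((corner, Rp + amp * g_cur, px_cur))

            def probe(delta):
                """Objective for per-particle axis displacement ``delta``."""
                E = np.zeros(len(idx))
                for v in range(nv):
                    corner, base, px_cur = cache[v]
                    px_new = px_cur + np.multiply.outer(delta, axis_shift_px[v, :, axis])
                    g_new = _patches_fixed_corner(corner, px_new, ws.sigma, ws.P)
                    d = base - amp * g_new
                    E += np.einsum("npq,npq->n", d, d)
                return E

            zeros = np.zeros(len(idx))
            E0, Em, Ep = probe(zeros), probe(zeros - h), probe(zeros + h)
            den = Em - 2 * E0 + Ep
            with np.errstate(divide="ignore", invalid="ignore"):
                dstar = np.where(den > 0, 0.5 * h * (Em - Ep) / den, 0.0)
            dstar = np.clip(dstar, -h, h)
            Es = probe(dstar)
            choice = np.argmin(np.stack([E0, Em, Ep, Es]), axis=0)
            delta = np.choose(choice, [zeros, zeros - h, zeros + h, dstar])
            moved = np.flatnonzero(delta != 0.0)
            if len(moved) == 0:
                continue
            # apply moves and update residuals in one scatter per view
            ws.pos[idx[moved], axis] += delta[moved]
            for v in range(nv):
                corner, base, px_cur = cache[v]
                px_new = px_cur[moved] + np.multiply.outer(delta[moved],
                                                           axis_shift_px[v, :, axis])
                g_new = _patches_fixed_corner(corner[moved], px_new, ws.sigma, ws.P)
                g_old = _patches_fixed_corner(corner[moved], px_cur[moved], ws.sigma, ws.P)
                _scatter_patches(ws.R[v], corner[moved],
                                 ws.amp[idx[moved]][:, None, None] * (g_old - g_new))

    for it in range(cfg.n_shake_iterations):
        for batch in color_batches:
            axis_update(batch)
        obj[it + 1] = ws.objective(np.arange(n), ws.pos)
        gobj[it + 1] = sum(float((r * r).sum()) for r in ws.R)

    if refine_pairs:
        _pair_refine(ws, cam, cfg, h)
    lost = ws.reestimate_intensities(cfg.intensity_threshold)
    residuals = np.clip(np.stack(ws.R), 0.0, None)
    return ShakeResult(ws.pos, ws.amp, lost, residuals, obj, gobj, ws.misfit())


def _pair_refine(ws: _ShakeWorkspace, cam: CameraModel, cfg: TrackerConfig,
                 h: float, max_rounds: int = 12) -> None:
    """Resolve shallow two-particle minima by antisymmetric pair probes.

    Particle-by-particle descent has spurious fixed points for closely
    spaced pairs (each position optimal given the other's wrong one, with
    brightness compensating). Probing both members simultaneously in
    opposite directions explores exactly the degenerate valley; moves are
    kept only when the pair's joint window residual drops. Brightnesses
    are re-balanced between rounds.
    """
    # only nearly-coincident spots are degenerate: limit to < 3 sigma
    radius = 3.0 * ws.sigma
    pairs = set()
    for v in range(cam.n_views):
        px = cam.project(ws.pos, v)
        for i, j in cKDTree(px).query_pairs(radius):
            pairs.add((min(i, j), max(i, j)))
    if not pairs:
        return
    # probe only pairs whose own (core-weighted) fit is actually poor;
    # residual junk from third parties does not qualify a pair
    mis = ws.misfit()
    active = sorted((i, j) for i, j in pairs
                    if max(mis[i], mis[j]) > 0.5 * cfg.max_misfit)
    if not active:
        return
    ws.reestimate_intensities(threshold=-np.inf, passes=2)
    for r in range(max_rounds):
        still = []
        for i, j in active:
            idx = np.array([i, j])
            E0 = float(ws.objective(idx, ws.pos[idx]).sum())
            improved = False
            for axis in range(3):
                for delta in (3 * h, -3 * h, h, -h):
                    old = ws.pos[idx].copy()
                    trial = old.copy()
                    trial[0, axis] += delta
                    trial[1, axis] -= delta
                    ws.move(idx, trial)
                    E1 = float(ws.objective(idx, ws.pos[idx]).sum())
                    if E1 < E0 * (1 - 1e-12):
                        E0 = E1
                        improved = True
                    else:
                        ws.move(idx, old)
            if improved:
                still.append((i, j))  # pairs that stop improving retire
        active = still
        if not active:
            break
        if r % 4 == 3:
            ws.reestimate_intensities(threshold=-np.inf, passes=2)


# ---------------------------------------------------------------------------
# Track state machine
# ---------------------------------------------------------------------------

INITIALIZING, PROBATION, ACTIVE, LOST, TERMINATED = (
    "initializing", "probation", "active", "lost", "terminated")


class _LiveTrack:
    __slots__ = ("id", "first_frame", "positions", "found", "quality", "status",
                 "intensity", "missed", "consecutive", "accepted",
                 "probation_good", "probation_age", "suspect")

    def __init__(self, tid, first_frame, position, intensity, status=INITIALIZING):
        self.id = tid
        self.first_frame = first_frame
        self.positions = [np.asarray(position, dtype=float)]
        self.found = [True]
        self.quality = [True]
        self.status = status
        self.intensity = float(intensity)
        self.missed = 0
        self.consecutive = 1
        self.accepted = status == ACTIVE
        self.probation_good = 0
        self.probation_age = 0
        self.suspect = 0

    def append(self, position, found, quality=True):
        self.positions.append(np.asarray(position, dtype=float))
        self.found.append(bool(found))
        self.quality.append(bool(quality))
        if found:
            self.missed = 0
            self.consecutive += 1
        else:
            self.missed += 1
            self.consecutive = 0

    def recent(self, k=3) -> np.ndarray:
        return np.array(self.positions[-k:])


class Tracker:
    """Stateful predict/shake/extend tracker over an image sequence."""

    def __init__(self, cfg: TrackerConfig, cam: CameraModel):
        self.cfg = cfg
        self.cam = cam
        self.tracks: list[_LiveTrack] = []
        self.frame = -1
        self._next_id = 0
        self.diagnostics: list[dict] = []

    # -- initialization ---------------------------------------------------
    def _ipr_frame(self, frame_images) -> list[ParticleCandidate]:
        """Iterative particle reconstruction on one frame.

        Triangulate, shake the ensemble, triangulate the residual images
        for missed particles (partners of merged spots), repeat. Residual
        sweeps demand support in every view and newly shaken particles
        must retain a brightness comparable to the first-sweep ensemble;
        both rules starve the cascade of spurious particles that imperfect
        subtraction would otherwise seed.
        """
        cfg, cam = self.cfg, self.cam
        cands: list[ParticleCandidate] = []
        residuals = [np.asarray(im, dtype=float) for im in frame_images]
        brightness_ref = None
        for sweep in range(max(cfg.ipr_sweeps, 8)):
            thr = cfg.intensity_threshold if brightness_ref is None \
                else max(cfg.intensity_threshold, 0.3 * brightness_ref)
            peaks = [detect_peaks(r, thr) for r in residuals]
            new = triangulate(peaks, cam, cfg.triangulation_tol,
                              min_views=3 if sweep == 0 else cam.n_views)
            if cands and new:
                tree = cKDTree(np.array([c.position_mm for c in cands]))
                new = [c for c in new
                       if not tree.query_ball_point(c.position_mm,
                                                    cfg.triangulation_tol * cam.mm_per_px)]
            if not new and sweep >= cfg.ipr_sweeps:
                break
            if new and sweep > 0:
                # depth scan against the residuals before the newcomers join
                refined = depth_scan(np.array([c.position_mm for c in new]),
                                     np.array([c.intensity for c in new]),
                                     residuals, cam)
                new = [ParticleCandidate(p, c.intensity, c.reprojection_error,
                                         c.n_supporting_views, c.support)
                       for p, c in zip(refined, new)]
            cands.extend(new)
            if not cands:
                break
            sr = shake_refine(np.array([c.position_mm for c in cands]), frame_images,
                              cam, cfg, np.array([c.intensity for c in cands]))
            if brightness_ref is None and (~sr.lost).any():
                brightness_ref = float(np.median(sr.intensities[~sr.lost]))
            floor = max(cfg.intensity_threshold,
                        0.35 * (brightness_ref or 0.0))
            cands = [ParticleCandidate(p, a, c.reprojection_error,
                                       c.n_supporting_views, c.support)
                     for p, a, c, lost in zip(sr.positions, sr.intensities, cands, sr.lost)
                     if not lost and a >= floor]
            residuals = sr.residual_images
            if not new:
                break
        return cands

    def initialize(self, images: np.ndarray) -> None:
        """Identify particles in the first ``init_frames`` frames and link
        them into tracks.

        Only chains spanning every init frame survive; a kinematic check
        rejects chains that cannot be fit by a smooth (quadratic)
        trajectory within the triangulation tolerance, and surviving
        chains still face image-based validation (probation) before being
        accepted. Particles missed here are recovered later through the
        residual-triangulation candidate chains.
        """
        cfg = self.cfg
        if images.shape[0] < cfg.init_frames:
            raise ValueError(f"need at least {cfg.init_frames} frames to initialize")
        per_frame = [self._ipr_frame(images[f]) for f in range(cfg.init_frames)]
        if any(len(c) == 0 for c in per_frame):
            import warnings
            warnings.warn("no particle candidates in an initialization frame; "
                          "tracker starts empty", stacklevel=2)
            self.frame = cfg.init_frames - 1
            return
        radius = cfg.search_radius * self.cam.mm_per_px
        chains = [[c] for c in per_frame[0]]
        for f in range(1, cfg.init_frames):
            cands = per_frame[f]
            cpos = np.array([c.position_mm for c in cands])
            pred = np.array([predict_positions(np.array([c.position_mm for c in ch]))
                             for ch in chains])
            chains = _greedy_extend(chains, pred, cands, cpos, radius)
        tol_mm = cfg.triangulation_tol * self.cam.mm_per_px
        for ch in chains:
            if len(ch) != cfg.init_frames:
                continue
            pos = np.array([c.position_mm for c in ch])
            if not _smooth_chain(pos, tol_mm):
                continue
            t = _LiveTrack(self._next_id, 0, ch[0].position_mm, ch[0].intensity,
                           status=PROBATION)
            for c in ch[1:]:
                t.append(c.position_mm, True)
            t.intensity = float(np.mean([c.intensity for c in ch]))
            self.tracks.append(t)
            self._next_id += 1
        self.frame = cfg.init_frames - 1

    # -- frame advance ----------------------------------------------------
    def advance(self, frame_images) -> dict:
        """Process the next frame: predict, shake all live particles
        (tracked, on probation, and freshly spawned chains alike), then
        spawn new candidates from the residual images."""
        cfg, cam = self.cfg, self.cam
        self.frame += 1
        shaken = [t for t in self.tracks
                  if t.status in (ACTIVE, PROBATION, INITIALIZING)]

        n_lost = 0
        residuals = np.clip(np.asarray(frame_images, dtype=float), 0, None)
        age_cap = cfg.min_track_len + 8
        if shaken:
            pred = np.array([predict_positions(t.recent()) for t in shaken])
            amp = np.array([t.intensity for t in shaken])
            sr = shake_refine(pred, frame_images, cam, cfg, amp)
            residuals = sr.residual_images
            for k, t in enumerate(shaken):
                if sr.lost[k]:
                    if t.status in (PROBATION, INITIALIZING):
                        # failed image-based validation: never reported
                        t.status = TERMINATED
                        continue
                    t.append(pred[k], found=False)
                    if t.missed >= cfg.max_missed:
                        t.status = LOST
                        n_lost += 1
                    continue
                good = sr.misfit[k] <= cfg.max_misfit
                t.append(sr.positions[k], found=True, quality=good)
                t.intensity = 0.7 * t.intensity + 0.3 * sr.intensities[k]
                if t.status == INITIALIZING:
                    # a chain is accepted only after min_track_len
                    # consecutive confirmations ending in a clean image
                    # match; chains that never stabilise age out
                    t.probation_age += 1
                    if good and t.consecutive >= cfg.min_track_len:
                        t.status = PROBATION
                    elif t.probation_age > age_cap:
                        t.status = TERMINATED
                elif t.status == PROBATION:
                    # final validation: a clean match for two consecutive
                    # frames; a transiently disturbed newcomer (unmodelled
                    # neighbours) gets a few frames of grace, a ghost never
                    # fits cleanly and is silently dropped
                    t.probation_age += 1
                    t.probation_good = t.probation_good + 1 if good else 0
                    if t.probation_good >= 2:
                        t.status = ACTIVE
                        t.accepted = True
                    elif t.probation_age > age_cap:
                        t.status = TERMINATED
                else:
                    # an accepted track must keep fitting the images;
                    # sustained misfit means it drifted off or stitched
                    # two particles together
                    t.suspect = t.suspect + 1 if not good else 0
                    if t.suspect >= 6:
                        t.status = LOST
                        n_lost += 1
            # two live particles collapsing onto the same position split a
            # single spot's intensity between them: keep the senior one
            alive = [t for t in shaken
                     if t.status in (ACTIVE, PROBATION, INITIALIZING) and t.found[-1]]
            if len(alive) > 1:
                pos = np.array([t.positions[-1] for t in alive])
                for i, j in cKDTree(pos).query_pairs(0.5 * cam.mm_per_px):
                    a, b = alive[i], alive[j]
                    junior = min(a, b, key=lambda t: (t.accepted, -t.first_frame, -t.id))
                    if junior.status != TERMINATED:
                        junior.status = TERMINATED if not junior.accepted else LOST

        # new particles from the residual images (full-view support: tracked
        # particles are subtracted, so genuine newcomers show in every view).
        # The spawn threshold sits well above the faint dipole residue that
        # sub-pixel position errors leave behind, but far below a real
        # unmodelled particle's brightness.
        spawn_thr = cfg.intensity_threshold
        if shaken:
            spawn_thr = max(spawn_thr,
                            0.3 * float(np.median([t.intensity for t in shaken])))
        peaks = [detect_peaks(r, spawn_thr) for r in residuals]
        cands = triangulate(peaks, cam, cfg.triangulation_tol, min_views=cam.n_views)
        live_now = [t for t in shaken
                    if t.status in (ACTIVE, PROBATION, INITIALIZING) and t.found[-1]]
        if live_now and cands:
            occupied = cKDTree(np.array([t.positions[-1] for t in live_now]))
            cands = [c for c in cands
                     if not occupied.query_ball_point(c.position_mm,
                                                      cfg.triangulation_tol * cam.mm_per_px)]
        if cands:
            # depth-scan then shake newcomers against the residual images:
            # sharpens the triangulated position (depth especially) and
            # measures their true brightness; dim leftovers of imperfect
            # subtraction die here
            refined = depth_scan(np.array([c.position_mm for c in cands]),
                                 np.array([c.intensity for c in cands]),
                                 residuals, cam)
            srn = shake_refine(refined, residuals,
                               cam, cfg, np.array([c.intensity for c in cands]))
            floor = cfg.intensity_threshold
            if shaken:
                floor = max(floor, 0.35 * float(np.median(
                    [t.intensity for t in shaken])))
            cands = [ParticleCandidate(p, a, c.reprojection_error,
                                       c.n_supporting_views, c.support)
                     for p, a, c, lost, mf in zip(srn.positions, srn.intensities,
                                                  cands, srn.lost, srn.misfit)
                     if not lost and a >= floor and mf <= 10 * cfg.max_misfit]

        n_new = 0
        for c in cands:
            self.tracks.append(_LiveTrack(self._next_id, self.frame,
                                          c.position_mm, c.intensity))
            self._next_id += 1
            n_new += 1

        diag = {"frame": self.frame,
                "n_active": sum(1 for t in self.tracks if t.status == ACTIVE),
                "n_initializing": sum(1 for t in self.tracks if t.status == INITIALIZING),
                "n_new": n_new, "n_lost": n_lost,
                "mean_residual": float(np.mean([r.mean() for r in residuals]))}
        self.diagnostics.append(diag)
        return diag

    # -- export -----------------------------------------------------------
    def to_trackset(self, n_frames: int, frame_rate: float) -> TrackSet:
        """Accepted tracks (those that ever reached active) as a dense TrackSet."""
        acc = [t for t in self.tracks if t.accepted]
        n = len(acc)
        positions = np.full((n, n_frames, 3), np.nan)
        active = np.zeros((n, n_frames), dtype=bool)
        ids = np.empty(n, dtype=np.int64)
        term = np.zeros(n, dtype=bool)
        for k, t in enumerate(acc):
            ids[k] = t.id
            term[k] = t.status in (LOST, TERMINATED)
            for off, (p, f, q) in enumerate(zip(t.positions, t.found, t.quality)):
                fr = t.first_frame + off
                if fr < n_frames and f and q:
                    positions[k, fr] = p
                    active[k, fr] = True
        return TrackSet(positions, active, time_step=1.0 / frame_rate, ids=ids,
                        terminated=term,
                        metadata={"diagnostics": self.diagnostics})


def _smooth_chain(positions: np.ndarray, tol_mm: float) -> bool:
    """True when the positions are consistent with a smooth trajectory:
    a per-component quadratic fit reproduces every sample within
    ``tol_mm``. Chains assembled from unrelated particles (ghosts) jump
    between frames and fail this."""
    n = len(positions)
    if n < 4:
        return True
    t = np.arange(n, dtype=float)
    M = np.stack([np.ones(n), t, t * t], axis=1)
    coef, *_ = np.linalg.lstsq(M, positions, rcond=None)
    resid = positions - M @ coef
    return bool(np.abs(resid).max() <= tol_mm)


def _greedy_links(pred: np.ndarray, cand_pos: np.ndarray, radius: float) -> np.ndarray:
    """Deterministic nearest-neighbour assignment: candidate links sorted by
    distance, each side claimed once. Returns per-prediction candidate index
    (-1 when unmatched)."""
    out = np.full(len(pred), -1, dtype=np.int64)
    if len(pred) == 0 or len(cand_pos) == 0:
        return out
    tree = cKDTree(cand_pos)
    pairs = []
    for i, p in enumerate(pred):
        for j in tree.query_ball_point(p, radius):
            pairs.append((np.linalg.norm(cand_pos[j] - p), i, j))
    used_c = np.zeros(len(cand_pos), dtype=bool)
    for d, i, j in sorted(pairs, key=lambda x: (x[0], x[1], x[2])):
        if out[i] < 0 and not used_c[j]:
            out[i] = j
            used_c[j] = True
    return out


def _greedy_extend(chains, pred, cands, cand_pos, radius):
    links = _greedy_links(pred, cand_pos, radius)
    return [ch + [cands[li]] for ch, li in zip(chains, links) if li >= 0]


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def initialize_tracks(images: np.ndarray, cfg: TrackerConfig, cam: CameraModel) -> Tracker:
    """Run particle identification on the first ``cfg.init_frames`` frames."""
    tracker = Tracker(cfg, cam)
    tracker.initialize(np.asarray(images))
    return tracker


def track_frame_advance(tracker: Tracker, frame_images, cfg: TrackerConfig | None = None,
                        cam: CameraModel | None = None) -> Tracker:
    """Advance an initialized tracker by one frame (see :meth:`Tracker.advance`)."""
    tracker.advance(frame_images)
    return tracker


def track_sequence(images: ImageSequence, cam: CameraModel,
                   cfg: TrackerConfig | None = None) -> TrackSet:
    """Full tracking of an image sequence; returns fitted tracks."""
    cfg = cfg or TrackerConfig()
    tracker = initialize_tracks(images.frames[:cfg.init_frames], cfg, cam)
    for f in range(cfg.init_frames, images.n_steps):
        tracker.advance(images.frames[f])
    ts = tracker.to_trackset(images.n_steps, images.frame_rate)
    return fit_tracks(ts, cfg)


# ---------------------------------------------------------------------------
# Track fitting (velocity / acceleration)
# ---------------------------------------------------------------------------

def _quadratic_weights(window: int, dt: float):
    """Derivative weights of a sliding quadratic least-squares fit.

    Returns ``(vel_w, acc_w)`` of shape (window, window): row j gives the
    weights producing velocity/acceleration at in-window position j.
    """
    tau = (np.arange(window) - np.arange(window)[:, None]) * dt  # (j, k)
    vel = np.empty((window, window))
    acc = np.empty((window, window))
    for j in range(window):
        M = np.stack([np.ones(window), tau[j], tau[j] ** 2], axis=1)
        pinv = np.linalg.pinv(M)
        vel[j] = pinv[1]
        acc[j] = 2.0 * pinv[2]
    return vel, acc


def fit_tracks(tracks: TrackSet, cfg: TrackerConfig | None = None) -> TrackSet:
    """Sliding quadratic fit of each track: velocity and acceleration.

    Windows of ``cfg.spline_window`` frames (in seconds via the frame
    rate) are fit with a quadratic polynomial per component; the analytic
    first/second derivatives are evaluated at each frame, with one-sided
    windows at the track ends. Tracks shorter than the window get
    finite-difference velocity and NaN (flagged) acceleration.
    """
    cfg = cfg or TrackerConfig()
    w = int(cfg.spline_window)
    if w < 3:
        raise ValueError("spline_window must be at least 3 for a quadratic fit")
    dt = tracks.time_step
    vel_w, acc_w = _quadratic_weights(w, dt)
    velocity = np.full_like(tracks.positions, np.nan)
    acceleration = np.full_like(tracks.positions, np.nan)
    half = w // 2
    mm = 1e-3  # mm -> m

    if tracks.active.all() and tracks.n_steps >= w:
        # dense case (e.g. lattice-seeded synthetic ensembles): vectorise
        # the sliding fits across all tracks at once
        p = tracks.positions * mm
        L = tracks.n_steps
        win = np.lib.stride_tricks.sliding_window_view(p, w, axis=1)  # (n, L-w+1, 3, w)
        velocity[:, half:L - half] = np.einsum("ntcw,w->ntc", win, vel_w[half])
        acceleration[:, half:L - half] = np.einsum("ntcw,w->ntc", win, acc_w[half])
        for i in range(half):
            velocity[:, i] = np.einsum("nwc,w->nc", p[:, :w], vel_w[i])
            acceleration[:, i] = np.einsum("nwc,w->nc", p[:, :w], acc_w[i])
            j = L - 1 - i
            velocity[:, j] = np.einsum("nwc,w->nc", p[:, L - w:], vel_w[w - 1 - i])
            acceleration[:, j] = np.einsum("nwc,w->nc", p[:, L - w:], acc_w[w - 1 - i])
        return TrackSet(tracks.positions, tracks.active, dt, ids=tracks.ids,
                        velocity=velocity, acceleration=acceleration,
                        terminated=tracks.terminated, metadata=dict(tracks.metadata))

    for k in range(tracks.n_tracks):
        act = np.flatnonzero(tracks.active[k])
        if len(act) == 0:
            continue
        # process contiguous runs separately
        splits = np.flatnonzero(np.diff(act) > 1)
        for run in np.split(act, splits + 1):
            L = len(run)
            p = tracks.positions[k, run] * mm
            if L < w:
                if L >= 2:
                    v = np.gradient(p, dt, axis=0)
                    velocity[k, run] = v
                continue
            for i in range(L):
                # window anchored so frame i sits at in-window index jj
                lo = min(max(i - half, 0), L - w)
                jj = i - lo
                seg = p[lo:lo + w]
                velocity[k, run[i]] = vel_w[jj] @ seg
                acceleration[k, run[i]] = acc_w[jj] @ seg

    out = TrackSet(tracks.positions, tracks.active, tracks.time_step, ids=tracks.ids,
                   velocity=velocity, acceleration=acceleration,
                   terminated=tracks.terminated, metadata=dict(tracks.metadata))
    return out


# ---------------------------------------------------------------------------
# Evaluation against ground truth
# ---------------------------------------------------------------------------

def match_tracks_to_truth(result: TrackSet, truth: TrackSet, cam: CameraModel,
                          tol_vox: float = 1.0) -> dict:
    """Match reconstructed track positions to ground-truth particles.

    A track-frame pair is matched when a true particle lies within
    ``tol_vox`` reconstruction voxels; a track is a ghost when fewer than
    half of its frames match. Returns the ghost percentage, the mean 3D
    match error expressed in image pixels via the camera magnification,
    and raw counts (the 1-voxel matching tolerance is part of the report).
    """
    tol_mm = tol_vox * cam.mm_per_px
    n_frames = min(result.n_steps, truth.n_steps)
    matched = np.zeros(result.n_tracks, dtype=np.int64)
    total = np.zeros(result.n_tracks, dtype=np.int64)
    errors = []
    for f in range(n_frames):
        _, tpos = truth.active_positions(f)
        ridx, rpos = result.active_positions(f)
        if len(rpos) == 0:
            continue
        total[ridx] += 1
        if len(tpos) == 0:
            continue
        tree = cKDTree(tpos)
        dd, _ = tree.query(rpos, k=1)
        hit = dd <= tol_mm
        matched[ridx[hit]] += 1
        errors.extend(dd[hit])
    has = total > 0
    ghost = has & (matched < 0.5 * total)
    n_tracks = int(has.sum())
    errors = np.asarray(errors)
    return {
        "n_tracks": n_tracks,
        "n_ghost": int(ghost.sum()),
        "ghost_fraction_pct": 100.0 * ghost.sum() / max(n_tracks, 1),
        "n_matched_samples": len(errors),
        "mean_position_error_px": float(errors.mean() / cam.mm_per_px) if len(errors) else np.nan,
        "matching_tolerance_vox": tol_vox,
    }
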