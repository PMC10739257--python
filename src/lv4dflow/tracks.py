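"""Lagrangian track container shared by the synthetic generator and the tracker."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrackSet"]


@dataclass
class TrackSet:
    """Per-particle, time-indexed 3D positions with optional fitted kinematics.

    Dense layout: ``positions`` has shape ``(n_tracks, n_steps, 3)`` in mm with
    NaN where a track is not alive; ``active`` marks frames at which a track
    carries a valid position. ``velocity`` (m/s) and ``acceleration`` (m/s^2)
    are filled in by the track fitter and are NaN where undefined.
    """

    positions: np.ndarray
    active: np.ndarray
    time_step: float
    ids: np.ndarray | None = None
    velocity: np.ndarray | None = None
    acceleration: np.ndarray | None = None
    terminated: np.ndarray | None = None  # per-track flag: left domain / lost
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)
        if self.positions.ndim != 3 or self.positions.shape[-1] != 3:
            raise ValueError(f"positions must be (n_tracks, n_steps, 3), got {self.positions.shape}")
        if self.active.shape != self.positions.shape[:2]:
            raise ValueError("active mask shape mismatch")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if self.ids is None:
            self.ids = np.arange(self.positions.shape[0], dtype=np.int64)
        else:
            self.ids = np.asarray(self.ids, dtype=np.int64)
            if len(np.unique(self.ids)) != len(self.ids):
                raise ValueError("track ids must be unique")
        if self.terminated is None:
            self.terminated = np.zeros(self.positions.shape[0], dtype=bool)

    @property
    def n_tracks(self) -> int:
        return self.positions.shape[0]

    @property
    def n_steps(self) -> int:
        return self.positions.shape[1]

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.time_step

    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.time_step

    def active_positions(self, step: int) -> tuple[np.ndarray, np.ndarray]:
        """(track indices, positions mm) of tracks alive at a frame."""
        sel = self.active[:, step]
        return np.flatnonzero(sel), self.positions[sel, step]

    def lengths(self) -> np.ndarray:
        return self.active.sum(axis=1)

    def samples(self, step: int, which: str = "velocity") -> tuple[np.ndarray, np.ndarray]:
        """Scattered (position, value) samples at one frame for binning.

        ``which`` selects ``velocity`` or ``acceleration``; only frames where
        the requested quantity is finite are returned.
        """
        arr = getattr(self, which)
        if arr is None:
            raise ValueError(f"tracks carry no fitted {which}; run fit_tracks first")
        sel = self.active[:, step] & np.isfinite(arr[:, step]).all(axis=1)
        return self.positions[sel, step], arr[sel, step]
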