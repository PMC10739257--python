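"""Standard desk-scale scenes shared by the analyses and the test suite.

These fix the problem sizes at which the pipeline is exercised on one
CPU: a coarse Eulerian grid over the ventricle for field/pressure work, a
four-view 512 x 512 camera rig at 2 kHz for the tracking experiment, and
the snapshot counts used by the POD studies.
"""

from __future__ import annotations

from .grid import GridSpec
from .imaging import CameraModel, default_camera_model
from .synthetic import LVFlowParams

__all__ = [
    "lv_grid", "lv_pod_grid", "tracking_camera", "PROBE_BASE_MM",
    "PROBE_APEX_MM", "FULL_CYCLE_SPECTRUM", "CYCLE_STEPS_2KHZ",
]

#: long-axis probe locations for base-to-apex pressure differences (mm)
PROBE_BASE_MM = (0.0, 20.0, 0.0)
PROBE_APEX_MM = (0.0, -38.0, 0.0)

#: full-cycle modal kinetic-energy fractions of the reference LV flow
#: (leading pair 50.3% / 26.2%; the next two pairs add 18.5%, so six modes
#: reach 95% of the energy)
FULL_CYCLE_SPECTRUM = (0.503, 0.262, 0.064, 0.052, 0.039, 0.030)

#: stored time steps of one 857 ms cycle recorded at 2 kHz
CYCLE_STEPS_2KHZ = 1714


def lv_grid(n_steps: int = 64, cycle_period: float | None = None) -> GridSpec:
    """Coarse ventricle-covering grid (2.75 mm voxels, 24 x 30 x 22)."""
    period = cycle_period if cycle_period is not None else LVFlowParams().cycle_period
    return GridSpec((-33.0, -52.0, -30.0), (2.75, 2.75, 2.75), (24, 30, 22),
                    period / n_steps, n_steps)


def lv_pod_grid(n_snapshots: int = 343) -> GridSpec:
    """Grid for the POD studies: 20 x 32 x 20 voxels, snapshot times at a
    5x subsampling of the 2 kHz cycle."""
    params = LVFlowParams()
    dt = params.cycle_period / CYCLE_STEPS_2KHZ * 5
    return GridSpec((-33.0, -52.0, -30.0), (3.3, 3.3, 3.0), (20, 32, 20),
                    dt, n_snapshots)


def tracking_camera(image_shape=(512, 512)) -> CameraModel:
    """The four-view rig of the desk-scale tracking experiment
    (0.2 mm/px magnification, 1.2 px Gaussian OTF, 1000-count peaks)."""
    return default_camera_model(image_shape=image_shape, mm_per_px=0.2)


def tracking_grid(n_frames: int = 100) -> GridSpec:
    """Flow sampling for the tracking scene: 2 kHz frames."""
    return GridSpec((-33.0, -52.0, -30.0), (2.75, 2.75, 2.75), (24, 30, 22),
                    1.0 / 2000.0, n_frames)
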