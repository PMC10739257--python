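"""End-to-end orchestration: synth -> track -> fields -> pressure -> pod.

A single YAML (or dict) config drives all stages; every stage writes its
outputs plus reproducibility metadata (global seed, config hash), and a
run manifest summarises inputs/outputs and wall time per stage. Stages
whose outputs already exist under a matching config hash are skipped.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import io as lvio
from .binning import BinningConfig, bin_velocity
from .fields import divergence_free_filter, lambda2
from .grid import GridSpec
from .imaging import default_camera_model, render_images
from .pod import interpolate_to_reference, snapshot_pod
from .pressure import (FluidProperties, PPEConfig, material_derivative_eulerian,
                       material_derivative_lagrangian, solve_pressure_series)
from .synthetic import LVFlowParams, advect_particles, make_lv_flow
from .tracking import TrackerConfig, fit_tracks, track_sequence

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "default_config"]

STAGES = ("synth", "track", "fields", "pressure", "pod")


def default_config() -> dict:
    """The small end-to-end demo scene (coarse grid, few particles, short
    sequence) — a smoke-test scale, not the study conditions."""
    return {
        "rng_seed": 0,
        "output_dir": "lv4dflow_run",
        "log_level": "info",
        "synth": {
            "lv_flow": {},  # LVFlowParams overrides
            "grid": {"origin": [-33.0, -52.0, -30.0], "spacing": [2.75, 2.75, 2.75],
                     "shape": [24, 30, 22], "time_step": 0.0005, "n_steps": 32},
            "n_particles": 400,
        },
        "cameras": {"image_shape": [256, 256], "mm_per_px": 0.45,
                    "otf_sigma": 1.2, "peak_intensity": 1000.0},
        "render": {"noise_sigma": 0.0, "ppp_target": None},
        "track": {},       # TrackerConfig overrides
        "fields": {"binning": {"initial_subvolume": 72.0, "final_subvolume": 24.0,
                               "mm_per_voxel": 0.45},
                   "divfree": False, "lambda2": True},
        "pressure": {"xi": 1.0, "source": "eulerian"},
        "pod": {"subsample": 2, "subtract_mean": False},
    }


@dataclass
class PipelineConfig:
    raw: dict

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = default_config()
        _deep_update(cfg, user)
        return cls(cfg)

    @classmethod
    def from_dict(cls, d: dict | None = None) -> "PipelineConfig":
        cfg = default_config()
        _deep_update(cfg, d or {})
        return cls(cfg)

    @property
    def seed(self) -> int:
        return int(self.raw.get("rng_seed", 0))

    @property
    def out(self) -> Path:
        return Path(self.raw["output_dir"])

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _deep_update(base: dict, new: dict) -> None:
    for k, v in new.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: dict = dc_field(default_factory=dict)

    def write(self, path) -> None:
        """Atomic write (temp file + rename)."""
        payload = {"config_hash": self.config_hash, "version": self.version,
                   "seed": self.seed, "stages": self.stages}
        tmp = Path(str(path) + ".tmp")
        with open(tmp, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)
        os.replace(tmp, path)


def _grid_from_cfg(d: dict) -> GridSpec:
    return GridSpec(tuple(d["origin"]), tuple(d["spacing"]), tuple(d["shape"]),
                    float(d["time_step"]), int(d["n_steps"]))


def run_pipeline(config: PipelineConfig | dict | None = None,
                 stages: tuple = STAGES) -> RunManifest:
    """Execute the requested stages in dependency order.

    Each stage is skipped when its output file exists and carries the
    current config hash; a missing dependency output raises an error
    naming the stage to run first.
    """
    from . import __version__

    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(config)
    cfg = config.raw
    out = config.out
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    manifest = RunManifest(chash, __version__, config.seed)
    stages = tuple(s for s in STAGES if s in stages)

    paths = {
        "flow": out / "flow_truth.h5",
        "tracks_truth": out / "tracks_truth.h5",
        "images": out / "images",
        "tracks": out / "tracks.h5",
        "fields": out / "fields.h5",
        "pressure": out / "pressure.h5",
        "pod": out / "pod.h5",
    }

    def fresh(p: Path) -> bool:
        if not p.exists():
            return False
        try:
            import h5py
            with h5py.File(p, "r") as f:
                return f.attrs.get("config_hash") == chash
        except Exception:
            return False

    def record(name, t0, outputs, skipped=False):
        manifest.stages[name] = {
            "outputs": [str(p) for p in outputs],
            "wall_s": round(time.time() - t0, 3),
            "skipped": skipped,
        }

    def require(p: Path, producer: str):
        if not p.exists():
            raise FileNotFoundError(
                f"missing dependency output {p}; run the '{producer}' stage first")

    cam = default_camera_model(
        image_shape=tuple(cfg["cameras"]["image_shape"]),
        mm_per_px=cfg["cameras"]["mm_per_px"],
        otf_sigma=cfg["cameras"]["otf_sigma"],
        peak_intensity=cfg["cameras"]["peak_intensity"])

    if "synth" in stages:
        t0 = time.time()
        if fresh(paths["flow"]) and fresh(paths["tracks_truth"]):
            record("synth", t0, [paths["flow"], paths["tracks_truth"], paths["images"]],
                   skipped=True)
        else:
            params = LVFlowParams(**cfg["synth"]["lv_flow"], rng_seed=config.seed)
            grid = _grid_from_cfg(cfg["synth"]["grid"])
            flow = make_lv_flow(params, grid)
            truth = advect_particles(flow, int(cfg["synth"]["n_particles"]),
                                     rng_seed=config.seed)
            images = render_images(truth, cam, ppp_target=cfg["render"]["ppp_target"],
                                   noise_sigma=cfg["render"]["noise_sigma"],
                                   rng_seed=config.seed)
            lvio.write_flow_h5(flow, paths["flow"], seed=config.seed, config_hash=chash)
            lvio.write_tracks_h5(truth, paths["tracks_truth"], seed=config.seed,
                                 config_hash=chash)
            lvio.write_image_sequence(images, cam, paths["images"], seed=config.seed)
            record("synth", t0, [paths["flow"], paths["tracks_truth"], paths["images"]])

    if "track" in stages:
        t0 = time.time()
        if fresh(paths["tracks"]):
            record("track", t0, [paths["tracks"]], skipped=True)
        else:
            require(paths["images"] / "images.json", "synth")
            images, cam_r = lvio.read_image_sequence(paths["images"])
            tcfg = TrackerConfig(**cfg["track"])
            tracks = track_sequence(images, cam_r, tcfg)
            lvio.write_tracks_h5(tracks, paths["tracks"], seed=config.seed,
                                 config_hash=chash)
            record("track", t0, [paths["tracks"]])

    if "fields" in stages:
        t0 = time.time()
        if fresh(paths["fields"]):
            record("fields", t0, [paths["fields"]], skipped=True)
        else:
            require(paths["tracks"], "track")
            tracks = lvio.read_tracks_h5(paths["tracks"])
            if tracks.velocity is None:
                tracks = fit_tracks(tracks, TrackerConfig(**cfg["track"]))
            grid = _grid_from_cfg(cfg["synth"]["grid"])
            bcfg = BinningConfig(**cfg["fields"]["binning"])
            flow = bin_velocity(tracks, grid, bcfg)
            if cfg["fields"].get("divfree"):
                flow = divergence_free_filter(flow)
            scalars = None
            if cfg["fields"].get("lambda2"):
                scalars = {"lambda2": lambda2(flow).lambda2}
            lvio.write_flow_h5(flow, paths["fields"], seed=config.seed, config_hash=chash)
            if scalars is not None:
                lvio.write_flow_vtk(flow, out / "fields_t{step:04d}.vtk", scalars=scalars)
            record("fields", t0, [paths["fields"]])

    if "pressure" in stages:
        t0 = time.time()
        if fresh(paths["pressure"]):
            record("pressure", t0, [paths["pressure"]], skipped=True)
        else:
            require(paths["fields"], "fields")
            flow = lvio.read_flow_h5(paths["fields"])
            pcfg = PPEConfig(xi=float(cfg["pressure"].get("xi", 1.0)))
            if cfg["pressure"].get("source", "eulerian") == "lagrangian":
                require(paths["tracks"], "track")
                tracks = lvio.read_tracks_h5(paths["tracks"])
                md = material_derivative_lagrangian(
                    tracks, flow.grid, BinningConfig(**cfg["fields"]["binning"]))
            else:
                md = material_derivative_eulerian(flow)
            p4d = solve_pressure_series(flow, md, FluidProperties(), pcfg)
            lvio.write_pressure_h5(p4d, paths["pressure"], seed=config.seed,
                                   config_hash=chash)
            record("pressure", t0, [paths["pressure"]])

    if "pod" in stages:
        t0 = time.time()
        if fresh(paths["pod"]):
            record("pod", t0, [paths["pod"]], skipped=True)
        else:
            require(paths["fields"], "fields")
            flow = lvio.read_flow_h5(paths["fields"])
            S = interpolate_to_reference(flow,
                                         subsample_factor=int(cfg["pod"]["subsample"]),
                                         strict=False)  # binned masks are patchy
            r = snapshot_pod(S, subtract_mean=bool(cfg["pod"]["subtract_mean"]))
            lvio.write_pod_h5(r, paths["pod"], seed=config.seed, config_hash=chash)
            record("pod", t0, [paths["pod"]])

    manifest.write(out / "manifest.json")
    return manifest
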