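"""Stage orchestration with artifact manifest and resumability.

Stages: synth -> segment -> track -> simulate -> quantify, plus the
independent sensitivity stage.  Every stage writes its artifacts into the
configured output directory and registers them in ``manifest.json``
together with the config hash and seed; a stage whose upstream artifacts
are missing raises a dependency error naming the stage to run first.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import DependencyError, ParameterError
from .flow import SolverConfig
from .geometry import (DynamicClotDomain, compute_kinematics,
                       downsample_check, fit_spline_boundary)
from .marking import MaterialParams
from .mesh import build_vessel_mesh, write_vtk
from .quantify import (LoadingSeries, boundary_traction, build_phase_portrait,
                       calb_decay_curve, lhs_sensitivity, reynolds_number)
from .segment import ImageStack, boundaries_to_csv, segment_stack
from .simulate import run_coupled_simulation
from .synth import (IntensityModel, SyntheticScene, VesselSpec,
                    make_growth_schedule, write_scene_outputs)

STAGES = ("synth", "segment", "track", "simulate", "quantify", "sensitivity")

__all__ = ["run_pipeline", "STAGES"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


class _Manifest:
    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.path = out_dir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"artifacts": {}, "stages": {}}
        self.data["config_hash"] = config.content_hash()
        self.data["seed"] = config.seed

    def add(self, stage: str, name: str, path: Path, t0: float) -> None:
        self.data["artifacts"][name] = {
            "path": str(path), "sha256": _sha256(Path(path)), "stage": stage,
        }
        self.data["stages"][stage] = {"elapsed_s": round(_time.time() - t0, 3)}
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))

    def has(self, name: str) -> bool:
        art = self.data["artifacts"].get(name)
        return art is not None and Path(art["path"]).exists()


def _scene_from_config(config: PipelineConfig) -> SyntheticScene:
    sc = config.scene
    h, w = sc.image_shape
    center = sc.center
    if center is None:
        center = (w * sc.pixel_size / 2.0, h * sc.pixel_size / 2.0)
    schedule = make_growth_schedule(
        n_frames=sc.n_frames, mode=sc.mode, base_axes=sc.base_axes,
        growth_rate=sc.growth_rate, embolize_frame=sc.embolize_frame,
        embolize_fraction=sc.embolize_fraction, seed=config.seed,
        center=center, rotation=sc.rotation,
        saturation_frames=sc.saturation_frames, aspect_drift=sc.aspect_drift,
        core_fraction=sc.core_fraction)
    vessel = VesselSpec(length=config.mesh.length,
                        diameter=config.mesh.diameter,
                        injury_center_x=config.mesh.injury_center_x,
                        injury_half_width=config.mesh.injury_half_width,
                        injury_depth=config.mesh.injury_depth)
    return SyntheticScene(image_shape=sc.image_shape, schedule=schedule,
                          vessel=vessel, intensity=IntensityModel(),
                          pixel_size=sc.pixel_size,
                          frame_interval=sc.frame_interval, seed=config.seed)


def _load_stack(config: PipelineConfig, out: Path, channel: str) -> ImageStack:
    if channel in config.input_tiffs:
        return ImageStack.from_tiff(config.input_tiffs[channel])
    tif = out / f"{channel}.tif"
    if not tif.exists():
        raise DependencyError(
            f"no {channel} stack found; run the 'synth' stage first or "
            "provide input_tiffs", required_stage="synth")
    return ImageStack.from_tiff(tif)


def _track_channel(config: PipelineConfig, out: Path, channel: str):
    stack = _load_stack(config, out, channel)
    boundaries, failed = segment_stack(stack, config.segmentation)
    splines = [None if b is None else
               fit_spline_boundary(b, degree=config.geometry.degree,
                                   pixel_size=stack.pixel_size,
                                   time=k * stack.frame_interval,
                                   channel=channel)
               for k, b in enumerate(boundaries)]
    return stack, boundaries, failed, splines


def run_pipeline(config: PipelineConfig, stages=("synth", "segment", "track"),
                 ) -> dict:
    """Run the requested stages in dependency order; returns the manifest."""
    config.validate()
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ParameterError(f"unknown stages: {bad}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config)
    ordered = [s for s in STAGES if s in stages]

    for stage in ordered:
        t0 = _time.time()
        if stage == "synth":
            scene = _scene_from_config(config)
            paths = write_scene_outputs(scene, out)
            for name, p in paths.items():
                manifest.add("synth", f"synth/{name}", Path(p), t0)

        elif stage == "segment":
            stack = _load_stack(config, out, "CD41")
            boundaries, failed = segment_stack(stack, config.segmentation)
            path = boundaries_to_csv(boundaries, stack.pixel_size,
                                     out / "boundaries_CD41.csv")
            (out / "segment_failures.json").write_text(json.dumps(failed))
            manifest.add("segment", "segment/boundaries_CD41", path, t0)
            manifest.add("segment", "segment/failures",
                         out / "segment_failures.json", t0)

        elif stage == "track":
            if not manifest.has("segment/boundaries_CD41"):
                raise DependencyError("track requires segmentation output",
                                      required_stage="segment")
            stack, _b, _f, splines = _track_channel(config, out, "CD41")
            _cs, _cb, _cf, core_splines = _track_channel(config, out, "PSelectin")
            domain = DynamicClotDomain.from_splines(
                splines, core_splines, n_rays=config.geometry.n_rays,
                n_sub=config.geometry.n_sub,
                frame_interval=stack.frame_interval)
            kin = compute_kinematics(domain, config.geometry.smooth_window)
            kin.to_csv(out / "kinematics.csv")
            np.save(out / "boundaries_overall.npy",
                    np.array(domain.overall), allow_pickle=False)
            np.save(out / "boundaries_core.npy",
                    np.array(domain.core), allow_pickle=False)
            np.save(out / "frame_times.npy", domain.times)
            ds = (downsample_check(domain.overall)
                  if len(domain.overall) >= 6 else None)
            (out / "track_summary.json").write_text(json.dumps(
                {"downsample_mean_distance_um": ds,
                 "n_rays": config.geometry.n_rays,
                 "n_sub": config.geometry.n_sub}))
            manifest.add("track", "track/kinematics", out / "kinematics.csv", t0)
            manifest.add("track", "track/boundaries",
                         out / "boundaries_overall.npy", t0)
            manifest.add("track", "track/summary",
                         out / "track_summary.json", t0)

        elif stage == "simulate":
            if not manifest.has("track/boundaries"):
                raise DependencyError("simulate requires tracking output",
                                      required_stage="track")
            overall = list(np.load(out / "boundaries_overall.npy"))
            core = list(np.load(out / "boundaries_core.npy"))
            times = np.load(out / "frame_times.npy")
            domain = DynamicClotDomain(times=times, overall=overall, core=core,
                                       n_rays=config.geometry.n_rays,
                                       n_sub=config.geometry.n_sub)
            mesh = build_vessel_mesh(config.mesh.length, config.mesh.diameter,
                                     config.mesh.injury(), h=config.mesh.h)
            result = run_coupled_simulation(
                domain, mesh, config.solver,
                material_params=config.materials, L_ref=config.mesh.L_ref)
            vtk_dir = out / "fields"
            vtk_dir.mkdir(exist_ok=True)
            for k, t in enumerate(result.times):
                write_vtk(vtk_dir / f"state_{k:04d}.vtk", mesh, {
                    "velocity": result.flow[k].u,
                    "pressure": result.flow[k].p,
                    "concentration": result.transport[k].c,
                    "porosity": result.materials[k].phi,
                    "indicator": result.overall_indicator[k].values,
                })
            load = LoadingSeries(entries=[
                boundary_traction(result.flow[k], result.boundaries[k], mesh,
                                  mu=config.solver.mu)
                for k in range(len(result.times))])
            load.to_frame().to_csv(out / "loading.csv", index=False)
            decay = calb_decay_curve(result.transport, mesh, result.materials)
            decay.to_frame().to_csv(out / "decay_overall.csv", index=False)
            np.save(out / "sim_times.npy", np.array(result.times))
            manifest.add("simulate", "simulate/loading", out / "loading.csv", t0)
            manifest.add("simulate", "simulate/decay",
                         out / "decay_overall.csv", t0)
            manifest.add("simulate", "simulate/fields",
                         vtk_dir / "state_0000.vtk", t0)

        elif stage == "quantify":
            if not (out / "loading.csv").exists() or not manifest.has(
                    "simulate/loading"):
                raise DependencyError("quantify requires simulation output",
                                      required_stage="simulate")
            load_df = pd.read_csv(out / "loading.csv")
            kin_df = pd.read_csv(out / "kinematics.csv")
            sim_times = np.load(out / "sim_times.npy")
            # align kinematics to the simulation checkpoints
            area = np.interp(sim_times, kin_df["time_s"], kin_df["area_um2"])
            from .quantify import detect_embolization
            idx = detect_embolization(sim_times, area,
                                      load_df["total_mag"].to_numpy(),
                                      smooth_window=config.quant.smooth_window,
                                      min_consecutive=config.quant.min_consecutive,
                                      peak_gap=config.quant.peak_gap)
            re_val = reynolds_number(config.solver, config.mesh.diameter)
            summary = {"embolization_index": idx,
                       "reynolds_number": re_val,
                       "peak_total_force": float(load_df["total_mag"].max())}
            (out / "quantify_summary.json").write_text(
                json.dumps(summary, indent=1))
            pd.DataFrame({"time_s": sim_times, "area_um2": area,
                          "total_force": load_df["total_mag"]}).to_csv(
                out / "phase_portrait.csv", index=False)
            manifest.add("quantify", "quantify/summary",
                         out / "quantify_summary.json", t0)
            manifest.add("quantify", "quantify/phase_portrait",
                         out / "phase_portrait.csv", t0)

        elif stage == "sensitivity":
            stack = _load_stack(config, out, "CD41")
            # percentile window spans thresholds from the upper background
            # tail to the background/foreground rank gap of the smallest
            # clot in a typical stack (~10% fill -> ~88th percentile)
            ranges = {
                "binarize_percentile": (70.0, 88.0),
                "median_kernel": (3, 5),
                "gaussian_sigma": (0.5, 2.0),
                "canny_sigma": (0.8, 1.6),
            }
            res = lhs_sensitivity(ranges, config.quant.lhs_samples,
                                  config.seed, stack,
                                  base_params=config.segmentation)
            (out / "sensitivity.json").write_text(json.dumps(
                {"area_variability_pct": res["area_variability_pct"],
                 "aspect_variability_pct": res["aspect_variability_pct"],
                 "n_successful": res["n_successful"],
                 "failed_samples": res["failed_samples"],
                 "param_names": res["param_names"]}, indent=1))
            manifest.add("sensitivity", "sensitivity/summary",
                         out / "sensitivity.json", t0)

    return manifest.data
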