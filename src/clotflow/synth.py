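"""Ground-truth-labelled synthetic intravital stacks.

Emulates the statistical structure of laser-injury microscopy: a vessel
lumen containing a growing/deforming bright elliptical clot patch (a nested
core inside the overall region) rendered as tightly packed high-intensity
foreground pixels, sparse bright salt noise, and textured background.  The
exact ellipse schedule is retained as ground truth so every downstream stage
can be scored without real data.

Default intensity statistics: 8-bit grayscale, foreground ~ N(180, 30) and
background ~ N(30, 10) clipped to [0, 255], salt noise as isolated pixels at
255.  Default pixel size 0.5 µm/pixel and frame interval 0.55 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, RenderingError
from .segment import ImageStack

__all__ = [
    "EllipseSpec",
    "VesselSpec",
    "IntensityModel",
    "SyntheticScene",
    "GroundTruth",
    "make_growth_schedule",
    "render_stack",
    "write_scene_outputs",
]

CHANNELS = ("CD41", "PSelectin", "cAlb")


@dataclass
class EllipseSpec:
    """Ellipse in physical coordinates: center (x, y) µm, semi-axes µm, rad."""

    center: tuple[float, float]
    axes: tuple[float, float]
    rotation: float = 0.0

    def __post_init__(self):
        if self.axes[0] <= 0 or self.axes[1] <= 0:
            raise ParameterError("ellipse semi-axes must be > 0")

    @property
    def area(self) -> float:
        return np.pi * self.axes[0] * self.axes[1]

    @property
    def aspect_ratio(self) -> float:
        a, b = self.axes
        return max(a, b) / min(a, b)

    def boundary(self, n: int = 360) -> np.ndarray:
        """Polyline of the exact boundary, (n, 2) in µm, closed implicitly."""
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        a, b = self.axes
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        x = a * np.cos(t)
        y = b * np.sin(t)
        return np.column_stack(
            [self.center[0] + c * x - s * y, self.center[1] + s * x + c * y]
        )

    def mask(self, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
        """Rasterized interior on a pixel grid (pixel centers)."""
        h, w = shape
        ys = (np.arange(h) + 0.5) * pixel_size
        xs = (np.arange(w) + 0.5) * pixel_size
        X, Y = np.meshgrid(xs, ys)
        dx, dy = X - self.center[0], Y - self.center[1]
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        xr = c * dx + s * dy
        yr = -s * dx + c * dy
        a, b = self.axes
        return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


@dataclass
class VesselSpec:
    """Axis-aligned lumen with a localized wall indentation at the injury."""

    length: float = 100.0
    diameter: float = 50.0
    injury_center_x: float = 50.0
    injury_half_width: float = 10.0
    injury_depth: float = 4.0

    def __post_init__(self):
        if not 30.0 <= self.diameter <= 100.0:
            raise ParameterError("vessel diameter must lie in 30-100 um")


@dataclass
class IntensityModel:
    fg_mean: float = 180.0
    fg_std: float = 30.0
    bg_mean: float = 30.0
    bg_std: float = 10.0
    salt_density: float = 0.01

    def __post_init__(self):
        if not 0.0 <= self.salt_density < 0.1:
            raise ParameterError("salt-noise density must lie in [0, 0.1)")


@dataclass
class SyntheticScene:
    """Complete description of a synthetic imaging experiment."""

    image_shape: tuple[int, int]
    schedule: list[dict]
    vessel: VesselSpec = field(default_factory=VesselSpec)
    intensity: IntensityModel = field(default_factory=IntensityModel)
    pixel_size: float = 0.5
    frame_interval: float = 0.55
    seed: int = 0

    def __post_init__(self):
        if len(self.schedule) < 1:
            raise ParameterError("schedule must contain at least one frame")
        for fr in self.schedule:
            ov, co = fr["overall"], fr["core"]
            # core boundary must fall strictly inside the overall ellipse
            pts = co.boundary(64)
            dx = pts[:, 0] - ov.center[0]
            dy = pts[:, 1] - ov.center[1]
            c, s = np.cos(ov.rotation), np.sin(ov.rotation)
            xr = c * dx + s * dy
            yr = -s * dx + c * dy
            if np.any((xr / ov.axes[0]) ** 2 + (yr / ov.axes[1]) ** 2 >= 1.0):
                raise ParameterError("core ellipse must be a subset of the overall ellipse")

    @property
    def n_frames(self) -> int:
        return len(self.schedule)


@dataclass
class GroundTruth:
    """Exact per-frame boundaries (µm), areas (µm²) and aspect ratios."""

    boundaries: dict            # region -> list of (n, 2) arrays
    areas: dict                 # region -> (n_frames,) array
    aspect_ratios: dict         # region -> (n_frames,) array
    pixel_size: float
    frame_interval: float

    def to_csv(self, path: str | Path) -> Path:
        rows = []
        for region, blist in self.boundaries.items():
            for f, pts in enumerate(blist):
                for i, (x, y) in enumerate(pts):
                    rows.append((f, region, i, x, y))
        df = pd.DataFrame(rows, columns=["frame", "region", "vertex", "x_um", "y_um"])
        path = Path(path)
        df.to_csv(path, index=False)
        return path


def make_growth_schedule(
    n_frames: int,
    mode: str = "growth",
    base_axes: tuple[float, float] = (10.0, 8.0),
    growth_rate: float = 0.35,
    embolize_frame: int | None = None,
    embolize_fraction: float = 0.5,
    seed: int = 0,
    center: tuple[float, float] | None = None,
    rotation: float = 0.0,
    saturation_frames: float | None = None,
    aspect_drift: float = 0.0,
    core_fraction: float = 0.5,
    center_jitter: float = 0.0,
) -> list[dict]:
    """Per-frame ellipse parameters for overall and core clot regions.

    Axes grow at ``growth_rate`` µm/frame; with ``saturation_frames`` set,
    growth follows the saturating ramp ``T·(1 − exp(−t/T))`` so the area
    curve shows the characteristic early growth followed by a plateau.  In
    ``growth_then_embolize`` mode the overall area drops by
    ``embolize_fraction`` at ``embolize_frame`` (axes scale by its square
    root, replacing that frame's growth increment) and growth resumes from
    the reduced size.  ``aspect_drift`` slows the minor-axis growth to give
    mild shape change; ``center_jitter`` adds seeded Gaussian wobble (µm) to
    emulate imaging registration noise.
    """
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    if base_axes[0] <= 0 or base_axes[1] <= 0:
        raise ParameterError("base axes must be > 0")
    if mode not in ("growth", "growth_then_embolize"):
        raise ParameterError(f"unknown mode {mode!r}")
    if mode == "growth_then_embolize":
        if embolize_frame is None or not 1 <= embolize_frame < n_frames:
            raise ParameterError("embolize_frame must lie in [1, n_frames)")
        if not 0.0 < embolize_fraction <= 1.0:
            raise ParameterError("embolize_fraction must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    if center is None:
        center = (0.0, 0.0)

    def ramp(t: float) -> float:
        if saturation_frames:
            return saturation_frames * (1.0 - np.exp(-t / saturation_frames))
        return float(t)

    schedule = []
    a, b = float(base_axes[0]), float(base_axes[1])
    for t in range(n_frames):
        if t > 0:
            da = growth_rate * (ramp(t) - ramp(t - 1))
            if mode == "growth_then_embolize" and t == embolize_frame:
                scale = np.sqrt(embolize_fraction)
                a, b = a * scale, b * scale
            else:
                a += da
                b += da * (1.0 - aspect_drift)
        jitter = rng.normal(0.0, center_jitter, size=2) if center_jitter > 0 else (0.0, 0.0)
        ctr = (center[0] + jitter[0], center[1] + jitter[1])
        overall = EllipseSpec(center=ctr, axes=(a, b), rotation=rotation)
        core = EllipseSpec(center=ctr, axes=(a * core_fraction, b * core_fraction),
                           rotation=rotation)
        schedule.append({"overall": overall, "core": core})
    return schedule


def _region_masks(scene: SyntheticScene, frame: dict) -> dict:
    """Foreground pixel masks per channel for one schedule entry."""
    shape, ps = scene.image_shape, scene.pixel_size
    overall = frame["overall"].mask(shape, ps)
    core = frame["core"].mask(shape, ps)
    calb = overall.copy()
    v = scene.vessel
    if v.injury_depth > 0:
        # stagnation pool at the injury indentation (extended-shell analogue)
        h, w = shape
        ys = (np.arange(h) + 0.5) * ps
        xs = (np.arange(w) + 0.5) * ps
        X, Y = np.meshgrid(xs, ys)
        pool = ((X - v.injury_center_x) ** 2 + (Y - ys[-1] * 0.98) ** 2
                <= v.injury_half_width ** 2)
        calb |= pool
    return {"CD41": overall, "PSelectin": core, "cAlb": calb}


def render_stack(scene: SyntheticScene) -> tuple[dict, GroundTruth]:
    """Render all channels of a scene; deterministic for a fixed seed.

    Foreground pixels are drawn i.i.d. from the foreground distribution
    inside each region, background pixels outside, and salt noise (isolated
    255 pixels) is superposed outside the overall clot.
    """
    h, w = scene.image_shape
    ps = scene.pixel_size
    extent_x, extent_y = w * ps, h * ps
    for fr in scene.schedule:
        for region in ("overall", "core"):
            e = fr[region]
            r = max(e.axes)
            if (e.center[0] - r < 0 or e.center[0] + r > extent_x
                    or e.center[1] - r < 0 or e.center[1] + r > extent_y):
                raise RenderingError(
                    f"{region} ellipse (center={e.center}, axes={e.axes}) "
                    "exceeds the image bounds")

    rng = np.random.default_rng(scene.seed)
    im = scene.intensity
    stacks = {ch: np.empty((scene.n_frames, h, w), dtype=np.uint8)
              for ch in CHANNELS}
    gt_boundaries = {"overall": [], "core": []}
    gt_areas = {"overall": [], "core": []}
    gt_aspect = {"overall": [], "core": []}

    for f, fr in enumerate(scene.schedule):
        masks = _region_masks(scene, fr)
        clot_mask = masks["CD41"]
        for ch in CHANNELS:
            bg = rng.normal(im.bg_mean, im.bg_std, size=(h, w))
            fg = rng.normal(im.fg_mean, im.fg_std, size=(h, w))
            img = np.where(masks[ch], fg, bg)
            if im.salt_density > 0:
                salt = (rng.random((h, w)) < im.salt_density) & ~clot_mask
                img[salt] = 255.0
            stacks[ch][f] = np.clip(img, 0, 255).astype(np.uint8)
        gt_boundaries["overall"].append(fr["overall"].boundary())
        gt_boundaries["core"].append(fr["core"].boundary())
        gt_areas["overall"].append(fr["overall"].area)
        gt_areas["core"].append(fr["core"].area)
        gt_aspect["overall"].append(fr["overall"].aspect_ratio)
        gt_aspect["core"].append(fr["core"].aspect_ratio)

    image_stacks = {
        ch: ImageStack(data=stacks[ch], pixel_size=ps,
                       frame_interval=scene.frame_interval, channel=ch)
        for ch in CHANNELS
    }
    truth = GroundTruth(
        boundaries=gt_boundaries,
        areas={k: np.array(v) for k, v in gt_areas.items()},
        aspect_ratios={k: np.array(v) for k, v in gt_aspect.items()},
        pixel_size=ps,
        frame_interval=scene.frame_interval,
    )
    return image_stacks, truth


def write_scene_outputs(scene: SyntheticScene, out_dir: str | Path) -> dict:
    """Render a scene and write TIFFs, ground-truth CSV and JSON metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stacks, truth = render_stack(scene)
    paths = {}
    for ch, stack in stacks.items():
        paths[ch] = str(stack.to_tiff(out_dir / f"{ch}.tif"))
    paths["ground_truth"] = str(truth.to_csv(out_dir / "ground_truth.csv"))
    meta = {
        "pixel_size_um": scene.pixel_size,
        "frame_interval_s": scene.frame_interval,
        "n_frames": scene.n_frames,
        "image_shape": list(scene.image_shape),
        "seed": scene.seed,
    }
    meta_path = out_dir / "scene.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    paths["metadata"] = str(meta_path)
    return paths
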