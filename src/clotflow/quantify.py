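"""Post-processing: traction loading, solute decay, Reynolds number,
force-volume phase portraits, embolization detection and LHS sensitivity.

Traction on the clot is the closed-boundary integral of the fluid stress
σ = −p I + µ(∇u + ∇uᵀ) evaluated on the fixed mesh (linear-element
gradients of the containing triangle), with the pressure and viscous parts
reported separately.  Forces are per unit out-of-plane depth and reported
in nN per µm of depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .errors import GeometryError, ParameterError
from .flow import FlowState, SolverConfig, UM
from .geometry import (DynamicClotDomain, KinematicsSeries, moving_average,
                       polygon_area, polygon_aspect_ratio)
from .marking import MaterialFields
from .mesh import VesselMesh
from .segment import ImageStack, SegmentationParams, segment_stack
from .transport import TransportState

__all__ = [
    "TractionEntry",
    "LoadingSeries",
    "DecayCurve",
    "PhasePortrait",
    "boundary_traction",
    "calb_decay_curve",
    "reynolds_number",
    "build_phase_portrait",
    "lhs_sensitivity",
]

# N/m (2D force per unit depth) -> nN per µm of depth
FORCE_TO_NN_PER_UM = 1e9 * 1e-6


@dataclass
class TractionEntry:
    """Boundary-integrated loading at one instant (nN/µm depth)."""

    time: float
    pressure_force: np.ndarray
    shear_force: np.ndarray

    @property
    def total_force(self) -> np.ndarray:
        return self.pressure_force + self.shear_force

    @property
    def pressure_magnitude(self) -> float:
        return float(np.linalg.norm(self.pressure_force))

    @property
    def shear_magnitude(self) -> float:
        return float(np.linalg.norm(self.shear_force))

    @property
    def total_magnitude(self) -> float:
        return float(np.linalg.norm(self.total_force))


@dataclass
class LoadingSeries:
    """Time series of boundary traction loading."""

    entries: list = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.entries])

    @property
    def total_magnitude(self) -> np.ndarray:
        return np.array([e.total_magnitude for e in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            "pressure_fx": [e.pressure_force[0] for e in self.entries],
            "pressure_fy": [e.pressure_force[1] for e in self.entries],
            "shear_fx": [e.shear_force[0] for e in self.entries],
            "shear_fy": [e.shear_force[1] for e in self.entries],
            "pressure_mag": [e.pressure_magnitude for e in self.entries],
            "shear_mag": [e.shear_magnitude for e in self.entries],
            "total_mag": [e.total_magnitude for e in self.entries],
            "sum_of_mags": [e.pressure_magnitude + e.shear_magnitude
                            for e in self.entries],
        })


def boundary_traction(flow: FlowState, boundary: np.ndarray,
                      mesh: VesselMesh, mu: float = 4.0e-3) -> TractionEntry:
    """Integrate the fluid stress over a closed boundary polyline.

    ``boundary`` is an (n, 2) µm polyline (closed implicitly); quadrature
    points are its vertices, fields are interpolated from the containing
    triangles, and the outward normal follows from counter-clockwise
    orientation.  Units: µ in Pa·s; forces in nN per µm depth.
    """
    pts = np.asarray(boundary, dtype=float)
    if len(pts) < 3:
        raise GeometryError("boundary needs at least 3 points")
    # enforce counter-clockwise orientation so the normal points outward
    x, y = pts[:, 0], pts[:, 1]
    if 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) < 0:
        pts = pts[::-1]
    elems = mesh.find_elements(pts)
    if np.any(elems < 0):
        raise GeometryError("boundary extends outside the mesh")

    tri = mesh.triangles
    g = mesh.p1_gradients() / UM                 # 1/m
    # nodal fields in SI
    u_si = flow.u * UM
    p = flow.p
    # element-constant velocity gradient dui/dxj (M_used, 2, 2)
    grad_u = np.einsum("qkd,qki->qdi", g[elems], u_si[tri[elems]])
    grad_u = grad_u.transpose(0, 2, 1)           # [q, i, j] = dui/dxj
    # pressure at quadrature points via barycentric interpolation
    p_q = _interp_p1(mesh, elems, pts, p)

    strain = grad_u + grad_u.transpose(0, 2, 1)
    sigma_visc = mu * strain
    # segment between consecutive vertices; normal (dy, -dx) is outward for CCW
    nxt = np.roll(pts, -1, axis=0)
    seg = (nxt - pts) * UM
    ds = np.linalg.norm(seg, axis=1)
    normal = np.column_stack([seg[:, 1], -seg[:, 0]])
    with np.errstate(invalid="ignore", divide="ignore"):
        normal = normal / ds[:, None]
    normal[ds == 0] = 0.0
    # midpoint-rule traction per segment (average the two endpoint stresses)
    p_mid = 0.5 * (p_q + np.roll(p_q, -1))
    sv_mid = 0.5 * (sigma_visc + np.roll(sigma_visc, -1, axis=0))
    f_press = -(p_mid[:, None] * normal) * ds[:, None]
    f_visc = np.einsum("qij,qj->qi", sv_mid, normal) * ds[:, None]
    return TractionEntry(
        time=flow.time,
        pressure_force=f_press.sum(axis=0) * FORCE_TO_NN_PER_UM,
        shear_force=f_visc.sum(axis=0) * FORCE_TO_NN_PER_UM,
    )


def _interp_p1(mesh: VesselMesh, elems: np.ndarray, pts: np.ndarray,
               nodal: np.ndarray) -> np.ndarray:
    """Barycentric P1 interpolation of a nodal field at points."""
    tri = mesh.triangles[elems]
    v = mesh.nodes[tri]
    d = v[:, :2] - v[:, 2:3]
    r = pts - v[:, 2]
    det = d[:, 0, 0] * d[:, 1, 1] - d[:, 0, 1] * d[:, 1, 0]
    l1 = (d[:, 1, 1] * r[:, 0] - d[:, 1, 0] * r[:, 1]) / det
    l2 = (-d[:, 0, 1] * r[:, 0] + d[:, 0, 0] * r[:, 1]) / det
    lam = np.column_stack([l1, l2, 1.0 - l1 - l2])
    return np.einsum("qk,qk->q", lam, nodal[tri])


@dataclass
class DecayCurve:
    """Clot-averaged normalized solute concentration vs time since pulse."""

    time: np.ndarray
    value: np.ndarray
    region: str = "overall"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time,
                             f"c_{self.region}": self.value})


def calb_decay_curve(states: list[TransportState], mesh: VesselMesh,
                     materials: list[MaterialFields] | MaterialFields,
                     region: str = "overall") -> DecayCurve:
    """φ-weighted average concentration over a clot region, pulse-normalized.

    ``region`` is one of overall / core / shell; the membership and porosity
    of each checkpoint's material fields are used (a single MaterialFields
    is broadcast for a static clot).
    """
    if not states:
        raise ParameterError("empty state series")
    if not isinstance(materials, list):
        materials = [materials] * len(states)
    areas = mesh.lumped_node_areas()
    times, values = [], []
    for st, mat in zip(states, materials):
        member = {"overall": mat.member_overall, "core": mat.member_core,
                  "shell": mat.member_shell}[region]
        if not member.any():
            raise ParameterError(f"region {region!r} is empty")
        w = areas[member] * mat.phi[member]
        values.append(float(np.sum(w * st.c[member]) / np.sum(w)))
        times.append(st.time)
    values = np.array(values)
    t0 = values[0]
    if t0 <= 0:
        raise ParameterError("pulse-time average concentration is zero")
    return DecayCurve(time=np.array(times) - times[0], value=values / t0,
                      region=region)


def reynolds_number(config: SolverConfig, d_vessel: float) -> float:
    """Channel Reynolds number Re = ρ U_mean d / µ with U_mean = U_peak/2.

    The factor 1/2 is the mean-to-peak ratio of a parabolic profile in a 2D
    channel; ``d_vessel`` in µm.
    """
    if d_vessel <= 0:
        raise ParameterError("d_vessel must be > 0")
    u_mean = 0.5 * config.u_peak * UM            # m/s
    return float(config.rho * u_mean * d_vessel * UM / config.mu)


@dataclass
class PhasePortrait:
    """Force-volume phase trajectory with embolization annotation."""

    force: np.ndarray
    area: np.ndarray
    time: np.ndarray
    embolization_index: int | None
    bounding_box: tuple | None      # ((F_min, F_max), (A_min, A_max))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "total_force": self.force,
                             "area_um2": self.area})


def detect_embolization(times: np.ndarray, area: np.ndarray,
                        force: np.ndarray, smooth_window: int = 5,
                        min_consecutive: int = 3,
                        peak_gap: int = 5) -> int | None:
    """First sustained area drop following the running force maximum.

    A candidate is a run of >= ``min_consecutive`` consecutive checkpoints
    with negative smoothed d(area)/dt whose start lies within ``peak_gap``
    checkpoints of the running maximum of the force series.  The reported
    index is the steepest single-checkpoint raw area decrease inside the
    run's smoothing window, which pins a clean step reduction to its exact
    drop frame.  Monotone-growth series return None.
    """
    area = np.asarray(area, float)
    area_s = moving_average(area, smooth_window)
    rate = np.gradient(area_s, np.asarray(times, float))
    force = np.asarray(force, float)
    neg = rate < 0
    i = 0
    n = len(rate)
    while i < n:
        if not neg[i]:
            i += 1
            continue
        j = i
        while j < n and neg[j]:
            j += 1
        if j - i >= min_consecutive:
            peak_idx = int(np.argmax(force[:i + 1]))
            if i - peak_idx <= peak_gap:
                lo = max(i - smooth_window // 2, 1)
                hi = min(j + smooth_window // 2, n - 1)
                diffs = np.diff(area)[lo - 1:hi]
                return int(lo + np.argmin(diffs))
        i = j
    return None


def build_phase_portrait(kin: KinematicsSeries, load: LoadingSeries,
                         smooth_window: int = 5, min_consecutive: int = 3,
                         peak_gap: int = 5) -> PhasePortrait:
    """Pair the loading and kinematics series into a phase portrait.

    The embolization bounding box spans from clot initiation to the detected
    embolization point in both the force and area axes; a monotone-growing
    clot yields no embolization index and no box.
    """
    t_load = load.times
    if len(t_load) != len(kin.time) or not np.allclose(t_load, kin.time):
        raise ParameterError("kinematics and loading series must share a time grid")
    force = load.total_magnitude
    idx = detect_embolization(kin.time, kin.area, force,
                              smooth_window=smooth_window,
                              min_consecutive=min_consecutive,
                              peak_gap=peak_gap)
    box = None
    if idx is not None:
        box = ((float(force[:idx + 1].min()), float(force[:idx + 1].max())),
               (float(kin.area[:idx + 1].min()), float(kin.area[:idx + 1].max())))
    return PhasePortrait(force=force, area=kin.area, time=kin.time,
                         embolization_index=idx, bounding_box=box)


def lhs_sensitivity(param_ranges: dict, n_samples: int, seed: int,
                    stack: ImageStack,
                    base_params: SegmentationParams | None = None,
                    ) -> dict:
    """Latin-hypercube sweep of segmentation parameters on one stack.

    ``param_ranges`` maps a subset of {"binarize_percentile",
    "median_kernel", "gaussian_sigma", "canny_low", "canny_high",
    "canny_sigma"} to (low, high) intervals.  Each sample re-runs the full
    segmentation chain; the reported variabilities are the time-averaged
    coefficient of variation (%) of enclosed area and of the moment-based
    aspect ratio across samples.  Samples failing on more than 20% of the
    frames are excluded and reported.
    """
    if n_samples < 10:
        raise ParameterError("n_samples must be >= 10")
    names = list(param_ranges)
    lo = np.array([param_ranges[k][0] for k in names], dtype=float)
    hi = np.array([param_ranges[k][1] for k in names], dtype=float)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n_samples)
    matrix = lo + unit * (hi - lo)   # zero-width intervals stay constant

    base = base_params or SegmentationParams()
    ps = stack.pixel_size
    per_sample_area, per_sample_aspect = [], []
    failed_samples = []
    for s_idx, row in enumerate(matrix):
        kwargs = {
            "median_kernel": base.median_kernel,
            "gaussian_sigma": base.gaussian_sigma,
            "canny_sigma": base.canny_sigma,
            "canny_low": base.canny_low,
            "canny_high": base.canny_high,
            "binarize_rule": base.binarize_rule,
            "seed": base.seed,
            "connectivity": base.connectivity,
        }
        for name, val in zip(names, row):
            if name == "binarize_percentile":
                kwargs["binarize_rule"] = ("percentile", float(val))
            elif name == "median_kernel":
                k = int(round(val))
                kwargs["median_kernel"] = max(3, k + (1 - k % 2))
            else:
                kwargs[name] = float(val)
        params = SegmentationParams(**kwargs)
        try:
            boundaries, failed = segment_stack(stack, params)
        except Exception:
            failed_samples.append(s_idx)
            continue
        if len(failed) > 0.2 * stack.n_frames:
            failed_samples.append(s_idx)
            continue
        areas = np.full(stack.n_frames, np.nan)
        aspects = np.full(stack.n_frames, np.nan)
        for f, b in enumerate(boundaries):
            if b is None:
                continue
            xy = b.xy(ps)
            try:
                areas[f] = polygon_area(xy)
                aspects[f] = polygon_aspect_ratio(xy)
            except GeometryError:
                continue   # degenerate loop counts as a missing frame
        per_sample_area.append(areas)
        per_sample_aspect.append(aspects)

    if len(per_sample_area) < 2:
        raise ParameterError("too few successful samples for variability statistics")
    area_mat = np.array(per_sample_area)
    aspect_mat = np.array(per_sample_aspect)

    def _cv_percent(mat: np.ndarray) -> float:
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(mat, axis=0)
            std = np.nanstd(mat, axis=0)
            cv = 100.0 * std / mean
        return float(np.nanmean(cv))

    return {
        "area_variability_pct": _cv_percent(area_mat),
        "aspect_variability_pct": _cv_percent(aspect_mat),
        "n_successful": len(per_sample_area),
        "failed_samples": failed_samples,
        "sample_matrix": matrix,
        "param_names": names,
    }
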