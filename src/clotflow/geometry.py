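"""Smooth clot-boundary curves, temporal interpolation and kinematics.

Pixel boundary loops are fitted with closed (periodic) B-splines; boundaries
between imaging frames are reconstructed by matching points of equal polar
angle about each frame's centroid (ray tracing against the curve) and
linearly interpolating the matched points.  Kinematic series (area, aspect
ratio and their rates) are computed from dense polygonal samplings of the
splines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate as si
from scipy.spatial import cKDTree

from .errors import GeometryError, ParameterError
from .segment import PixelBoundary

__all__ = [
    "SplineBoundary",
    "DynamicClotDomain",
    "KinematicsSeries",
    "fit_spline_boundary",
    "resample_by_angle",
    "interpolate_in_time",
    "compute_kinematics",
    "downsample_check",
    "polygon_area",
    "polygon_centroid",
    "polygon_aspect_ratio",
]


def polygon_area(pts: np.ndarray) -> float:
    """Shoelace area of a closed polygon given by its vertices (µm²)."""
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_centroid(pts: np.ndarray) -> np.ndarray:
    """Area centroid of a closed polygon."""
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return pts.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def _polygon_second_moments(pts: np.ndarray) -> tuple[float, float, float]:
    """Second area moments (Ixx, Iyy, Ixy) about the centroid."""
    c = polygon_centroid(pts)
    x, y = pts[:, 0] - c[0], pts[:, 1] - c[1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    # ensure counter-clockwise orientation for the Green's-theorem formulas
    if cross.sum() < 0:
        x, y = x[::-1], y[::-1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
    ixx = (cross * (y ** 2 + y * yn + yn ** 2)).sum() / 12.0
    iyy = (cross * (x ** 2 + x * xn + xn ** 2)).sum() / 12.0
    ixy = (cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)).sum() / 24.0
    return ixx, iyy, ixy


def polygon_aspect_ratio(pts: np.ndarray) -> float:
    """Rotation-invariant aspect ratio sqrt(λ_max/λ_min) of the area moments.

    For an exact ellipse with semi-axes a ≥ b this equals a/b.
    """
    ixx, iyy, ixy = _polygon_second_moments(pts)
    tr = 0.5 * (ixx + iyy)
    det = np.sqrt(max(0.25 * (ixx - iyy) ** 2 + ixy ** 2, 0.0))
    lam_max, lam_min = tr + det, tr - det
    if lam_min <= 0:
        raise GeometryError("degenerate polygon: zero minor moment")
    return float(np.sqrt(lam_max / lam_min))


@dataclass
class SplineBoundary:
    """Closed B-spline clot boundary in physical (µm) coordinates."""

    tck: tuple
    degree: int
    time: float = 0.0
    channel: str = "CD41"

    @property
    def control_points(self) -> np.ndarray:
        return np.column_stack(self.tck[1])

    @property
    def knots(self) -> np.ndarray:
        return np.asarray(self.tck[0])

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        x, y = si.splev(np.asarray(u), self.tck)
        return np.column_stack([x, y])

    def dense(self, n: int = 2048) -> np.ndarray:
        """Uniform-parameter polygonal sampling of the curve."""
        return self.evaluate(np.linspace(0.0, 1.0, n, endpoint=False))

    def length(self, n: int = 4096) -> float:
        pts = self.dense(n)
        seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        return float(np.linalg.norm(seg, axis=1).sum())


def fit_spline_boundary(b: PixelBoundary | np.ndarray, degree: int = 3,
                        pixel_size: float = 1.0, time: float = 0.0,
                        channel: str = "CD41",
                        smoothing: float | None = None) -> SplineBoundary:
    """Fit a closed B-spline through an ordered pixel loop.

    The default smoothing budget adapts to the input's stair-step roughness
    (estimated from local second differences), so pixelated loops are ironed
    flat while already-smooth polylines are reproduced to a fraction of a
    pixel; in all cases the maximum deviation of the curve from the input
    polyline is kept below one pixel, reducing the budget if necessary.
    """
    if isinstance(b, PixelBoundary):
        pts = b.xy(pixel_size)
    else:
        pts = np.asarray(b, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ParameterError("boundary must be an (n, 2) array")
    # drop consecutive duplicates (splprep rejects zero-length chords)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
    pts = pts[keep]
    if np.linalg.norm(pts[0] - pts[-1]) < 1e-12:
        pts = pts[:-1]
    m = len(pts)
    if m < degree + 1:
        raise GeometryError(f"need at least degree+1={degree + 1} points, got {m}")

    closed = np.vstack([pts, pts[:1]])
    if smoothing is None:
        # roughness ~ half the distance of each vertex from its neighbours'
        # midpoint: ~0 for smooth polylines, ~0.25-0.5 px for stair-steps
        mid = 0.5 * (np.roll(pts, 1, axis=0) + np.roll(pts, -1, axis=0))
        rough = np.median(np.linalg.norm(pts - mid, axis=1)) / 2.0
        rough = min(max(rough, 0.02 * pixel_size), 0.5 * pixel_size)
        s = m * (2.0 * rough) ** 2
    else:
        s = smoothing
    for _ in range(4):
        tck, _u = si.splprep([closed[:, 0], closed[:, 1]], per=1,
                             k=min(degree, m - 1), s=s)
        sb = SplineBoundary(tck=tck, degree=min(degree, m - 1),
                            time=time, channel=channel)
        dev = _max_deviation(sb, pts)
        if dev <= pixel_size or s == 0:
            return sb
        s /= 4.0
        if s < 1e-10:
            s = 0
    return sb


def _max_deviation(sb: SplineBoundary, pts: np.ndarray, n: int = 4096) -> float:
    tree = cKDTree(sb.dense(n))
    d, _ = tree.query(pts)
    return float(d.max())


def _point_in_polygon(poly: np.ndarray, point: np.ndarray) -> bool:
    """Even-odd rule point-in-polygon test."""
    x, y = point
    px, py = poly[:, 0], poly[:, 1]
    pxn, pyn = np.roll(px, -1), np.roll(py, -1)
    crosses = ((py > y) != (pyn > y)) & (
        x < px + (y - py) * (pxn - px) / np.where(pyn != py, pyn - py, 1.0)
    )
    return bool(crosses.sum() % 2)


def resample_by_angle(sb: SplineBoundary | np.ndarray, n_rays: int = 180,
                      center: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Points on the curve at equally spaced polar angles about the center.

    Point ``i`` lies on the boundary at angle ``2πi/n_rays`` from the
    centroid (or supplied center); the nearest intersection along each ray
    is taken, which makes the construction single-valued on non-star-shaped
    curves as well.  Returns ``(points, center)``.
    """
    if n_rays < 8:
        raise ParameterError("n_rays must be >= 8")
    dense = sb.dense(max(2048, 16 * n_rays)) if isinstance(sb, SplineBoundary) \
        else np.asarray(sb, dtype=float)
    if center is None:
        center = polygon_centroid(dense)
    center = np.asarray(center, dtype=float)
    if not _point_in_polygon(dense, center):
        raise GeometryError("ray center lies outside the boundary curve")

    p0 = dense
    e = np.roll(dense, -1, axis=0) - dense          # segment vectors
    w = p0 - center                                  # segment start offsets
    angles = 2 * np.pi * np.arange(n_rays) / n_rays
    out = np.empty((n_rays, 2))
    for i, th in enumerate(angles):
        d = np.array([np.cos(th), np.sin(th)])
        det = e[:, 0] * d[1] - e[:, 1] * d[0]
        ok = np.abs(det) > 1e-14
        # solve  center + t·d = p0 + u·e  for t (along ray) and u (on segment)
        t = np.where(ok, (e[:, 0] * w[:, 1] - e[:, 1] * w[:, 0]) / np.where(ok, det, 1.0), -1.0)
        u = np.where(ok, (d[0] * w[:, 1] - d[1] * w[:, 0]) / np.where(ok, det, 1.0), -1.0)
        # tolerant segment bounds so rays through shared vertices still hit
        valid = ok & (t > 1e-12) & (u >= -1e-9) & (u <= 1.0 + 1e-9)
        if not valid.any():
            raise GeometryError(f"no boundary intersection along ray at angle {th:.3f}")
        out[i] = center + t[valid].min() * d
    return out, center


def interpolate_in_time(p0: np.ndarray, p1: np.ndarray,
                        n_sub: int) -> list[np.ndarray]:
    """Linear interpolation of matched angular samples between two frames.

    Both inputs must be resampled with the same number of rays about their
    own centroids; ``n_sub − 1`` intermediate boundaries are returned.
    """
    p0, p1 = np.asarray(p0, dtype=float), np.asarray(p1, dtype=float)
    if p0.shape != p1.shape:
        raise GeometryError("mismatched n_rays between the two boundaries")
    if n_sub < 1:
        raise ParameterError("n_sub must be >= 1")
    return [(1.0 - s) * p0 + s * p1
            for s in (np.arange(1, n_sub) / n_sub)]


@dataclass
class DynamicClotDomain:
    """Time-indexed angular-sampled boundaries for overall and core regions.

    ``overall[k]`` and ``core[k]`` are ``(n_rays, 2)`` µm arrays at
    ``times[k]``.  Failed (``None``) frames are filled by interpolating the
    matched samples between the nearest valid neighbours.
    """

    times: np.ndarray
    overall: list[np.ndarray]
    core: list[np.ndarray] | None = None
    n_rays: int = 180
    n_sub: int = 11

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        self.overall = _fill_missing(self.overall)
        if self.core is not None:
            self.core = _fill_missing(self.core)

    @classmethod
    def from_splines(cls, splines: list, core_splines: list | None = None,
                     times: np.ndarray | None = None, n_rays: int = 180,
                     n_sub: int = 11, frame_interval: float = 0.55,
                     ) -> "DynamicClotDomain":
        if times is None:
            times = np.arange(len(splines)) * frame_interval

        def _resample(lst):
            out = []
            for sb in lst:
                out.append(None if sb is None
                           else resample_by_angle(sb, n_rays=n_rays)[0])
            return out

        return cls(times=np.asarray(times), overall=_resample(splines),
                   core=None if core_splines is None else _resample(core_splines),
                   n_rays=n_rays, n_sub=n_sub)

    def boundary_at(self, t: float, region: str = "overall") -> np.ndarray:
        """Boundary at an arbitrary time by matched-point linear interpolation."""
        series = self.overall if region == "overall" else self.core
        if series is None:
            raise GeometryError(f"region {region!r} not tracked")
        t = float(np.clip(t, self.times[0], self.times[-1]))
        k = int(np.searchsorted(self.times, t, side="right") - 1)
        k = min(k, len(series) - 2) if len(series) > 1 else 0
        if len(series) == 1 or self.times[k + 1] == self.times[k]:
            return series[k]
        s = (t - self.times[k]) / (self.times[k + 1] - self.times[k])
        return (1.0 - s) * series[k] + s * series[k + 1]

    def substep_times(self) -> np.ndarray:
        dt = np.diff(self.times).mean() / self.n_sub
        return np.arange(self.times[0], self.times[-1] + 0.5 * dt, dt)


def _fill_missing(series: list) -> list:
    """Replace None entries by interpolating between neighbouring frames."""
    series = list(series)
    good = [i for i, s in enumerate(series) if s is not None]
    if not good:
        raise GeometryError("no valid frames in boundary series")
    for i, s in enumerate(series):
        if s is not None:
            continue
        prev = max((g for g in good if g < i), default=None)
        nxt = min((g for g in good if g > i), default=None)
        if prev is None:
            series[i] = series[nxt].copy()
        elif nxt is None:
            series[i] = series[prev].copy()
        else:
            w = (i - prev) / (nxt - prev)
            series[i] = (1.0 - w) * series[prev] + w * series[nxt]
    return [np.asarray(s, dtype=float) for s in series]


@dataclass
class KinematicsSeries:
    """Clot area/aspect time series and their smoothed rates of change."""

    time: np.ndarray
    area: np.ndarray
    aspect_ratio: np.ndarray
    darea_dt: np.ndarray
    daspect_dt: np.ndarray
    smooth_window: int = 5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time,
            "area_um2": self.area,
            "aspect_ratio": self.aspect_ratio,
            "darea_dt_um2_s": self.darea_dt,
            "daspect_dt_1_s": self.daspect_dt,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with reflected ends (length preserved)."""
    if window <= 1:
        return np.asarray(x, dtype=float)
    half = window // 2
    padded = np.concatenate([x[half:0:-1], x, x[-2:-2 - half:-1]])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def compute_kinematics(domain: DynamicClotDomain,
                       smooth_window: int = 5) -> KinematicsSeries:
    """Area (shoelace), moment-based aspect ratio, and smoothed rates.

    High-frequency imaging noise is suppressed by a centered moving average
    before central differencing.
    """
    if len(domain.overall) < 3:
        raise ParameterError("kinematics needs at least 3 time points")
    area = np.array([polygon_area(p) for p in domain.overall])
    if np.any(area <= 0):
        raise GeometryError("degenerate zero-area boundary in series")
    aspect = np.array([polygon_aspect_ratio(p) for p in domain.overall])
    a_s = moving_average(area, smooth_window)
    r_s = moving_average(aspect, smooth_window)
    darea = np.gradient(a_s, domain.times)
    daspect = np.gradient(r_s, domain.times)
    return KinematicsSeries(time=domain.times, area=area, aspect_ratio=aspect,
                            darea_dt=darea, daspect_dt=daspect,
                            smooth_window=smooth_window)


def downsample_check(boundaries: list[np.ndarray], keep_every: int = 3,
                     ) -> float:
    """Temporal-interpolation fidelity score (mean point distance, µm).

    Keeps every ``keep_every``-th frame, re-interpolates the removed frames
    from the kept neighbours via the matched angular samples, and reports the
    average over removed frames of the mean point-wise distance to the
    original boundaries.
    """
    boundaries = [np.asarray(b, dtype=float) for b in boundaries]
    n = len(boundaries)
    if n < 6:
        raise ParameterError("downsample check needs at least 6 frames")
    kept = list(range(0, n, keep_every))
    dists = []
    for k0, k1 in zip(kept[:-1], kept[1:]):
        intermediates = interpolate_in_time(boundaries[k0], boundaries[k1],
                                            n_sub=k1 - k0)
        for offset, interp in enumerate(intermediates, start=1):
            orig = boundaries[k0 + offset]
            dists.append(np.linalg.norm(interp - orig, axis=1).mean())
    if not dists:
        raise ParameterError("no removed frames to score; stack too short")
    return float(np.mean(dists))
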