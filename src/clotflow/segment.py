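"""Automated per-frame clot-boundary extraction from fluorescence stacks.

The workflow mirrors common intravital-microscopy practice: intensity
binarization, median + Gaussian denoising of the binary image, two-cluster
k-means labelling of the denoised grayscale frame, Canny edge detection on
the clot label, and selection of the largest connected edge component as the
single clot boundary loop.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import tifffile
from scipy.spatial import cKDTree
from skimage.feature import canny
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

from .errors import (
    DegenerateClusteringError,
    ParameterError,
    PipelineError,
    SegmentationFailure,
)

__all__ = [
    "ImageStack",
    "SegmentationParams",
    "PixelBoundary",
    "binarize_frame",
    "denoise_mask",
    "cluster_labels",
    "extract_boundary",
    "segment_frame",
    "segment_stack",
    "boundaries_to_csv",
]


@dataclass
class ImageStack:
    """Time-lapse single-channel intensity stack with physical metadata.

    ``data`` is indexed ``[frame, row, col]``; ``pixel_size`` is in µm/pixel
    and ``frame_interval`` in seconds.  Channels follow the fluorescent
    markers used in laser-injury experiments: CD41 (overall platelet mass),
    PSelectin (activated core), cAlb (caged plasma albumin).
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float = 0.55
    channel: str = "CD41"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError("stack data must be [n_frames, H, W]")
        if self.data.shape[0] < 1:
            raise ParameterError("stack needs at least one frame")
        if np.any(self.data < 0):
            raise ParameterError("intensities must be non-negative")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ParameterError("pixel_size and frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def to_tiff(self, path: str | Path) -> Path:
        """Write a multi-page TIFF plus a JSON metadata sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.data.astype(np.uint8))
        meta = {
            "pixel_size_um": self.pixel_size,
            "frame_interval_s": self.frame_interval,
            "channel": self.channel,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        return path

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_size: float | None = None,
                  frame_interval: float | None = None,
                  channel: str | None = None) -> "ImageStack":
        path = Path(path)
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        meta_path = path.with_suffix(".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            data=data,
            pixel_size=pixel_size or meta.get("pixel_size_um", 1.0),
            frame_interval=frame_interval or meta.get("frame_interval_s", 0.55),
            channel=channel or meta.get("channel", "CD41"),
        )


@dataclass
class SegmentationParams:
    """Tunable knobs of the segmentation chain.

    ``binarize_rule`` is either ``"otsu"`` or ``("percentile", q)``.  The
    k-means cluster count is fixed at two (clot vs background); it is kept as
    a field only so that configs are explicit about it.
    """

    binarize_rule: object = "otsu"
    median_kernel: int = 3
    gaussian_sigma: float = 1.0
    kmeans_k: int = 2
    kmeans_restarts: int = 10
    canny_sigma: float = 1.0
    canny_low: float | None = None
    canny_high: float | None = None
    connectivity: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.kmeans_k != 2:
            raise ParameterError("clot/background labelling requires exactly 2 clusters")
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ParameterError("median_kernel must be odd and >= 3")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")


@dataclass
class PixelBoundary:
    """Ordered closed loop of boundary pixels for one frame.

    ``pixels`` holds ``(row, col)`` coordinates ordered along the loop; the
    perimeter is the pixel count of the connected edge component the loop was
    traced from.
    """

    frame_index: int
    pixels: np.ndarray
    perimeter: int = field(default=0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ParameterError("pixels must be an (n, 2) array of (row, col)")
        if len(self.pixels) < 8:
            raise SegmentationFailure(
                f"boundary of frame {self.frame_index} has fewer than 8 pixels",
                frame_index=self.frame_index,
            )
        if not self.perimeter:
            self.perimeter = len(self.pixels)

    def xy(self, pixel_size: float = 1.0) -> np.ndarray:
        """Loop vertices as (x, y) in µm with x = col·s, y = row·s."""
        return np.column_stack(
            [self.pixels[:, 1] * pixel_size, self.pixels[:, 0] * pixel_size]
        )

    def enclosed_area(self, pixel_size: float = 1.0) -> float:
        """Shoelace area of the ordered loop polygon, in µm²."""
        p = self.xy(pixel_size)
        x, y = p[:, 0], p[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def binarize_frame(frame: np.ndarray, rule: object = "otsu") -> np.ndarray:
    """Threshold an intensity frame into a {0,1} foreground mask.

    A constant frame has no defined threshold: a warning is emitted and an
    all-background mask returned.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ParameterError("empty frame")
    if frame.min() == frame.max():
        warnings.warn("constant-intensity frame: threshold undefined, "
                      "returning all-background mask", stacklevel=2)
        return np.zeros(frame.shape, dtype=bool)
    if rule == "otsu":
        thr = threshold_otsu(frame)
        # threshold_otsu returns the upper edge of the background class;
        # use strictly-greater so two-level images split exactly.
        return frame > thr
    if isinstance(rule, (tuple, list)) and len(rule) == 2 and rule[0] == "percentile":
        q = float(rule[1])
        if not 0.0 < q < 100.0:
            raise ParameterError("percentile must be in (0, 100)")
        return frame >= np.percentile(frame, q)
    raise ParameterError(f"unknown binarization rule: {rule!r}")


def denoise_mask(mask: np.ndarray, median_kernel: int = 3,
                 gaussian_sigma: float = 1.0) -> np.ndarray:
    """Remove salt pixels and fill pinholes in a binary mask.

    A median filter removes sparsely spaced bright pixels, a Gaussian filter
    closes small interior holes, and the result is re-binarized at 0.5.
    Larger interior pores survive; only single-pixel scale defects are
    intended to be repaired here.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, [0, 1]).all():
        raise ParameterError("denoise_mask expects a binary input")
    if median_kernel % 2 == 0 or median_kernel < 3:
        raise ParameterError("median_kernel must be odd and >= 3")
    if median_kernel > min(mask.shape):
        raise ParameterError("median kernel larger than image")
    med = ndi.median_filter(mask.astype(np.uint8), size=median_kernel)
    if gaussian_sigma > 0:
        smooth = ndi.gaussian_filter(med.astype(float), gaussian_sigma)
    else:
        smooth = med.astype(float)
    return smooth >= 0.5


def cluster_labels(frame_processed: np.ndarray, seed: int = 0,
                   n_restarts: int = 10) -> np.ndarray:
    """Two-cluster k-means on pixel intensity; returns the clot (bright) label.

    Clustering runs on the unique intensity values weighted by their counts
    (exactly equivalent to clustering all pixels, but independent of image
    size), so the result is deterministic for a fixed seed.
    """
    frame = np.asarray(frame_processed, dtype=float)
    values, counts = np.unique(frame, return_counts=True)
    if len(values) < 2:
        raise DegenerateClusteringError("all pixels identical: clustering undefined")
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    km.fit(values.reshape(-1, 1), sample_weight=counts)
    centers = km.cluster_centers_.ravel()
    # 1D two-means partitions at the midpoint of the final centers
    cut = centers.mean()
    return frame > cut


_OFFSETS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_OFFSETS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def _prune_spurs(graph: nx.Graph) -> nx.Graph:
    """Iteratively strip degree-1 pixels (Canny spurs) off the edge ring."""
    g = graph.copy()
    while True:
        leaves = [node for node, deg in g.degree() if deg <= 1]
        if not leaves or g.number_of_nodes() - len(leaves) < 8:
            return g
        g.remove_nodes_from(leaves)


def _order_loop(coords: np.ndarray) -> np.ndarray:
    """Order edge pixels into a closed loop by nearest-neighbour walking.

    Gaps of up to 2 pixels are bridged; dead ends (residual spurs, double
    rings) are handled by backtracking.  If the walk still fails to close,
    ordering falls back to polar angle about the centroid, which is exact
    for star-shaped boundaries.
    """
    tree = cKDTree(coords)
    n = len(coords)
    visited = np.zeros(n, dtype=bool)
    start = int(np.lexsort((coords[:, 1], coords[:, 0]))[0])
    order = [start]
    visited[start] = True
    stack = [start]
    while stack:
        current = stack[-1]
        neigh = tree.query_ball_point(coords[current], r=2.9)
        cand = [i for i in neigh if not visited[i]]
        if cand:
            d = np.linalg.norm(coords[cand] - coords[current], axis=1)
            nxt = cand[int(np.argmin(d))]
            order.append(nxt)
            visited[nxt] = True
            stack.append(nxt)
        else:
            stack.pop()
    loop = coords[order]
    closes = np.linalg.norm(loop[0] - loop[-1]) <= 2.9
    if len(order) < 0.9 * n or not closes:
        center = coords.mean(axis=0)
        ang = np.arctan2(coords[:, 0] - center[0], coords[:, 1] - center[1])
        loop = coords[np.argsort(ang)]
    return loop


def extract_boundary(labels: np.ndarray, connectivity: int = 8,
                     canny_sigma: float = 1.0,
                     canny_low: float | None = None,
                     canny_high: float | None = None,
                     frame_index: int = 0) -> PixelBoundary:
    """Canny edges on the clot label, graph components, largest loop.

    Edge pixels become graph nodes; pixels adjacent under ``connectivity``
    are linked; connected components are enumerated and the one with the
    largest perimeter (pixel count; ties broken by larger hull area, then
    lowest centroid row) is returned as an ordered closed loop.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.sum() == 0:
        raise SegmentationFailure("empty clot label", frame_index=frame_index)
    h, w = labels.shape
    pad = 3
    padded = np.pad(labels, pad).astype(float)
    edges = canny(padded, sigma=canny_sigma,
                  low_threshold=canny_low, high_threshold=canny_high)
    coords = np.argwhere(edges) - pad
    if len(coords) == 0:
        raise SegmentationFailure("no edge pixels found", frame_index=frame_index)
    # clamp pad-region detections (foreground touching the frame border)
    coords[:, 0] = np.clip(coords[:, 0], 0, h - 1)
    coords[:, 1] = np.clip(coords[:, 1], 0, w - 1)
    coords = np.unique(coords, axis=0)

    offsets = _OFFSETS_8 if connectivity == 8 else _OFFSETS_4
    pixel_set = {tuple(c) for c in coords}
    graph = nx.Graph()
    graph.add_nodes_from(pixel_set)
    for r, c in pixel_set:
        for dr, dc in offsets:
            nb = (r + dr, c + dc)
            if nb in pixel_set:
                graph.add_edge((r, c), nb)

    def _hull_area(pts: np.ndarray) -> float:
        from scipy.spatial import ConvexHull, QhullError
        try:
            return float(ConvexHull(pts).volume)
        except (QhullError, ValueError):
            return 0.0

    best = None
    best_key = None
    for comp in nx.connected_components(graph):
        pts = np.array(sorted(comp))
        key = (len(pts), _hull_area(pts), -pts[:, 0].mean())
        if best_key is None or key > best_key:
            best, best_key = pts, key
    if best is None or len(best) < 8:
        raise SegmentationFailure("largest boundary component has < 8 pixels",
                                  frame_index=frame_index)
    ring = _prune_spurs(graph.subgraph(map(tuple, best)))
    loop = _order_loop(np.array(sorted(ring.nodes)))
    return PixelBoundary(frame_index=frame_index, pixels=loop,
                         perimeter=len(best))


def segment_frame(frame: np.ndarray, params: SegmentationParams,
                  frame_index: int = 0) -> PixelBoundary:
    """Run the full chain on a single frame and return its boundary loop."""
    mask = binarize_frame(frame, params.binarize_rule)
    if mask.sum() == 0:
        raise SegmentationFailure("binarization produced an empty mask",
                                  frame_index=frame_index)
    mask = denoise_mask(mask, params.median_kernel, params.gaussian_sigma)
    if mask.sum() == 0:
        raise SegmentationFailure("denoising removed all foreground",
                                  frame_index=frame_index)
    # cluster the denoised grayscale frame (background suppressed by the mask)
    processed = np.asarray(frame, dtype=float) * mask
    clot = cluster_labels(processed, seed=params.seed,
                          n_restarts=params.kmeans_restarts)
    return extract_boundary(clot, connectivity=params.connectivity,
                            canny_sigma=params.canny_sigma,
                            canny_low=params.canny_low,
                            canny_high=params.canny_high,
                            frame_index=frame_index)


def segment_stack(stack: ImageStack, params: SegmentationParams | None = None,
                  max_failure_fraction: float = 0.2,
                  ) -> tuple[list[PixelBoundary | None], list[int]]:
    """Segment every frame; flag unsegmentable frames.

    Returns ``(boundaries, failed_indices)`` where failed frames hold
    ``None`` (downstream geometry interpolates over them).  More than
    ``max_failure_fraction`` failed frames aborts the stage.
    """
    params = params or SegmentationParams()
    boundaries: list[PixelBoundary | None] = []
    failed: list[int] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(stack.n_frames):
            try:
                boundaries.append(segment_frame(stack.data[k], params, k))
            except (SegmentationFailure, DegenerateClusteringError):
                boundaries.append(None)
                failed.append(k)
    if len(failed) > max_failure_fraction * stack.n_frames:
        raise PipelineError(
            f"{len(failed)}/{stack.n_frames} frames failed segmentation "
            f"(> {max_failure_fraction:.0%})"
        )
    return boundaries, failed


def boundaries_to_csv(boundaries: list[PixelBoundary | None],
                      pixel_size: float, path: str | Path) -> Path:
    """Write boundaries as CSV rows (frame, vertex, x_um, y_um)."""
    rows = []
    for b in boundaries:
        if b is None:
            continue
        xy = b.xy(pixel_size)
        for i, (x, y) in enumerate(xy):
            rows.append((b.frame_index, i, x, y))
    df = pd.DataFrame(rows, columns=["frame", "vertex", "x_um", "y_um"])
    path = Path(path)
    df.to_csv(path, index=False)
    return path
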