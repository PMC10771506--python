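"""Fixed background vessel mesh for the fictitious-domain solver.

The lumen is a straight 2D channel (length × diameter, µm) with an optional
circular-arc indentation ("bite") in the bottom wall at the injury site,
where the laser perforation locally deforms the lumen.  The triangulation is
structured (alternating quad diagonals) and is generated once: all clot
motion is carried by nodal indicator fields, never by remeshing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError

__all__ = ["InjurySpec", "VesselMesh", "build_vessel_mesh", "write_vtk"]


@dataclass
class InjurySpec:
    """Circular-arc wall bite: center (µm along the axis), half-width, depth."""

    center_x: float
    half_width: float = 10.0
    depth: float = 4.0

    def wall_offset(self, x: np.ndarray) -> np.ndarray:
        """Bottom-wall y-offset (≤ 0): the lumen widens into the bite."""
        x = np.asarray(x, dtype=float)
        y = np.zeros_like(x)
        if self.depth <= 0:
            return y
        w, d = self.half_width, self.depth
        r = (w * w + d * d) / (2.0 * d)
        inside = np.abs(x - self.center_x) <= w
        dx = x[inside] - self.center_x
        y[inside] = (r - d) - np.sqrt(np.maximum(r * r - dx * dx, 0.0))
        return np.minimum(y, 0.0)


@dataclass
class VesselMesh:
    """Conforming triangulation of the vessel lumen with tagged boundaries."""

    nodes: np.ndarray                    # (N, 2) µm
    triangles: np.ndarray                # (M, 3) int
    boundary_edges: dict                 # tag -> (K, 2) int node pairs
    h: float
    length: float
    diameter: float
    injury: InjurySpec | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if np.any(self.tri_areas() <= 0):
            raise ParameterError("triangulation contains non-positive areas")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def tri_areas(self) -> np.ndarray:
        if "areas" not in self._cache:
            p = self.nodes[self.triangles]
            v1 = p[:, 1] - p[:, 0]
            v2 = p[:, 2] - p[:, 0]
            self._cache["areas"] = 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
        return self._cache["areas"]

    def p1_gradients(self) -> np.ndarray:
        """Constant gradients of the three P1 basis functions, (M, 3, 2)."""
        if "grads" not in self._cache:
            p = self.nodes[self.triangles]
            a2 = 2.0 * self.tri_areas()
            g = np.empty((self.n_triangles, 3, 2))
            for i in range(3):
                j, k = (i + 1) % 3, (i + 2) % 3
                g[:, i, 0] = (p[:, j, 1] - p[:, k, 1]) / a2
                g[:, i, 1] = (p[:, k, 0] - p[:, j, 0]) / a2
            self._cache["grads"] = g
        return self._cache["grads"]

    def element_sizes(self) -> np.ndarray:
        """Characteristic element length: longest edge of each triangle."""
        if "hsizes" not in self._cache:
            p = self.nodes[self.triangles]
            e = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 1], p[:, 0] - p[:, 2]])
            self._cache["hsizes"] = np.linalg.norm(e, axis=2).max(axis=0)
        return self._cache["hsizes"]

    def lumped_node_areas(self) -> np.ndarray:
        """Lumped (1/3-per-vertex) nodal area weights, (N,)."""
        if "lumped" not in self._cache:
            w = np.zeros(self.n_nodes)
            np.add.at(w, self.triangles.ravel(),
                      np.repeat(self.tri_areas() / 3.0, 3))
            self._cache["lumped"] = w
        return self._cache["lumped"]

    def boundary_nodes(self, tags=None) -> np.ndarray:
        tags = tags if tags is not None else list(self.boundary_edges)
        ids = [self.boundary_edges[t].ravel() for t in tags
               if len(self.boundary_edges[t])]
        if not ids:
            return np.array([], dtype=int)
        return np.unique(np.concatenate(ids))

    def trifinder(self):
        if "finder" not in self._cache:
            import matplotlib.tri as mtri
            tri = mtri.Triangulation(self.nodes[:, 0], self.nodes[:, 1],
                                     self.triangles)
            self._cache["tri"] = tri
            self._cache["finder"] = tri.get_trifinder()
        return self._cache["finder"]

    def find_elements(self, points: np.ndarray) -> np.ndarray:
        """Element index containing each point (-1 outside the mesh)."""
        points = np.asarray(points, dtype=float)
        return np.asarray(self.trifinder()(points[:, 0], points[:, 1]))

    def node_neighbors(self) -> list[np.ndarray]:
        """Adjacent-node index lists (mesh edge graph), one per node."""
        if "nbrs" not in self._cache:
            t = self.triangles
            pairs = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
            pairs = np.unique(np.sort(pairs, axis=1), axis=0)
            nbrs = [[] for _ in range(self.n_nodes)]
            for a, b in pairs:
                nbrs[a].append(b)
                nbrs[b].append(a)
            self._cache["nbrs"] = [np.array(v, dtype=int) for v in nbrs]
        return self._cache["nbrs"]

    def interior_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Interior edge node pairs (E, 2) and adjacent triangles (E, 2)."""
        if "iedges" not in self._cache:
            t = self.triangles
            pairs = np.sort(np.concatenate(
                [t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1)
            owner = np.tile(np.arange(self.n_triangles), 3)
            order = np.lexsort((pairs[:, 1], pairs[:, 0]))
            pairs, owner = pairs[order], owner[order]
            same = np.all(pairs[1:] == pairs[:-1], axis=1)
            idx = np.nonzero(same)[0]
            self._cache["iedges"] = (
                pairs[idx],
                np.column_stack([owner[idx], owner[idx + 1]]),
            )
        return self._cache["iedges"]


def build_vessel_mesh(length: float, diameter: float,
                      injury: InjurySpec | None = None,
                      h: float = 2.5) -> VesselMesh:
    """Structured triangulation of the (possibly indented) channel lumen.

    Node spacing is ≈ h in both directions, giving ≈ (L/h)(d/h) nodes and
    ≈ 2(L/h)(d/h) triangles; the injury bite is absorbed by vertically
    grading each node column between the indented bottom wall and the flat
    top wall.
    """
    if length <= 0 or diameter <= 0 or h <= 0:
        raise ParameterError("length, diameter and h must be > 0")
    if h > diameter / 10.0:
        raise ParameterError("element size h must be <= diameter/10")
    if not 30.0 <= diameter <= 100.0:
        warnings.warn("vessel diameter outside the typical 30-100 um range",
                      stacklevel=2)
    nx = int(round(length / h))
    ny = int(round(diameter / h))
    xs = np.linspace(0.0, length, nx + 1)
    ybot = injury.wall_offset(xs) if injury is not None else np.zeros_like(xs)

    nodes = np.empty(((nx + 1) * (ny + 1), 2))
    for i, x in enumerate(xs):
        s = np.linspace(0.0, 1.0, ny + 1)
        ys = ybot[i] + s * (diameter - ybot[i])
        nodes[i * (ny + 1):(i + 1) * (ny + 1), 0] = x
        nodes[i * (ny + 1):(i + 1) * (ny + 1), 1] = ys

    def nid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                tris.append([a, b, c])
                tris.append([a, c, d])
            else:
                tris.append([a, b, d])
                tris.append([b, c, d])
    triangles = np.array(tris, dtype=int)

    inlet = np.array([[nid(0, j), nid(0, j + 1)] for j in range(ny)])
    outlet = np.array([[nid(nx, j), nid(nx, j + 1)] for j in range(ny)])
    wall = np.array(
        [[nid(i, 0), nid(i + 1, 0)] for i in range(nx)]
        + [[nid(i, ny), nid(i + 1, ny)] for i in range(nx)]
    )
    return VesselMesh(nodes=nodes, triangles=triangles,
                      boundary_edges={"inlet": inlet, "outlet": outlet,
                                      "wall": wall},
                      h=h, length=length, diameter=diameter, injury=injury)


def write_vtk(path: str | Path, mesh: VesselMesh,
              point_data: dict | None = None) -> Path:
    """Write the mesh and nodal fields as a legacy ASCII VTK unstructured grid."""
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "clotflow vessel mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [f"{x:.8g} {y:.8g} 0" for x, y in mesh.nodes]
    lines.append(f"CELLS {mesh.n_triangles} {4 * mesh.n_triangles}")
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.triangles]
    lines.append(f"CELL_TYPES {mesh.n_triangles}")
    lines += ["5"] * mesh.n_triangles
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.8g}" for v in arr]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [f"{v[0]:.8g} {v[1]:.8g} 0" for v in arr]
    path.write_text("\n".join(lines) + "\n")
    return path
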