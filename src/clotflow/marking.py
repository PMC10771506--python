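"""Clot-domain marking on the fixed mesh and porous material fields.

A moving clot boundary is transferred onto the background triangulation by
the Laplace point-set method: solve ∇²I = 0 with I = 1 clamped on all nodes
of elements containing boundary points and I = 0 on the outer domain
boundary, then mark nodes with I ≥ 1 − ε as clot interior (the maximum
principle fills the region enclosed by the I = 1 ring).  Porosity,
diffusivity and Kozeny-Carman permeability fields are then assigned by
region with core values taking precedence over shell over free lumen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import GeometryError, ParameterError
from .geometry import SplineBoundary
from .mesh import VesselMesh

__all__ = [
    "IndicatorField",
    "MaterialParams",
    "MaterialFields",
    "WT_PARAMS",
    "DIYF_PARAMS",
    "assemble_stiffness",
    "mark_indicator",
    "kozeny_carman",
    "assemble_material_fields",
]


@dataclass
class IndicatorField:
    """Nodal Laplace indicator and thresholded clot membership."""

    values: np.ndarray            # I in [0, 1]
    membership: np.ndarray        # bool, I >= 1 - eps
    eps: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.membership = np.asarray(self.membership, dtype=bool)

    @property
    def n_members(self) -> int:
        return int(self.membership.sum())


@dataclass
class MaterialParams:
    """Region-wise porosity and effective diffusivity (µm²/s)."""

    phi_c: float
    phi_s: float
    D_f: float
    D_c: float
    D_s: float

    def __post_init__(self):
        for phi in (self.phi_c, self.phi_s):
            if not 0.0 < phi <= 1.0:
                raise ParameterError("porosities must lie in (0, 1]")
        if not self.D_c <= self.D_s <= self.D_f:
            raise ParameterError("diffusivities must satisfy D_c <= D_s <= D_f")


# Literature-based defaults for the two mouse strains: hindered core/shell
# diffusion of cAlb relative to its free-plasma value of 60 um^2/s.
WT_PARAMS = MaterialParams(phi_c=0.2, phi_s=0.3, D_f=60.0, D_c=0.4, D_s=0.8)
DIYF_PARAMS = MaterialParams(phi_c=0.2, phi_s=0.4, D_f=60.0, D_c=0.5, D_s=1.0)


@dataclass
class MaterialFields:
    """Nodal porosity, diffusivity and dimensional permeability fields.

    ``K_um2`` is the Kozeny-Carman permeability scaled by L_ref² (µm²); it
    is ``inf`` outside the clot, where the Brinkman drag is disabled.
    """

    phi: np.ndarray
    D: np.ndarray
    K_um2: np.ndarray
    member_overall: np.ndarray
    member_core: np.ndarray
    member_shell: np.ndarray
    params: MaterialParams
    L_ref: float


def assemble_stiffness(mesh: VesselMesh,
                       coeff: np.ndarray | float = 1.0) -> sp.csr_matrix:
    """P1 stiffness matrix ∫ c ∇φ_i · ∇φ_j with element-wise coefficient."""
    g = mesh.p1_gradients()
    areas = mesh.tri_areas()
    c = np.broadcast_to(np.asarray(coeff, dtype=float), areas.shape)
    tri = mesh.triangles
    rows, cols, data = [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(tri[:, i])
            cols.append(tri[:, j])
            data.append(c * areas * np.einsum("md,md->m", g[:, i], g[:, j]))
    K = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(mesh.n_nodes, mesh.n_nodes),
    )
    return K.tocsr()


def mark_indicator(mesh: VesselMesh,
                   boundary: SplineBoundary | np.ndarray,
                   eps: float = 1e-2,
                   n_boundary_samples: int = 720) -> IndicatorField:
    """Laplace point-set marking of the clot interior on the fixed mesh.

    Dirichlet data: I = 1 on every node of an element containing a boundary
    sample point, I = 0 on the outer domain boundary (domain-boundary nodes
    win when the clot hugs the wall).  One symmetric sparse solve per call.
    """
    if not 0.0 < eps < 1.0:
        raise ParameterError("eps must lie in (0, 1)")
    pts = boundary.dense(n_boundary_samples) if isinstance(boundary, SplineBoundary) \
        else np.asarray(boundary, dtype=float)
    elems = mesh.find_elements(pts)
    hit = elems[elems >= 0]
    if len(hit) == 0:
        raise GeometryError(
            "no mesh element contains any clot-boundary point; refine the "
            "mesh or check boundary placement")

    one_nodes = np.unique(mesh.triangles[np.unique(hit)].ravel())
    outside = pts[elems < 0]
    if len(outside):
        # a clot bulging through the wall (injury site) is closed along the
        # wall: snap escaped boundary samples to their nearest mesh nodes so
        # the wall-adjacent elements are seeded and no spurious free channel
        # opens beneath the clot
        from scipy.spatial import cKDTree
        _, near = cKDTree(mesh.nodes).query(outside)
        nbrs_all = mesh.node_neighbors()
        extra = np.unique(np.concatenate(
            [np.atleast_1d(near)] + [nbrs_all[k] for k in np.unique(near)]))
        one_nodes = np.union1d(one_nodes, extra)
    zero_nodes = mesh.boundary_nodes()
    one_nodes = np.setdiff1d(one_nodes, zero_nodes, assume_unique=False)

    n = mesh.n_nodes
    values = np.zeros(n)
    values[one_nodes] = 1.0
    fixed = np.zeros(n, dtype=bool)
    fixed[one_nodes] = True
    fixed[zero_nodes] = True
    free = ~fixed

    K = assemble_stiffness(mesh)
    if free.any():
        rhs = -K[np.ix_(free, fixed)] @ values[fixed]
        values[free] = spla.spsolve(K[np.ix_(free, free)].tocsc(), rhs)
    membership = values >= 1.0 - eps

    # The seeded ring spans one element layer on either side of the true
    # boundary; erode seeded members that touch a non-member neighbour so
    # the marked set tracks the enclosed interior without outward bias.
    seeded = np.zeros(n, dtype=bool)
    seeded[one_nodes] = True
    is_zero = np.zeros(n, dtype=bool)
    is_zero[zero_nodes] = True
    nbrs = mesh.node_neighbors()
    erode = np.zeros(n, dtype=bool)
    for node in np.nonzero(seeded & membership)[0]:
        nb = nbrs[node]
        nb = nb[~is_zero[nb]]   # I=0 wall nodes carry no inside/outside vote
        if len(nb) and not membership[nb].all():
            erode[node] = True
    eroded = membership & ~erode
    if eroded.any():
        membership = eroded
    return IndicatorField(values=values, membership=membership, eps=eps)


def kozeny_carman(phi_f):
    """Dimensionless Kozeny-Carman permeability  K = φ³ / (150 (1−φ)²).

    Defined for porosities in [0, 1); a fully fluid region (φ = 1) must
    bypass the Brinkman drag rather than evaluate this relation.
    """
    phi = np.asarray(phi_f, dtype=float)
    if np.any(phi < 0.0) or np.any(phi >= 1.0):
        raise ParameterError("Kozeny-Carman requires porosity in [0, 1)")
    out = phi ** 3 / (150.0 * (1.0 - phi) ** 2)
    return float(out) if np.isscalar(phi_f) else out


def assemble_material_fields(overall: IndicatorField,
                             core: IndicatorField | None,
                             params: MaterialParams = WT_PARAMS,
                             L_ref: float = 3.0) -> MaterialFields:
    """Nodal φ, D, K fields from the overall and core indicator fields.

    The shell is overall-membership minus core-membership; core values
    override shell where the regions overlap, and the free lumen keeps
    φ = 1, D = D_f and no Brinkman drag (K = inf).  The dimensionless
    Kozeny-Carman permeability is dimensionalized by L_ref² (µm²), with
    L_ref defaulting to the platelet length scale of 3 µm.
    """
    if L_ref <= 0:
        raise ParameterError("L_ref must be > 0")
    member_overall = overall.membership.copy()
    if core is not None:
        member_core = core.membership & member_overall
    else:
        member_core = np.zeros_like(member_overall)
    member_shell = member_overall & ~member_core

    n = len(member_overall)
    phi = np.ones(n)
    D = np.full(n, params.D_f)
    phi[member_shell] = params.phi_s
    D[member_shell] = params.D_s
    phi[member_core] = params.phi_c
    D[member_core] = params.D_c

    K = np.full(n, np.inf)
    K[member_overall] = kozeny_carman(phi[member_overall]) * L_ref ** 2
    return MaterialFields(phi=phi, D=D, K_um2=K,
                          member_overall=member_overall,
                          member_core=member_core,
                          member_shell=member_shell,
                          params=params, L_ref=L_ref)
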