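"""Stabilized advection-diffusion transport of uncaged solute (cAlb).

Solves  φ ∂c/∂t + u·∇c = ∇·(φ D ∇c)  on the fixed mesh with nodal porosity
φ and effective diffusivity D from the material fields: streamline-upwind
(SUPG) stabilization plus a continuous-interior-penalty term on
inter-element gradient jumps, scaled by the local advective speed so the
scheme reduces to plain Galerkin diffusion (exactly conservative) in a
closed quiescent box.  Backward Euler in time; inlet c = 0, zero diffusive
flux on walls, advective outflow at the outlet.

Concentrations are normalized to the uncaging pulse (c = 1 inside the clot
at pulse time); geometry in µm, velocities in µm/s, diffusivity in µm²/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ParameterError, SolverError
from .flow import FlowState, SolverConfig, _scatter
from .marking import IndicatorField, MaterialFields
from .mesh import VesselMesh

__all__ = ["TransportState", "solve_transport_step", "init_uncaging",
           "total_mass"]

OVERSHOOT_BOUND = 0.05


@dataclass
class TransportState:
    """Nodal normalized concentration at one time level."""

    c: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=float)


def init_uncaging(mesh: VesselMesh, overall: IndicatorField,
                  time: float = 0.0) -> TransportState:
    """Uncaging pulse: c = 1 on clot-member nodes, 0 elsewhere.

    Called once per light pulse; repeated pulses simply re-initialize.
    """
    if overall.n_members == 0:
        raise ParameterError("cannot uncage: clot membership is empty")
    c = overall.membership.astype(float)
    return TransportState(c=c, time=time)


def _cip_matrix(mesh: VesselMesh, u_nodal: np.ndarray,
                coeff: float) -> sp.csr_matrix:
    """Gradient-jump penalty  γ Σ_e |u|_e h_e² L_e [∂c/∂n][∂v/∂n]."""
    edges, owners = mesh.interior_edges()
    if len(edges) == 0 or coeff == 0.0:
        return sp.csr_matrix((mesh.n_nodes, mesh.n_nodes))
    g = mesh.p1_gradients()
    tri = mesh.triangles
    p0, p1 = mesh.nodes[edges[:, 0]], mesh.nodes[edges[:, 1]]
    tang = p1 - p0
    lengths = np.linalg.norm(tang, axis=1)
    normals = np.column_stack([tang[:, 1], -tang[:, 0]]) / lengths[:, None]
    u_edge = 0.5 * (np.linalg.norm(u_nodal[edges[:, 0]], axis=1)
                    + np.linalg.norm(u_nodal[edges[:, 1]], axis=1))
    h_edge = lengths

    rows, cols, data = [], [], []
    for e in range(len(edges)):
        tA, tB = owners[e]
        n_hat = normals[e]
        nodes = []
        jumps = []
        for t_idx, sign in ((tA, 1.0), (tB, -1.0)):
            for loc in range(3):
                nodes.append(tri[t_idx, loc])
                jumps.append(sign * float(g[t_idx, loc] @ n_hat))
        nodes = np.array(nodes)
        jumps = np.array(jumps)
        w = coeff * u_edge[e] * h_edge[e] ** 2 * lengths[e]
        block = w * np.outer(jumps, jumps)
        rows.append(np.repeat(nodes, 6))
        cols.append(np.tile(nodes, 6))
        data.append(block.ravel())
    return sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(mesh.n_nodes, mesh.n_nodes),
    ).tocsr()


def solve_transport_step(mesh: VesselMesh, materials: MaterialFields,
                         flow: FlowState, c_prev: TransportState | np.ndarray,
                         config: SolverConfig,
                         closed: bool = False) -> TransportState:
    """One backward-Euler step of the stabilized scalar transport problem.

    With ``closed=True`` no inlet Dirichlet value is imposed and the problem
    becomes a sealed box (used for conservation checks); otherwise fresh
    plasma (c = 0) enters at the inlet and the outlet is purely advective.
    """
    n = mesh.n_nodes
    if isinstance(c_prev, TransportState):
        t_prev, c_prev = c_prev.time, c_prev.c
    else:
        t_prev = flow.time - config.dt
    c_prev = np.asarray(c_prev, dtype=float)
    tri = mesh.triangles
    area = mesh.tri_areas()
    g = mesh.p1_gradients()
    hsz = mesh.element_sizes()
    dt = config.dt

    u = flow.u                       # µm/s, consistent µm-s unit system
    u_e = u[tri].mean(axis=1)
    u_mag = np.linalg.norm(u_e, axis=1)
    phi = materials.phi
    phi_e = phi[tri].mean(axis=1)
    phiD_e = (phi * materials.D)[tri].mean(axis=1)

    tau = 1.0 / np.sqrt((2.0 * phi_e / dt) ** 2 + (2.0 * u_mag / hsz) ** 2
                        + (4.0 * phiD_e / hsz ** 2) ** 2)

    third = area / 3.0
    udg = np.einsum("md,mid->mi", u_e, g)          # u·∇φ_i
    gdot = np.einsum("mid,mjd->mij", g, g)

    # Galerkin: lumped φ-weighted storage + advection + φD diffusion
    phi_lumped = phi[tri] * third[:, None]
    A_gal = (phi_lumped[:, :, None] / dt * np.eye(3)[None]
             + third[:, None, None] * udg[:, None, :]
             + phiD_e[:, None, None] * area[:, None, None] * gdot)
    # SUPG: τ (u·∇v) [ φ c/Δt + u·∇c ]
    coef = tau * area
    A_supg = (coef[:, None, None] * udg[:, :, None]
              * (udg[:, None, :] + (phi_e / dt)[:, None, None] / 3.0))
    A = _scatter(mesh, A_gal + A_supg)
    A = A + _cip_matrix(mesh, u, config.cip_coeff)

    b = np.zeros(n)
    np.add.at(b, tri.ravel(),
              (phi_lumped / dt * c_prev[tri]).ravel())
    cn_e = c_prev[tri].mean(axis=1)
    np.add.at(b, tri.ravel(),
              (coef[:, None] * udg * (phi_e * cn_e / dt)[:, None]).ravel())

    if not closed:
        inlet_nodes = mesh.boundary_nodes(["inlet"])
        A = A.tolil()
        for node in inlet_nodes:
            A.rows[node] = [node]
            A.data[node] = [1.0]
            b[node] = 0.0
        A = A.tocsr()

    c_new = spla.spsolve(A.tocsc(), b)
    if not np.all(np.isfinite(c_new)):
        raise SolverError("transport solve produced non-finite values")
    over = max(c_new.max() - 1.0, -c_new.min(), 0.0)
    if over > OVERSHOOT_BOUND:
        pe = (u_mag * hsz / np.maximum(2.0 * phiD_e, 1e-30)).max()
        warnings.warn(
            f"concentration overshoot {over:.3f} exceeds bound "
            f"{OVERSHOOT_BOUND}; max cell Peclet {pe:.1f}", stacklevel=2)
    return TransportState(c=c_new, time=t_prev + dt)


def total_mass(mesh: VesselMesh, materials: MaterialFields,
               state: TransportState | np.ndarray) -> float:
    """φ-weighted solute content  Σ_i A_i φ_i c_i  (lumped quadrature)."""
    c = state.c if isinstance(state, TransportState) else np.asarray(state)
    return float(np.sum(mesh.lumped_node_areas() * materials.phi * c))
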