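"""Stabilized finite-element Brinkman-Navier-Stokes flow on the fixed mesh.

Momentum (divided by density) and mass balance,

    (u − uⁿ)/Δt + a·∇u = −∇p̂ + ν∇²u − (σ/ρ) u·χ_clot,    ∇·u = 0,

with p̂ = p/ρ, ν = µ/ρ and Brinkman drag σ = µ/K inside the clot, are
discretized with equal-order linear velocity-pressure triangles, SUPG/PSPG
stabilization (τ from the inverse-estimate formula with transient,
advective, viscous and Brinkman-reaction contributions) plus a grad-div
term, integrated with backward Euler, and linearized by Picard iteration on
the advective velocity.  Boundary conditions: parabolic inlet, no-slip
walls, traction-free outlet.

Geometry enters in µm and velocities in µm/s; the solve itself runs in SI
units and results are converted back (pressure is reported in Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ParameterError, SolverError
from .marking import MaterialFields
from .mesh import VesselMesh

__all__ = ["SolverConfig", "FlowState", "solve_flow_step", "inlet_profile"]

UM = 1e-6  # µm -> m


@dataclass
class SolverConfig:
    """Physical and numerical parameters of the flow/transport solver.

    Defaults follow murine cremaster arteriole conditions: blood treated as
    Newtonian with µ = 4.0 cP and ρ = 1.06 g/cc, and a steady parabolic
    inflow with measured centerline velocity 1300 µm/s.  ``dt`` is the
    sub-step interval (frame interval / n_sub).  ``pulsatile`` optionally
    modulates the inflow sinusoidally; it is off by default because the
    imaging provides a single averaged centerline velocity.
    """

    rho: float = 1060.0          # kg/m^3
    mu: float = 4.0e-3           # Pa s
    u_peak: float = 1300.0       # µm/s centerline inflow
    dt: float = 0.05             # s
    picard_tol: float = 1e-6
    picard_max: int = 25
    grad_div: bool = True
    cip_coeff: float = 0.01      # transport gradient-jump coefficient
    pulsatile: bool = False
    pulsation_amplitude: float = 0.2
    pulsation_period: float = 0.1

    def __post_init__(self):
        if min(self.rho, self.mu, self.dt) <= 0 or self.u_peak < 0:
            raise ParameterError("rho, mu, dt must be > 0 and u_peak >= 0")


@dataclass
class FlowState:
    """Nodal velocity (µm/s) and pressure (Pa) at one time level."""

    u: np.ndarray
    p: np.ndarray
    time: float = 0.0
    picard_iters: int = 0
    residuals: list = field(default_factory=list)

    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=1)


def inlet_profile(mesh: VesselMesh, config: SolverConfig,
                  time: float = 0.0) -> np.ndarray:
    """Parabolic axial velocity (µm/s) on the inlet nodes."""
    nodes = mesh.boundary_nodes(["inlet"])
    y = mesh.nodes[nodes, 1]
    d = mesh.diameter
    amp = config.u_peak
    if config.pulsatile:
        amp *= 1.0 + config.pulsation_amplitude * np.sin(
            2 * np.pi * time / config.pulsation_period)
    ux = amp * (1.0 - ((y - d / 2.0) / (d / 2.0)) ** 2)
    return np.clip(ux, 0.0, None)


def _scatter(mesh: VesselMesh, data_ij: np.ndarray) -> sp.csr_matrix:
    """Assemble an N×N matrix from per-element 3×3 blocks (M, 3, 3)."""
    tri = mesh.triangles
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    data = np.broadcast_to(data_ij, (len(tri), 3, 3))
    return sp.coo_matrix(
        (data.ravel(), (rows, cols)),
        shape=(mesh.n_nodes, mesh.n_nodes),
    ).tocsr()


def _flow_matrices(mesh: VesselMesh, materials: MaterialFields,
                   a_nodal: np.ndarray, u_prev: np.ndarray,
                   config: SolverConfig):
    """Assemble the 3N×3N Picard system and right-hand side (SI units).

    Unknown ordering [ux, uy, p̂]; a_nodal is the current advective velocity
    iterate in m/s, u_prev the previous time level in m/s.
    """
    n = mesh.n_nodes
    tri = mesh.triangles
    area = mesh.tri_areas() * UM ** 2
    g = mesh.p1_gradients() / UM                  # 1/m
    hsz = mesh.element_sizes() * UM               # m
    nu = config.mu / config.rho
    dt = config.dt

    sigma_nodal = np.where(np.isfinite(materials.K_um2),
                           config.mu / (materials.K_um2 * UM ** 2), 0.0)
    sig_hat_nodal = sigma_nodal / config.rho      # 1/s
    sig_e = sig_hat_nodal[tri].mean(axis=1)

    a_e = a_nodal[tri].mean(axis=1)               # (M, 2) element advection
    a_mag = np.linalg.norm(a_e, axis=1)
    tau = 1.0 / np.sqrt((2.0 / dt) ** 2 + (2.0 * a_mag / hsz) ** 2
                        + (4.0 * nu / hsz ** 2) ** 2 + sig_e ** 2)

    adg = np.einsum("md,mid->mi", a_e, g)         # a·∇φ_i, (M, 3)
    gdot = np.einsum("mid,mjd->mij", g, g)        # ∇φ_i·∇φ_j

    third = area / 3.0
    eye_like = np.eye(3)[None]

    # Galerkin velocity blocks: lumped transient + lumped reaction +
    # viscous + advection
    sig_lumped = sig_hat_nodal[tri] * third[:, None]          # (M, 3)
    A_gal = (np.einsum("m,ij->mij", third / dt, np.eye(3))
             + sig_lumped[:, :, None] * eye_like
             + nu * area[:, None, None] * gdot
             + third[:, None, None] * adg[:, None, :])

    # SUPG on velocity: τ (a·∇φ_i) [ φ_j (1/Δt + σ̂)/3·3?  ->  A/3 per j ] etc.
    coef = tau * area
    A_supg = (coef[:, None, None] * adg[:, :, None]
              * (adg[:, None, :] + (1.0 / dt + sig_e)[:, None, None] / 3.0))

    A_uu = _scatter(mesh, A_gal + A_supg)

    # grad-div: δ (∇·u, ∇·v) with δ = ν
    if config.grad_div:
        gd = nu * area
        G_xx = _scatter(mesh, gd[:, None, None] * np.einsum("mi,mj->mij", g[:, :, 0], g[:, :, 0]))
        G_yy = _scatter(mesh, gd[:, None, None] * np.einsum("mi,mj->mij", g[:, :, 1], g[:, :, 1]))
        G_xy = _scatter(mesh, gd[:, None, None] * np.einsum("mi,mj->mij", g[:, :, 0], g[:, :, 1]))
        G_yx = G_xy.T.tocsr()
    else:
        G_xx = G_yy = G_xy = G_yx = sp.csr_matrix((n, n))

    # pressure gradient  −(p̂, ∇·v)  and SUPG pressure  τ (a·∇v, ∇p̂)
    # B[i, j] = −(A/3) ∂φ_i/∂x  (independent of j: p̂ is P1, ∫φ_j = A/3)
    ones_j = np.ones((1, 1, 3))
    B_x = _scatter(mesh, -third[:, None, None] * g[:, :, 0][:, :, None] * ones_j)
    B_y = _scatter(mesh, -third[:, None, None] * g[:, :, 1][:, :, None] * ones_j)
    S_px = _scatter(mesh, coef[:, None, None] * adg[:, :, None] * g[:, :, 0][:, None, :])
    S_py = _scatter(mesh, coef[:, None, None] * adg[:, :, None] * g[:, :, 1][:, None, :])

    # continuity (q, ∇·u) and PSPG  τ (∇q, R_m)
    D_x = _scatter(mesh, third[:, None, None] * g[:, :, 0][:, None, :])
    D_y = _scatter(mesh, third[:, None, None] * g[:, :, 1][:, None, :])
    P_xu = _scatter(mesh, coef[:, None, None] * g[:, :, 0][:, :, None]
                    * (adg[:, None, :] + (1.0 / dt + sig_e)[:, None, None] / 3.0))
    P_yu = _scatter(mesh, coef[:, None, None] * g[:, :, 1][:, :, None]
                    * (adg[:, None, :] + (1.0 / dt + sig_e)[:, None, None] / 3.0))
    P_pp = _scatter(mesh, coef[:, None, None] * gdot)

    A = sp.bmat([
        [A_uu + G_xx, G_xy, B_x + S_px],
        [G_yx, A_uu + G_yy, B_y + S_py],
        [D_x + P_xu, D_y + P_yu, P_pp],
    ], format="csr")

    # RHS: transient terms (Galerkin lumped + SUPG/PSPG residual parts)
    un_e = u_prev[tri].mean(axis=1)               # (M, 2)
    b = np.zeros(3 * n)
    lump = np.zeros((n, 2))
    np.add.at(lump, tri.ravel(),
              np.repeat(third, 3)[:, None] * u_prev[tri].reshape(-1, 2))
    b[:n] += lump[:, 0] / dt
    b[n:2 * n] += lump[:, 1] / dt
    supg_rhs = coef[:, None] * adg / dt           # (M, 3) scalar weights
    pspg_x = coef[:, None] * g[:, :, 0] / dt
    pspg_y = coef[:, None] * g[:, :, 1] / dt
    np.add.at(b[:n], tri.ravel(), (supg_rhs * un_e[:, None, 0]).ravel())
    np.add.at(b[n:2 * n], tri.ravel(), (supg_rhs * un_e[:, None, 1]).ravel())
    np.add.at(b[2 * n:], tri.ravel(),
              (pspg_x * un_e[:, None, 0] + pspg_y * un_e[:, None, 1]).ravel())
    return A, b


def _apply_velocity_dirichlet(A: sp.csr_matrix, b: np.ndarray, n: int,
                              nodes: np.ndarray, values: np.ndarray):
    """Impose u = values on the given nodes by row replacement."""
    dofs = np.concatenate([nodes, nodes + n])
    vals = np.concatenate([values[:, 0], values[:, 1]])
    A = A.tolil()
    for dof, v in zip(dofs, vals):
        A.rows[dof] = [dof]
        A.data[dof] = [1.0]
        b[dof] = v
    return A.tocsr(), b


def solve_flow_step(mesh: VesselMesh, materials: MaterialFields,
                    u_prev: np.ndarray | FlowState | None,
                    config: SolverConfig, time: float = 0.0) -> FlowState:
    """One implicit (backward Euler) step of the stabilized flow problem.

    ``u_prev`` is the previous velocity field in µm/s (zeros if None);
    Picard iteration on the advective velocity runs until the relative
    update falls below ``picard_tol``.
    """
    n = mesh.n_nodes
    if isinstance(u_prev, FlowState):
        u_prev = u_prev.u
    u_prev = np.zeros((n, 2)) if u_prev is None else np.asarray(u_prev, float)
    if np.any(materials.K_um2[materials.member_overall] <= 0):
        raise SolverError("non-positive permeability inside the clot")

    u_prev_si = u_prev * UM
    inlet_nodes = mesh.boundary_nodes(["inlet"])
    # walls keep priority at the outlet corners; the inlet profile is zero
    # at its own corners so either assignment is consistent there
    wall_nodes = np.setdiff1d(mesh.boundary_nodes(["wall"]), inlet_nodes)
    bc_nodes = np.concatenate([inlet_nodes, wall_nodes])
    bc_vals = np.zeros((len(bc_nodes), 2))
    bc_vals[:len(inlet_nodes), 0] = inlet_profile(mesh, config, time) * UM

    a = u_prev_si.copy()
    a[bc_nodes] = bc_vals
    residuals = []
    u_new = u_prev_si
    p_hat = np.zeros(n)
    for it in range(config.picard_max):
        A, b = _flow_matrices(mesh, materials, a, u_prev_si, config)
        A, b = _apply_velocity_dirichlet(A, b, n, bc_nodes, bc_vals)
        sol = spla.spsolve(A.tocsc(), b)
        if not np.all(np.isfinite(sol)):
            raise SolverError("flow solve produced non-finite values",
                              residual_history=residuals)
        u_new = sol[:2 * n].reshape(2, n).T
        p_hat = sol[2 * n:]
        denom = max(np.linalg.norm(u_new), 1e-30)
        change = np.linalg.norm(u_new - a) / denom
        residuals.append(change)
        a = u_new
        if change < config.picard_tol:
            break
    else:
        if residuals[-1] > 1e-2:
            raise SolverError(
                f"Picard iteration did not converge: {residuals[-1]:.3e}",
                residual_history=residuals)
    return FlowState(u=u_new / UM, p=p_hat * config.rho, time=time,
                     picard_iters=len(residuals), residuals=residuals)
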