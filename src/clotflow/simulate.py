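"""Coupled moving-domain flow and transport simulation.

At every sub-step the clot boundary is interpolated in time, transferred to
the fixed mesh by the Laplace indicator, material fields are re-assembled,
and one implicit flow step plus one transport step are taken.  States are
checkpointed at imaging-frame times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SolverError
from .flow import FlowState, SolverConfig, solve_flow_step
from .geometry import DynamicClotDomain
from .marking import (IndicatorField, MaterialFields, MaterialParams,
                      WT_PARAMS, assemble_material_fields, mark_indicator)
from .mesh import VesselMesh
from .transport import TransportState, init_uncaging, solve_transport_step

__all__ = ["SimulationResult", "run_coupled_simulation"]


@dataclass
class SimulationResult:
    """Checkpointed fields of a coupled run (one entry per checkpoint)."""

    times: list = field(default_factory=list)
    flow: list = field(default_factory=list)
    transport: list = field(default_factory=list)
    materials: list = field(default_factory=list)
    overall_indicator: list = field(default_factory=list)
    core_indicator: list = field(default_factory=list)
    boundaries: list = field(default_factory=list)

    def append(self, time, flow, transport, materials, overall, core, boundary):
        self.times.append(time)
        self.flow.append(flow)
        self.transport.append(transport)
        self.materials.append(materials)
        self.overall_indicator.append(overall)
        self.core_indicator.append(core)
        self.boundaries.append(boundary)


def run_coupled_simulation(domain: DynamicClotDomain, mesh: VesselMesh,
                           config: SolverConfig,
                           material_params: MaterialParams = WT_PARAMS,
                           L_ref: float = 3.0, eps: float = 1e-2,
                           with_transport: bool = True,
                           uncage_times: tuple = (0.0,),
                           checkpoint_every: int | None = None,
                           n_steps: int | None = None) -> SimulationResult:
    """Run the full sub-stepped pipeline over the tracked clot domain.

    ``uncage_times`` lists the light-pulse instants at which the solute is
    re-initialized to 1 inside the clot.  ``checkpoint_every`` defaults to
    the domain's sub-step count so that states are stored at frame times;
    ``n_steps`` optionally truncates the run.
    """
    times = domain.substep_times()
    if n_steps is not None:
        times = times[:n_steps + 1]
    checkpoint_every = checkpoint_every or domain.n_sub
    config.dt = float(np.diff(times).mean()) if len(times) > 1 else config.dt

    result = SimulationResult()
    u_state: FlowState | None = None
    c_state: TransportState | None = None
    pending_pulses = sorted(uncage_times)

    for step, t in enumerate(times):
        try:
            overall_pts = domain.boundary_at(t, "overall")
            overall = mark_indicator(mesh, overall_pts, eps=eps)
            core = None
            if domain.core is not None:
                core = mark_indicator(mesh, domain.boundary_at(t, "core"),
                                      eps=eps)
            materials = assemble_material_fields(overall, core,
                                                 material_params, L_ref=L_ref)
            u_state = solve_flow_step(mesh, materials,
                                      u_state.u if u_state else None,
                                      config, time=t)
            if with_transport:
                pulsed = False
                while pending_pulses and t >= pending_pulses[0] - 1e-12:
                    c_state = init_uncaging(mesh, overall, time=t)
                    pending_pulses.pop(0)
                    pulsed = True
                if c_state is None:
                    c_state = init_uncaging(mesh, overall, time=t)
                elif step > 0 and not pulsed:
                    c_state = solve_transport_step(mesh, materials, u_state,
                                                   c_state, config)
        except SolverError as err:
            raise SolverError(
                f"coupled simulation failed at sub-step {step} "
                f"(t={t:.3f} s): {err}",
                residual_history=getattr(err, "residual_history", None),
            ) from err
        if step % checkpoint_every == 0 or step == len(times) - 1:
            result.append(t, u_state, c_state, materials, overall, core,
                          overall_pts)
    return result
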