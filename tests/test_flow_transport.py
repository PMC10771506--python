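"""Flow and transport solver physics: analytic limits and conservation."""

import warnings

import numpy as np
import pytest

from clotflow.errors import ParameterError, SolverError
from clotflow.flow import FlowState, SolverConfig, solve_flow_step
from clotflow.geometry import DynamicClotDomain
from clotflow.marking import (IndicatorField, MaterialParams, WT_PARAMS,
                              assemble_material_fields, mark_indicator)
from clotflow.mesh import build_vessel_mesh
from clotflow.simulate import run_coupled_simulation
from clotflow.transport import (TransportState, init_uncaging,
                                solve_transport_step, total_mass)

MU = 4.0e-3


def circle(r, center, n=360):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(t),
                            center[1] + r * np.sin(t)])


class TestFlow:
    def test_poiseuille_recovery_within_two_percent(self, channel_mesh,
                                                    poiseuille_state):
        out = channel_mesh.boundary_nodes(["outlet"])
        y = channel_mesh.nodes[out, 1]
        ux = poiseuille_state.u[out, 0]
        exact = 1300.0 * (1 - ((y - 25) / 25) ** 2)
        assert np.linalg.norm(ux - exact) / np.linalg.norm(exact) < 0.02
        assert ux[np.argmin(abs(y - 25))] == pytest.approx(1300.0, rel=0.02)

    def test_poiseuille_interior_pressure_gradient(self, channel_mesh,
                                                   poiseuille_state):
        sel = np.isclose(channel_mesh.nodes[:, 1], 25.0)
        x, p = channel_mesh.nodes[sel, 0], poiseuille_state.p[sel]
        o = np.argsort(x)
        inner = (x[o] >= 10) & (x[o] <= 90)
        slope = np.polyfit(x[o][inner], p[o][inner], 1)[0]
        exact = -2 * MU * 1300e-6 / (25e-6) ** 2 * 1e-6   # Pa/um
        assert slope == pytest.approx(exact, rel=0.02)

    def test_zero_inflow_gives_rest_state(self, channel_mesh, free_materials):
        config = SolverConfig(u_peak=0.0, dt=0.5)
        state = solve_flow_step(channel_mesh, free_materials, None, config)
        assert np.abs(state.u).max() < 1e-10
        assert np.ptp(state.p) < 1e-10

    def test_brinkman_slab_darcy_balance(self, channel_mesh):
        x, y = channel_mesh.nodes.T
        member = (x >= 40) & (x <= 60)
        ind = IndicatorField(values=member.astype(float), membership=member,
                             eps=1e-2)
        params = MaterialParams(phi_c=0.2, phi_s=0.2, D_f=60.0,
                                D_c=0.4, D_s=0.4)
        mats = assemble_material_fields(ind, ind, params, L_ref=3.0)
        config = SolverConfig(dt=0.5)
        state = None
        for _ in range(10):
            state = solve_flow_step(channel_mesh, mats, state, config)
        interior = (x >= 45) & (x <= 55) & (y > 10) & (y < 40)
        u_int = state.u[interior, 0]
        # plug flow: uniform interior velocity
        assert u_int.std() < 0.02 * abs(u_int.mean())
        sel = np.isclose(y, 25.0) & (x >= 42.5) & (x <= 57.5)
        o = np.argsort(x[sel])
        slope = np.polyfit(x[sel][o], state.p[sel][o], 1)[0]   # Pa/um
        K_m2 = mats.K_um2[member][0] * 1e-12
        darcy = -MU / K_m2 * (u_int.mean() * 1e-6) * 1e-6      # Pa/um
        assert slope == pytest.approx(darcy, rel=0.05)

    def test_refinement_reduces_poiseuille_error(self, channel_mesh,
                                                 poiseuille_state):
        def profile_error(mesh, state):
            out = mesh.boundary_nodes(["outlet"])
            y = mesh.nodes[out, 1]
            exact = 1300.0 * (1 - ((y - 25) / 25) ** 2)
            return (np.linalg.norm(state.u[out, 0] - exact)
                    / np.linalg.norm(exact))

        coarse = build_vessel_mesh(100.0, 50.0, None, h=5.0)
        n = coarse.n_nodes
        empty = IndicatorField(values=np.zeros(n),
                               membership=np.zeros(n, bool), eps=1e-2)
        mats = assemble_material_fields(empty, None, WT_PARAMS)
        config = SolverConfig(dt=0.5)
        state = None
        for _ in range(8):
            state = solve_flow_step(coarse, mats, state, config)
        assert profile_error(channel_mesh, poiseuille_state) < \
            profile_error(coarse, state)

    def test_nonpositive_permeability_rejected(self, channel_mesh,
                                               free_materials):
        mats = free_materials
        bad = assemble_material_fields(
            IndicatorField(values=np.ones(channel_mesh.n_nodes),
                           membership=np.ones(channel_mesh.n_nodes, bool),
                           eps=1e-2), None, WT_PARAMS)
        bad.K_um2 = np.zeros_like(bad.K_um2)
        with pytest.raises(SolverError):
            solve_flow_step(channel_mesh, bad, None, SolverConfig(dt=0.5))
        del mats


class TestTransport:
    def test_closed_box_mass_conserved(self, channel_mesh):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        ind = mark_indicator(channel_mesh, circle(15.0, (50, 25)))
        mats = assemble_material_fields(ind, None, WT_PARAMS)
        config = SolverConfig(dt=0.05)
        rest = FlowState(u=np.zeros((channel_mesh.n_nodes, 2)),
                         p=np.zeros(channel_mesh.n_nodes))
        state = init_uncaging(channel_mesh, ind)
        m0 = total_mass(channel_mesh, mats, state)
        for _ in range(5):
            state = solve_transport_step(channel_mesh, mats, rest, state,
                                         config, closed=True)
        m1 = total_mass(channel_mesh, mats, state)
        assert abs(m1 - m0) / m0 < 1e-10
        del t

    def test_gaussian_blob_advects_at_flow_speed(self):
        mesh = build_vessel_mesh(200.0, 50.0, None, h=2.5)
        n = mesh.n_nodes
        empty = IndicatorField(values=np.zeros(n),
                               membership=np.zeros(n, bool), eps=1e-2)
        params = MaterialParams(phi_c=0.2, phi_s=0.3, D_f=1e-6,
                                D_c=1e-7, D_s=1e-7)
        mats = assemble_material_fields(empty, None, params)
        speed = 500.0
        flow = FlowState(u=np.tile([speed, 0.0], (n, 1)), p=np.zeros(n))
        x, y = mesh.nodes.T
        state = TransportState(
            c=np.exp(-((x - 60) ** 2 + (y - 25) ** 2) / (2 * 8 ** 2)))
        config = SolverConfig(dt=0.005)
        areas = mesh.lumped_node_areas()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(10):
                state = solve_transport_step(mesh, mats, flow, state, config)
        cx = (areas * state.c * x).sum() / (areas * state.c).sum()
        assert cx - 60.0 == pytest.approx(speed * 10 * config.dt, rel=0.02)

    def test_uncaging_initialization(self, channel_mesh):
        ind = mark_indicator(channel_mesh, circle(15.0, (50, 25)))
        state = init_uncaging(channel_mesh, ind)
        assert np.array_equal(state.c, ind.membership.astype(float))
        mats = assemble_material_fields(ind, None, WT_PARAMS)
        expect = (channel_mesh.lumped_node_areas() * mats.phi)[
            ind.membership].sum()
        assert total_mass(channel_mesh, mats, state) == pytest.approx(expect)

    def test_uncaging_empty_clot_rejected(self, channel_mesh):
        empty = IndicatorField(values=np.zeros(channel_mesh.n_nodes),
                               membership=np.zeros(channel_mesh.n_nodes, bool),
                               eps=1e-2)
        with pytest.raises(ParameterError):
            init_uncaging(channel_mesh, empty)


@pytest.fixture(scope="module")
def static_clot_run(channel_mesh):
    """Coupled run over a static wall-attached clot (WT parameters)."""
    t = np.linspace(0, 2 * np.pi, 180, endpoint=False)
    overall = np.column_stack([50 + 16 * np.cos(t), 12 + 14 * np.sin(t)])
    core = np.column_stack([50 + 8 * np.cos(t), 10 + 7 * np.sin(t)])
    times = np.arange(6) * 0.55
    domain = DynamicClotDomain(times=times, overall=[overall] * 6,
                               core=[core] * 6, n_rays=180, n_sub=4)
    config = SolverConfig(dt=0.05)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_coupled_simulation(domain, channel_mesh, config,
                                      WT_PARAMS, checkpoint_every=1)


class TestCoupledSimulation:
    def test_static_clot_reaches_steady_flow(self, static_clot_run):
        u1 = static_clot_run.flow[-1].u
        u0 = static_clot_run.flow[-2].u
        assert np.linalg.norm(u1 - u0) / np.linalg.norm(u1) < 1e-6

    def test_clot_average_concentration_decays_monotonically(
            self, channel_mesh, static_clot_run):
        from clotflow.quantify import calb_decay_curve
        curve = calb_decay_curve(static_clot_run.transport, channel_mesh,
                                 static_clot_run.materials)
        assert curve.value[0] == pytest.approx(1.0)
        assert (np.diff(curve.value) <= 1e-12).all()

    def test_occlusion_growth_accelerates_gap_flow(self, channel_mesh):
        config = SolverConfig(dt=0.05)
        speeds = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for r in (8.0, 12.0, 16.0, 20.0):
                t = np.linspace(0, 2 * np.pi, 180, endpoint=False)
                curve = np.column_stack([50 + 1.2 * r * np.cos(t),
                                         2.0 + r * np.sin(t)])
                ind = mark_indicator(channel_mesh, curve)
                mats = assemble_material_fields(ind, None, WT_PARAMS)
                state = None
                for _ in range(8):
                    state = solve_flow_step(channel_mesh, mats, state, config)
                gap = ((channel_mesh.nodes[:, 0] > 40)
                       & (channel_mesh.nodes[:, 0] < 60) & ~ind.membership)
                speeds.append(state.speed()[gap].max())
        assert (np.diff(speeds) > 0).all()

    def test_reynolds_number_in_reported_regime(self):
        from clotflow.quantify import reynolds_number
        re = reynolds_number(SolverConfig(), 50.0)
        assert 1e-3 <= re <= 1e-2
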