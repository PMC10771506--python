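"""Traction integrals, decay curves, embolization detection, LHS sweep."""

import warnings

import numpy as np
import pytest

from clotflow.errors import ParameterError
from clotflow.flow import FlowState, SolverConfig, solve_flow_step
from clotflow.marking import WT_PARAMS, assemble_material_fields, mark_indicator
from clotflow.quantify import (boundary_traction, calb_decay_curve,
                               detect_embolization, lhs_sensitivity,
                               reynolds_number)
from clotflow.synth import render_stack
from conftest import make_ellipse_scene


def circle(r, center, n=360):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(t),
                            center[1] + r * np.sin(t)])


class TestBoundaryTraction:
    def test_constant_pressure_closed_curve_zero_force(self, channel_mesh):
        n = channel_mesh.n_nodes
        flow = FlowState(u=np.zeros((n, 2)), p=np.full(n, 123.0))
        entry = boundary_traction(flow, circle(12.0, (50, 25)), channel_mesh)
        assert entry.pressure_magnitude < 1e-12
        assert entry.shear_magnitude < 1e-12

    def test_fictitious_curve_in_pure_fluid_balances(self, channel_mesh,
                                                     poiseuille_state):
        # momentum balance: net force on fluid-only control curve ~ 0
        entry = boundary_traction(poiseuille_state, circle(12.0, (50, 25)),
                                  channel_mesh)
        # reference scale: force on an actual porous plug of the same size
        ind = mark_indicator(channel_mesh, circle(12.0, (50, 25)))
        mats = assemble_material_fields(ind, None, WT_PARAMS)
        config = SolverConfig(dt=0.5)
        state = None
        for _ in range(8):
            state = solve_flow_step(channel_mesh, mats, state, config)
        plug = boundary_traction(state, circle(12.0, (50, 25)), channel_mesh)
        assert entry.total_magnitude < 1e-3 * plug.total_magnitude

    def test_occlusive_plug_pressure_dominates_shear(self, channel_mesh):
        t = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        curve = np.column_stack([50 + 18 * np.cos(t), 20 + 18 * np.sin(t)])
        ind = mark_indicator(channel_mesh, curve)
        mats = assemble_material_fields(ind, None, WT_PARAMS)
        state = None
        for _ in range(8):
            state = solve_flow_step(channel_mesh, mats, state,
                                    SolverConfig(dt=0.5))
        entry = boundary_traction(state, curve, channel_mesh)
        assert abs(entry.pressure_force[0]) > abs(entry.shear_force[0])

    def test_quadrature_refinement_converges(self, channel_mesh,
                                             poiseuille_state):
        t = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        curve = np.column_stack([50 + 14 * np.cos(t), 22 + 14 * np.sin(t)])
        ind = mark_indicator(channel_mesh, curve)
        mats = assemble_material_fields(ind, None, WT_PARAMS)
        state = None
        for _ in range(8):
            state = solve_flow_step(channel_mesh, mats, state,
                                    SolverConfig(dt=0.5))
        mags = [boundary_traction(state, circle(14.0, (50, 22), n),
                                  channel_mesh).total_magnitude
                for n in (24, 48, 192, 384)]
        # Richardson-style: refinement differences shrink from coarse to fine
        assert abs(mags[3] - mags[2]) < abs(mags[1] - mags[0])

    def test_boundary_outside_mesh_rejected(self, channel_mesh,
                                            poiseuille_state):
        from clotflow.errors import GeometryError
        with pytest.raises(GeometryError):
            boundary_traction(poiseuille_state, circle(12.0, (500, 25)),
                              channel_mesh)


class TestDecayCurve:
    def test_frozen_field_stays_at_one(self, channel_mesh):
        from clotflow.transport import TransportState, init_uncaging
        ind = mark_indicator(channel_mesh, circle(15.0, (50, 25)))
        mats = assemble_material_fields(ind, None, WT_PARAMS)
        s0 = init_uncaging(channel_mesh, ind)
        states = [s0, TransportState(c=s0.c.copy(), time=0.55)]
        curve = calb_decay_curve(states, channel_mesh, mats)
        assert np.allclose(curve.value, 1.0)

    def test_empty_region_rejected(self, channel_mesh):
        from clotflow.transport import init_uncaging
        ind = mark_indicator(channel_mesh, circle(15.0, (50, 25)))
        mats = assemble_material_fields(ind, None, WT_PARAMS)  # no core
        s0 = init_uncaging(channel_mesh, ind)
        with pytest.raises(ParameterError):
            calb_decay_curve([s0], channel_mesh, mats, region="core")


class TestReynolds:
    @pytest.mark.parametrize("d,expect", [
        (50.0, 8.6125e-3),
        (100.0, 1.7225e-2),
    ])
    def test_values(self, d, expect):
        assert reynolds_number(SolverConfig(), d) == pytest.approx(expect,
                                                                   rel=1e-4)

    def test_zero_inflow(self):
        assert reynolds_number(SolverConfig(u_peak=0.0), 50.0) == 0.0


class TestEmbolizationDetector:
    times = np.arange(40) * 0.55

    def test_monotone_growth_yields_no_index(self):
        area = 300 + 20 * self.times
        assert detect_embolization(self.times, area, 0.01 * area) is None

    @pytest.mark.parametrize("drop", [10, 20, 30])
    def test_step_drop_detected_exactly(self, drop):
        area = 300 + 20 * self.times
        area[drop:] = area[drop - 1] * 0.5 + 10 * (self.times[drop:]
                                                   - self.times[drop])
        idx = detect_embolization(self.times, area, 0.01 * area)
        assert idx == drop

    def test_no_false_positives_on_noisy_monotone_schedules(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            area = 300 + 20 * self.times + rng.normal(0, 3, len(self.times))
            assert detect_embolization(self.times, area, 0.01 * area) is None

    def test_larger_clot_larger_bounding_box(self):
        from clotflow.geometry import KinematicsSeries, moving_average
        from clotflow.quantify import LoadingSeries, TractionEntry, \
            build_phase_portrait

        def portrait(scale):
            area = scale * (300 + 20 * self.times)
            area[25:] = area[24] * 0.5
            force = 0.01 * area
            entries = [TractionEntry(time=t, pressure_force=np.array([f, 0]),
                                     shear_force=np.zeros(2))
                       for t, f in zip(self.times, force)]
            kin = KinematicsSeries(
                time=self.times, area=area,
                aspect_ratio=np.ones_like(area),
                darea_dt=np.gradient(moving_average(area, 5), self.times),
                daspect_dt=np.zeros_like(area))
            return build_phase_portrait(kin, LoadingSeries(entries=entries))

        small, big = portrait(1.0), portrait(2.0)
        assert small.embolization_index == big.embolization_index == 25
        assert big.bounding_box[0][1] > small.bounding_box[0][1]
        assert big.bounding_box[1][1] > small.bounding_box[1][1]


@pytest.fixture(scope="module")
def small_stack():
    scene = make_ellipse_scene(16.0, 12.0, rotation=0.3, seed=9, n_frames=4)
    stacks, _ = render_stack(scene)
    return stacks["CD41"]


class TestLHSSensitivity:
    def test_degenerate_ranges_give_zero_variability(self, small_stack):
        ranges = {"gaussian_sigma": (1.0, 1.0), "canny_sigma": (1.0, 1.0)}
        res = lhs_sensitivity(ranges, 10, seed=1, stack=small_stack)
        assert res["area_variability_pct"] == pytest.approx(0.0, abs=1e-12)
        assert res["aspect_variability_pct"] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_seed_reproduces_sample_matrix(self, small_stack):
        ranges = {"gaussian_sigma": (0.5, 2.0), "canny_sigma": (0.8, 1.6)}
        r1 = lhs_sensitivity(ranges, 10, seed=4, stack=small_stack)
        r2 = lhs_sensitivity(ranges, 10, seed=4, stack=small_stack)
        assert np.array_equal(r1["sample_matrix"], r2["sample_matrix"])
        assert r1["area_variability_pct"] == r2["area_variability_pct"]

    def test_too_few_samples_rejected(self, small_stack):
        with pytest.raises(ParameterError):
            lhs_sensitivity({"gaussian_sigma": (0.5, 2.0)}, 5, 0, small_stack)
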