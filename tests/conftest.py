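"""Shared fixtures: meshes, steady channel flow, synthetic scene factory."""

import numpy as np
import pytest

from clotflow import (
    IndicatorField,
    SolverConfig,
    assemble_material_fields,
    build_vessel_mesh,
    solve_flow_step,
)
from clotflow.marking import WT_PARAMS
from clotflow.synth import (
    EllipseSpec,
    IntensityModel,
    SyntheticScene,
    VesselSpec,
    render_stack,
)


@pytest.fixture(scope="session")
def channel_mesh():
    """100 x 50 um straight channel at h = d/20."""
    return build_vessel_mesh(100.0, 50.0, None, h=2.5)


@pytest.fixture(scope="session")
def free_materials(channel_mesh):
    """Material fields of an empty (clot-free) lumen."""
    n = channel_mesh.n_nodes
    empty = IndicatorField(values=np.zeros(n),
                           membership=np.zeros(n, dtype=bool), eps=1e-2)
    return assemble_material_fields(empty, None, WT_PARAMS)


@pytest.fixture(scope="session")
def poiseuille_state(channel_mesh, free_materials):
    """Steady clot-free channel flow (large time steps to steady state)."""
    config = SolverConfig(dt=0.5)
    state = None
    for k in range(8):
        state = solve_flow_step(channel_mesh, free_materials, state, config,
                                time=k * config.dt)
    return state


def make_ellipse_scene(a, b, rotation=0.0, seed=0, n_frames=2,
                       salt_density=0.02, pixel_size=0.5, margin=12.0,
                       core_fraction=0.5):
    """Static centered ellipse scene sized to fit the clot with a margin."""
    half = a + margin
    n_px = int(2 * half / pixel_size)
    center = (half, half)
    frame = {
        "overall": EllipseSpec(center, (a, b), rotation),
        "core": EllipseSpec(center, (a * core_fraction, b * core_fraction),
                            rotation),
    }
    return SyntheticScene(
        image_shape=(n_px, n_px),
        schedule=[frame] * n_frames,
        vessel=VesselSpec(length=2 * half, diameter=50.0,
                          injury_center_x=half, injury_depth=0.0),
        intensity=IntensityModel(salt_density=salt_density),
        pixel_size=pixel_size,
        seed=seed,
    )


@pytest.fixture()
def ellipse_scene_factory():
    return make_ellipse_scene


@pytest.fixture(scope="session")
def rendered_ellipse():
    """One rendered 25 x 15 um ellipse stack with paper-like noise."""
    scene = make_ellipse_scene(25.0, 15.0, rotation=0.4, seed=42)
    stacks, truth = render_stack(scene)
    return scene, stacks, truth
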