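import numpy as np
import pytest
from hypothesis import settings
from shapely.geometry import Polygon

from perfusim.flow import FlowBC, solve_flow
from perfusim.geometry import ChamberGeometry, build_geometry, generate_mesh
from perfusim.physics import TABLE_DEFAULTS, FluidProperties

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

ML_MIN = 1e-6 / 60.0


def make_channel_geometry(h=2e-3, length=2e-2, depth=1e-2):
    """Straight planar channel with inlet at x=0 and outlet at x=L."""
    return ChamberGeometry(
        name="channel",
        mode="planar",
        dimensions={"h": h, "length": length},
        regions={"lumen": Polygon([(0, 0), (length, 0), (length, h), (0, h)])},
        porous={},
        sink_regions=[],
        boundaries={"inlet": [((0.0, 0.0), (0.0, h))], "outlet": [((length, 0.0), (length, h))]},
        inlet_split={"inlet": 1.0},
        port_ids={"inlet": h, "outlet": h},
        extrusion_depth=depth,
        target_volume=h * length * depth,
        default_resolution=(2.5e-4, 1e-4),
    )


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def channel_flow(fluid):
    geom = make_channel_geometry()
    mesh = generate_mesh(geom, (2.5e-4, 1e-4))
    sol = solve_flow(mesh, fluid, FlowBC(1.0 * ML_MIN))
    return geom, mesh, sol


@pytest.fixture(scope="session")
def reactor_flows(fluid):
    """Default flow solutions for the three chambers at their study rates."""
    out = {}
    for name in ("realbio", "fluidizedbed", "quasivivo"):
        geom = build_geometry(name)
        mesh = generate_mesh(geom)
        q = TABLE_DEFAULTS.flow_rates[name]
        out[name] = (geom, mesh, solve_flow(mesh, fluid, FlowBC(q)))
    return out
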