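import numpy as np
import pytest

from perfusim.flow import (
    FlowBC,
    SolverError,
    cell_level_shear,
    flow_diagnostics,
    poiseuille_profile,
    solve_flow,
    solve_pipe_flow,
    wall_shear,
)
from perfusim.geometry import build_fluidizedbed, generate_mesh
from perfusim.physics import InvalidParameterError

from conftest import ML_MIN, make_channel_geometry


class TestPoiseuilleOracle:
    def test_velocity_profile(self, channel_flow):
        geom, mesh, sol = channel_flow
        q2d = sol.bc.flow_rate / geom.extrusion_depth
        y = (np.arange(mesh.ny) + 0.5) * mesh.dy
        exact = poiseuille_profile(y, q2d, geom.dimensions["h"])
        mid = mesh.nx // 2
        computed = 0.5 * (sol.u[:, mid] + sol.u[:, mid + 1])
        err = np.linalg.norm(computed - exact) / np.linalg.norm(exact)
        assert err < 0.01

    def test_wall_shear(self, channel_flow, fluid):
        geom, mesh, sol = channel_flow
        q2d = sol.bc.flow_rate / geom.extrusion_depth
        exact = 6.0 * fluid.viscosity * q2d / geom.dimensions["h"] ** 2
        tau = wall_shear(sol, "wall")
        assert np.median(tau.tau) == pytest.approx(exact, rel=0.02)

    def test_grid_convergence(self, fluid):
        geom = make_channel_geometry()
        errs = []
        for res in ((5e-4, 2e-4), (2.5e-4, 1e-4)):
            mesh = generate_mesh(geom, res)
            sol = solve_flow(mesh, fluid, FlowBC(1.0 * ML_MIN))
            q2d = sol.bc.flow_rate / geom.extrusion_depth
            y = (np.arange(mesh.ny) + 0.5) * mesh.dy
            exact = poiseuille_profile(y, q2d, geom.dimensions["h"])
            mid = mesh.nx // 2
            computed = 0.5 * (sol.u[:, mid] + sol.u[:, mid + 1])
            errs.append(np.linalg.norm(computed - exact) / np.linalg.norm(exact))
        assert errs[1] < errs[0]

    def test_zero_flow(self, fluid):
        geom = make_channel_geometry()
        mesh = generate_mesh(geom, (5e-4, 2e-4))
        sol = solve_flow(mesh, fluid, FlowBC(0.0))
        assert np.abs(sol.u).max() == pytest.approx(0.0, abs=1e-16)
        tau = wall_shear(sol, "wall")
        assert np.abs(tau.tau).max() == pytest.approx(0.0, abs=1e-12)
        diag = flow_diagnostics(sol, geom)
        assert diag.reynolds_inlet == 0.0
        assert diag.recirculation_fraction == 0.0


class TestPipeFlow:
    def test_peak_is_twice_mean(self):
        sol = solve_pipe_flow(0.5e-3, 0.5 * ML_MIN)
        assert sol.peak_speed == pytest.approx(2.0 * sol.mean_speed, rel=1e-3)

    def test_published_inlet_peak(self):
        # 0.5 mL/min through a 1-mm ID port
        sol = solve_pipe_flow(0.5e-3, 0.5 * ML_MIN)
        assert sol.peak_speed == pytest.approx(0.022, rel=0.05)

    def test_wall_shear_analytic(self):
        # tau_w = 4 mu Q / (pi R^3)
        r, q = 0.5e-3, 0.5 * ML_MIN
        sol = solve_pipe_flow(r, q)
        assert sol.wall_shear == pytest.approx(4e-3 * q / (np.pi * r**3), rel=0.01)

    def test_invalid(self):
        with pytest.raises(InvalidParameterError):
            solve_pipe_flow(-1.0, 1e-8)


class TestMassConservation:
    def test_all_reactors(self, reactor_flows):
        for name, (_, _, sol) in reactor_flows.items():
            assert sol.mass_error < 1e-3, name


class TestDiagnostics:
    def test_qv_inlet_reynolds_laminar(self, reactor_flows):
        _, _, sol = reactor_flows["quasivivo"]
        diag = flow_diagnostics(sol)
        assert diag.reynolds_inlet == pytest.approx(10.6, rel=0.01)
        assert diag.reynolds_inlet < 2000

    def test_fb_inlet_reynolds(self, reactor_flows):
        _, _, sol = reactor_flows["fluidizedbed"]
        assert flow_diagnostics(sol).reynolds_inlet == pytest.approx(14.1, rel=0.01)

    def test_turbulent_rate_refused(self, reactor_flows, fluid):
        geom, mesh, _ = reactor_flows["quasivivo"]
        with pytest.raises(SolverError):
            solve_flow(mesh, fluid, FlowBC(200e-6))  # ~200 mL/s -> Re >> 2000


class TestPorousFlow:
    def test_fb_porosity_insensitivity(self, fluid):
        # mean cell-compartment (superficial) speed barely changes with
        # bead-bed porosity from 0.1 to 0.7 (flow is forced through the bed)
        speeds = []
        for eps in (0.1, 0.3, 0.7):
            geom = build_fluidizedbed(overrides={"bed_porosity": eps})
            mesh = generate_mesh(geom)
            sol = solve_flow(mesh, fluid, FlowBC(1.0 * ML_MIN))
            speeds.append(np.mean(sol.speed()[mesh.region_mask("bed")]))
        ref = speeds[1]
        assert max(abs(s - ref) / ref for s in speeds) < 0.10

    def test_cell_level_shear_ordering(self, reactor_flows):
        medians = {}
        sink = {"realbio": "scaffold", "fluidizedbed": "bed", "quasivivo": "bed"}
        for name, (geom, mesh, sol) in reactor_flows.items():
            medians[name] = np.median(cell_level_shear(sol, sink[name]))
        assert medians["fluidizedbed"] > 10 * medians["quasivivo"]
        assert medians["fluidizedbed"] > medians["realbio"] > medians["quasivivo"]

    def test_rb_scaffold_cross_flow_present(self, reactor_flows):
        geom, mesh, sol = reactor_flows["realbio"]
        v_scaffold = np.abs(sol.cell_velocity()[1][mesh.region_mask("scaffold")])
        assert np.median(v_scaffold) > 1e-7  # genuine through-scaffold flow

    def test_non_porous_region_rejected(self, reactor_flows):
        _, _, sol = reactor_flows["quasivivo"]
        with pytest.raises(InvalidParameterError):
            cell_level_shear(sol, "lumen")
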