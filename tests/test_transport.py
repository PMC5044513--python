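import numpy as np
import pytest

from perfusim.flow import FlowBC, solve_flow
from perfusim.geometry import generate_mesh
from perfusim.physics import (
    TABLE_DEFAULTS,
    InvalidParameterError,
    OxygenKinetics,
    SpeciesTransport,
    km_to_concentration,
    vmax_from_cells,
)
from perfusim.transport import (
    ConcentrationField,
    OxygenScenario,
    TransportScenario,
    min_concentration,
    solve_oxygen_steady,
    solve_transient_transport,
    time_to_uniformity,
)

from conftest import ML_MIN, make_channel_geometry

TEST_COMPOUND = SpeciesTransport("test_compound", 1e-8)


class TestTransient:
    def test_equilibrium_is_stationary(self, channel_flow):
        _, _, sol = channel_flow
        scen = TransportScenario(inlet_concentration=1.0, initial_concentration=1.0,
                                 duration=60.0, dt=2.0)
        series = solve_transient_transport(sol, TEST_COMPOUND, scen)
        for f in series.fields:
            vals = f.values[np.isfinite(f.values)]
            assert np.allclose(vals, 1.0, atol=1e-9)
        assert time_to_uniformity(series) == 0.0

    def test_maximum_principle(self, channel_flow):
        _, _, sol = channel_flow
        scen = TransportScenario(inlet_concentration=1.0, duration=120.0, dt=2.0)
        series = solve_transient_transport(sol, TEST_COMPOUND, scen)
        assert series.metrics["max"].max() <= 1.0 + 1e-9
        assert series.metrics["min"].min() >= -1e-12

    def test_mass_balance_once_through(self, channel_flow):
        _, _, sol = channel_flow
        scen = TransportScenario(inlet_concentration=1.0, duration=120.0, dt=2.0)
        series = solve_transient_transport(sol, TEST_COMPOUND, scen)
        assert series.mass_balance_error < 0.01

    def test_plug_flow_breakthrough(self, fluid):
        # narrow channel in the Taylor regime: the flux-weighted outlet
        # concentration crosses 50% at the residence time V/Q
        geom = make_channel_geometry(h=5e-4, length=5e-2, depth=1e-2)
        mesh = generate_mesh(geom, (1e-3, 5e-5))
        q = 5e-4 * 5e-4 * 1e-2  # mean speed 0.5 mm/s
        sol = solve_flow(mesh, fluid, FlowBC(q))
        tau = geom.area() * geom.extrusion_depth / q
        scen = TransportScenario(inlet_concentration=1.0, duration=3 * tau, dt=tau / 200,
                                 output_dt=tau / 100)
        series = solve_transient_transport(sol, TEST_COMPOUND, scen)
        m = series.metrics
        crossing = np.interp(0.5, m["outlet"], m["time_s"])
        assert crossing == pytest.approx(tau, rel=0.10)

    def test_recirculating_closed_loop_conserves_mass(self, channel_flow):
        _, _, sol = channel_flow
        scen = TransportScenario(inlet_concentration=1.0, recirculating=True,
                                 reservoir_volume=2e-6, duration=3600.0, dt=5.0)
        series = solve_transient_transport(sol, TEST_COMPOUND, scen)
        assert series.mass_balance_error < 0.01

    def test_recirculating_dilutes_to_equilibrium(self, channel_flow):
        geom, _, sol = channel_flow
        v_chamber = geom.area() * geom.extrusion_depth
        v_res = 2e-6
        scen = TransportScenario(inlet_concentration=1.0, recirculating=True,
                                 reservoir_volume=v_res, duration=3600.0, dt=5.0)
        series = solve_transient_transport(sol, TEST_COMPOUND, scen)
        expected = v_res / (v_res + v_chamber)
        assert series.metrics["outlet"].iloc[-1] == pytest.approx(expected, rel=0.02)


class TestUniformityTiming:
    def test_threshold_validation(self, channel_flow):
        _, _, sol = channel_flow
        scen = TransportScenario(inlet_concentration=1.0, duration=30.0, dt=5.0)
        series = solve_transient_transport(sol, TEST_COMPOUND, scen)
        with pytest.raises(InvalidParameterError):
            time_to_uniformity(series, threshold=1.5)

    def test_not_reached_sentinel(self, channel_flow):
        _, _, sol = channel_flow
        scen = TransportScenario(inlet_concentration=1.0, duration=4.0, dt=2.0)
        series = solve_transient_transport(sol, TEST_COMPOUND, scen)
        assert np.isnan(time_to_uniformity(series))


def oxygen_setup(reactor_flows, name, vmax_scale=1.0):
    geom, mesh, sol = reactor_flows[name]
    td = TABLE_DEFAULTS
    sink = geom.sink_regions[0]
    vmax = vmax_from_cells(td.cell_counts[name], 4e-16, geom.volume(sink)) * vmax_scale
    kin = OxygenKinetics(vmax=vmax, km=km_to_concentration(5.6, td.henry))
    membrane = td.c0 if "gas_membrane" in geom.boundaries else None
    scen = OxygenScenario(inlet_concentration=td.c0, membrane_concentration=membrane)
    return geom, sol, {sink: kin}, scen


class TestOxygen:
    def test_no_sink_gives_inlet_concentration(self, reactor_flows):
        geom, sol, kin_map, scen = oxygen_setup(reactor_flows, "quasivivo")
        tiny = {k: OxygenKinetics(vmax=1e-20, km=v.km) for k, v in kin_map.items()}
        field = solve_oxygen_steady(sol, tiny, scen)
        vals = field.values[np.isfinite(field.values)]
        assert np.allclose(vals, TABLE_DEFAULTS.c0, rtol=1e-6)

    def test_bounded_by_sources(self, reactor_flows):
        geom, sol, kin_map, scen = oxygen_setup(reactor_flows, "realbio")
        field = solve_oxygen_steady(sol, kin_map, scen)
        vals = field.values[np.isfinite(field.values)]
        assert vals.max() <= TABLE_DEFAULTS.c0 * (1 + 1e-9)
        assert vals.min() >= -1e-12

    def test_consumption_bounded_by_capacity(self, reactor_flows):
        # net O2 influx (= total consumption at steady state) cannot exceed
        # sum over regions of vmax * region volume
        geom, sol, kin_map, scen = oxygen_setup(reactor_flows, "quasivivo")
        field = solve_oxygen_steady(sol, kin_map, scen)
        from perfusim.physics import oxygen_consumption_rate
        sink = geom.sink_regions[0]
        kin = kin_map[sink]
        mask = field.mesh.region_mask(sink)
        cell_area = field.mesh.dx * field.mesh.dy
        total = np.nansum(oxygen_consumption_rate(field.values[mask], kin)) * cell_area
        cap = kin.vmax * field.mesh.area(sink)
        assert total <= cap * (1 + 1e-6)

    def test_rb_minimum_inside_scaffold(self, reactor_flows):
        geom, sol, kin_map, scen = oxygen_setup(reactor_flows, "realbio")
        field = solve_oxygen_steady(sol, kin_map, scen)
        _, loc = min_concentration(field)
        scaffold = geom.regions["scaffold"]
        ys = [c[1] for c in scaffold.exterior.coords]
        assert min(ys) <= loc[1] <= max(ys)

    def test_unknown_sink_region(self, reactor_flows):
        geom, sol, kin_map, scen = oxygen_setup(reactor_flows, "quasivivo")
        with pytest.raises(InvalidParameterError):
            solve_oxygen_steady(sol, {"nowhere": list(kin_map.values())[0]}, scen)


class TestMinConcentration:
    def test_uniform_field(self, reactor_flows):
        geom, mesh, _ = reactor_flows["quasivivo"]
        vals = np.where(mesh.fluid, 0.214, np.nan)
        field = ConcentrationField("oxygen", mesh, vals, 0.0)
        value, _ = min_concentration(field)
        assert value == pytest.approx(0.214)

    def test_missing_region(self, reactor_flows):
        geom, mesh, _ = reactor_flows["quasivivo"]
        vals = np.where(mesh.fluid, 1.0, np.nan)
        field = ConcentrationField("oxygen", mesh, vals, 0.0)
        with pytest.raises(Exception):
            min_concentration(field, "not_a_region")
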