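"""End-to-end scenario runs and parameter sweeps.

A :class:`ScenarioSpec` names a bioreactor and operating point (flow rate,
gas-phase oxygen fraction, cell load); :func:`run_scenario` builds the
geometry and mesh, solves flow, and — depending on the mode — transient
tracer transport and/or the steady oxygen balance, returning a summary
bundle with the derived metrics (time to uniformity, minimum oxygen by
region, shear statistics, Reynolds number).

Sweeps re-run a scenario over a list of flow rates or gas fractions and
report per-value minima with a monotonicity summary, mirroring the
flow-rate / oxygen-fraction optimization study of the single-chamber device.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .comparison import percent_error  # noqa: F401  (re-exported surface)
from .flow import FlowBC, FlowSolution, cell_level_shear, flow_diagnostics, solve_flow
from .geometry import ChamberGeometry, build_geometry, generate_mesh
from .physics import (
    TABLE_DEFAULTS,
    FluidProperties,
    InvalidParameterError,
    OxygenKinetics,
    SpeciesTransport,
    km_to_concentration,
    vmax_from_cells,
)
from .transport import (
    ConcentrationField,
    ConcentrationSeries,
    OxygenScenario,
    TransportScenario,
    min_concentration,
    solve_oxygen_steady,
    solve_transient_transport,
    time_to_uniformity,
)

__all__ = ["ScenarioSpec", "ScenarioResult", "run_scenario", "sweep"]


@dataclass(frozen=True)
class ScenarioSpec:
    """One reproducible operating point of one bioreactor."""

    bioreactor: str
    flow_rate: float | None = None  # m^3/s; default: the device's study value
    gas_fraction: float = 0.21
    species: str = "test_compound"
    cell_count: float | None = None  # default: the device's estimated load
    mode: str = "all"  # flow | transport | oxygen | all
    width_variant: str = "original"  # fluidized-bed design variant
    recirculating: bool = False
    reservoir_volume: float = 2.0e-6
    duration: float = 3600.0
    uniformity_threshold: float = 0.95
    resolution: tuple | None = None
    geometry_overrides: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("flow", "transport", "oxygen", "all"):
            raise InvalidParameterError("mode must be flow|transport|oxygen|all")
        if self.flow_rate is not None and self.flow_rate <= 0:
            raise InvalidParameterError("flow rate must be positive")
        if not 0.0 < self.gas_fraction <= 1.0:
            raise InvalidParameterError("gas fraction must be in (0, 1]")

    def resolved_flow_rate(self) -> float:
        if self.flow_rate is not None:
            return self.flow_rate
        try:
            return TABLE_DEFAULTS.flow_rates[self.bioreactor]
        except KeyError:
            raise InvalidParameterError(f"unknown bioreactor {self.bioreactor!r}")

    def resolved_cell_count(self) -> float:
        if self.cell_count is not None:
            return self.cell_count
        return TABLE_DEFAULTS.cell_counts[self.bioreactor]

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    geometry: ChamberGeometry
    flow: FlowSolution
    oxygen: ConcentrationField | None = None
    transport: ConcentrationSeries | None = None
    metrics: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "config_hash": self.spec.config_hash(),
            "version": __version__,
            "bioreactor": self.spec.bioreactor,
            "flow_rate_mL_min": self.spec.resolved_flow_rate() * 6e7,
            "gas_fraction": self.spec.gas_fraction,
            **self.metrics,
        }


def _oxygen_kinetics(spec: ScenarioSpec, geom: ChamberGeometry) -> OxygenKinetics:
    td = TABLE_DEFAULTS
    sink = geom.sink_regions[0]
    vmax = vmax_from_cells(spec.resolved_cell_count(), td.kinetics.per_cell_rate,
                           geom.volume(sink))
    return OxygenKinetics(vmax=vmax, km=km_to_concentration(td.km_mmhg, td.henry),
                          c_cr=td.kinetics.c_cr, per_cell_rate=td.kinetics.per_cell_rate)


def run_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Execute one scenario end to end; deterministic for identical specs."""
    td = TABLE_DEFAULTS
    stage = "geometry"
    try:
        geom = build_geometry(spec.bioreactor, spec.geometry_overrides, spec.width_variant)
        stage = "mesh"
        mesh = generate_mesh(geom, spec.resolution)
        stage = "flow"
        q = spec.resolved_flow_rate()
        flow = solve_flow(mesh, td.fluid, FlowBC(q))
        diag = flow_diagnostics(flow, geom)
        sink = geom.sink_regions[0]
        shear = cell_level_shear(flow, sink) if sink in geom.porous else np.array([])
        result = ScenarioResult(spec=spec, geometry=geom, flow=flow)
        result.metrics.update(
            {
                "reynolds_inlet": diag.reynolds_inlet,
                "peak_speed_m_s": diag.peak_speed,
                "recirculation_fraction": diag.recirculation_fraction,
                "mass_error": flow.mass_error,
                "shear_median_uPa": float(np.median(shear)) * 1e6 if shear.size else float("nan"),
                "shear_p10_uPa": float(np.quantile(shear, 0.10)) * 1e6 if shear.size else float("nan"),
                "shear_p90_uPa": float(np.quantile(shear, 0.90)) * 1e6 if shear.size else float("nan"),
            }
        )

        if spec.mode in ("transport", "all"):
            stage = "transport"
            species = td.test_compound if spec.species == "test_compound" else td.oxygen
            tscen = TransportScenario(
                inlet_concentration=1.0,
                recirculating=spec.recirculating,
                reservoir_volume=spec.reservoir_volume,
                duration=spec.duration,
            )
            series = solve_transient_transport(flow, species, tscen)
            result.transport = series
            t_unif = time_to_uniformity(series, spec.uniformity_threshold)
            result.metrics.update(
                {
                    "time_to_uniformity_min": t_unif / 60.0,
                    "transport_mass_error": series.mass_balance_error,
                }
            )

        if spec.mode in ("oxygen", "all"):
            stage = "oxygen"
            kin = _oxygen_kinetics(spec, geom)
            membrane = td.c0 if "gas_membrane" in geom.boundaries else None
            oscen = OxygenScenario(
                inlet_concentration=td.c0,
                membrane_concentration=membrane,
                gas_fraction=spec.gas_fraction,
            )
            ox = solve_oxygen_steady(flow, {geom.sink_regions[0]: kin}, oscen,
                                     diffusion=td.oxygen.diffusion_coefficient)
            result.oxygen = ox
            mn, loc = min_concentration(ox, geom.sink_regions[0])
            mn_all, _ = min_concentration(ox)
            result.metrics.update(
                {
                    "min_o2_sink_uM": mn * 1e3,
                    "min_o2_sink_location_m": loc,
                    "min_o2_global_uM": mn_all * 1e3,
                    "vmax_mol_m3_s": kin.vmax,
                }
            )
        return result
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


def sweep(spec: ScenarioSpec, parameter: str, values) -> pd.DataFrame:
    """Re-run a scenario across flow rates or gas fractions.

    Returns one row per value with the bead-level oxygen minimum and shear
    summary; ``attrs['monotonic_min_o2']`` reports whether the minimum
    strictly increases along the sweep.
    """
    if parameter not in ("flow_rate", "gas_fraction"):
        raise InvalidParameterError("parameter must be 'flow_rate' or 'gas_fraction'")
    vals = list(values)
    if any(v <= 0 for v in vals) or sorted(vals) != vals:
        raise InvalidParameterError("sweep values must be positive and sorted")
    rows = []
    for v in vals:
        sub = replace(spec, mode="oxygen", **{parameter: v})
        try:
            res = run_scenario(sub)
        except Exception as exc:
            raise type(exc)(f"[sweep {parameter}={v}] {exc}") from exc
        rows.append(
            {
                parameter: v,
                "min_o2_sink_uM": res.metrics["min_o2_sink_uM"],
                "shear_median_uPa": res.metrics["shear_median_uPa"],
                "reynolds_inlet": res.metrics["reynolds_inlet"],
            }
        )
    df = pd.DataFrame(rows)
    mins = df["min_o2_sink_uM"].to_numpy()
    df.attrs["monotonic_min_o2"] = bool(np.all(np.diff(mins) > 0))
    return df
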