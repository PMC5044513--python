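"""Physical constants and oxygen-consumption kinetics.

All quantities are kept in SI units internally (m, s, Pa, mol/m^3); the
reporting layer converts to the μM / μPa scales common in the bioreactor
literature (1 mol/m^3 = 1000 μM).

The oxygen sink follows saturating Michaelis–Menten kinetics multiplied by a
smooth cubic "step-down" switch that extinguishes consumption as the local
concentration approaches the critical level for hepatocyte survival.  The
switch is C^1 at both ends of its ramp, which keeps nonlinear solvers stable
when transport undershoots produce slightly negative concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluidProperties",
    "SpeciesTransport",
    "HenryLaw",
    "OxygenKinetics",
    "BeadLoading",
    "TABLE_DEFAULTS",
    "henry_concentration",
    "partial_pressure",
    "km_to_concentration",
    "stepdown_delta",
    "oxygen_consumption_rate",
    "vmax_from_cells",
    "cells_per_bead",
    "sphere_volume",
]

MMHG_PER_ATM = 760.0


class InvalidParameterError(ValueError):
    """Raised when a physical parameter violates its validity constraints."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian culture-medium properties (water-like by default)."""

    density: float = 1000.0  # kg/m^3
    viscosity: float = 1.0e-3  # kg/m/s (dynamic)
    temperature: float = 37.0  # degC, metadata only

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise InvalidParameterError("density and viscosity must be positive")


@dataclass(frozen=True)
class SpeciesTransport:
    """A transported solute: name, diffusivity and whether cells consume it."""

    name: str
    diffusion_coefficient: float  # m^2/s
    reactive: bool = False

    def __post_init__(self) -> None:
        if self.diffusion_coefficient <= 0:
            raise InvalidParameterError("diffusion coefficient must be positive")


@dataclass(frozen=True)
class HenryLaw:
    """Henry's-law equilibrium between gas-phase O2 and dissolved O2.

    ``k_o2`` is in atm per (mol/L); ``p_o2`` is the gas-phase O2 partial
    pressure in atm (0.21 atm for air at 1 atm total pressure).
    """

    k_o2: float = 932.4
    p_o2: float = 0.21

    def __post_init__(self) -> None:
        if self.k_o2 <= 0:
            raise InvalidParameterError("Henry constant must be positive")
        if self.p_o2 < 0:
            raise InvalidParameterError("partial pressure must be non-negative")


def henry_concentration(p_o2: float, law: HenryLaw) -> float:
    """Dissolved O2 concentration (mol/m^3) in equilibrium with ``p_o2`` (atm).

    C [mol/L] = P / K_O2, then converted to mol/m^3 (x1000).
    """
    if p_o2 < 0:
        raise InvalidParameterError("partial pressure must be non-negative")
    return p_o2 / law.k_o2 * 1000.0


def partial_pressure(c: float, law: HenryLaw) -> float:
    """Inverse of :func:`henry_concentration`: P (atm) for c in mol/m^3."""
    return c / 1000.0 * law.k_o2


def km_to_concentration(km_mmhg: float, law: HenryLaw) -> float:
    """Convert a Michaelis constant quoted in mmHg to mol/m^3 via Henry's law."""
    if km_mmhg <= 0:
        raise InvalidParameterError("km must be positive")
    return henry_concentration(km_mmhg / MMHG_PER_ATM, law)


@dataclass(frozen=True)
class OxygenKinetics:
    """Volumetric Michaelis–Menten O2 consumption with critical-level cutoff.

    Fields are in mol/m^3 and mol/m^3/s.  ``km`` must already be in
    concentration units (see :func:`km_to_concentration`); the conversion used
    is recorded in run metadata by the configuration layer.
    """

    vmax: float  # mol/m^3/s
    km: float  # mol/m^3
    c_cr: float = 2.82e-3  # mol/m^3
    per_cell_rate: float = 4.0e-16  # mol/s/cell (0.4 nmol/s/10^6 cells)

    def __post_init__(self) -> None:
        if min(self.vmax, self.km, self.c_cr, self.per_cell_rate) <= 0:
            raise InvalidParameterError("kinetic constants must be positive")


def stepdown_delta(c, c_cr: float):
    """Cubic step-down switch in [0, 1], C^1 continuous at +-c_cr.

    0 for c < -c_cr; 0.5 + 0.75 (c/c_cr) - 0.25 (c/c_cr)^3 on |c| <= c_cr;
    1 for c > c_cr.  Accepts scalars or arrays.
    """
    if c_cr <= 0:
        raise InvalidParameterError("c_cr must be positive")
    x = np.clip(np.asarray(c, dtype=float) / c_cr, -1.0, 1.0)
    out = 0.5 + 0.75 * x - 0.25 * x**3
    if np.ndim(c) == 0:
        return float(out)
    return out


def oxygen_consumption_rate(c, kin: OxygenKinetics):
    """Local volumetric O2 sink R = Vmax * c/(c+km) * delta(c) (mol/m^3/s).

    Slightly negative concentrations (numerical transport undershoot) are
    admitted; the step-down switch drives the rate to zero there.
    """
    carr = np.asarray(c, dtype=float)
    delta = stepdown_delta(carr, kin.c_cr)
    # below -km the MM factor changes sign/poles; delta is 0 well before that
    denom = carr + kin.km
    mm = np.where(denom > 0, carr / np.where(denom > 0, denom, 1.0), 0.0)
    out = kin.vmax * mm * delta
    if np.ndim(c) == 0:
        return float(out)
    return out


def vmax_from_cells(n_cells: float, per_cell_rate: float, compartment_volume: float) -> float:
    """Volumetric Vmax (mol/m^3/s) from cell count and compartment volume."""
    if n_cells <= 0 or per_cell_rate <= 0:
        raise InvalidParameterError("cell count and per-cell rate must be positive")
    if compartment_volume <= 0:
        raise InvalidParameterError("compartment volume must be positive")
    return n_cells * per_cell_rate / compartment_volume


def sphere_volume(diameter: float) -> float:
    return math.pi / 6.0 * diameter**3


@dataclass(frozen=True)
class BeadLoading:
    """Hepatocyte loading of an alginate bead (50% v/v cells by default)."""

    cell_volume_fraction: float = 0.5
    cell_diameter: float = 20e-6  # m
    bead_diameter: float = 500e-6  # m

    def __post_init__(self) -> None:
        if not 0.0 < self.cell_volume_fraction < 1.0:
            raise InvalidParameterError("cell volume fraction must be in (0, 1)")
        if self.cell_diameter <= 0 or self.bead_diameter <= 0:
            raise InvalidParameterError("diameters must be positive")

    def cells_per_bead(self) -> int:
        return cells_per_bead(self)

    def volumetric_vmax(self, per_cell_rate: float = 4.0e-16) -> float:
        """Vmax inside the bead interior at this packing (mol/m^3/s)."""
        cell_vol = sphere_volume(self.cell_diameter)
        return self.cell_volume_fraction / cell_vol * per_cell_rate


def cells_per_bead(loading: BeadLoading) -> int:
    """Whole number of cells in one bead, both modeled as spheres."""
    bead_vol = sphere_volume(loading.bead_diameter)
    cell_vol = sphere_volume(loading.cell_diameter)
    return int(math.floor(bead_vol * loading.cell_volume_fraction / cell_vol))


def _default_kinetics() -> OxygenKinetics:
    law = HenryLaw()
    return OxygenKinetics(
        vmax=BeadLoading().volumetric_vmax(),
        km=km_to_concentration(5.6, law),
        c_cr=2.82e-3,
        per_cell_rate=4.0e-16,
    )


@dataclass(frozen=True)
class TableDefaults:
    """Bundled defaults reproducing the published parameter table.

    ``o2_solubility`` (0.2 mol/m^3) is carried as an unused constant; the
    inlet/membrane oxygen concentration used throughout is ``c0`` =
    0.214 mol/m^3.
    """

    fluid: FluidProperties = field(default_factory=FluidProperties)
    henry: HenryLaw = field(default_factory=HenryLaw)
    oxygen: SpeciesTransport = field(
        default_factory=lambda: SpeciesTransport("oxygen", 3.0e-9, reactive=True)
    )
    test_compound: SpeciesTransport = field(
        default_factory=lambda: SpeciesTransport("test_compound", 1.0e-8, reactive=False)
    )
    c0: float = 0.214  # mol/m^3, inlet & gas-membrane O2 concentration
    o2_solubility: float = 0.2  # mol/m^3 (recorded, unused)
    km_mmhg: float = 5.6
    kinetics: OxygenKinetics = field(default_factory=_default_kinetics)
    cell_counts: dict = field(
        default_factory=lambda: {"realbio": 15e6, "fluidizedbed": 70e6, "quasivivo": 1.5e6}
    )
    flow_rates: dict = field(  # m^3/s
        default_factory=lambda: {
            "realbio": 1.0e-6 / 60.0,
            "fluidizedbed": 1.0e-6 / 60.0,
            "quasivivo": 0.5e-6 / 60.0,
        }
    )


TABLE_DEFAULTS = TableDefaults()
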