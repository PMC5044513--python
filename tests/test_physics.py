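import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from perfusim.physics import (
    TABLE_DEFAULTS,
    BeadLoading,
    FluidProperties,
    HenryLaw,
    InvalidParameterError,
    OxygenKinetics,
    SpeciesTransport,
    cells_per_bead,
    henry_concentration,
    km_to_concentration,
    oxygen_consumption_rate,
    partial_pressure,
    stepdown_delta,
    vmax_from_cells,
)

LAW = HenryLaw()


class TestHenry:
    def test_zero_partial_pressure(self):
        assert henry_concentration(0.0, LAW) == 0.0

    def test_inlet_concentration_implies_air_pressure(self):
        # dissolved 0.214 mol/m^3 corresponds to ~0.1995 atm O2
        assert partial_pressure(TABLE_DEFAULTS.c0, LAW) == pytest.approx(0.19953, abs=1e-4)

    @given(st.floats(min_value=1e-6, max_value=10.0))
    def test_round_trip(self, p):
        assert partial_pressure(henry_concentration(p, LAW), LAW) == pytest.approx(p, rel=1e-12)

    def test_negative_pressure_rejected(self):
        with pytest.raises(InvalidParameterError):
            henry_concentration(-0.1, LAW)

    def test_invalid_constant_rejected(self):
        with pytest.raises(InvalidParameterError):
            HenryLaw(k_o2=-1.0)


class TestKmConversion:
    @pytest.mark.parametrize(
        "mmhg,expected",
        [(5.6, 7.90e-3), (760.0, 1.0725e0 / 1000 * 1000)],
    )
    def test_values(self, mmhg, expected):
        assert km_to_concentration(mmhg, LAW) == pytest.approx(expected, rel=2e-3)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidParameterError):
            km_to_concentration(0.0, LAW)

    def test_km_above_critical_concentration(self):
        # the graded MM response near the critical level requires km > c_cr
        assert km_to_concentration(5.6, LAW) > TABLE_DEFAULTS.kinetics.c_cr


class TestStepDown:
    CCR = 2.82e-3

    @pytest.mark.parametrize(
        "c,expected", [(2.82e-3, 1.0), (-2.82e-3, 0.0), (0.0, 0.5), (1.0, 1.0), (-1.0, 0.0)]
    )
    def test_anchor_points(self, c, expected):
        assert stepdown_delta(c, self.CCR) == pytest.approx(expected)

    @given(st.floats(min_value=-0.1, max_value=0.1))
    def test_bounded(self, c):
        assert 0.0 <= stepdown_delta(c, self.CCR) <= 1.0

    def test_monotone_and_c1(self):
        c = np.linspace(-2 * self.CCR, 2 * self.CCR, 20001)
        d = stepdown_delta(c, self.CCR)
        assert np.all(np.diff(d) >= -1e-15)
        # finite-difference derivative continuous across the ramp edges
        h = c[1] - c[0]
        deriv = np.gradient(d, h)
        for edge in (-self.CCR, self.CCR):
            i = int(np.argmin(np.abs(c - edge)))
            window = deriv[i - 5: i + 6]
            assert np.max(np.abs(np.diff(window))) < 1e-2 * max(deriv.max(), 1e-12)


class TestConsumptionRate:
    KIN = OxygenKinetics(vmax=0.05, km=7.9e-3)

    def test_zero_concentration(self):
        assert oxygen_consumption_rate(0.0, self.KIN) == pytest.approx(0.0)

    def test_half_saturation(self):
        kin = OxygenKinetics(vmax=0.05, km=1.0, c_cr=1e-9)
        assert oxygen_consumption_rate(1.0, kin) == pytest.approx(0.025, rel=1e-9)

    def test_saturation_limit(self):
        assert oxygen_consumption_rate(1e6, self.KIN) == pytest.approx(self.KIN.vmax, rel=1e-5)

    @given(st.floats(min_value=-1.0, max_value=10.0))
    def test_bounded_by_vmax(self, c):
        assert oxygen_consumption_rate(c, self.KIN) <= self.KIN.vmax + 1e-15

    def test_pure_mm_above_critical(self):
        c = 10 * self.KIN.c_cr
        expected = self.KIN.vmax * c / (c + self.KIN.km)
        assert oxygen_consumption_rate(c, self.KIN) == pytest.approx(expected, rel=1e-12)

    def test_monotone_nonnegative_side(self):
        c = np.linspace(0, 0.3, 5000)
        r = oxygen_consumption_rate(c, self.KIN)
        assert np.all(np.diff(r) >= -1e-18)


class TestVmaxFromCells:
    def test_bead_interior_rate(self):
        # 50% v/v hepatocytes of 20 um at 0.4 nmol/s/10^6 cells
        assert BeadLoading().volumetric_vmax() == pytest.approx(4.77e-2, rel=1e-3)

    def test_formula(self):
        assert vmax_from_cells(1.5e6, 4e-16, 1.2e-7) == pytest.approx(5e-3)

    @pytest.mark.parametrize("n,rate,vol", [(0, 4e-16, 1e-6), (1e6, 4e-16, 0.0)])
    def test_invalid(self, n, rate, vol):
        with pytest.raises(InvalidParameterError):
            vmax_from_cells(n, rate, vol)

    def test_small_count_limit(self):
        assert vmax_from_cells(1e-6, 4e-16, 1e-6) < 1e-15


class TestCellsPerBead:
    @pytest.mark.parametrize("d,expected", [(500e-6, 7812), (250e-6, 976)])
    def test_published_loadings(self, d, expected):
        assert cells_per_bead(BeadLoading(bead_diameter=d)) == expected

    def test_vanishing_fraction(self):
        assert cells_per_bead(BeadLoading(cell_volume_fraction=1e-9)) == 0

    def test_invalid_fraction(self):
        with pytest.raises(InvalidParameterError):
            BeadLoading(cell_volume_fraction=1.5)


class TestTypes:
    def test_fluid_validation(self):
        with pytest.raises(InvalidParameterError):
            FluidProperties(density=-1)

    def test_species_validation(self):
        with pytest.raises(InvalidParameterError):
            SpeciesTransport("x", 0.0)

    def test_table_defaults_consistency(self):
        td = TABLE_DEFAULTS
        assert td.c0 == pytest.approx(0.214)
        assert td.o2_solubility == pytest.approx(0.2)
        assert td.oxygen.diffusion_coefficient == 3e-9
        assert td.test_compound.diffusion_coefficient == 1e-8
        assert td.kinetics.km == pytest.approx(7.90e-3, rel=1e-3)
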