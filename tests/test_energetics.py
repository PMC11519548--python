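"""Reaction thermodynamics, energy yields, and maintenance benchmarks."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airmob import (
    CO_OXIDATION,
    HYDROGEN_OXIDATION,
    METHANE_OXIDATION,
    MaintenanceBenchmark,
    Reaction,
    cell_energy_yield,
    cmol_energy_yield,
    fold_below_maintenance,
    in_situ_reaction_energy,
    maintenance_at_temperature,
    standard_reaction_energy,
)
from airmob.errors import (
    InfiniteQuotientError,
    RegistryError,
    ThermodynamicInconsistencyError,
)
from airmob.gas_budget import R_KJ

#: Standard-table formation energies used in the hand-evaluated examples.
FE = {"CH4": -50.8, "O2": 0.0, "CO2": -394.4, "H2O(l)": -237.1, "CO": -137.2, "H2": 0.0}

#: Atmospheric composition of the incubations (p.p.m.v.).
ATM = {"CH4": 1.87, "H2": 0.5, "CO": 0.2, "O2": 209000.0, "CO2": 400.0}


class TestReaction:
    def test_element_balance_enforced(self):
        with pytest.raises(ValueError, match="balance"):
            Reaction({"CH4": -1, "O2": -1, "CO2": 1, "H2O(l)": 2}, per_mole_of="CH4")

    def test_reference_species_must_participate(self):
        with pytest.raises(ValueError, match="reference"):
            Reaction({"H2": -2, "O2": -1, "H2O(l)": 2}, per_mole_of="CH4")


class TestStandardReactionEnergy:
    def test_empty_reaction_is_zero(self):
        assert standard_reaction_energy(_null()) == 0.0

    def test_methane_oxidation_signed_sum(self):
        # (-394.4 + 2*(-237.1)) - (-50.8) per mol CH4
        assert standard_reaction_energy(METHANE_OXIDATION, FE) == pytest.approx(
            -817.8, abs=1e-9
        )

    def test_co_oxidation_normalized_per_mol_gas(self):
        # 2CO + O2 -> 2CO2: signed sum / 2
        assert standard_reaction_energy(CO_OXIDATION, FE) == pytest.approx(
            -257.2, abs=1e-9
        )

    def test_missing_species_raises(self):
        with pytest.raises(RegistryError):
            standard_reaction_energy(METHANE_OXIDATION, {"CH4": -50.8})


def _null():
    """A degenerate empty reaction, built without validation for the
    zero-energy check."""
    r = object.__new__(Reaction)
    object.__setattr__(r, "stoichiometry", {})
    object.__setattr__(r, "per_mole_of", "")
    object.__setattr__(r, "name", "null")
    return r


class TestInSituReactionEnergy:
    def test_standard_state_recovers_delta_g0(self):
        # all activities 1: mixing ratio 1e6 p.p.m.v. at 1 bar
        ones = {sp: 1e6 for sp in ("CH4", "O2", "CO2")}
        e = in_situ_reaction_energy(METHANE_OXIDATION, 293.15, ones, pressure=1.0,
                                    formation_energies=FE)
        assert e.reaction_quotient == pytest.approx(1.0, rel=1e-12)
        assert e.delta_g == pytest.approx(e.delta_g_standard, rel=1e-12)

    def test_methane_at_atmospheric_conditions(self):
        """Reproduces the printed in-situ value for CH4 oxidation."""
        e = in_situ_reaction_energy(METHANE_OXIDATION, 293.15, ATM, pressure=1.013)
        assert e.delta_g == pytest.approx(-797.4, abs=0.5)

    def test_hydrogen_at_atmospheric_conditions(self):
        """Hand evaluation per mol H2: -237.1 + 37.2 = -199.9 (see methods
        note on the printed H2/CO values)."""
        e = in_situ_reaction_energy(HYDROGEN_OXIDATION, 293.15, ATM, pressure=1.013,
                                    formation_energies=FE)
        assert e.delta_g_standard == pytest.approx(-237.1, abs=1e-9)
        assert e.delta_g == pytest.approx(-199.9, abs=0.1)

    def test_zero_reactant_raises(self):
        ratios = dict(ATM, CH4=0.0)
        with pytest.raises(InfiniteQuotientError):
            in_situ_reaction_energy(METHANE_OXIDATION, 293.15, ratios)

    @settings(max_examples=50, derandomize=True)
    @given(
        ch4=st.floats(0.1, 100.0),
        o2=st.floats(1e4, 5e5),
        co2=st.floats(10.0, 1e4),
        temp=st.floats(283.15, 308.15),
    )
    def test_identity_holds_on_randomized_inputs(self, ch4, o2, co2, temp):
        """delta_g == delta_g0 + RT ln Q on the returned fields."""
        e = in_situ_reaction_energy(
            METHANE_OXIDATION, temp, {"CH4": ch4, "O2": o2, "CO2": co2}
        )
        assert e.delta_g == pytest.approx(
            e.delta_g_standard + R_KJ * temp * np.log(e.reaction_quotient), rel=1e-9
        )

    def test_monotone_in_reactant_depletion(self):
        """delta_rG becomes less negative as the reactant thins out."""
        energies = [
            in_situ_reaction_energy(
                METHANE_OXIDATION, 293.15, dict(ATM, CH4=x), pressure=1.013
            ).delta_g
            for x in (1.87, 1.0, 0.5, 0.1)
        ]
        assert all(a < b for a, b in zip(energies, energies[1:]))


class TestEnergyYield:
    ENER = {
        gas: in_situ_reaction_energy(rxn, 293.15, ATM, pressure=1.013)
        for gas, rxn in (
            ("CH4", METHANE_OXIDATION),
            ("H2", HYDROGEN_OXIDATION),
            ("CO", CO_OXIDATION),
        )
    }

    def test_zero_rates_zero_total(self):
        y = cell_energy_yield({"CH4": 0.0, "H2": 0.0}, self.ENER)
        assert y.total_per_cell == 0.0

    def test_single_gas_multiplication(self):
        e = in_situ_reaction_energy(METHANE_OXIDATION, 293.15, ATM, pressure=1.013)
        y = cell_energy_yield({"CH4": 1e-18}, {"CH4": e})
        assert y.per_gas["CH4"] == pytest.approx(1e-18 * abs(e.delta_g) * 1e3, rel=1e-12)
        assert y.per_gas["CH4"] == pytest.approx(7.974e-13, rel=1e-3)

    def test_additivity_over_gases(self):
        rates = {"CH4": 2e-18, "H2": 3e-18, "CO": 1.5e-18}
        total = cell_energy_yield(rates, self.ENER).total_per_cell
        parts = sum(
            cell_energy_yield({g: r}, self.ENER).total_per_cell
            for g, r in rates.items()
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_endergonic_input_refused(self):
        e = self.ENER["CH4"]
        bad = type(e)(
            reaction=e.reaction, delta_g_standard=e.delta_g_standard,
            reaction_quotient=e.reaction_quotient, delta_g=+10.0,
            temperature=e.temperature,
        )
        with pytest.raises(ThermodynamicInconsistencyError):
            cell_energy_yield({"CH4": 1e-18}, {"CH4": bad})

    def test_per_cmol_hand_example(self):
        from airmob import EnergyYield

        y = EnergyYield(per_gas={"CH4": 2.21e-12}, total_per_cell=2.21e-12)
        out = cmol_energy_yield(y, dry_mass_fg=180.0, carbon_fraction=0.48)
        assert out.cmol_per_cell == pytest.approx(7.194e-15, rel=1e-3)
        assert out.per_cmol == pytest.approx(0.307, abs=5e-4)

    def test_per_cmol_inverse_in_dry_mass(self):
        y = cell_energy_yield({"CH4": 1e-15}, self.ENER)
        a = cmol_energy_yield(y, 180.0, 0.48).per_cmol
        b = cmol_energy_yield(y, 360.0, 0.48).per_cmol
        assert a == pytest.approx(2 * b, rel=1e-12)

    def test_zero_total_gives_zero_per_cmol(self):
        y = cell_energy_yield({}, self.ENER)
        assert cmol_energy_yield(y, 180.0, 0.48).per_cmol == 0.0

    def test_carbon_fraction_bounds(self):
        y = cell_energy_yield({}, self.ENER)
        with pytest.raises(ValueError):
            cmol_energy_yield(y, 180.0, 1.0)


class TestMaintenance:
    def test_same_temperature_unchanged(self):
        b = MaintenanceBenchmark(4.5, 298.15)
        assert maintenance_at_temperature(b, 298.15) == pytest.approx(4.5)

    def test_25C_to_20C(self):
        """4.5 kJ C-mol-1 h-1 at 25 C scales to 2.8 at 20 C."""
        b = MaintenanceBenchmark(4.5, 298.15)
        assert maintenance_at_temperature(b, 293.15) == pytest.approx(2.8, abs=0.05)

    def test_round_trip(self):
        b = MaintenanceBenchmark(2.8, 293.15)
        up = maintenance_at_temperature(b, 298.15)
        assert up == pytest.approx(4.51, abs=0.05)
        back = maintenance_at_temperature(MaintenanceBenchmark(up, 298.15), 293.15)
        assert back == pytest.approx(2.8, rel=1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            maintenance_at_temperature(MaintenanceBenchmark(2.8, 293.15), 350.0)


class TestFoldBelowMaintenance:
    def test_strain_yields_bracket(self):
        lo, hi = fold_below_maintenance([0.40, 0.71, 0.38, 0.65], 2.8)
        assert round(lo, 1) == 3.9
        assert round(hi, 1) == 7.4

    def test_yield_equal_to_maintenance(self):
        assert fold_below_maintenance([2.8], 2.8) == (1.0, 1.0)

    def test_homogeneity(self):
        lo, hi = fold_below_maintenance([0.4, 0.8], 2.8)
        lo2, hi2 = fold_below_maintenance([0.2, 0.4], 2.8)
        assert (lo2, hi2) == pytest.approx((2 * lo, 2 * hi), rel=1e-12)

    def test_zero_yield_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fold_below_maintenance([0.0, 0.4], 2.8)
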