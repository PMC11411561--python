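"""Plume-mixing energetics: mixing, standard-state and in-situ Gibbs energies."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ventplume import thermo
from ventplume.thermo import (
    BUILTIN_REACTIONS,
    HYDROGEN_OXIDATION,
    IRINOVSKOE,
    R_KJ,
    SULFIDE_OXIDATION,
    DegenerateActivityError,
    EndmemberFluid,
    IncompleteThermoDataError,
    InvalidDilutionError,
    Reaction,
    SeawaterBackground,
    UnknownSpeciesError,
    decade_shift,
    delta_r_G,
    energetics_table,
    energy_density,
    mix_conservative,
    per_electron,
    round_report,
    standard_gibbs,
)


class TestMixConservative:
    @pytest.mark.parametrize(
        "dilution, expected",
        [(1.0, 7.5e-3), (1e4, 7.5e-7)],
    )
    def test_donor_dilutes_linearly(self, seawater, dilution, expected):
        state = mix_conservative(IRINOVSKOE, seawater, dilution)
        assert state.concentrations["H2"] == pytest.approx(expected)

    def test_co_reaches_picomolar_at_full_dilution(self, seawater):
        """A micromolar endmember CO load drops to picomolar at 1e6-fold."""
        state = mix_conservative(IRINOVSKOE, seawater, 1e6)
        assert state.concentrations["CO"] == pytest.approx(1.9e-12)

    def test_invalid_dilution(self, seawater):
        with pytest.raises(InvalidDilutionError):
            mix_conservative(IRINOVSKOE, seawater, 0.5)

    def test_unknown_species(self, seawater):
        fluid = EndmemberFluid("x", {"unobtainium": 1e-3})
        with pytest.raises(UnknownSpeciesError):
            mix_conservative(fluid, seawater, 10.0)

    def test_temperature_equilibrated_at_high_dilution(self, seawater):
        hot = EndmemberFluid("hot", {"H2": 1e-3}, temperature=630.0)
        assert mix_conservative(hot, seawater, 1e4).temperature == seawater.temperature
        # below the equilibration dilution, temperature mixes conservatively
        t10 = mix_conservative(hot, seawater, 10.0).temperature
        assert t10 == pytest.approx(seawater.temperature + (630.0 - seawater.temperature) / 10)

    @given(d=st.floats(min_value=1.0, max_value=1e9))
    @settings(deadline=None, max_examples=50)
    def test_linear_in_inverse_dilution(self, d):
        """c_mix - c_sw scales as 1/d; the limit d -> inf is seawater."""
        sw = SeawaterBackground()
        state = mix_conservative(IRINOVSKOE, sw, d)
        for name, c_em in IRINOVSKOE.concentrations.items():
            assert state.concentrations[name] == pytest.approx(c_em / d)
            assert 0 <= state.concentrations[name] <= c_em


class TestStandardGibbs:
    def test_reference_temperature_is_formation_sum(self):
        """At 298.15 K the value is the hand-summed formation terms."""
        # -237.14 - 17.7 - 0.5 * 16.5 = -263.09
        assert standard_gibbs(HYDROGEN_OXIDATION, 298.15) == pytest.approx(-263.09)

    def test_linear_in_temperature(self):
        """Gibbs-Helmholtz with constant dH is linear in T with slope
        -(dH - dG298)/298.15."""
        g1 = standard_gibbs(HYDROGEN_OXIDATION, 280.0)
        g2 = standard_gibbs(HYDROGEN_OXIDATION, 290.0)
        g3 = standard_gibbs(HYDROGEN_OXIDATION, 300.0)
        assert g2 - g1 == pytest.approx(g3 - g2)

    def test_missing_formation_data(self):
        rxn = Reaction("bad", {"Xe": -1.0, "H2O": 1.0}, 1, "Xe")
        with pytest.raises(IncompleteThermoDataError):
            standard_gibbs(rxn, 298.15)


class TestDeltaRG:
    def test_unit_activities_reduce_to_standard_state(self, seawater):
        """With Q = 1 the in-situ value equals the standard-state value."""
        sw = SeawaterBackground(oxygen=1.0)
        # H2 at unit molality, O2 at unit molality: Q = 1 for H2 oxidation
        fluid = EndmemberFluid("unit", {"H2": 1.0})
        state = mix_conservative(fluid, sw, 1.0)
        g = delta_r_G(HYDROGEN_OXIDATION, state, sw)
        assert g == pytest.approx(standard_gibbs(HYDROGEN_OXIDATION, sw.temperature))

    def test_decade_difference_is_rtln10(self, seawater):
        """Diluting the donor tenfold costs exactly R*T*ln 10."""
        s1 = mix_conservative(IRINOVSKOE, seawater, 1e4)
        s2 = mix_conservative(IRINOVSKOE, seawater, 1e5)
        diff = delta_r_G(HYDROGEN_OXIDATION, s2, seawater) - delta_r_G(
            HYDROGEN_OXIDATION, s1, seawater
        )
        assert diff == pytest.approx(R_KJ * 275.9 * math.log(10), abs=1e-9)
        assert diff == pytest.approx(5.28, abs=0.01)

    def test_zero_donor_concentration(self, seawater):
        fluid = EndmemberFluid("empty", {"H2": 0.0})
        state = mix_conservative(fluid, seawater, 1.0)
        with pytest.raises(DegenerateActivityError):
            delta_r_G(HYDROGEN_OXIDATION, state, seawater)


class TestPerElectronAndDensity:
    @pytest.mark.parametrize(
        "parent, reaction, expected",
        [(-222.67, HYDROGEN_OXIDATION, -111.34), (-783.33, SULFIDE_OXIDATION, -97.92)],
    )
    def test_per_electron_reported(self, parent, reaction, expected):
        assert round_report(per_electron(parent, reaction)) == expected

    def test_identity_for_single_electron(self):
        rxn = Reaction("one", {"H2": -1.0, "H2O": 1.0, "O2": -0.5}, 1, "H2")
        assert per_electron(-42.0, rxn) == -42.0

    def test_energy_density_product(self):
        v = energy_density(-212.12, IRINOVSKOE, HYDROGEN_OXIDATION)
        assert v == pytest.approx(-212.12 * 7.5e-3)
        assert v == pytest.approx(-1.59, abs=0.01)

    def test_energy_density_zero_and_sign(self):
        fluid = EndmemberFluid("z", {"H2": 0.0})
        assert energy_density(-100.0, fluid, HYDROGEN_OXIDATION) == 0.0
        assert energy_density(-100.0, IRINOVSKOE, HYDROGEN_OXIDATION) < 0
        with pytest.raises(UnknownSpeciesError):
            energy_density(-100.0, EndmemberFluid("n", {}), HYDROGEN_OXIDATION)


class TestEnergeticsTable:
    def test_row_layout(self, seawater, irinovskoe):
        rows = energetics_table(irinovskoe, seawater)
        assert len(rows) == 6
        assert [r.reaction for r in rows] == ["H2"] * 3 + ["H2S"] * 3
        assert [r.dilution for r in rows[:3]] == [1e4, 1e5, 1e6]

    def test_single_cell(self, seawater, irinovskoe):
        rows = energetics_table(irinovskoe, seawater, dilutions=[1e4])
        assert len(rows) == len(BUILTIN_REACTIONS)

    def test_monotone_in_dilution(self, seawater, irinovskoe):
        """Yields weaken (become less negative) as the plume dilutes."""
        rows = energetics_table(irinovskoe, seawater, dilutions=[1e2, 1e4, 1e6, 1e8])
        for rxn in ("H2", "H2S"):
            vals = [r.delta_r_G for r in rows if r.reaction == rxn]
            assert vals == sorted(vals)

    def test_per_electron_consistency(self, seawater, irinovskoe):
        for r in energetics_table(irinovskoe, seawater):
            n_e = 2 if r.reaction == "H2" else 8
            assert r.delta_r_G_per_electron * n_e == pytest.approx(r.delta_r_G)

    def test_sulfide_always_richer_per_mole(self, seawater, irinovskoe):
        rows = energetics_table(irinovskoe, seawater)
        by = {(r.reaction, r.dilution): r.delta_r_G for r in rows}
        for d in (1e4, 1e5, 1e6):
            assert by[("H2S", d)] < by[("H2", d)]


def test_decade_shift_reconstruction():
    """One decade of donor dilution adds R*T*ln 10 (about 5.28 kJ)."""
    assert decade_shift(-222.67) - (-222.67) == pytest.approx(5.282, abs=1e-3)
    assert decade_shift(0.0, decades=2) == pytest.approx(2 * R_KJ * 275.9 * math.log(10))


def test_round_report_half_away_from_zero():
    assert round_report(-111.335) == -111.34
    assert round_report(2.675) == 2.68
    assert round_report(-97.98625) == -97.99


def test_reaction_validation():
    with pytest.raises(ValueError):  # charge imbalance
        Reaction("bad", {"H2S": -1.0, "O2": -2.0, "SO4-2": 1.0}, 8, "H2S")
    with pytest.raises(ValueError):  # donor must be a reactant
        Reaction("bad", {"H2": 1.0, "O2": -0.5, "H2O": 1.0}, 2, "H2")


def test_yaml_config_roundtrip(tmp_path):
    cfg = tmp_path / "run.yaml"
    cfg.write_text(
        """
endmember:
  label: Irinovskoe
  H2:  {value: 7.5, unit: mM}
  H2S: {value: 3.2, unit: mM}
seawater:
  oxygen: {value: 250, unit: umol/kg}
  sulfate: {value: 28, unit: mmol/kg}
  pH: 8.0
  temperature: 275.9
"""
    )
    endmember, sw = thermo.load_config(cfg)
    assert endmember.concentrations["H2"] == pytest.approx(7.5e-3)
    assert sw.oxygen == pytest.approx(250e-6)
    assert sw.temperature == 275.9
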