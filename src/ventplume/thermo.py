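"""Catabolic energetics of hydrothermal plume mixing.

Gibbs free-energy yields of aerobic H2 and H2S oxidation as a hot,
reduced endmember fluid mixes conservatively into cold oxygenated
seawater.  The central quantity is

    dG_r = dG0(T) + R * T * ln Q

evaluated per mole of electron donor at a seawater:fluid dilution
factor ``d``.  The donor activity falls linearly with 1/d while the
oxidant, pH and ionic-strength terms are held at their seawater
background values, so consecutive decade dilutions differ by exactly
``R*T*ln 10`` (about 5.28 kJ at 2.7 degC).

Standard-state formation data are CODATA/SUPCRT-style values at
298.15 K, 1 bar; the temperature correction is Gibbs-Helmholtz with a
constant reaction enthalpy, and the pressure correction is neglected
(the dilution term dominates the dilution trend; absolute values carry
the usual thermodynamic-database uncertainty of a few percent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "R_KJ",
    "T_REF",
    "ChemicalSpecies",
    "Reaction",
    "EndmemberFluid",
    "SeawaterBackground",
    "MixedFluidState",
    "EnergeticsResult",
    "SPECIES",
    "HYDROGEN_OXIDATION",
    "SULFIDE_OXIDATION",
    "BUILTIN_REACTIONS",
    "IRINOVSKOE",
    "ENDMEMBERS",
    "InvalidDilutionError",
    "UnknownSpeciesError",
    "IncompleteThermoDataError",
    "DegenerateActivityError",
    "mix_conservative",
    "standard_gibbs",
    "delta_r_G",
    "per_electron",
    "energy_density",
    "energetics_table",
    "decade_shift",
    "results_frame",
    "round_report",
    "load_config",
]

#: Gas constant in kJ mol-1 K-1.
R_KJ = 8.31446261815324e-3
#: Reference temperature for standard-state data, K.
T_REF = 298.15

#: Dilution above which the plume is treated as thermally equilibrated
#: with ambient seawater.
THERMAL_EQUILIBRATION_DILUTION = 1e3


class InvalidDilutionError(ValueError):
    """Dilution factor below 1 (mixture cannot contain more fluid than fluid)."""


class UnknownSpeciesError(KeyError):
    """A species name with no entry in the thermodynamic registry."""


class IncompleteThermoDataError(ValueError):
    """A reaction references a species without formation data."""


class DegenerateActivityError(ValueError):
    """A reacting species has zero or negative activity (ln undefined)."""


# ---------------------------------------------------------------------------
# Species and reactions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChemicalSpecies:
    """Standard-state thermodynamic data for one dissolved species.

    Formation properties are at 298.15 K, 1 bar, in kJ/mol.
    """

    name: str
    phase: str  # "aqueous" or "liquid-water"
    charge: int
    gibbs_formation_298: float
    enthalpy_formation_298: float

    def __post_init__(self) -> None:
        if self.phase not in ("aqueous", "liquid-water"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.phase == "liquid-water" and self.name != "H2O":
            raise ValueError("phase liquid-water is reserved for H2O")
        if not (math.isfinite(self.gibbs_formation_298)
                and math.isfinite(self.enthalpy_formation_298)):
            raise ValueError(f"non-finite formation data for {self.name}")


# CODATA / SUPCRT-consistent aqueous formation data (kJ/mol, 298.15 K).
SPECIES: dict[str, ChemicalSpecies] = {
    s.name: s
    for s in (
        ChemicalSpecies("H2O", "liquid-water", 0, -237.14, -285.83),
        ChemicalSpecies("H2", "aqueous", 0, 17.7, -4.2),
        ChemicalSpecies("O2", "aqueous", 0, 16.5, -11.7),
        ChemicalSpecies("H2S", "aqueous", 0, -27.92, -38.6),
        ChemicalSpecies("SO4-2", "aqueous", -2, -744.46, -909.6),
        ChemicalSpecies("H+", "aqueous", 1, 0.0, 0.0),
        ChemicalSpecies("CO", "aqueous", 0, -119.9, -120.96),
        ChemicalSpecies("CH4", "aqueous", 0, -34.45, -87.91),
    )
}


@dataclass(frozen=True)
class Reaction:
    """A balanced catabolic reaction.

    ``stoichiometry`` maps species name to a signed coefficient
    (reactants negative, products positive).  ``electrons_transferred``
    is per mole of the electron donor.
    """

    name: str
    stoichiometry: Mapping[str, float]
    electrons_transferred: int
    donor: str

    def __post_init__(self) -> None:
        if self.electrons_transferred <= 0:
            raise ValueError("electrons_transferred must be positive")
        if self.stoichiometry.get(self.donor, 0) >= 0:
            raise ValueError("donor must appear as a reactant (negative coefficient)")
        net_charge = 0.0
        for name, coeff in self.stoichiometry.items():
            sp = SPECIES.get(name)
            if sp is not None:
                net_charge += coeff * sp.charge
        if abs(net_charge) > 1e-9:
            raise ValueError(f"reaction {self.name} is not charge balanced")


HYDROGEN_OXIDATION = Reaction(
    name="H2",
    stoichiometry={"H2": -1.0, "O2": -0.5, "H2O": 1.0},
    electrons_transferred=2,
    donor="H2",
)

SULFIDE_OXIDATION = Reaction(
    name="H2S",
    stoichiometry={"H2S": -1.0, "O2": -2.0, "SO4-2": 1.0, "H+": 2.0},
    electrons_transferred=8,
    donor="H2S",
)

BUILTIN_REACTIONS: tuple[Reaction, ...] = (HYDROGEN_OXIDATION, SULFIDE_OXIDATION)


# ---------------------------------------------------------------------------
# Fluids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EndmemberFluid:
    """Endmember vent-fluid composition (mol per kg fluid)."""

    label: str
    concentrations: Mapping[str, float]
    temperature: float | None = None  # K; None = unknown/irrelevant

    def __post_init__(self) -> None:
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name}")


#: Endmember dissolved-gas compositions of the four MAR vent fields
#: (mol/kg): H2, H2S, CH4 in mM; CO in uM.
IRINOVSKOE = EndmemberFluid(
    "Irinovskoe", {"H2": 7.5e-3, "H2S": 3.2e-3, "CH4": 0.78e-3, "CO": 1.9e-6}
)
SEMENOV2 = EndmemberFluid(
    "Semenov-2", {"H2": 6.2e-3, "H2S": 4.4e-3, "CH4": 3.5e-3, "CO": 5.8e-6}
)
ASHADZE2 = EndmemberFluid("Ashadze-2", {"H2": 26e-3, "CH4": 0.8e-3})
LOGATCHEV1 = EndmemberFluid(
    "Logatchev-1", {"H2": 5.6e-3, "H2S": 2.5e-3, "CH4": 1.5e-3}
)

ENDMEMBERS: dict[str, EndmemberFluid] = {
    f.label: f for f in (IRINOVSKOE, SEMENOV2, ASHADZE2, LOGATCHEV1)
}


@dataclass(frozen=True)
class SeawaterBackground:
    """Ambient deep-seawater composition and conditions.

    Defaults: O2 = 250 umol/kg, SO4 = 28 mmol/kg, pH 8.0, T = 275.9 K
    (2.7 degC, the plume potential-temperature range), P = 265 bar.
    Activity coefficients: unity for neutral dissolved gases, 0.12 for
    sulfate at seawater ionic strength.
    """

    oxygen: float = 250e-6
    sulfate: float = 28e-3
    pH: float = 8.0
    temperature: float = 275.9
    pressure: float = 265.0
    activity_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"SO4-2": 0.12}
    )

    def __post_init__(self) -> None:
        if self.oxygen <= 0:
            raise ValueError("seawater oxygen must be positive")
        if not 7.0 <= self.pH <= 9.0:
            raise ValueError("seawater pH outside 7-9")
        if not 271.0 <= self.temperature <= 300.0:
            raise ValueError("seawater temperature outside 271-300 K")
        for name, g in self.activity_coefficients.items():
            if not 0 < g <= 1.5:
                raise ValueError(f"activity coefficient for {name} outside (0, 1.5]")

    def gamma(self, species: str) -> float:
        return float(self.activity_coefficients.get(species, 1.0))

    def concentration(self, species: str) -> float | None:
        """Background concentration of a species, mol/kg, if known."""
        if species == "O2":
            return self.oxygen
        if species == "SO4-2":
            return self.sulfate
        return None


@dataclass(frozen=True)
class MixedFluidState:
    """Endmember-derived concentrations after d-fold seawater dilution."""

    dilution: float
    concentrations: Mapping[str, float]
    temperature: float

    def __post_init__(self) -> None:
        if self.dilution < 1:
            raise InvalidDilutionError(f"dilution {self.dilution} < 1")


@dataclass(frozen=True)
class EnergeticsResult:
    """One reaction x dilution row of an energetics table."""

    reaction: str
    dilution: float
    delta_r_G: float  # kJ per mol donor
    delta_r_G_per_electron: float  # kJ per mol electrons
    energy_density: float  # kJ per litre vent fluid


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def mix_conservative(
    endmember: EndmemberFluid,
    seawater: SeawaterBackground,
    dilution: float,
) -> MixedFluidState:
    """Conservatively mix endmember fluid into seawater at a given ratio.

    For every endmember species, ``c_mix = c_sw + (c_em - c_sw) / d``
    with the deep-seawater concentration of the vent-derived gases taken
    as zero.  For d >= 1e3 the mixture is thermally equilibrated with
    seawater; below that an endmember temperature, when known, mixes
    conservatively as well.
    """
    if dilution < 1:
        raise InvalidDilutionError(f"dilution {dilution} < 1")
    mixed: dict[str, float] = {}
    for name, c_em in endmember.concentrations.items():
        if name not in SPECIES:
            raise UnknownSpeciesError(name)
        c_sw = seawater.concentration(name) or 0.0
        mixed[name] = c_sw + (c_em - c_sw) / dilution
    t = seawater.temperature
    if dilution < THERMAL_EQUILIBRATION_DILUTION and endmember.temperature is not None:
        t = seawater.temperature + (endmember.temperature - seawater.temperature) / dilution
    return MixedFluidState(dilution=dilution, concentrations=mixed, temperature=t)


def standard_gibbs(
    reaction: Reaction,
    temperature: float,
    species: Mapping[str, ChemicalSpecies] | None = None,
) -> float:
    """Standard Gibbs energy of reaction at ``temperature``, kJ/mol donor.

    dG0(298.15) = sum(nu * dGf); corrected to T by Gibbs-Helmholtz with
    constant reaction enthalpy:  dG0(T) = dH0 - (T/298.15)*(dH0 - dG0).
    """
    registry = SPECIES if species is None else species
    dg = 0.0
    dh = 0.0
    for name, coeff in reaction.stoichiometry.items():
        sp = registry.get(name)
        if sp is None:
            raise IncompleteThermoDataError(f"no formation data for {name}")
        dg += coeff * sp.gibbs_formation_298
        dh += coeff * sp.enthalpy_formation_298
    return dh - (temperature / T_REF) * (dh - dg)


def _activity(
    name: str,
    state: MixedFluidState,
    seawater: SeawaterBackground,
) -> float:
    """In-situ activity of one species in the diluted plume."""
    if name == "H2O":
        return 1.0
    if name == "H+":
        return 10.0 ** (-seawater.pH)
    if name in state.concentrations:
        return seawater.gamma(name) * state.concentrations[name]
    c_sw = seawater.concentration(name)
    if c_sw is None:
        raise UnknownSpeciesError(name)
    return seawater.gamma(name) * c_sw


def delta_r_G(
    reaction: Reaction,
    state: MixedFluidState,
    seawater: SeawaterBackground,
) -> float:
    """In-situ Gibbs energy of reaction, kJ per mole of electron donor.

    dG_r = dG0(T) + R*T*ln Q with Q the product of activities raised to
    their stoichiometric coefficients; a(H2O) = 1, a(H+) = 10^-pH,
    a_i = gamma_i * m_i otherwise.
    """
    t = state.temperature
    g0 = standard_gibbs(reaction, t)
    ln_q = 0.0
    for name, coeff in reaction.stoichiometry.items():
        a = _activity(name, state, seawater)
        if a <= 0:
            raise DegenerateActivityError(f"non-positive activity for {name}")
        ln_q += coeff * math.log(a)
    return g0 + R_KJ * t * ln_q


def per_electron(delta_r_g: float, reaction: Reaction) -> float:
    """Gibbs energy per mole of electrons transferred."""
    return delta_r_g / reaction.electrons_transferred


def energy_density(
    delta_r_g: float,
    endmember: EndmemberFluid,
    reaction: Reaction,
) -> float:
    """Energy per litre of vent fluid: dG_r times the endmember donor
    concentration (fluid density taken as 1 kg/L)."""
    if reaction.donor not in endmember.concentrations:
        raise UnknownSpeciesError(reaction.donor)
    return delta_r_g * endmember.concentrations[reaction.donor]


def energetics_table(
    endmember: EndmemberFluid,
    seawater: SeawaterBackground,
    reactions: Sequence[Reaction] = BUILTIN_REACTIONS,
    dilutions: Sequence[float] = (1e4, 1e5, 1e6),
) -> list[EnergeticsResult]:
    """Energetics across reactions and dilutions.

    Rows are reaction-major with dilutions ascending.
    """
    if not dilutions:
        raise ValueError("dilutions must be non-empty")
    rows: list[EnergeticsResult] = []
    for reaction in reactions:
        for d in sorted(dilutions):
            state = mix_conservative(endmember, seawater, d)
            g = delta_r_G(reaction, state, seawater)
            rows.append(
                EnergeticsResult(
                    reaction=reaction.name,
                    dilution=d,
                    delta_r_G=g,
                    delta_r_G_per_electron=per_electron(g, reaction),
                    energy_density=energy_density(g, endmember, reaction),
                )
            )
    return rows


def decade_shift(delta_r_g: float, temperature: float = 275.9, decades: float = 1.0) -> float:
    """Shift a donor-dilution energetics value by whole decades of dilution.

    Because only the donor activity changes with d, moving one decade up
    adds exactly R*T*ln(10); this reconstructs adjacent table columns
    from a single anchor value.
    """
    return delta_r_g + decades * R_KJ * temperature * math.log(10.0)


def round_report(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report/table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def results_frame(rows: Iterable[EnergeticsResult]) -> pd.DataFrame:
    """Energetics rows as a report table (2-decimal rounding)."""
    return pd.DataFrame(
        {
            "reaction": r.reaction,
            "dilution": r.dilution,
            "delta_r_G_kJ_per_mol": round_report(r.delta_r_G),
            "delta_r_G_per_e": round_report(r.delta_r_G_per_electron),
            "energy_density_kJ_per_L": round_report(r.energy_density, 4),
        }
        for r in rows
    )


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

_UNIT_FACTORS = {
    "M": 1.0, "mol/kg": 1.0,
    "mM": 1e-3, "mmol/kg": 1e-3,
    "uM": 1e-6, "umol/kg": 1e-6, "μM": 1e-6,
    "nM": 1e-9, "nmol/kg": 1e-9,
}


def _to_molal(entry) -> float:
    """Convert a ``{value, unit}`` mapping (or bare mol/kg number) to mol/kg."""
    if isinstance(entry, Mapping):
        unit = entry.get("unit", "mol/kg")
        if unit not in _UNIT_FACTORS:
            raise ValueError(f"unknown concentration unit {unit!r}")
        return float(entry["value"]) * _UNIT_FACTORS[unit]
    return float(entry)


def load_config(path) -> tuple[EndmemberFluid, SeawaterBackground]:
    """Read endmember and seawater composition from a YAML run config.

    Schema::

        endmember:
          label: Irinovskoe
          H2:  {value: 7.5, unit: mM}
          H2S: {value: 3.2, unit: mM}
        seawater:
          oxygen:  {value: 250, unit: umol/kg}
          sulfate: {value: 28, unit: mmol/kg}
          pH: 8.0
          temperature: 275.9
          pressure: 265
          activity_coefficients: {SO4-2: 0.12}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    em_cfg = dict(cfg.get("endmember", {}))
    label = em_cfg.pop("label", "endmember")
    temperature = em_cfg.pop("temperature", None)
    concentrations = {name: _to_molal(v) for name, v in em_cfg.items()}
    endmember = EndmemberFluid(label, concentrations, temperature)

    sw_cfg = dict(cfg.get("seawater", {}))
    kwargs = {}
    for key in ("oxygen", "sulfate"):
        if key in sw_cfg:
            kwargs[key] = _to_molal(sw_cfg[key])
    for key in ("pH", "temperature", "pressure"):
        if key in sw_cfg:
            kwargs[key] = float(sw_cfg[key])
    if "activity_coefficients" in sw_cfg:
        kwargs["activity_coefficients"] = {
            k: float(v) for k, v in sw_cfg["activity_coefficients"].items()
        }
    return endmember, SeawaterBackground(**kwargs)
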