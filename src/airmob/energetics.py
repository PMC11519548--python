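"""Reaction thermodynamics and cellular energy yields.

Standard and in-situ Gibbs free energy changes of trace-gas oxidation
(delta_rG = delta_rG0 + RT ln Q_r), conversion of per-cell oxidation
rates into energy yields per cell and per carbon-mole of biomass, and
temperature scaling of maintenance-energy benchmarks.

Gas activities are partial pressures in bar relative to a 1 bar standard
state; liquid water has activity 1.  Energies are normalized per mole of
the trace gas being oxidized (the reaction's reference species), matching
how per-mole values are conventionally quoted.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    InfiniteQuotientError,
    RegistryError,
    ThermodynamicInconsistencyError,
)
from .gas_budget import R_KJ, GasRegistry, default_registry

#: Molar mass of carbon, g mol-1.
CARBON_MOLAR_MASS = 12.011

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def _element_counts(species: str) -> dict[str, int]:
    formula = re.sub(r"\((l|g|aq)\)$", "", species)
    counts: dict[str, int] = {}
    for el, num in _ELEMENT_RE.findall(formula):
        if el:
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    return counts


def _is_liquid(species: str) -> bool:
    return species.endswith("(l)") or species.endswith("(aq)")


@dataclass(frozen=True)
class Reaction:
    """A balanced reaction with signed stoichiometry (products positive).

    Liquid-phase species are marked with an ``(l)`` suffix (activity 1);
    all other species are gases whose activity is their partial pressure
    in bar.  ``per_mole_of`` names the reference species used to normalize
    energies.
    """

    stoichiometry: Mapping[str, float]
    per_mole_of: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.per_mole_of not in self.stoichiometry:
            raise ValueError(
                f"reference species {self.per_mole_of!r} not in the reaction"
            )
        for element in ("C", "H", "O"):
            balance = sum(
                nu * _element_counts(sp).get(element, 0)
                for sp, nu in self.stoichiometry.items()
            )
            if abs(balance) > 1e-9:
                raise ValueError(f"reaction does not balance element {element}")

    @property
    def reference_coefficient(self) -> float:
        return abs(self.stoichiometry[self.per_mole_of])


#: CH4 + 2 O2 -> CO2 + 2 H2O(l)
METHANE_OXIDATION = Reaction(
    {"CH4": -1, "O2": -2, "CO2": 1, "H2O(l)": 2}, per_mole_of="CH4", name="CH4 oxidation"
)
#: 2 H2 + O2 -> 2 H2O(l)
HYDROGEN_OXIDATION = Reaction(
    {"H2": -2, "O2": -1, "H2O(l)": 2}, per_mole_of="H2", name="H2 oxidation"
)
#: 2 CO + O2 -> 2 CO2
CO_OXIDATION = Reaction(
    {"CO": -2, "O2": -1, "CO2": 2}, per_mole_of="CO", name="CO oxidation"
)

OXIDATION_REACTIONS: dict[str, Reaction] = {
    "CH4": METHANE_OXIDATION,
    "H2": HYDROGEN_OXIDATION,
    "CO": CO_OXIDATION,
}


@dataclass(frozen=True)
class ReactionEnergetics:
    """Gibbs energy bookkeeping for one reaction at stated conditions.

    All quantities are normalized per mole of the reference species, so the
    identity ``delta_g == delta_g_standard + R * T * ln(reaction_quotient)``
    holds on the stored fields (``reaction_quotient`` is the reaction-as-
    written quotient raised to 1/|nu_ref|).
    """

    reaction: Reaction
    delta_g_standard: float  # kJ per mol of reference species
    reaction_quotient: float  # unitless, per-reference normalization
    delta_g: float  # kJ per mol of reference species
    temperature: float  # K
    gas_constant: float = R_KJ  # kJ mol-1 K-1


def standard_reaction_energy(
    reaction: Reaction, formation_energies: Mapping[str, float] | None = None
) -> float:
    """Standard Gibbs energy change, kJ per mole of the reference species.

    ``sum(nu_i * delta_fG0_i) / |nu_ref|`` over the signed stoichiometry.
    """
    if formation_energies is None:
        formation_energies = default_registry().formation_energies
    if not reaction.stoichiometry:
        return 0.0
    total = 0.0
    for sp, nu in reaction.stoichiometry.items():
        if sp not in formation_energies:
            raise RegistryError(f"no formation energy for species {sp!r}")
        total += nu * formation_energies[sp]
    return total / reaction.reference_coefficient


def in_situ_reaction_energy(
    reaction: Reaction,
    temperature: float,
    mixing_ratios_ppmv: Mapping[str, float],
    pressure: float = 1.013,
    formation_energies: Mapping[str, float] | None = None,
) -> ReactionEnergetics:
    """In-situ Gibbs energy change: delta_rG = delta_rG0 + RT ln Q_r.

    Parameters
    ----------
    temperature : float
        Incubation temperature, K.
    mixing_ratios_ppmv : mapping
        Mixing ratio (p.p.m.v.) for every gas-phase participant; liquid
        species take activity 1 and need no entry.
    pressure : float
        Total pressure, bar; gas activities are ``x * 1e-6 * P / 1 bar``.
    """
    dg0 = standard_reaction_energy(reaction, formation_energies)
    ln_q = 0.0
    for sp, nu in reaction.stoichiometry.items():
        if _is_liquid(sp):
            continue  # activity 1
        if sp not in mixing_ratios_ppmv:
            raise RegistryError(f"no mixing ratio supplied for gas {sp!r}")
        activity = mixing_ratios_ppmv[sp] * 1e-6 * pressure
        if activity <= 0:
            if nu < 0:
                raise InfiniteQuotientError(
                    f"reactant {sp!r} has zero partial pressure: "
                    "the reaction quotient diverges"
                )
            # a product at zero activity drives Q to 0 (ln Q -> -inf);
            # equally unusable for a finite energy
            raise InfiniteQuotientError(
                f"product {sp!r} has zero partial pressure: ln Q_r diverges"
            )
        ln_q += nu * np.log(activity)
    ln_q /= reaction.reference_coefficient
    delta_g = dg0 + R_KJ * temperature * ln_q
    return ReactionEnergetics(
        reaction=reaction,
        delta_g_standard=dg0,
        reaction_quotient=float(np.exp(ln_q)),
        delta_g=float(delta_g),
        temperature=temperature,
    )


def atmospheric_energetics(
    registry: GasRegistry | None = None,
    temperature: float = 293.15,
    pressure: float = 1.013,
    overrides: Mapping[str, float] | None = None,
) -> dict[str, ReactionEnergetics]:
    """In-situ energetics of CH4, H2, and CO oxidation at atmospheric
    composition taken from the gas registry (optionally overridden)."""
    registry = registry if registry is not None else default_registry()
    ratios = {name: sp.atm_mixing_ratio for name, sp in registry.species.items()}
    if overrides:
        ratios.update(overrides)
    return {
        gas: in_situ_reaction_energy(
            rxn, temperature, ratios, pressure, registry.formation_energies
        )
        for gas, rxn in OXIDATION_REACTIONS.items()
    }


@dataclass
class EnergyYield:
    """Energy conserved from trace-gas oxidation, per cell and per C-mol."""

    per_gas: dict[str, float] = field(default_factory=dict)  # J cell-1 h-1
    total_per_cell: float = 0.0  # J cell-1 h-1
    per_cmol: float | None = None  # kJ C-mol-1 h-1
    cmol_per_cell: float | None = None  # C-mol cell-1


def cell_energy_yield(
    rates_per_cell: Mapping[str, float],
    energetics: Mapping[str, ReactionEnergetics],
) -> EnergyYield:
    """Per-cell energy yield from per-cell oxidation rates.

    Parameters
    ----------
    rates_per_cell : mapping
        Gas -> oxidation rate, mol cell-1 h-1.
    energetics : mapping
        Gas -> :class:`ReactionEnergetics` with an exergonic (negative)
        ``delta_g``.

    Returns J cell-1 h-1 per gas (``rate * |delta_g| * 1e3``) and the total.
    """
    per_gas: dict[str, float] = {}
    for gas, rate in rates_per_cell.items():
        if gas not in energetics:
            raise RegistryError(f"no reaction energetics supplied for {gas!r}")
        dg = energetics[gas].delta_g
        if dg > 0:
            raise ThermodynamicInconsistencyError(
                f"reaction for {gas!r} is endergonic (delta_rG = {dg:.1f} kJ/mol); "
                "it cannot be an energy source"
            )
        if rate < 0:
            raise ValueError(f"negative oxidation rate for {gas!r}")
        per_gas[gas] = rate * abs(dg) * 1e3  # kJ -> J
    return EnergyYield(per_gas=per_gas, total_per_cell=sum(per_gas.values()))


def cmol_energy_yield(
    yield_per_cell: EnergyYield, dry_mass_fg: float, carbon_fraction: float
) -> EnergyYield:
    """Normalize a per-cell energy yield per carbon-mole of biomass.

    ``cmol_per_cell = dry_mass * carbon_fraction / 12.011`` and
    ``per_cmol = total_per_cell [J] * 1e-3 / cmol_per_cell`` in
    kJ C-mol-1 h-1.  Dry mass in fg per cell.
    """
    if dry_mass_fg <= 0:
        raise ValueError("dry mass must be > 0")
    if not 0 < carbon_fraction < 1:
        raise ValueError("carbon fraction must lie in (0, 1)")
    cmol = dry_mass_fg * 1e-15 * carbon_fraction / CARBON_MOLAR_MASS
    return EnergyYield(
        per_gas=dict(yield_per_cell.per_gas),
        total_per_cell=yield_per_cell.total_per_cell,
        per_cmol=yield_per_cell.total_per_cell * 1e-3 / cmol,
        cmol_per_cell=cmol,
    )


@dataclass(frozen=True)
class MaintenanceBenchmark:
    """A maintenance-energy requirement at a stated temperature.

    Default: 2.8 kJ C-mol-1 h-1 at 20 C, the benchmark commonly used for
    aerobic bacteria, with the Tijhuis-type activation energy of
    69.4 kJ mol-1 for temperature conversion.
    """

    value: float = 2.8  # kJ C-mol-1 h-1
    temperature: float = 293.15  # K
    activation_energy: float = 69.4  # kJ mol-1

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("maintenance value must be > 0")


def maintenance_at_temperature(
    benchmark: MaintenanceBenchmark, target_temperature: float
) -> float:
    """Arrhenius-scale a maintenance benchmark to another temperature.

    ``m(T) = m(T_ref) * exp(-(E_a / R) * (1/T - 1/T_ref))``; valid over
    the mesophilic window (273, 323) K.
    """
    for t in (benchmark.temperature, target_temperature):
        if not 273.0 < t < 323.0:
            raise ValueError(f"temperature {t} K outside the supported range (273, 323)")
    exponent = -(benchmark.activation_energy / R_KJ) * (
        1.0 / target_temperature - 1.0 / benchmark.temperature
    )
    return benchmark.value * float(np.exp(exponent))


def fold_below_maintenance(
    per_cmol_yields: Sequence[float], maintenance: float
) -> tuple[float, float]:
    """Range of maintenance-to-yield ratios over a set of strains.

    Returns ``(min_fold, max_fold)`` with ``fold_i = maintenance / yield_i``.
    """
    yields = np.asarray(per_cmol_yields, dtype=float)
    if yields.size == 0:
        raise ValueError("need at least one yield")
    if np.any(yields <= 0):
        raise ZeroDivisionError("per-C-mol yields must be > 0")
    folds = maintenance / yields
    return float(folds.min()), float(folds.max())
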