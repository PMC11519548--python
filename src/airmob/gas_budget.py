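"""Closed-bottle headspace gas accounting.

Converts between headspace mixing ratios (p.p.m.v.), molar amounts, and
dissolved concentrations (nM) for trace-gas incubations in sealed bottles,
including the pressure drop caused by withdrawing gas samples with a
syringe at each measurement.

Unit conventions (everywhere in this package): volumes in L, pressure in
bar absolute, temperature in K, time in h.  Mixing ratios (p.p.m.v.) and
dissolved concentrations (nM) appear only at interfaces.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    DegenerateSamplingError,
    InvalidBottleError,
    RegistryError,
    UnsupportedGasError,
)

#: Gas constant, L bar mol-1 K-1.
R_L_BAR = 0.0831446261815324
#: Gas constant, kJ mol-1 K-1 (used by the energetics module).
R_KJ = 8.31446261815324e-3

PRESSURE_SANITY = (0.5, 2.0)  # bar; closed bottles outside this are suspect


@dataclass(frozen=True)
class GasSpecies:
    """Physical registry entry for one gas.

    Parameters
    ----------
    name : str
        Species identifier (``CH4``, ``H2``, ``CO``, ``O2``, ``CO2``, ``N2``).
    henry_constant : float or None
        Henry's-law solubility constant, mol L-1 bar-1, valid at
        ``henry_t_ref``.
    henry_t_ref : float
        Reference temperature of ``henry_constant`` (K).
    henry_van_t_hoff : float or None
        van 't Hoff temperature coefficient B (K):
        ``k_H(T) = k_H(T_ref) * exp(B * (1/T - 1/T_ref))``.
    atm_mixing_ratio : float
        Default atmospheric mixing ratio, p.p.m.v.
    delta_f_g_standard : mapping
        Standard Gibbs free energies of formation (kJ mol-1) for the
        participants of this gas's oxidation reaction.
    """

    name: str
    henry_constant: float | None = None
    henry_t_ref: float = 293.15
    henry_van_t_hoff: float | None = None
    atm_mixing_ratio: float = 0.0
    delta_f_g_standard: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.henry_constant is not None and self.henry_constant <= 0:
            raise ValueError(f"Henry constant must be > 0 for {self.name}")
        if self.atm_mixing_ratio < 0:
            raise ValueError(f"atmospheric mixing ratio must be >= 0 for {self.name}")

    def henry_at(self, temperature: float) -> float:
        """Henry constant (mol L-1 bar-1) extrapolated to ``temperature``."""
        if self.henry_constant is None:
            raise UnsupportedGasError(f"no Henry parameters for {self.name}")
        if self.henry_van_t_hoff is None or temperature == self.henry_t_ref:
            return self.henry_constant
        return self.henry_constant * np.exp(
            self.henry_van_t_hoff * (1.0 / temperature - 1.0 / self.henry_t_ref)
        )


class GasRegistry:
    """Collection of :class:`GasSpecies` plus a formation-energy table."""

    def __init__(
        self,
        species: Mapping[str, GasSpecies],
        formation_energies: Mapping[str, float],
    ):
        self.species = dict(species)
        self.formation_energies = dict(formation_energies)

    def __getitem__(self, name: str) -> GasSpecies:
        try:
            return self.species[name]
        except KeyError:
            raise RegistryError(f"gas {name!r} not in registry") from None

    def __contains__(self, name: str) -> bool:
        return name in self.species

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "GasRegistry":
        fe = dict(cfg.get("formation_energies", {}))
        species = {}
        for name, entry in cfg.get("gases", {}).items():
            if name in species:
                raise RegistryError(f"duplicate registry entry {name!r}")
            species[name] = GasSpecies(
                name=name,
                henry_constant=entry.get("henry_constant"),
                henry_t_ref=entry.get("henry_t_ref", 293.15),
                henry_van_t_hoff=entry.get("henry_van_t_hoff"),
                atm_mixing_ratio=entry.get("atm_mixing_ratio", 0.0),
                delta_f_g_standard=fe,
            )
        return cls(species, fe)

    @classmethod
    def from_yaml(cls, path) -> "GasRegistry":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def default_registry() -> GasRegistry:
    """Registry shipped with the package (atmospheric defaults, CH4 Henry
    constant calibrated to the 250 nM <-> 159.3 p.p.m.v. anchor at 20 C)."""
    ref = resources.files("airmob.data").joinpath("gases.yaml")
    return GasRegistry.from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))


@dataclass(frozen=True)
class BottleState:
    """Geometry and physical state of a closed incubation bottle.

    Defaults mirror the incubation setup: 250 mL bottle with 50 mL medium
    (0.2 L headspace), 1.05 bar, 20 C.
    """

    headspace_volume: float = 0.2  # L
    liquid_volume: float = 0.05  # L
    pressure: float = 1.05  # bar absolute
    temperature: float = 293.15  # K

    def __post_init__(self) -> None:
        if (
            self.headspace_volume <= 0
            or self.liquid_volume <= 0
            or self.pressure <= 0
            or self.temperature <= 0
        ):
            raise InvalidBottleError(
                "bottle volumes, pressure, and temperature must be strictly positive"
            )
        lo, hi = PRESSURE_SANITY
        if not lo < self.pressure < hi:
            raise InvalidBottleError(
                f"pressure {self.pressure} bar outside the sanity window {PRESSURE_SANITY}"
            )

    def replace_pressure(self, pressure: float) -> "BottleState":
        return BottleState(
            self.headspace_volume, self.liquid_volume, pressure, self.temperature
        )


@dataclass
class HeadspaceSeries:
    """One bottle's time-stamped mixing ratios for a single gas."""

    gas: str
    bottle: BottleState
    times_h: np.ndarray
    mixing_ratios_ppmv: np.ndarray
    sample_volume: float = 0.002  # L withdrawn per measurement
    bottle_id: str = ""

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.mixing_ratios_ppmv = np.asarray(self.mixing_ratios_ppmv, dtype=float)
        if self.times_h.shape != self.mixing_ratios_ppmv.shape:
            raise ValueError("times and mixing ratios must have equal length")
        if self.times_h.size and np.any(np.diff(self.times_h) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(self.mixing_ratios_ppmv < 0):
            raise ValueError("mixing ratios must be >= 0")
        if self.sample_volume < 0:
            raise ValueError("sample volume must be >= 0")

    def __len__(self) -> int:
        return self.times_h.size


def moles_in_headspace(mixing_ratio_ppmv: float, bottle: BottleState) -> float:
    """Molar amount of a gas in the headspace via the ideal gas law.

    ``n = x * 1e-6 * P * V_headspace / (R * T)`` with x in p.p.m.v.
    """
    x = np.asarray(mixing_ratio_ppmv, dtype=float)
    if np.any(x < 0):
        raise ValueError("mixing ratio must be >= 0")
    n = (
        x
        * 1e-6
        * bottle.pressure
        * bottle.headspace_volume
        / (R_L_BAR * bottle.temperature)
    )
    return float(n) if np.isscalar(mixing_ratio_ppmv) else n


def apply_sampling_correction(series: HeadspaceSeries) -> np.ndarray:
    """Headspace pressure in effect at each observation.

    Each syringe withdrawal of ``sample_volume`` at bottle pressure
    (isothermal, fixed headspace volume) multiplies the pressure by
    ``1 - sample_volume / headspace_volume``; observation i is measured
    after i prior withdrawals.  Molar amounts per time point should use
    these corrected pressures.
    """
    v_h = series.bottle.headspace_volume
    if series.sample_volume >= v_h:
        raise DegenerateSamplingError(
            f"sample volume {series.sample_volume} L >= headspace {v_h} L"
        )
    factor = 1.0 - series.sample_volume / v_h
    return series.bottle.pressure * factor ** np.arange(len(series))


def headspace_moles(series: HeadspaceSeries) -> np.ndarray:
    """Sampling-corrected molar amount of the gas at each observation."""
    pressures = apply_sampling_correction(series)
    return (
        series.mixing_ratios_ppmv
        * 1e-6
        * pressures
        * series.bottle.headspace_volume
        / (R_L_BAR * series.bottle.temperature)
    )


def dissolved_concentration(
    mixing_ratio_ppmv: float, bottle: BottleState, gas: GasSpecies
) -> float:
    """Equilibrium dissolved concentration (nM) for a headspace mixing ratio.

    Henry's law: ``C = k_H(T) * p_gas`` with the partial pressure
    ``p_gas = x * 1e-6 * P_total`` in bar; returned in nmol L-1.
    """
    k_h = gas.henry_at(bottle.temperature)  # mol L-1 bar-1
    partial_pressure = mixing_ratio_ppmv * 1e-6 * bottle.pressure
    return k_h * partial_pressure * 1e9


def ppmv_from_dissolved(
    concentration_nm: float, bottle: BottleState, gas: GasSpecies
) -> float:
    """Exact inverse of :func:`dissolved_concentration`."""
    k_h = gas.henry_at(bottle.temperature)
    return concentration_nm * 1e-9 / (k_h * bottle.pressure) * 1e6


def series_from_observations(
    gas: str,
    observations: Sequence[tuple[float, float]],
    bottle: BottleState | None = None,
    sample_volume: float = 0.002,
    bottle_id: str = "",
) -> HeadspaceSeries:
    """Convenience constructor from ``[(time_h, mixing_ratio_ppmv), ...]``."""
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ValueError("observations must be (time, mixing_ratio) pairs")
    return HeadspaceSeries(
        gas=gas,
        bottle=bottle if bottle is not None else BottleState(),
        times_h=obs[:, 0],
        mixing_ratios_ppmv=obs[:, 1],
        sample_volume=sample_volume,
        bottle_id=bottle_id,
    )
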