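"""Absolute cell counts and single-cell dry mass.

Cell numbers on filters are estimated from bead-spiked flow-cytometry
records: a known number of counting beads is added to the cell suspension
and the acquired bead fraction scales the acquired cell count back to the
whole filter, ``x_filter = (b_abs / b_c) * x_c``.

Single-cell dry mass comes from buoyant masses measured in two fluids of
known density (an H2O-based and a D2O-based buffer).  Because buoyant mass
is ``m_dry - rho_fluid * V_dry``, two fluids solve for the dry mass:

    m_dry = (rho_D2O * m_b.H2O - rho_H2O * m_b.D2O) / (rho_D2O - rho_H2O)

The population statistic is the median of each single-cell buoyant-mass
distribution, taken before the dry-mass formula (the two aliquots are
measured separately, so cells are not individually paired).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .energetics import CARBON_MOLAR_MASS

#: Default fluid densities at 20 C, g cm-3 (1x PBS in H2O / in 9:1 D2O:H2O).
RHO_H2O = 1.0043
RHO_D2O = 1.1033


@dataclass(frozen=True)
class CellCountRecord:
    """One bead-spiked cytometry acquisition."""

    beads_added: float  # b_abs
    beads_counted: float  # b_c
    cells_counted: float  # x_c
    sample_id: str = ""

    def __post_init__(self) -> None:
        if min(self.beads_added, self.beads_counted, self.cells_counted) < 0:
            raise ValueError("counts must be >= 0")
        if self.beads_counted > self.beads_added:
            raise ValueError(
                f"beads counted ({self.beads_counted}) exceed beads added "
                f"({self.beads_added})"
            )


def count_cells(record: CellCountRecord) -> float:
    """Absolute cell number on the filter: ``(b_abs / b_c) * x_c``."""
    if record.beads_counted == 0:
        raise ZeroDivisionError("no beads counted: cannot scale the cell count")
    return record.beads_added / record.beads_counted * record.cells_counted


@dataclass(frozen=True)
class BuoyantMassPair:
    """Median buoyant masses (fg) of one population in the two fluids."""

    mb_h2o: float  # fg
    mb_d2o: float  # fg
    rho_h2o: float = RHO_H2O  # g cm-3
    rho_d2o: float = RHO_D2O  # g cm-3

    def __post_init__(self) -> None:
        for rho in (self.rho_h2o, self.rho_d2o):
            if not 0.9 < rho < 1.3:
                raise ValueError(f"fluid density {rho} g cm-3 outside (0.9, 1.3)")
        if self.rho_d2o <= self.rho_h2o:
            raise ValueError("the D2O-based fluid must be denser than the H2O-based one")


def dry_mass(pair: BuoyantMassPair) -> float:
    """Single-cell dry mass (fg) from a pair of buoyant masses.

    A negative result is physically inconsistent (it implies the cell is
    less dense than both fluids in a contradictory way, usually from
    mis-specified densities) and is flagged with a warning, not clipped.
    """
    denom = pair.rho_d2o - pair.rho_h2o
    m = (pair.rho_d2o * pair.mb_h2o - pair.rho_h2o * pair.mb_d2o) / denom
    if m < 0:
        warnings.warn(
            f"negative dry mass ({m:.3g} fg): check fluid densities and "
            "aliquot labels",
            stacklevel=2,
        )
    return m


def dry_mass_from_distributions(
    masses_h2o_fg: Sequence[float],
    masses_d2o_fg: Sequence[float],
    rho_h2o: float = RHO_H2O,
    rho_d2o: float = RHO_D2O,
) -> float:
    """Population dry mass (fg): medians of the two buoyant-mass
    distributions, then the two-fluid formula."""
    pair = BuoyantMassPair(
        mb_h2o=float(np.median(np.asarray(masses_h2o_fg, dtype=float))),
        mb_d2o=float(np.median(np.asarray(masses_d2o_fg, dtype=float))),
        rho_h2o=rho_h2o,
        rho_d2o=rho_d2o,
    )
    return dry_mass(pair)


@dataclass(frozen=True)
class CellComposition:
    """Dry mass and carbon content of a strain's cells."""

    dry_mass_fg: float
    carbon_fraction: float  # g C per g dry mass

    def __post_init__(self) -> None:
        if self.dry_mass_fg <= 0:
            raise ValueError("dry mass must be > 0")
        if not 0 < self.carbon_fraction < 1:
            raise ValueError("carbon fraction must lie strictly in (0, 1)")

    @property
    def cmol_per_cell(self) -> float:
        return cmol_per_cell(self.dry_mass_fg, self.carbon_fraction)


def cmol_per_cell(dry_mass_fg: float, carbon_fraction: float) -> float:
    """Carbon-moles of biomass per cell: ``m_dry * f_C / 12.011`` (m in g)."""
    if not 0 < carbon_fraction < 1:
        raise ValueError("carbon fraction must lie strictly in (0, 1)")
    if dry_mass_fg < 0:
        raise ValueError("dry mass must be >= 0")
    return dry_mass_fg * 1e-15 * carbon_fraction / CARBON_MOLAR_MASS


#: Typical bacterial carbon fraction used when no strain value is supplied.
DEFAULT_CARBON_FRACTION = 0.48


def default_composition(dry_mass_fg: float) -> CellComposition:
    """Composition with the generic 0.48 g C / g dry mass carbon fraction.

    Strain-specific carbon fractions should be supplied whenever measured;
    the default is a typical bacterial value, not a measurement.
    """
    warnings.warn(
        "using the generic carbon fraction 0.48 g/g; supply a strain-specific "
        "measured value for quantitative per-C-mol yields",
        stacklevel=2,
    )
    return CellComposition(dry_mass_fg=dry_mass_fg, carbon_fraction=DEFAULT_CARBON_FRACTION)
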