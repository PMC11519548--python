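"""Synthetic datasets with the statistical structure the analysis assumes.

Emulates the four raw-data modalities of the study so every estimator can
be exercised without instrument data: exponential trace-gas depletion in
closed bottles with multiplicative (log-normal) gas-chromatograph noise
and discrete sampling-pressure drops; Michaelis-Menten rate observations
on the incubation concentration grid; unimodal single-cell buoyant-mass
distributions in H2O- and D2O-based fluids; and bead/cell subsampling by
a flow cytometer.

All generators are deterministic given a seed (one
``numpy.random.Generator`` per scenario).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biomass import RHO_D2O, RHO_H2O, CellCountRecord
from .gas_budget import (
    BottleState,
    GasRegistry,
    HeadspaceSeries,
    default_registry,
    dissolved_concentration,
)

#: Approximate trace-gas spike used for oxidation experiments (1 mL of
#: 1000 p.p.m.v. gas into a 0.2 L headspace on top of ambient background).
DEFAULT_SPIKE_PPMV = 5.0

#: Headspace mixing-ratio grid of the kinetics experiments (p.p.m.v.).
MM_PPMV_GRID = (1.9, 14.0, 30.0, 70.0, 175.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Shared scenario settings; one seeded random stream per scenario."""

    seed: int = 0
    noise_sd: float = 0.02  # multiplicative log-normal sd (fraction)
    times_h: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0, 96.0, 120.0)
    sample_volume_l: float = 0.002
    bottle: BottleState = field(default_factory=BottleState)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def simulate_incubation(
    k_per_gas: Mapping[str, float],
    config: SimulationConfig = SimulationConfig(),
    c0_ppmv: float | Mapping[str, float] = DEFAULT_SPIKE_PPMV,
) -> dict[str, HeadspaceSeries]:
    """Closed-bottle depletion series, one per gas.

    Mixing ratios follow ``C(t) = C0 * exp(-k t)`` perturbed by
    multiplicative log-normal noise at each scheduled observation.  The
    mixing ratio itself is unaffected by syringe sampling (withdrawal
    removes all gases proportionally); the sampling-pressure drops are
    carried on the returned series via ``sample_volume`` so molar budgets
    downstream apply the correction.
    """
    rng = config.rng()
    t = np.asarray(config.times_h, dtype=float)
    out: dict[str, HeadspaceSeries] = {}
    for gas, k in k_per_gas.items():
        c0 = c0_ppmv[gas] if isinstance(c0_ppmv, Mapping) else c0_ppmv
        truth = c0 * np.exp(-k * t)
        noisy = truth * np.exp(rng.normal(0.0, config.noise_sd, size=t.size))
        out[gas] = HeadspaceSeries(
            gas=gas,
            bottle=config.bottle,
            times_h=t,
            mixing_ratios_ppmv=noisy,
            sample_volume=config.sample_volume_l,
            bottle_id=f"sim-{config.seed}",
        )
    return out


def simulate_mm_observations(
    km_nm: float = 48.54,
    vmax_nmol: float = 4.91e-8,
    config: SimulationConfig = SimulationConfig(noise_sd=0.05),
    ppmv_grid: Sequence[float] = MM_PPMV_GRID,
    replicates: int = 2,
    registry: GasRegistry | None = None,
    strain: str = "sim",
) -> pd.DataFrame:
    """Michaelis-Menten observation table on the incubation design grid.

    Headspace mixing ratios are converted to dissolved nM via Henry's law
    (the substrate axis of the kinetics analysis) and per-cell rates are
    ``V_max S / (K_m + S)`` with multiplicative log-normal noise.
    Columns: strain, replicate, substrate_nM, rate_nmol_per_cell_h.
    """
    registry = registry if registry is not None else default_registry()
    ch4 = registry["CH4"]
    rng = config.rng()
    rows = []
    for rep in range(replicates):
        for ppmv in ppmv_grid:
            s = dissolved_concentration(ppmv, config.bottle, ch4)
            v = vmax_nmol * s / (km_nm + s)
            v_obs = v * float(np.exp(rng.normal(0.0, config.noise_sd)))
            rows.append(
                {
                    "strain": strain,
                    "replicate": rep,
                    "substrate_nM": s,
                    "rate_nmol_per_cell_h": v_obs,
                }
            )
    return pd.DataFrame(rows)


def simulate_buoyant_masses(
    true_dry_mass_fg: float = 180.0,
    cv: float = 0.3,
    n_cells: int = 500,
    config: SimulationConfig = SimulationConfig(noise_sd=0.01),
    dry_density: float = 1.4,  # g cm-3
    rho_h2o: float = RHO_H2O,
    rho_d2o: float = RHO_D2O,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-aliquot buoyant-mass lists (fg) in the two measurement fluids.

    Cell dry masses are log-normal with median ``true_dry_mass_fg`` and
    coefficient of variation ``cv``; two independent aliquots are drawn
    (the instrument measures separate aliquots, cells are not paired) and
    converted to buoyant masses via ``m_b = m_dry * (1 - rho_fluid /
    rho_dry)``, then perturbed by multiplicative measurement noise.
    """
    if not rho_h2o < dry_density and not rho_d2o < dry_density:
        raise ValueError("dry density should exceed the fluid densities")
    rng = config.rng()
    sigma = np.sqrt(np.log1p(cv**2))
    out = []
    for rho in (rho_h2o, rho_d2o):
        dry = true_dry_mass_fg * np.exp(rng.normal(0.0, sigma, size=n_cells))
        buoyant = dry * (1.0 - rho / dry_density)
        buoyant *= np.exp(rng.normal(0.0, config.noise_sd, size=n_cells))
        out.append(buoyant)
    return out[0], out[1]


def simulate_bead_mixture(
    true_cells: int = 20_000,
    beads_added: int = 50_000,
    acquisition_fraction: float = 0.1,
    config: SimulationConfig = SimulationConfig(),
) -> CellCountRecord:
    """Bead-spiked cytometry acquisition by binomial subsampling.

    Beads and cells are acquired independently at a common fraction; the
    returned record feeds the bead-ratio cell-count estimator, which is
    unbiased because the same fraction governs both populations.
    """
    if not 0 < acquisition_fraction <= 1:
        raise ValueError("acquisition fraction must lie in (0, 1]")
    rng = config.rng()
    if acquisition_fraction == 1.0:
        beads_counted, cells_counted = beads_added, true_cells
    else:
        beads_counted = int(rng.binomial(beads_added, acquisition_fraction))
        cells_counted = int(rng.binomial(true_cells, acquisition_fraction))
    return CellCountRecord(
        beads_added=beads_added,
        beads_counted=beads_counted,
        cells_counted=cells_counted,
        sample_id=f"sim-{config.seed}",
    )
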