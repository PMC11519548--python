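"""Oxidation kinetics: first-order rate constants and Michaelis-Menten fits.

Pseudo-first-order consumption rate constants are estimated from headspace
time series by ordinary least squares on the integrated rate law
``ln C_t = ln C_0 - k t``.  Mixing ratios are used as the concentration
variable: syringe sampling removes all gases proportionally, so the mixing
ratio carries the pure consumption signal while the sampling-pressure
correction enters the molar budget (rates in mol h-1).

Whole-cell Michaelis-Menten kinetics ``v = V_max S / (K_m + S)`` are fit
by Levenberg-Marquardt nonlinear least squares (unweighted), yielding the
apparent half-saturation constant K_m(app) (nM dissolved), the maximum
per-cell rate V_max(app) (nmol cell-1 h-1), and the specific affinity
a0_A = V_max / K_m (L cell-1 h-1), the volume of medium cleared of
substrate per cell per hour.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np

from .errors import FitFailureError, InsufficientDataError, LogDomainError
from .gas_budget import BottleState, HeadspaceSeries, moles_in_headspace


@dataclass(frozen=True)
class FirstOrderFit:
    """Estimated first-order consumption kinetics for one series."""

    k: float  # h-1; >= 0 for consumption
    c0: float  # fitted initial mixing ratio, p.p.m.v.
    r_squared: float
    n_obs: int
    gas: str = ""
    bottle_id: str = ""


@dataclass(frozen=True)
class MichaelisMentenFit:
    """Apparent Michaelis-Menten parameters for whole-cell oxidation."""

    km_app: float  # nM
    vmax_app: float  # nmol cell-1 h-1
    specific_affinity: float  # L cell-1 h-1
    standard_errors: Mapping[str, float | None] = field(default_factory=dict)
    n_obs: int = 0
    r_squared: float = float("nan")

    def predict(self, substrate_nm):
        s = np.asarray(substrate_nm, dtype=float)
        return self.vmax_app * s / (self.km_app + s)


@dataclass(frozen=True)
class CellRate:
    """A bottle-level oxidation rate divided over the counted cells."""

    rate_per_cell: float  # mol cell-1 h-1
    cell_count: float
    rate_total: float  # mol h-1


def fit_first_order_xy(
    times_h: Sequence[float], mixing_ratios_ppmv: Sequence[float]
) -> tuple[float, float, float]:
    """Log-linear OLS of the integrated first-order rate law.

    Returns ``(k, c0, r_squared)``; exact for noiseless exponential input
    and identical to the closed form ``k = ln(C1/C2) / (t2 - t1)`` for two
    points.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(mixing_ratios_ppmv, dtype=float)
    if t.size < 2:
        raise InsufficientDataError("need at least 2 observations to fit a rate")
    if np.any(c <= 0):
        raise LogDomainError(
            "non-positive mixing ratio in series; truncate the series at "
            "depletion before fitting the integrated rate law"
        )
    log_c = np.log(c)
    slope, intercept = np.polyfit(t, log_c, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((log_c - fitted) ** 2))
    ss_tot = float(np.sum((log_c - log_c.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return -float(slope), float(np.exp(intercept)), r2


def fit_first_order(series: HeadspaceSeries) -> FirstOrderFit:
    """Fit ``ln C_t = ln C_0 - k t`` to one headspace series.

    A negative fitted k (net production) is reported with a warning rather
    than clamped, preserving its diagnostic value.
    """
    k, c0, r2 = fit_first_order_xy(series.times_h, series.mixing_ratios_ppmv)
    if k < 0:
        warnings.warn(
            f"fitted k = {k:.4g} h-1 is negative (net production) for "
            f"{series.gas} {series.bottle_id!r}",
            stacklevel=2,
        )
    return FirstOrderFit(
        k=k,
        c0=c0,
        r_squared=r2,
        n_obs=len(series),
        gas=series.gas,
        bottle_id=series.bottle_id,
    )


def rate_at_mixing_ratio(
    fit: FirstOrderFit, mixing_ratio_ppmv: float, bottle: BottleState
) -> float:
    """Instantaneous consumption rate (mol h-1) the bottle would sustain
    at the stated mixing ratio: ``k * n_headspace(x)``.

    Used with the registry's atmospheric mixing ratios to express rates at
    atmospheric trace-gas levels.
    """
    return fit.k * moles_in_headspace(mixing_ratio_ppmv, bottle)


def per_cell_rate(rate_total: float, cell_count: float) -> CellRate:
    """Divide a bottle-level oxidation rate over the counted cells."""
    if cell_count <= 0:
        raise ValueError("cell count must be > 0")
    return CellRate(
        rate_per_cell=rate_total / cell_count,
        cell_count=cell_count,
        rate_total=rate_total,
    )


def _mm_model(s, km, vmax):
    return vmax * s / (km + s)


def fit_michaelis_menten(
    substrate_nm: Sequence[float],
    rate_nmol_per_cell_h: Sequence[float],
    start: tuple[float, float] | None = None,
) -> MichaelisMentenFit:
    """Nonlinear least-squares fit of ``v = V_max S / (K_m + S)``.

    Parameters
    ----------
    substrate_nm : sequence
        Dissolved substrate concentrations, nM.
    rate_nmol_per_cell_h : sequence
        Per-cell oxidation rates, nmol cell-1 h-1.
    start : (km, vmax), optional
        Start values; defaults to ``(median(S), max(v))``.

    Residuals are unweighted.  Negative parameter estimates are flagged
    with a warning rather than constrained away.
    """
    s = np.asarray(substrate_nm, dtype=float)
    v = np.asarray(rate_nmol_per_cell_h, dtype=float)
    if s.size != v.size:
        raise ValueError("substrate and rate vectors must have equal length")
    if s.size < 3:
        raise InsufficientDataError("need at least 3 points for a Michaelis-Menten fit")
    if s.max() < 5 * s.min():
        warnings.warn(
            "substrate concentrations span less than a 5-fold range; "
            "K_m and V_max may be poorly identified",
            stacklevel=2,
        )
    km0, vmax0 = start if start is not None else (float(np.median(s)), float(v.max()))
    model = lmfit.Model(_mm_model, independent_vars=["s"])
    params = model.make_params(km=km0, vmax=vmax0)
    result = model.fit(v, params, s=s)
    if not result.success:
        raise FitFailureError(
            f"Michaelis-Menten fit did not converge: {result.message}",
            residuals=result.residual,
        )
    km = float(result.params["km"].value)
    vmax = float(result.params["vmax"].value)
    if km <= 0 or vmax <= 0:
        warnings.warn(
            f"non-positive parameter estimate (K_m={km:.4g}, V_max={vmax:.4g}); "
            "check the concentration design",
            stacklevel=2,
        )
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else 1.0 - float(np.sum(result.residual**2)) / ss_tot
    return MichaelisMentenFit(
        km_app=km,
        vmax_app=vmax,
        specific_affinity=specific_affinity(km, vmax),
        standard_errors={
            "km": result.params["km"].stderr,
            "vmax": result.params["vmax"].stderr,
        },
        n_obs=int(s.size),
        r_squared=r2,
    )


def specific_affinity(km_app_nm: float, vmax_app_nmol: float) -> float:
    """Specific affinity a0_A = V_max(app) / K_m(app), L cell-1 h-1.

    With V_max in nmol cell-1 h-1 and K_m in nM (nmol L-1) the units cancel
    directly to L cell-1 h-1.
    """
    if km_app_nm == 0:
        raise ZeroDivisionError("K_m(app) must be nonzero")
    return vmax_app_nmol / km_app_nm
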