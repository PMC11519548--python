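"""Delimited-text readers/writers and run configuration.

All tables are comma-separated UTF-8 with "." decimals and units stated
in the headers: times in hours, mixing ratios in p.p.m.v., dissolved
concentrations in nM, masses in fg.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import ParseError, SchemaError
from .gas_budget import (
    BottleState,
    GasRegistry,
    HeadspaceSeries,
    default_registry,
)

log = logging.getLogger("airmob")

TIMESERIES_COLUMNS = ["bottle_id", "gas", "time_h", "mixing_ratio_ppmv"]
KINETICS_COLUMNS = ["strain", "replicate", "substrate_nM", "rate_nmol_per_cell_h"]
COUNTS_COLUMNS = ["sample_id", "beads_added", "beads_counted", "cells_counted"]
ISOTOPE_COLUMNS = ["roi_id", "c15n_counts", "c14n_counts"]


@dataclass
class RunConfig:
    """Configuration for a pipeline run."""

    registry: GasRegistry = field(default_factory=default_registry)
    bottle: BottleState = field(default_factory=BottleState)
    sample_volume_l: float = 0.002
    temperature: float = 293.15  # K
    pressure: float = 1.013  # bar, for in-situ energetics
    seed: int = 0
    out_dir: Path = Path(".")

    def __post_init__(self) -> None:
        if not 273.0 < self.temperature < 323.0:
            raise ValueError(
                f"temperature {self.temperature} K outside the supported range"
            )


def load_run_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file plus keyword overrides.

    Recognized keys: ``registry`` (path to a gas-registry YAML), ``bottle``
    (headspace_volume_l, liquid_volume_l, pressure_bar, temperature_k),
    ``sample_volume_l``, ``temperature_k``, ``pressure_bar``, ``seed``.
    """
    cfg: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
    registry = (
        GasRegistry.from_yaml(cfg["registry"]) if "registry" in cfg else default_registry()
    )
    b = cfg.get("bottle", {})
    temperature = overrides.get("temperature", cfg.get("temperature_k", 293.15))
    bottle = BottleState(
        headspace_volume=b.get("headspace_volume_l", 0.2),
        liquid_volume=b.get("liquid_volume_l", 0.05),
        pressure=b.get("pressure_bar", 1.05),
        temperature=b.get("temperature_k", temperature),
    )
    return RunConfig(
        registry=registry,
        bottle=bottle,
        sample_volume_l=overrides.get(
            "sample_volume_l", cfg.get("sample_volume_l", 0.002)
        ),
        temperature=temperature,
        pressure=overrides.get("pressure", cfg.get("pressure_bar", 1.013)),
        seed=overrides.get("seed", cfg.get("seed", 0)),
        out_dir=Path(overrides.get("out_dir", cfg.get("out_dir", "."))),
    )


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _coerce_numeric(df: pd.DataFrame, columns, path, strict: bool) -> pd.DataFrame:
    """Coerce columns to float; malformed rows are reported by line number
    and either raise (strict) or are dropped with a warning."""
    coerced = df.copy()
    bad_rows = pd.Series(False, index=df.index)
    for col in columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        bad_rows |= bad | df[col].isna()
        coerced[col] = values
    if bad_rows.any():
        # +2: one for the header row, one for 1-based numbering
        lines = [int(i) + 2 for i in df.index[bad_rows]]
        msg = f"{path}: malformed numeric value(s) on line(s) {lines}"
        if strict:
            raise ParseError(msg)
        log.warning("%s; dropping %d row(s)", msg, int(bad_rows.sum()))
        coerced = coerced[~bad_rows]
    return coerced


def read_timeseries(
    path: str | Path,
    bottles: Mapping[str, BottleState] | BottleState | None = None,
    sample_volume_l: float = 0.002,
    strict: bool = True,
) -> list[HeadspaceSeries]:
    """Read a headspace time-series table into typed series.

    One series per (bottle_id, gas) pair, rows kept in input order.
    ``bottles`` maps bottle_id to its geometry (or one shared
    :class:`BottleState`); defaults to the standard incubation bottle.
    """
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    _require_columns(df, TIMESERIES_COLUMNS, path)
    df = _coerce_numeric(df, ["time_h", "mixing_ratio_ppmv"], path, strict)
    series = []
    for (bottle_id, gas), group in df.groupby(["bottle_id", "gas"], sort=False):
        if isinstance(bottles, Mapping):
            bottle = bottles.get(bottle_id, BottleState())
        else:
            bottle = bottles if bottles is not None else BottleState()
        series.append(
            HeadspaceSeries(
                gas=str(gas),
                bottle=bottle,
                times_h=group["time_h"].to_numpy(dtype=float),
                mixing_ratios_ppmv=group["mixing_ratio_ppmv"].to_numpy(dtype=float),
                sample_volume=sample_volume_l,
                bottle_id=str(bottle_id),
            )
        )
    return series


def write_timeseries(series: list[HeadspaceSeries], path: str | Path) -> None:
    rows = [
        {
            "bottle_id": s.bottle_id,
            "gas": s.gas,
            "time_h": t,
            "mixing_ratio_ppmv": x,
        }
        for s in series
        for t, x in zip(s.times_h, s.mixing_ratios_ppmv)
    ]
    pd.DataFrame(rows, columns=TIMESERIES_COLUMNS).to_csv(path, index=False)


def read_kinetics_table(path: str | Path, strict: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    _require_columns(df, KINETICS_COLUMNS, path)
    return _coerce_numeric(df, ["substrate_nM", "rate_nmol_per_cell_h"], path, strict)


def read_counts_table(path: str | Path, strict: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    _require_columns(df, COUNTS_COLUMNS, path)
    return _coerce_numeric(
        df, ["beads_added", "beads_counted", "cells_counted"], path, strict
    )


def read_isotope_table(path: str | Path, strict: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    _require_columns(df, ISOTOPE_COLUMNS, path)
    return _coerce_numeric(df, ["c15n_counts", "c14n_counts"], path, strict)
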