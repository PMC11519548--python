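"""15N enrichment from secondary-ion counts.

Atom percent 15N of a cell (region of interest) is computed from the
12C15N- and 12C14N- ion counts as ``100 * c15n / (c15n + c14n)``; counts
are assumed dead-time/QSA-corrected upstream.  Per region, counts are
summed over acquisition cycles before taking the ratio (ratio of sums:
the lower-variance estimator for count data).

A region counts as labeled when its atom percent exceeds the unlabeled
baseline mean by more than ``threshold_sd`` standard deviations (default
3, the conventional detection limit).
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import UndefinedFractionError

#: Natural abundance of 15N in air N2, at%.
NATURAL_ABUNDANCE_15N = 0.366


@dataclass(frozen=True)
class IsotopeCounts:
    """Summed ion counts for one region of interest (one cell)."""

    c15n: float  # 12C15N- counts
    c14n: float  # 12C14N- counts
    roi_id: str = ""

    def __post_init__(self) -> None:
        if self.c15n < 0 or self.c14n < 0:
            raise ValueError("ion counts must be >= 0")


@dataclass(frozen=True)
class EnrichmentBaseline:
    """Unlabeled-population baseline, at% (mean +/- 1 SD).

    Default: 0.369 +/- 0.043 at%, the natural-abundance value measured on
    unlabeled cells.
    """

    mean_at_percent: float = 0.369
    sd_at_percent: float = 0.043

    def __post_init__(self) -> None:
        if not 0 < self.mean_at_percent < 100:
            raise ValueError("baseline mean must lie in (0, 100) at%")
        if self.sd_at_percent <= 0:
            raise ValueError("baseline SD must be > 0")


def atom_percent_15n(counts: IsotopeCounts) -> float:
    """15N atom percent: ``100 * c15n / (c15n + c14n)``, bounded in [0, 100]."""
    total = counts.c15n + counts.c14n
    if total <= 0:
        raise UndefinedFractionError(
            f"zero total ion counts for ROI {counts.roi_id!r}"
        )
    return 100.0 * counts.c15n / total


def classify_enrichment(
    at_percent: float,
    baseline: EnrichmentBaseline = EnrichmentBaseline(),
    threshold_sd: float = 3.0,
) -> bool:
    """True ("labeled") iff strictly above mean + threshold_sd * SD."""
    return at_percent > baseline.mean_at_percent + threshold_sd * baseline.sd_at_percent


def headspace_label_fraction(
    air_n2_volume_ml: float,
    label_volume_ml: float,
    label_purity_at_percent: float = 98.0,
    natural_abundance_at_percent: float = NATURAL_ABUNDANCE_15N,
) -> float:
    """15N atom percent of headspace N2 after adding labeled N2 gas.

    Volumes proxy for moles at equal pressure and temperature:
    ``(V_label * purity + V_air_N2 * natural) / (V_label + V_air_N2)``.
    Bounded between natural abundance and label purity, monotone in the
    label volume.
    """
    if air_n2_volume_ml < 0 or label_volume_ml < 0:
        raise ValueError("volumes must be >= 0")
    total = air_n2_volume_ml + label_volume_ml
    if total == 0:
        raise ValueError("no N2 present")
    return (
        label_volume_ml * label_purity_at_percent
        + air_n2_volume_ml * natural_abundance_at_percent
    ) / total
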