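"""Exposure metrics on gridded PM2.5 and population fields.

Population-weighted means, threshold exceedance, block coarsening for the
resolution sensitivity, and the concentration-cap sensitivity transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .grids import GriddedField, GridSpec

#: The seven emission sectors that are zeroed out one at a time:
#: agriculture, biomass burning, dust, power generation, industry
#: (non-power), residential energy use, land transport.
SECTORS = ("AGR", "BBU", "DUS", "ENE", "IND", "RES", "TRA")


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties away from zero (as printed tables do)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ScenarioSet:
    """The control PM2.5 field plus the seven sector-off fields.

    All fields share one grid; sector labels are exactly ``SECTORS``.
    """

    control: GriddedField
    sector_off: Mapping[str, GriddedField]

    def __post_init__(self) -> None:
        if set(self.sector_off) != set(SECTORS):
            raise ValueError(f"sector labels must be exactly {SECTORS}")
        for name, f in self.sector_off.items():
            if f.spec != self.control.spec:
                raise ValueError(f"sector field {name} is on a different grid")

    @property
    def spec(self) -> GridSpec:
        return self.control.spec


def _check_grids(*fields: GriddedField) -> None:
    spec = fields[0].spec
    for f in fields[1:]:
        if f.spec != spec:
            raise ValueError("fields are defined on different grids")


def population_weighted_mean(conc: GriddedField, pop: GriddedField) -> float:
    """Sum(c * P) / Sum(P) over grid cells, in ug m^-3.

    Cells with zero population contribute nothing; the result lies within
    the concentration range of the populated cells.
    """
    _check_grids(conc, pop)
    total = pop.values.sum()
    if total <= 0:
        raise ValueError("total population must be positive")
    return float((conc.values * pop.values).sum() / total)


def sector_reduction(
    scen: ScenarioSet, pop: GriddedField, sector: str
) -> tuple[float, float]:
    """Population-weighted PM2.5 reduction from removing one sector.

    Returns ``(absolute ug m^-3, fraction of control)``.  The fraction is
    the quantity the attribution method scales total mortality by.
    """
    if sector not in scen.sector_off:
        raise KeyError(f"unknown sector {sector!r}")
    pwm_control = population_weighted_mean(scen.control, pop)
    pwm_off = population_weighted_mean(scen.sector_off[sector], pop)
    absolute = pwm_control - pwm_off
    return absolute, absolute / pwm_control


def exceedance_fraction(
    conc: GriddedField, pop: GriddedField, threshold: float
) -> float:
    """Fraction of the population living in cells with c > threshold."""
    _check_grids(conc, pop)
    total = pop.values.sum()
    if total <= 0:
        raise ValueError("total population must be positive")
    return float(pop.values[conc.values > threshold].sum() / total)


def cap_concentrations(field: GriddedField, cap: float) -> GriddedField:
    """Clip concentrations at ``cap`` cell-wise (idempotent).

    This is the sensitivity transform that forces annual means not to
    exceed a stated ceiling (e.g. 80 or 50 ug m^-3) everywhere.
    """
    if cap < 0:
        raise ValueError("cap must be non-negative")
    return field.copy_with(np.minimum(field.values, cap))


def coarsen(field: GriddedField, factor: int, mode: str) -> GriddedField:
    """Aggregate a field onto a grid ``factor`` times coarser.

    mode="concentration" takes the area-weighted mean per block;
    mode="population" sums counts per block (exact conservation).  If the
    factor does not divide the grid shape, the field is padded and the
    padding is masked out (zero area weight / zero count).
    """
    if factor < 1:
        raise ValueError("coarsening factor must be >= 1")
    if mode not in ("concentration", "population"):
        raise ValueError("mode must be 'concentration' or 'population'")
    spec = field.spec
    n_lat = -(-spec.n_lat // factor) * factor
    n_lon = -(-spec.n_lon // factor) * factor
    pad = ((0, n_lat - spec.n_lat), (0, n_lon - spec.n_lon))
    values = np.pad(field.values, pad)

    new_spec = GridSpec(
        n_lat=n_lat // factor,
        n_lon=n_lon // factor,
        lat_min=spec.lat_min,
        lat_max=spec.lat_min + n_lat * spec.dlat,
        lon_min=spec.lon_min,
        lon_max=spec.lon_min + n_lon * spec.dlon,
    )
    blocks = values.reshape(n_lat // factor, factor, n_lon // factor, factor)
    if mode == "population":
        coarse = blocks.sum(axis=(1, 3))
    else:
        areas = np.pad(spec.cell_areas(), pad)  # padded cells get zero weight
        w = areas.reshape(n_lat // factor, factor, n_lon // factor, factor)
        coarse = (blocks * w).sum(axis=(1, 3)) / w.sum(axis=(1, 3))
    return GriddedField(coarse, new_spec)


def exposure_summary(scen: ScenarioSet, pop: GriddedField):
    """Per-sector population-weighted reductions, as a tidy table.

    Columns: sector, pwm_control, pwm_sector_off, reduction, fraction,
    percent (half-up integer, as printed).
    """
    import pandas as pd

    pwm_control = population_weighted_mean(scen.control, pop)
    rows = []
    for sector in SECTORS:
        absolute, fraction = sector_reduction(scen, pop, sector)
        rows.append(
            {
                "sector": sector,
                "pwm_control": pwm_control,
                "pwm_sector_off": pwm_control - absolute,
                "reduction": absolute,
                "fraction": fraction,
                "percent": round_half_up(100 * fraction),
            }
        )
    return pd.DataFrame(rows)
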