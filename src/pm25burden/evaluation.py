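"""Model-versus-observation statistics for surface PM2.5 evaluation.

Normalised mean bias, Pearson correlation and an ordinary-least-squares
best-fit slope over paired model/observation series, plus sampling of a
gridded field at monitoring-site coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

from .grids import GriddedField

SEASONS = ("annual", "DJF", "MAM", "JJA", "SON")


@dataclass
class PairedSeries:
    """Matched model/observed values at the same sites and season."""

    model: np.ndarray
    observed: np.ndarray
    season: str = "annual"

    def __post_init__(self) -> None:
        self.model = np.asarray(self.model, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        if self.model.shape != self.observed.shape or self.model.ndim != 1:
            raise ValueError("model and observed must be matched 1-D arrays")
        if self.model.size < 2:
            raise ValueError("at least two pairs are required")
        if not (np.all(np.isfinite(self.model)) and np.all(np.isfinite(self.observed))):
            raise ValueError("paired values must be finite")
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}")


def nmb(p: PairedSeries) -> float:
    """Normalised mean bias: sum(model - obs) / sum(obs)."""
    denom = p.observed.sum()
    if denom == 0:
        raise ValueError("observed values sum to zero; NMB undefined")
    return float((p.model - p.observed).sum() / denom)


def pearson_r(p: PairedSeries) -> float:
    """Pearson correlation coefficient; errors on a constant series."""
    if np.std(p.model) == 0 or np.std(p.observed) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(p.observed, p.model).statistic)


def best_fit_slope(p: PairedSeries) -> float:
    """OLS slope of model on observed (fit includes an intercept)."""
    if np.std(p.observed) == 0:
        raise ValueError("slope undefined for constant observations")
    return float(stats.linregress(p.observed, p.model).slope)


def week_seasons(n_weeks: int = 52) -> np.ndarray:
    """Meteorological season (DJF/MAM/JJA/SON) of each week of the year."""
    month_season = np.array(
        ["DJF", "DJF", "MAM", "MAM", "MAM", "JJA",
         "JJA", "JJA", "SON", "SON", "SON", "DJF"]
    )
    mid_day = np.arange(n_weeks) * 7 + 3.5
    month = np.clip((mid_day / 365.0 * 12).astype(int), 0, 11)
    return month_season[month]


def sample_at_sites(
    field: GriddedField, sites: pd.DataFrame, method: str = "bilinear"
) -> np.ndarray:
    """Sample a gridded field at site (lat, lon) coordinates.

    ``method`` is "bilinear" (between the four surrounding cell centres,
    edge-clamped) or "nearest".  Sites outside the grid bounds are
    rejected.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError("method must be 'bilinear' or 'nearest'")
    spec = field.spec
    lat = np.asarray(sites["lat"], dtype=float)
    lon = np.asarray(sites["lon"], dtype=float)
    if np.any(lat < spec.lat_min) or np.any(lat > spec.lat_max) or np.any(
        lon < spec.lon_min
    ) or np.any(lon > spec.lon_max):
        raise ValueError("site outside the grid bounds")
    interp = RegularGridInterpolator(
        (spec.lat_centers, spec.lon_centers),
        field.values,
        method="linear" if method == "bilinear" else "nearest",
        bounds_error=False,
        fill_value=None,  # clamp to the edge cells
    )
    return interp(np.column_stack([lat, lon]))


def evaluation_report(
    field_by_season: dict[str, GriddedField],
    obs: pd.DataFrame,
    method: str = "bilinear",
) -> pd.DataFrame:
    """NMB, Pearson r and OLS slope per season.

    ``obs`` is a long table (site_id, lat, lon, season, value); seasons
    without a model field are skipped.
    """
    rows = []
    for season, field in field_by_season.items():
        sel = obs[obs["season"] == season]
        if sel.empty:
            continue
        p = PairedSeries(
            model=sample_at_sites(field, sel, method=method),
            observed=sel["value"].to_numpy(),
            season=season,
        )
        rows.append(
            {
                "season": season,
                "n_sites": len(sel),
                "nmb": nmb(p),
                "pearson_r": pearson_r(p),
                "slope": best_fit_slope(p),
            }
        )
    return pd.DataFrame(rows)
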