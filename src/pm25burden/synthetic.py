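"""Synthetic inputs emulating the statistical structure of the real study data.

The real inputs — chemistry-transport model PM2.5 fields, gridded census
population, GBD exposure-response parameter files and baseline mortality
rates, monitoring-network observations — are external and licensed.
This module generates stand-ins with the features the downstream
analysis relies on:

* an annual-mean PM2.5 field with a high-concentration east–west band
  across the north (the Indo-Gangetic-Plain analogue, exceeding
  100 ug m^-3) over a lower background, spatially correlated;
* 52 weekly fields whose mean equals the annual field cell-wise;
* sector-off fields that are fractional reductions of the control, with
  sector shares defaulting to the study's population-weighted values;
* a heterogeneous population raster with dense urban cells
  (>= 400 persons km^-2) that sums exactly to the requested total;
* right-skewed (lognormal) IER parameter ensembles with uniform TMREL
  draws on [2.4, 5.9] ug m^-3 — a synthetic stand-in, NOT the GBD joint
  distribution;
* deterministic baseline-mortality and life tables with plausible
  age profiles, and noisy monitoring-site observations.

Every generator is deterministic given the configuration seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .burden import ADULT_AGE_GROUPS, AGE_GROUPS, AgeStructure, LifeTable
from .exposure import SECTORS, ScenarioSet
from .grids import GriddedField, GridSpec
from .ier import (
    AGE_SPECIFIC_DISEASES,
    DISEASES,
    IERParameterEnsemble,
    TMREL_HIGH,
    TMREL_LOW,
)

#: Default sector shares of population-weighted PM2.5 (fraction of the
#: control mean removed when the sector is switched off).  These are the
#: study conditions: reductions of 0.2, 1.6, 0.01, 12.0, 9.3, 29.5 and
#: 5.9 ug m^-3 against a 57.2 ug m^-3 control mean.
DEFAULT_SECTOR_FRACTIONS: dict[str, float] = {
    "AGR": 0.2 / 57.2,
    "BBU": 1.6 / 57.2,
    "DUS": 0.01 / 57.2,
    "ENE": 12.0 / 57.2,
    "IND": 9.3 / 57.2,
    "RES": 29.5 / 57.2,
    "TRA": 5.9 / 57.2,
}

#: Total population of India used in the study (persons, 2015).
INDIA_POPULATION = 1_302_000_000


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic-data generators.

    Defaults reproduce the study conditions: a polluted northern band
    peaking above 140 ug m^-3 over a ~25 ug m^-3 background, a
    population-weighted annual mean near 57 ug m^-3, weekly variability
    with a 0.3 coefficient of variation, and sector shares matching the
    population-weighted reductions of the zero-out runs.
    """

    seed: int = 0
    background_level: float = 25.0
    pollution_band_amplitude: float = 120.0
    band_lat: float = 27.0
    band_width: float = 2.0
    spatial_correlation_length: float = 3.0
    noise_sigma: float = 0.15
    weekly_cv: float = 0.3
    sector_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SECTOR_FRACTIONS)
    )
    sector_fraction_sigma: float = 0.15
    urban_fraction: float = 0.05
    urban_boost: float = 40.0
    population_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.pollution_band_amplitude < 0 or self.background_level < 0:
            raise ValueError("concentration amplitudes must be non-negative")
        if self.weekly_cv < 0:
            raise ValueError("weekly_cv must be non-negative")
        if self.noise_sigma < 0 or self.sector_fraction_sigma < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0 <= self.urban_fraction <= 1:
            raise ValueError("urban_fraction must lie in [0, 1]")
        for sector, f in self.sector_fractions.items():
            if not 0 <= f <= 1:
                raise ValueError(f"sector fraction for {sector} outside [0, 1]")
        total = sum(self.sector_fractions.values())
        if total > 1.05:
            warnings.warn(
                f"sector fractions sum to {total:.3f} > 1.05; sector-off fields "
                "will overlap substantially",
                stacklevel=2,
            )


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg_seed).spawn(stream + 1)[-1])


def _correlated_noise(
    rng: np.random.Generator, shape: tuple[int, int], corr_len: float
) -> np.ndarray:
    """Zero-mean, unit-variance stationary field via smoothed white noise."""
    white = rng.standard_normal(shape)
    if corr_len <= 0:
        return white
    smooth = gaussian_filter(white, sigma=corr_len, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def gen_pm25_control(
    spec: GridSpec, cfg: SyntheticConfig
) -> tuple[GriddedField, np.ndarray]:
    """Annual-mean control PM2.5 field plus its 52 weekly fields.

    The annual field is a background plus a Gaussian-in-latitude band
    modulated by correlated lognormal noise (so concentrations stay
    non-negative and a contiguous band exceeds 100 ug m^-3 whenever the
    band amplitude does).  Weekly fields are the annual mean times
    lognormal multiplicative noise with the configured coefficient of
    variation, renormalised per cell so the 52-week mean equals the
    annual mean exactly.
    """
    rng = _rng(cfg.seed, 0)
    lat = spec.lat_centers[:, None]
    profile = np.exp(-0.5 * ((lat - cfg.band_lat) / cfg.band_width) ** 2)
    profile = np.broadcast_to(profile, spec.shape)
    noise = _correlated_noise(rng, spec.shape, cfg.spatial_correlation_length)
    modulation = np.exp(cfg.noise_sigma * noise - cfg.noise_sigma**2 / 2)
    annual = cfg.background_level + cfg.pollution_band_amplitude * profile * modulation

    n_weeks = 52
    if cfg.weekly_cv == 0:
        weekly = np.repeat(annual[None, :, :], n_weeks, axis=0)
    else:
        sigma = np.sqrt(np.log(1 + cfg.weekly_cv**2))
        mult = np.exp(rng.normal(0.0, sigma, size=(n_weeks,) + spec.shape))
        mult /= mult.mean(axis=0, keepdims=True)  # exact weekly/annual consistency
        weekly = annual[None, :, :] * mult
    return GriddedField(annual, spec), weekly


def gen_sector_off_fields(
    control: GriddedField, cfg: SyntheticConfig
) -> ScenarioSet:
    """Sector-off fields: control times (1 - f_sector(cell)).

    Each sector's cell-wise removal fraction is the configured mean
    modulated by correlated lognormal noise (mean preserved), clipped to
    [0, 1], so sector-off concentrations stay within [0, control].
    """
    missing = set(SECTORS) - set(cfg.sector_fractions)
    if missing:
        raise ValueError(f"sector fractions missing for {sorted(missing)}")
    spec = control.spec
    fields = {}
    for k, sector in enumerate(SECTORS):
        f_mean = cfg.sector_fractions[sector]
        rng = _rng(cfg.seed, 10 + k)
        noise = _correlated_noise(rng, spec.shape, cfg.spatial_correlation_length)
        sigma = cfg.sector_fraction_sigma
        f_cell = np.clip(f_mean * np.exp(sigma * noise - sigma**2 / 2), 0.0, 1.0)
        fields[sector] = control.copy_with(control.values * (1.0 - f_cell))
    return ScenarioSet(control=control, sector_off=fields)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to weights, summing exactly to total."""
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quota = weights / weights.sum() * total
    alloc = np.floor(quota).astype(np.int64)
    short = total - int(alloc.sum())
    if short > 0:
        order = np.argsort(-(quota - alloc), kind="stable")
        alloc[order[:short]] += 1
    return alloc


def gen_population(
    spec: GridSpec, total: int, cfg: SyntheticConfig
) -> GriddedField:
    """Heterogeneous population raster summing exactly to ``total``.

    A correlated lognormal base (tilted toward the polluted band, as the
    dense northern plains are) with a random subset of cells boosted to
    urban densities; counts are integers allocated by largest remainder
    so conservation is exact.
    """
    if total < 0:
        raise ValueError("total population must be non-negative")
    rng = _rng(cfg.seed, 20)
    noise = _correlated_noise(rng, spec.shape, cfg.spatial_correlation_length)
    lat = spec.lat_centers[:, None]
    band = np.exp(-0.5 * ((lat - cfg.band_lat) / cfg.band_width) ** 2)
    base = np.exp(cfg.population_sigma * noise) * (0.6 + np.broadcast_to(band, spec.shape))
    n_urban = int(round(cfg.urban_fraction * base.size))
    if n_urban > 0:
        flat = base.ravel().copy()
        idx = rng.choice(base.size, size=n_urban, replace=False)
        flat[idx] *= cfg.urban_boost
        base = flat.reshape(spec.shape)
    counts = _largest_remainder(base, int(total)).reshape(spec.shape)
    return GriddedField(counts.astype(float), spec)


# ---------------------------------------------------------------------------
# IER parameter ensemble
# ---------------------------------------------------------------------------

#: Per-disease medians of (alpha, beta, gamma).  Chosen so the mean
#: curves have GBD-like shapes: RR around 1.5-1.9 at 60 ug m^-3,
#: saturating above ~50 ug m^-3 (synthetic stand-in, not GBD values).
IER_MEDIANS: dict[str, tuple[float, float, float]] = {
    "ALRI": (2.5, 0.045, 0.80),
    "IHD": (0.9, 0.045, 0.80),
    "CEV": (0.8, 0.045, 0.80),
    "COPD": (1.0, 0.035, 0.80),
    "LC": (0.7, 0.030, 0.85),
}

#: Geometric standard deviations (lognormal sigma) of the marginals.
IER_SIGMAS = {"alpha": 0.25, "beta": 0.30, "gamma": 0.10}


def _age_modifier(age_group: str) -> float:
    """Excess-risk attenuation with age for IHD/CEV (younger adults have
    proportionally larger excess risk)."""
    k = ADULT_AGE_GROUPS.index(age_group)
    return 1.6 - 1.1 * k / (len(ADULT_AGE_GROUPS) - 1)


def gen_ier_parameters(
    diseases: Sequence[str] = DISEASES,
    age_groups: Sequence[str] = ADULT_AGE_GROUPS,
    n_draws: int = 1000,
    seed: int = 0,
) -> IERParameterEnsemble:
    """Lognormal (alpha, beta, gamma) draws with uniform TMREL on [2.4, 5.9].

    IHD and CEV get one stratum per adult age group (alpha scaled by an
    age modifier); other diseases share a single "ALL" stratum.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be at least 2")
    rng = np.random.default_rng(seed)
    rows = []
    for disease in diseases:
        med_a, med_b, med_g = IER_MEDIANS[disease]
        strata = age_groups if disease in AGE_SPECIFIC_DISEASES else ["ALL"]
        for age_group in strata:
            a_med = med_a * (_age_modifier(age_group) if age_group != "ALL" else 1.0)
            alpha = a_med * np.exp(rng.normal(0, IER_SIGMAS["alpha"], n_draws))
            beta = med_b * np.exp(rng.normal(0, IER_SIGMAS["beta"], n_draws))
            gamma = med_g * np.exp(rng.normal(0, IER_SIGMAS["gamma"], n_draws))
            tmrel = rng.uniform(TMREL_LOW, TMREL_HIGH, n_draws)
            rows.append(
                pd.DataFrame(
                    {
                        "disease": disease,
                        "age_group": age_group,
                        "draw": np.arange(n_draws),
                        "alpha": alpha,
                        "beta": beta,
                        "gamma": gamma,
                        "tmrel": tmrel,
                    }
                )
            )
    return IERParameterEnsemble(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Baseline mortality, life table, age structure
# ---------------------------------------------------------------------------

#: Adult baseline mortality anchor rates (deaths per person-year) at
#: ages 25-29 and 80+; rates interpolate log-linearly between them.
_ADULT_RATE_ANCHORS = {
    "IHD": (2.0e-4, 2.2e-2),
    "CEV": (1.2e-4, 1.6e-2),
    "COPD": (6.0e-5, 1.6e-2),
    "LC": (1.0e-5, 1.1e-3),
}

#: ALRI rates per age group: dominated by the neonatal/infant groups.
_ALRI_RATES = {
    "EN": 2.5e-3, "LN": 1.5e-3, "PN": 9.0e-4, "1-4": 4.0e-4,
    "5-9": 4.0e-5, "10-14": 2.0e-5, "15-19": 2.0e-5, "20-24": 2.5e-5,
    "25-29": 3.0e-5, "30-34": 3.5e-5, "35-39": 4.0e-5, "40-44": 5.0e-5,
    "45-49": 7.0e-5, "50-54": 1.0e-4, "55-59": 1.5e-4, "60-64": 2.2e-4,
    "65-69": 3.5e-4, "70-74": 6.0e-4, "75-79": 1.0e-3, "80+": 2.0e-3,
}


def gen_baseline_mortality(
    diseases: Sequence[str] = DISEASES,
    age_groups: Sequence[str] = AGE_GROUPS,
) -> pd.DataFrame:
    """Deterministic baseline-mortality table with (mean, lower, upper).

    Adult disease rates rise log-linearly with age between plausible
    anchor values; ALRI is concentrated in the youngest groups.  Bounds
    are +/-15% of the mean, mirroring the defined upper/lower values the
    source tables carry.
    """
    rows = []
    n_adult = len(ADULT_AGE_GROUPS)
    for disease in diseases:
        if disease == "ALRI":
            groups = [g for g in age_groups]
            rates = {g: _ALRI_RATES[g] for g in groups}
        else:
            groups = [g for g in age_groups if g in ADULT_AGE_GROUPS]
            r0, r1 = _ADULT_RATE_ANCHORS[disease]
            rates = {
                g: r0 * (r1 / r0) ** (ADULT_AGE_GROUPS.index(g) / (n_adult - 1))
                for g in groups
            }
        for g in groups:
            mean = rates[g]
            rows.append(
                {
                    "disease": disease,
                    "age_group": g,
                    "mean": mean,
                    "lower": 0.85 * mean,
                    "upper": 1.15 * mean,
                }
            )
    return pd.DataFrame(rows)


#: Reference life expectancy remaining (years) per age group — a
#: synthetic approximation to a standard reference life table.
_REFERENCE_LE = {
    "EN": 86.6, "LN": 86.5, "PN": 86.3, "1-4": 85.0,
    "5-9": 81.3, "10-14": 76.3, "15-19": 71.4, "20-24": 66.5,
    "25-29": 61.5, "30-34": 56.6, "35-39": 51.7, "40-44": 46.9,
    "45-49": 42.1, "50-54": 37.4, "55-59": 32.7, "60-64": 28.1,
    "65-69": 23.6, "70-74": 19.2, "75-79": 15.1, "80+": 11.4,
}


def gen_life_table() -> LifeTable:
    """Reference life table: LE remaining, strictly decreasing with age."""
    return LifeTable(dict(_REFERENCE_LE))


#: India-like 2015 age composition (raw weights; normalised on use).
_AGE_WEIGHTS = {
    "EN": 0.0004, "LN": 0.0011, "PN": 0.0160, "1-4": 0.0780,
    "5-9": 0.0920, "10-14": 0.0940, "15-19": 0.0960, "20-24": 0.0950,
    "25-29": 0.0890, "30-34": 0.0790, "35-39": 0.0710, "40-44": 0.0620,
    "45-49": 0.0530, "50-54": 0.0450, "55-59": 0.0370, "60-64": 0.0300,
    "65-69": 0.0220, "70-74": 0.0150, "75-79": 0.0090, "80+": 0.0070,
}


def gen_age_structure() -> AgeStructure:
    """National age composition (fractions normalised to sum to 1)."""
    w = np.array([_AGE_WEIGHTS[g] for g in AGE_GROUPS])
    return AgeStructure(groups=AGE_GROUPS, fractions=w / w.sum())


def gen_observation_sites(
    field: GriddedField,
    n_sites: int = 45,
    noise_sd: float = 10.0,
    seed: int = 0,
    weekly: np.ndarray | None = None,
) -> pd.DataFrame:
    """Monitoring-site observations: bilinear field samples plus noise.

    Returns a long table (site_id, lat, lon, season, value) with an
    annual row per site and, when a weekly stack is given, one row per
    meteorological season.  Negative noisy values are floored at zero.
    """
    from .evaluation import sample_at_sites, week_seasons

    if n_sites < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(seed)
    spec = field.spec
    pad_lat = 0.5 * spec.dlat
    pad_lon = 0.5 * spec.dlon
    sites = pd.DataFrame(
        {
            "site_id": [f"S{i:03d}" for i in range(n_sites)],
            "lat": rng.uniform(spec.lat_min + pad_lat, spec.lat_max - pad_lat, n_sites),
            "lon": rng.uniform(spec.lon_min + pad_lon, spec.lon_max - pad_lon, n_sites),
        }
    )
    season_fields = {"annual": field}
    if weekly is not None:
        labels = week_seasons(weekly.shape[0])
        for season in ("DJF", "MAM", "JJA", "SON"):
            season_fields[season] = field.copy_with(
                weekly[labels == season].mean(axis=0)
            )
    rows = []
    for season, f in season_fields.items():
        values = sample_at_sites(f, sites, method="bilinear")
        values = np.maximum(values + rng.normal(0.0, noise_sd, n_sites), 0.0)
        for i in range(n_sites):
            rows.append(
                {
                    "site_id": sites["site_id"][i],
                    "lat": sites["lat"][i],
                    "lon": sites["lon"][i],
                    "season": season,
                    "value": values[i],
                }
            )
    return pd.DataFrame(rows)


def gen_regions(spec: GridSpec, n_lat_bands: int = 2, n_lon_bands: int = 2) -> dict:
    """Rectangular state-like regions tiling the grid, as GeoJSON."""
    from .regions import regions_to_geojson

    boxes = {}
    dlat = (spec.lat_max - spec.lat_min) / n_lat_bands
    dlon = (spec.lon_max - spec.lon_min) / n_lon_bands
    for i in range(n_lat_bands):
        for j in range(n_lon_bands):
            boxes[f"state_{i}{j}"] = (
                spec.lon_min + j * dlon,
                spec.lat_min + i * dlat,
                spec.lon_min + (j + 1) * dlon,
                spec.lat_min + (i + 1) * dlat,
            )
    return regions_to_geojson(boxes)
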