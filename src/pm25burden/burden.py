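"""Premature mortality and years of life lost from ambient PM2.5.

The core identity per grid cell ``i`` and disease endpoint ``j`` is

    M_ij = P_i * I_j * (RR_jc - 1) / RR_jc

with ``P`` the cell population, ``I`` the baseline mortality rate
(deaths per person-year) and ``RR`` the relative risk at the cell's
annual-mean concentration ``c``; ``(RR - 1)/RR`` is the population
attributable fraction.  Years of life lost multiply deaths by the life
expectancy remaining at the age of death:  YLL_ij = M_ij * LE.

ALRI burden is computed for all age groups; IHD, CEV, COPD and LC only
for adults 25 years and older, in 5-year age groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import GriddedField
from .ier import DISEASES, IERParameterEnsemble

#: Age groups: early/late/post-neonatal, 1-4, then 5-year bands to 80+.
AGE_GROUPS = (
    "EN", "LN", "PN", "1-4",
    "5-9", "10-14", "15-19", "20-24",
    "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80+",
)

#: 5-year adult groups (>= 25) to which IHD/CEV/COPD/LC apply.
ADULT_AGE_GROUPS = AGE_GROUPS[8:]

#: Urban definition: population density of at least 400 persons per km^2.
URBAN_DENSITY_THRESHOLD = 400.0

#: Baseline mortality rates for these diseases may be rescaled by
#: state-to-nation ratios in the state sensitivity; LC and ALRI keep the
#: national value.
STATE_SCALED_DISEASES = ("COPD", "IHD", "CEV")


def disease_age_groups(disease: str) -> tuple[str, ...]:
    """Age groups a disease endpoint applies to."""
    return AGE_GROUPS if disease == "ALRI" else ADULT_AGE_GROUPS


@dataclass
class AgeStructure:
    """Population fraction per age group (national composition).

    Fractions are non-negative and sum to 1; the same composition is
    applied in every grid cell.
    """

    groups: tuple[str, ...]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.groups) != len(self.fractions):
            raise ValueError("groups and fractions differ in length")
        if np.any(self.fractions < 0):
            raise ValueError("age fractions must be non-negative")
        if not np.isclose(self.fractions.sum(), 1.0, atol=1e-9):
            raise ValueError("age fractions must sum to 1")

    def fraction(self, group: str) -> float:
        return float(self.fractions[self.groups.index(group)])


class LifeTable:
    """Life expectancy remaining (years) per age group.

    Strictly positive and non-increasing with age.
    """

    def __init__(self, le_by_group: Mapping[str, float]):
        values = [le_by_group[g] for g in AGE_GROUPS if g in le_by_group]
        if any(v <= 0 for v in values):
            raise ValueError("life expectancy values must be positive")
        for a, b in zip(values, values[1:]):
            if b > a:
                raise ValueError("life expectancy must be non-increasing with age")
        self._le = dict(le_by_group)

    def le(self, group: str) -> float:
        return float(self._le[group])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_group": list(self._le), "le_remaining": list(self._le.values())}
        )


def validate_baseline_mortality(bm: pd.DataFrame) -> pd.DataFrame:
    """Check a baseline-mortality table (disease, age_group, mean, lower, upper)."""
    required = {"disease", "age_group", "mean", "lower", "upper"}
    if not required <= set(bm.columns):
        raise ValueError(f"baseline mortality table needs columns {sorted(required)}")
    if (bm[["mean", "lower", "upper"]] < 0).any().any():
        raise ValueError("baseline mortality rates must be non-negative")
    if ((bm["lower"] > bm["mean"]) | (bm["mean"] > bm["upper"])).any():
        raise ValueError("baseline mortality must satisfy lower <= mean <= upper")
    return bm


def attributable_fraction(rr) -> np.ndarray | float:
    """Population attributable fraction (RR - 1) / RR, equal to 1 - 1/RR."""
    rr_arr = np.asarray(rr, dtype=float)
    if np.any(rr_arr < 1.0):
        raise ValueError("relative risk must be >= 1")
    af = 1.0 - 1.0 / rr_arr
    return float(af) if np.isscalar(rr) or rr_arr.ndim == 0 else af


def mortality_cell(population: float, rate: float, rr: float) -> float:
    """Premature deaths per year in one cell/stratum: P * I * (RR-1)/RR."""
    if population < 0 or rate < 0:
        raise ValueError("population and baseline rate must be non-negative")
    return population * rate * attributable_fraction(rr)


def classify_urban(pop: GriddedField) -> np.ndarray:
    """Boolean mask: cell is urban iff density >= 400 persons km^-2."""
    density = pop.values / pop.spec.cell_areas()
    return density >= URBAN_DENSITY_THRESHOLD


def apply_state_scaling(
    bm: pd.DataFrame, ratios: Mapping[str, float]
) -> dict[str, pd.DataFrame]:
    """Region-specific baseline mortality via state-to-nation ratios.

    COPD, IHD and CEV rates (mean, lower and upper alike) are multiplied
    by each region's ratio; LC and ALRI keep the national values.
    """
    validate_baseline_mortality(bm)
    out = {}
    for region, ratio in ratios.items():
        if ratio < 0:
            raise ValueError("state-to-nation ratio must be non-negative")
        scaled = bm.copy()
        mask = scaled["disease"].isin(STATE_SCALED_DISEASES)
        scaled.loc[mask, ["mean", "lower", "upper"]] *= ratio
        out[region] = scaled
    return out


def _rates(bm: pd.DataFrame, disease: str, age_group: str) -> tuple[float, float, float]:
    row = bm[(bm["disease"] == disease) & (bm["age_group"] == age_group)]
    if len(row) != 1:
        raise KeyError(f"baseline mortality missing stratum {disease}/{age_group}")
    r = row.iloc[0]
    return float(r["mean"]), float(r["lower"]), float(r["upper"])


def compute_burden(
    conc: GriddedField,
    pop: GriddedField,
    ages: AgeStructure,
    bm: pd.DataFrame,
    ens: IERParameterEnsemble,
    lt: LifeTable,
    region_masks: Mapping[str, np.ndarray] | None = None,
    bm_by_region: Mapping[str, pd.DataFrame] | None = None,
    urban_split: bool = True,
    diseases: Sequence[str] = DISEASES,
) -> pd.DataFrame:
    """Mortality and YLL by disease, age group, region and urban/rural class.

    The cell-level RR is the ensemble-mean IER evaluated at the cell's
    annual-mean concentration.  Stratum-level lower/upper carry the
    baseline-rate uncertainty; the national 95UI is assembled separately
    by quadrature over all components.  Rows with region="India" cover
    the full grid; extra rows appear per region mask and, when
    ``urban_split``, per urban/rural class (a cell is wholly one or the
    other).  ``bm_by_region`` optionally overrides the national baseline
    mortality within named regions (state sensitivity).
    """
    if conc.spec != pop.spec:
        raise ValueError("concentration and population grids differ")
    validate_baseline_mortality(bm)

    c_flat = conc.values.ravel()
    p_flat = pop.values.ravel()
    urban = classify_urban(pop).ravel()

    scopes: list[tuple[str, str, np.ndarray, pd.DataFrame]] = [
        ("India", "total", np.ones_like(urban, dtype=bool), bm)
    ]
    if urban_split:
        scopes.append(("India", "urban", urban, bm))
        scopes.append(("India", "rural", ~urban, bm))
    for region, mask in (region_masks or {}).items():
        mask = np.asarray(mask, dtype=bool).ravel()
        region_bm = (bm_by_region or {}).get(region, bm)
        validate_baseline_mortality(region_bm)
        scopes.append((region, "total", mask, region_bm))

    rows = []
    for disease in diseases:
        # ensemble-mean AF per cell, per parameter stratum (age-specific
        # diseases carry one stratum per adult age group)
        af_cache: dict[str, np.ndarray] = {}
        for age_group in disease_age_groups(disease):
            key = age_group if (disease, age_group) in ens._groups else "ALL"
            if key not in af_cache:
                rr_mean = ens.mean_rr(c_flat, disease, key)
                af_cache[key] = attributable_fraction(rr_mean)
            af = af_cache[key]
            frac = ages.fraction(age_group)
            le = lt.le(age_group)
            for region, klass, mask, scope_bm in scopes:
                rate_mean, rate_lo, rate_hi = _rates(scope_bm, disease, age_group)
                base = float((p_flat[mask] * af[mask]).sum()) * frac
                m_mean, m_lo, m_hi = base * rate_mean, base * rate_lo, base * rate_hi
                rows.append(
                    {
                        "disease": disease,
                        "age_group": age_group,
                        "region": region,
                        "class": klass,
                        "mortality_mean": m_mean,
                        "mortality_lower": m_lo,
                        "mortality_upper": m_hi,
                        "yll_mean": m_mean * le,
                        "yll_lower": m_lo * le,
                        "yll_upper": m_hi * le,
                    }
                )
    return pd.DataFrame(rows)


def mortality_field(
    conc: GriddedField,
    pop: GriddedField,
    ages: AgeStructure,
    bm: pd.DataFrame,
    ens: IERParameterEnsemble,
    diseases: Sequence[str] = DISEASES,
) -> np.ndarray:
    """Per-cell total premature mortality (all diseases and ages), for mapping."""
    validate_baseline_mortality(bm)
    c_flat = conc.values.ravel()
    out = np.zeros_like(c_flat)
    for disease in diseases:
        af_cache: dict[str, np.ndarray] = {}
        for age_group in disease_age_groups(disease):
            key = age_group if (disease, age_group) in ens._groups else "ALL"
            if key not in af_cache:
                af_cache[key] = attributable_fraction(ens.mean_rr(c_flat, disease, key))
            rate_mean, _, _ = _rates(bm, disease, age_group)
            out += pop.values.ravel() * ages.fraction(age_group) * rate_mean * af_cache[key]
    return out.reshape(conc.shape)


def yll_from_mortality(bt: pd.DataFrame, lt: LifeTable) -> pd.DataFrame:
    """(Re)compute YLL columns from mortality columns: YLL = M * LE(age)."""
    out = bt.copy()
    le = out["age_group"].map(lt.le)
    for side in ("mean", "lower", "upper"):
        out[f"yll_{side}"] = out[f"mortality_{side}"] * le
    return out


def total_burden(bt: pd.DataFrame, region: str = "India", klass: str = "total") -> float:
    """Total mean mortality summed over diseases and ages for one scope."""
    sel = bt[(bt["region"] == region) & (bt["class"] == klass)]
    return float(sel["mortality_mean"].sum())


def total_yll(bt: pd.DataFrame, region: str = "India", klass: str = "total") -> float:
    sel = bt[(bt["region"] == region) & (bt["class"] == klass)]
    return float(sel["yll_mean"].sum())
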