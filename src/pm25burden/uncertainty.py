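"""95% uncertainty intervals by quadrature over component fractional errors.

Each uncertain input (population, PM2.5 concentration, exposure-response
relative risk, baseline mortality) contributes a fractional error
|bound - mean| / mean per side; the sides are combined as the square
root of the sum of squares and applied multiplicatively to the mean
burden.  The two sides may differ (the RR and baseline-rate intervals
are asymmetric), so intervals are asymmetric in general.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .burden import attributable_fraction, disease_age_groups
from .grids import GriddedField
from .ier import IERParameterEnsemble, rr_ensemble

#: Stated uncertainty of the gridded population data (fraction per side).
POPULATION_FRACTIONAL_ERROR = 0.02


@dataclass(frozen=True)
class UncertainQuantity:
    """A mean with its 95% interval; fractional errors are |bound-mean|/mean."""

    mean: float
    lower_95: float
    upper_95: float

    def __post_init__(self) -> None:
        if not (self.lower_95 <= self.mean <= self.upper_95):
            raise ValueError("interval must satisfy lower <= mean <= upper")

    @property
    def fractional_error_low(self) -> float:
        return (self.mean - self.lower_95) / self.mean if self.mean > 0 else 0.0

    @property
    def fractional_error_high(self) -> float:
        return (self.upper_95 - self.mean) / self.mean if self.mean > 0 else 0.0


def quadrature(fracs: Iterable[float]) -> float:
    """Square root of the sum of squared fractional errors.

    At least as large as any single component; the identity on a
    one-element list.
    """
    arr = np.asarray(list(fracs), dtype=float)
    if arr.size and np.any(arr < 0):
        raise ValueError("fractional errors must be non-negative")
    return float(np.sqrt(np.sum(arr**2)))


def pm25_fractional_error(
    weekly: np.ndarray, pop: GriddedField
) -> float:
    """National fractional error of annual-mean PM2.5 from weekly variability.

    Per cell the 95% bound is the annual mean +/- 2 sample standard
    deviations of the 52 weekly concentrations (Gaussian assumption);
    the per-cell fractions 2*SD/mean are combined into one national
    fraction by population weighting.  Cells with zero annual mean (or
    zero population) are excluded.
    """
    weekly = np.asarray(weekly, dtype=float)
    if weekly.ndim != 3:
        raise ValueError("weekly stack must have shape (n_weeks, n_lat, n_lon)")
    mean = weekly.mean(axis=0)
    sd = weekly.std(axis=0, ddof=1)
    w = pop.values.copy()
    valid = (mean > 0) & (w > 0)
    if not valid.any():
        return 0.0
    frac = np.zeros_like(mean)
    frac[valid] = 2.0 * sd[valid] / mean[valid]
    return float((frac[valid] * w[valid]).sum() / w[valid].sum())


def rr_fractional_errors(
    ens: IERParameterEnsemble,
    concentration: float,
    disease_weights: Mapping[str, float],
    pm_fraction: float = 0.0,
) -> tuple[float, float]:
    """(low, high) fractional errors of the attributable fraction.

    For each disease the IER ensemble is evaluated at the national
    population-weighted concentration; when ``pm_fraction`` is non-zero
    the concentration uncertainty is folded in by evaluating the lower
    RR bound at c*(1 - pm_fraction) and the upper at c*(1 + pm_fraction),
    mirroring how concentration error widens the risk interval.  The
    per-disease fractions (on the attributable-fraction scale, which is
    what enters the burden) are averaged with the supplied burden-share
    weights.
    """
    lows, highs, weights = [], [], []
    for disease, weight in disease_weights.items():
        if weight <= 0:
            continue
        groups = [g for g in disease_age_groups(disease)
                  if (disease, g) in ens._groups] or ["ALL"]
        d_low, d_high = [], []
        for g in groups:
            mid = rr_ensemble(concentration, ens, disease, g)
            lo = rr_ensemble(max(concentration * (1 - pm_fraction), 0.0), ens, disease, g)
            hi = rr_ensemble(concentration * (1 + pm_fraction), ens, disease, g)
            af_mid = attributable_fraction(mid.mean)
            if af_mid <= 0:
                continue
            d_low.append((af_mid - attributable_fraction(lo.lower_95)) / af_mid)
            d_high.append((attributable_fraction(hi.upper_95) - af_mid) / af_mid)
        if d_low:
            lows.append(float(np.mean(d_low)))
            highs.append(float(np.mean(d_high)))
            weights.append(weight)
    if not weights:
        return 0.0, 0.0
    w = np.asarray(weights) / np.sum(weights)
    return float(np.dot(w, lows)), float(np.dot(w, highs))


def baseline_fractional_errors(bm: pd.DataFrame,
                               burden: pd.DataFrame | None = None) -> tuple[float, float]:
    """(low, high) fractional errors of the baseline mortality rates.

    Weighted by each stratum's share of the mean burden when a burden
    table is given; otherwise a plain average over strata.
    """
    bm = bm[bm["mean"] > 0]
    low = (bm["mean"] - bm["lower"]) / bm["mean"]
    high = (bm["upper"] - bm["mean"]) / bm["mean"]
    if burden is not None:
        sel = burden[(burden["region"] == "India") & (burden["class"] == "total")]
        shares = sel.groupby(["disease", "age_group"])["mortality_mean"].sum()
        keys = list(zip(bm["disease"], bm["age_group"]))
        w = np.asarray([shares.get(k, 0.0) for k in keys], dtype=float)
        if w.sum() > 0:
            w = w / w.sum()
            return float(np.dot(w, low)), float(np.dot(w, high))
    return float(low.mean()), float(high.mean())


def combine_burden_ui(
    mean_burden: float,
    components: Mapping[str, float | tuple[float, float]],
) -> UncertainQuantity:
    """Assemble a 95UI around a mean burden from component fractional errors.

    ``components`` maps a component name to either a symmetric fraction
    or a ``(low, high)`` pair.  lower = mean * (1 - q_low) and
    upper = mean * (1 + q_high) with each side combined in quadrature.
    """
    lows, highs = [], []
    for frac in components.values():
        if isinstance(frac, tuple):
            lo, hi = frac
        else:
            lo = hi = float(frac)
        lows.append(lo)
        highs.append(hi)
    q_low = quadrature(lows)
    q_high = quadrature(highs)
    return UncertainQuantity(
        mean=mean_burden,
        lower_95=mean_burden * max(1.0 - q_low, 0.0),
        upper_95=mean_burden * (1.0 + q_high),
    )
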