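"""Integrated exposure-response (IER) model for ambient PM2.5.

The IER gives the relative risk of death from a disease as a saturating
function of annual-mean PM2.5 concentration ``c``::

    RR(c) = 1                                          for c <= TMREL
    RR(c) = 1 + alpha * (1 - exp(-beta * (c - TMREL)**gamma))   otherwise

where ``alpha`` is the maximum excess risk (RR saturates at 1 + alpha),
``beta`` a rate, ``gamma`` a shape, and TMREL the theoretical minimum
risk exposure level, below which no excess risk is assigned.  Parameter
uncertainty is carried by an ensemble of joint (alpha, beta, gamma,
TMREL) draws per disease and age group; the ensemble mean and empirical
2.5th/97.5th percentiles give the mean RR with its 95% uncertainty
interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Disease endpoints: acute lower respiratory infection, ischaemic heart
#: disease, cerebrovascular disease, chronic obstructive pulmonary
#: disease, lung cancer.
DISEASES = ("ALRI", "IHD", "CEV", "COPD", "LC")

#: Diseases whose RR varies by 5-year adult age group (age-specific
#: parameter strata); the others use one parameter set across ages.
AGE_SPECIFIC_DISEASES = ("IHD", "CEV")

TMREL_LOW = 2.4
TMREL_HIGH = 5.9

_ENSEMBLE_COLUMNS = ["disease", "age_group", "draw", "alpha", "beta", "gamma", "tmrel"]


@dataclass(frozen=True)
class IERParameterSet:
    """One joint draw of IER parameters for a disease/age stratum."""

    alpha: float
    beta: float
    gamma: float
    tmrel: float
    disease: str = ""
    age_group: str = ""

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) <= 0:
            raise ValueError("alpha, beta, gamma must all be positive")
        if not (TMREL_LOW <= self.tmrel <= TMREL_HIGH):
            raise ValueError(f"tmrel must lie in [{TMREL_LOW}, {TMREL_HIGH}]")


@dataclass(frozen=True)
class RelativeRiskResult:
    """Ensemble-mean RR with empirical 95% bounds (1 <= lower <= mean <= upper)."""

    mean: float
    lower_95: float
    upper_95: float

    def __post_init__(self) -> None:
        if not (1.0 <= self.lower_95 <= self.mean <= self.upper_95):
            raise ValueError("RR bounds must satisfy 1 <= lower <= mean <= upper")


def relative_risk(c, p: IERParameterSet):
    """Evaluate the IER at concentration(s) ``c`` (ug m^-3) for one draw.

    Accepts a scalar or array; returns the same shape.  RR equals 1 at and
    below the TMREL, increases monotonically above it and saturates at
    1 + alpha.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be non-negative")
    excess = np.where(
        c_arr > p.tmrel,
        p.alpha * (1.0 - np.exp(-p.beta * np.maximum(c_arr - p.tmrel, 0.0) ** p.gamma)),
        0.0,
    )
    rr = 1.0 + excess
    return float(rr) if np.isscalar(c) or c_arr.ndim == 0 else rr


def _rr_matrix(c: np.ndarray, alpha, beta, gamma, tmrel) -> np.ndarray:
    """Vectorised RR for draws x concentrations, shape (n_draws, n_c)."""
    c = np.atleast_1d(np.asarray(c, dtype=float))
    delta = np.maximum(c[None, :] - tmrel[:, None], 0.0)
    rr = 1.0 + alpha[:, None] * (1.0 - np.exp(-beta[:, None] * delta ** gamma[:, None]))
    rr[delta == 0.0] = 1.0
    return rr


class IERParameterEnsemble:
    """N joint (alpha, beta, gamma, tmrel) draws per (disease, age_group).

    Backed by a long-format DataFrame (columns: disease, age_group, draw,
    alpha, beta, gamma, tmrel).  Every stratum must hold the same number
    of draws, and at least 2 (otherwise no uncertainty interval can be
    formed).  Strata for diseases without age-specific parameters use the
    age label ``"ALL"``; lookups fall back to it.
    """

    def __init__(self, table: pd.DataFrame):
        missing = set(_ENSEMBLE_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"ensemble table missing columns: {sorted(missing)}")
        table = table[_ENSEMBLE_COLUMNS].reset_index(drop=True)
        counts = table.groupby(["disease", "age_group"], sort=False).size()
        if counts.nunique() != 1:
            raise ValueError("all strata must hold the same number of draws")
        n = int(counts.iloc[0])
        if n < 2:
            raise ValueError("at least 2 draws are required for an uncertainty interval")
        for col in ("alpha", "beta", "gamma"):
            if (table[col] <= 0).any():
                raise ValueError(f"{col} draws must be positive")
        if ((table["tmrel"] < TMREL_LOW) | (table["tmrel"] > TMREL_HIGH)).any():
            raise ValueError(f"tmrel draws must lie in [{TMREL_LOW}, {TMREL_HIGH}]")
        self.table = table
        self.n_draws = n
        self._groups = {
            key: grp[["alpha", "beta", "gamma", "tmrel"]].to_numpy().T
            for key, grp in table.groupby(["disease", "age_group"], sort=False)
        }

    def strata(self) -> list[tuple[str, str]]:
        return list(self._groups)

    def params_for(self, disease: str, age_group: str) -> tuple[np.ndarray, ...]:
        """(alpha, beta, gamma, tmrel) draw arrays; falls back to age 'ALL'."""
        for key in ((disease, age_group), (disease, "ALL")):
            if key in self._groups:
                a, b, g, t = self._groups[key]
                return a, b, g, t
        raise KeyError(f"no parameter stratum for {disease}/{age_group}")

    def draws_for(self, disease: str, age_group: str) -> list[IERParameterSet]:
        a, b, g, t = self.params_for(disease, age_group)
        return [
            IERParameterSet(*vals, disease=disease, age_group=age_group)
            for vals in zip(a, b, g, t)
        ]

    # -- CSV round trip ------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IERParameterEnsemble":
        return cls(pd.read_csv(path))

    # -- ensemble statistics -------------------------------------------
    def rr_draws(self, c, disease: str, age_group: str) -> np.ndarray:
        """RR per draw at concentration(s) c, shape (n_draws, n_c)."""
        a, b, g, t = self.params_for(disease, age_group)
        return _rr_matrix(c, a, b, g, t)

    def mean_rr(self, c, disease: str, age_group: str) -> np.ndarray:
        """Ensemble-mean RR at concentration array c, shape (n_c,)."""
        return self.rr_draws(c, disease, age_group).mean(axis=0)


def rr_ensemble(
    c: float, ens: IERParameterEnsemble, disease: str, age_group: str
) -> RelativeRiskResult:
    """Mean RR and empirical 95% interval at one concentration."""
    rr = ens.rr_draws(c, disease, age_group)[:, 0]
    lower, upper = np.percentile(rr, [2.5, 97.5])
    mean = float(rr.mean())
    # floating ties (all draws equal) can invert the ordering by an ulp
    lower = min(lower, mean)
    upper = max(upper, mean)
    return RelativeRiskResult(mean=mean, lower_95=float(lower), upper_95=float(upper))


def rr_curve(
    ens: IERParameterEnsemble,
    disease: str,
    age_group: str,
    c_grid: Sequence[float] | np.ndarray,
) -> pd.DataFrame:
    """Mean RR with 95% bounds along a concentration grid.

    Returns a DataFrame (c, mean, lower_95, upper_95); the mean RR is
    non-decreasing along an increasing grid.
    """
    c_grid = np.asarray(list(c_grid), dtype=float)
    rr = ens.rr_draws(c_grid, disease, age_group)
    lower, upper = np.percentile(rr, [2.5, 97.5], axis=0)
    mean = rr.mean(axis=0)
    return pd.DataFrame(
        {
            "c": c_grid,
            "mean": mean,
            "lower_95": np.minimum(lower, mean),
            "upper_95": np.maximum(upper, mean),
        }
    )
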