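"""End-to-end orchestration: generate -> exposure -> burden -> apportion
-> uncertainty -> evaluate, with reproducible seeds and a run manifest.

Each stage is a plain function over the library types so the numbered
analysis drivers, the CLI and the tests all share one code path.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import (
    AgeStructure,
    LifeTable,
    apply_state_scaling,
    compute_burden,
    mortality_field,
    total_burden,
    total_yll,
)
from .apportion import apportion_all
from .evaluation import evaluation_report, week_seasons
from .exposure import (
    ScenarioSet,
    cap_concentrations,
    coarsen,
    exceedance_fraction,
    exposure_summary,
    population_weighted_mean,
)
from .grids import GriddedField, GridSpec
from .ier import IERParameterEnsemble
from .regions import rasterize_regions
from .synthetic import (
    INDIA_POPULATION,
    SyntheticConfig,
    gen_age_structure,
    gen_baseline_mortality,
    gen_ier_parameters,
    gen_life_table,
    gen_observation_sites,
    gen_pm25_control,
    gen_population,
    gen_regions,
    gen_sector_off_fields,
)
from . import io as pio

logger = logging.getLogger(__name__)

#: WHO annual-mean guideline and first interim target, ug m^-3.
WHO_AQG = 10.0
WHO_IT1 = 35.0


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Sensitivity toggles mirror the study's sensitivity analyses: block
    coarsening of the concentration/population grids, a hard cap on
    annual-mean concentrations, state-specific baseline-mortality
    scaling, and an alternative (lower) life table.
    """

    seed: int = 0
    n_lat: int = 60
    n_lon: int = 60
    population_total: int = INDIA_POPULATION
    n_draws: int = 1000
    n_sites: int = 45
    obs_noise_sd: float = 10.0
    coarsen_factor: int | None = None
    cap: float | None = None
    state_scaling: bool = False
    alt_life_table: bool = False
    n_region_bands: int = 2
    synthetic: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def grid_spec(self) -> GridSpec:
        return GridSpec(n_lat=self.n_lat, n_lon=self.n_lon)

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(seed=self.seed, **self.synthetic)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def generate_inputs(cfg: RunConfig) -> dict[str, Any]:
    """Run every synthetic generator; returns the input bundle."""
    spec = cfg.grid_spec()
    scfg = cfg.synthetic_config()
    control, weekly = gen_pm25_control(spec, scfg)
    scen = gen_sector_off_fields(control, scfg)
    pop = gen_population(spec, cfg.population_total, scfg)
    ens = gen_ier_parameters(n_draws=cfg.n_draws, seed=cfg.seed)
    bm = gen_baseline_mortality()
    lt = gen_life_table()
    ages = gen_age_structure()
    regions_geojson = gen_regions(spec, cfg.n_region_bands, cfg.n_region_bands)
    obs = gen_observation_sites(
        control, n_sites=cfg.n_sites, noise_sd=cfg.obs_noise_sd,
        seed=cfg.seed, weekly=weekly,
    )
    logger.info(
        "generated inputs: pm25 %s pop %s", _checksum(control.values), _checksum(pop.values)
    )
    return {
        "spec": spec,
        "control": control,
        "weekly": weekly,
        "scenarios": scen,
        "population": pop,
        "ensemble": ens,
        "baseline_mortality": bm,
        "life_table": lt,
        "ages": ages,
        "regions_geojson": regions_geojson,
        "observations": obs,
    }


def _apply_sensitivities(cfg: RunConfig, bundle: dict[str, Any]) -> dict[str, Any]:
    """Cap and/or coarsen the concentration fields (and population for
    coarsening), per the run configuration."""
    scen: ScenarioSet = bundle["scenarios"]
    pop: GriddedField = bundle["population"]
    if cfg.cap is not None:
        scen = ScenarioSet(
            control=cap_concentrations(scen.control, cfg.cap),
            sector_off={
                s: cap_concentrations(f, cfg.cap) for s, f in scen.sector_off.items()
            },
        )
    if cfg.coarsen_factor:
        k = cfg.coarsen_factor
        scen = ScenarioSet(
            control=coarsen(scen.control, k, "concentration"),
            sector_off={
                s: coarsen(f, k, "concentration") for s, f in scen.sector_off.items()
            },
        )
        pop = coarsen(pop, k, "population")
    out = dict(bundle)
    out["scenarios"] = scen
    out["population"] = pop
    return out


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline and write all artifacts under ``outdir``."""
    from .uncertainty import (
        POPULATION_FRACTIONAL_ERROR,
        baseline_fractional_errors,
        combine_burden_ui,
        pm25_fractional_error,
        rr_fractional_errors,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fine = generate_inputs(cfg)  # native-resolution, untransformed inputs
    bundle = _apply_sensitivities(cfg, fine)
    scen: ScenarioSet = bundle["scenarios"]
    pop: GriddedField = bundle["population"]
    control = scen.control
    ens: IERParameterEnsemble = bundle["ensemble"]
    bm = bundle["baseline_mortality"]
    ages: AgeStructure = bundle["ages"]
    lt: LifeTable = bundle["life_table"]
    if cfg.alt_life_table:
        lt = LifeTable({g: 0.4 * lt.le(g) for g in lt.to_frame()["age_group"]})

    # ---- persist inputs ------------------------------------------------
    pio.write_weekly(fine["control"], fine["weekly"], outdir / "pm25_weekly.nc")
    pio.write_scenarios(scen, outdir / "scenarios.nc")
    pio.write_field(pop, outdir / "population.nc", name="population")
    ens.to_csv(outdir / "ier_parameters.csv")
    bm.to_csv(outdir / "baseline_mortality.csv", index=False)
    lt.to_frame().to_csv(outdir / "life_table.csv", index=False)
    pio.write_json(bundle["regions_geojson"], outdir / "regions.geojson")
    bundle["observations"].to_csv(outdir / "observations.csv", index=False)

    # ---- exposure ------------------------------------------------------
    expo = exposure_summary(scen, pop)
    expo.to_csv(outdir / "exposure_summary.csv", index=False)
    pd.DataFrame(
        [
            {"threshold": WHO_AQG,
             "fraction": exceedance_fraction(control, pop, WHO_AQG)},
            {"threshold": WHO_IT1,
             "fraction": exceedance_fraction(control, pop, WHO_IT1)},
        ]
    ).to_csv(outdir / "exceedance.csv", index=False)

    # ---- burden --------------------------------------------------------
    region_masks = rasterize_regions(bundle["regions_geojson"], control.spec)
    bm_by_region = None
    if cfg.state_scaling:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(99)[-1])
        ratios = {
            name: float(np.exp(rng.normal(0.0, 0.15))) for name in region_masks
        }
        bm_by_region = apply_state_scaling(bm, ratios)
    bt = compute_burden(
        control, pop, ages, bm, ens, lt,
        region_masks=region_masks, bm_by_region=bm_by_region,
    )
    bt.to_csv(outdir / "burden_by_stratum.csv", index=False)
    mort = mortality_field(control, pop, ages, bm, ens)
    pio.write_field(
        GriddedField(mort, control.spec), outdir / "mortality.nc", name="mortality"
    )

    # ---- uncertainty on the national totals ----------------------------
    pwm = population_weighted_mean(control, pop)
    # weekly variability is defined on the native grid regardless of the
    # coarsening sensitivity
    pm_frac = pm25_fractional_error(fine["weekly"], fine["population"])
    sel = bt[(bt["region"] == "India") & (bt["class"] == "total")]
    disease_weights = sel.groupby("disease")["mortality_mean"].sum().to_dict()
    rr_lo, rr_hi = rr_fractional_errors(ens, pwm, disease_weights, pm_fraction=pm_frac)
    base_lo, base_hi = baseline_fractional_errors(bm, bt)
    components = {
        "population": POPULATION_FRACTIONAL_ERROR,
        "rr": (rr_lo, rr_hi),
        "baseline": (base_lo, base_hi),
    }
    m_total = total_burden(bt)
    y_total = total_yll(bt)
    m_ui = combine_burden_ui(m_total, components)
    y_ui = combine_burden_ui(y_total, components)
    urban_share = total_burden(bt, klass="urban") / m_total if m_total > 0 else 0.0
    totals = pd.DataFrame(
        [
            {"quantity": "mortality", "mean": m_ui.mean,
             "lower_95": m_ui.lower_95, "upper_95": m_ui.upper_95},
            {"quantity": "yll", "mean": y_ui.mean,
             "lower_95": y_ui.lower_95, "upper_95": y_ui.upper_95},
            {"quantity": "urban_share", "mean": urban_share,
             "lower_95": urban_share, "upper_95": urban_share},
            {"quantity": "pwm_pm25", "mean": pwm, "lower_95": pwm * (1 - pm_frac),
             "upper_95": pwm * (1 + pm_frac)},
        ]
    )
    totals.to_csv(outdir / "burden_totals.csv", index=False)

    # ---- sector apportionment ------------------------------------------
    app = apportion_all(scen, pop, ages, bm, ens, lt)
    frac_lo = m_ui.fractional_error_low
    frac_hi = m_ui.fractional_error_high
    for method in ("subtraction", "attribution"):
        app[f"{method}_lower"] = app[f"m_{method}"] * (1 - frac_lo)
        app[f"{method}_upper"] = app[f"m_{method}"] * (1 + frac_hi)
    app.to_csv(outdir / "apportionment.csv", index=False)
    for method in ("subtraction", "attribution"):
        app[["sector", f"m_{method}", f"{method}_lower", f"{method}_upper",
             f"percent_{method}"]].rename(
            columns={
                f"m_{method}": "mean",
                f"{method}_lower": "lower",
                f"{method}_upper": "upper",
                f"percent_{method}": "percent",
            }
        ).to_csv(outdir / f"apportionment_{method}.csv", index=False)

    # ---- evaluation (always against the native-grid fields) ------------
    labels = week_seasons(fine["weekly"].shape[0])
    season_fields = {"annual": fine["control"]}
    for season in ("DJF", "MAM", "JJA", "SON"):
        season_fields[season] = fine["control"].copy_with(
            fine["weekly"][labels == season].mean(axis=0)
        )
    evaluation_report(season_fields, fine["observations"]).to_csv(
        outdir / "evaluation_metrics.csv", index=False
    )

    # ---- manifest ------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "checksums": {
            "pm25_control": _checksum(control.values),
            "population": _checksum(pop.values),
        },
        "totals": {
            "mortality_mean": m_total,
            "yll_mean": y_total,
            "pwm_pm25": pwm,
        },
    }
    pio.write_json(manifest, outdir / "manifest.json")
    logger.info("pipeline complete: %s", outdir)
    return outdir
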