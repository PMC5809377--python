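# pm25burden

Health-impact assessment of ambient fine particulate matter (PM2.5)
exposure, with source-sector apportionment. The package is aimed at air
quality and environmental-health researchers who have gridded annual-mean
PM2.5 fields from a chemistry-transport model — a control run plus runs
with individual emission sectors switched off — and want the resulting
premature-mortality and years-of-life-lost burden, its uncertainty, and
its split across emission sectors.

## The model

Relative risk of death from a disease endpoint follows the integrated
exposure–response (IER) form

```
RR(c) = 1                                      c ≤ TMREL
RR(c) = 1 + α·(1 − exp(−β·(c − TMREL)^γ))      c > TMREL
```

with `c` the annual-mean PM2.5 concentration (µg m⁻³), `α` the maximum
excess risk, `β` a rate, `γ` a shape, and TMREL the theoretical minimum
risk exposure level (uniform on 2.4–5.9 µg m⁻³). Parameter uncertainty is
carried by an ensemble of joint (α, β, γ, TMREL) draws per disease and age
group; the ensemble mean and empirical 2.5th/97.5th percentiles give the
mean RR and its 95% uncertainty interval.

Premature mortality per grid cell `i` and disease `j` is

```
M_ij = P_i · I_j · (RR_jc − 1) / RR_jc
```

(`P` cell population, `I` baseline mortality rate), and years of life lost
multiply deaths by the life expectancy remaining at the age of death,
`YLL_ij = M_ij · LE`. Five endpoints are covered: acute lower respiratory
infection (all ages) and ischaemic heart disease, cerebrovascular disease,
COPD and lung cancer (adults ≥ 25, 5-year age groups).

Sector contributions are computed two ways, which answer different
questions and disagree wherever the IER saturates:

* **subtraction (zero-out)**: `M_SECTOR = M_ALL − M_SECTOR_OFF` — deaths
  averted by removing the sector;
* **attribution**: `M_SECTOR = M_ALL · (PM_ALL − PM_SECTOR_OFF) / PM_ALL`
  — deaths attributed to the sector's share of population-weighted PM2.5.

95% uncertainty intervals combine component fractional errors (population
±2%, PM2.5 from ±2 SD of weekly concentrations folded into the RR
interval, baseline-rate bounds) in quadrature.

All external inputs — the gridded fields, population, exposure–response
parameters, baseline rates, life table and site observations — are
emulated by a seeded synthetic-data module (`pm25burden.synthetic`) that
reproduces their statistical structure, so the full pipeline runs offline.

## Worked example

```python
from pm25burden.pipeline import RunConfig, run_pipeline
run_pipeline(RunConfig(seed=42, n_lat=60, n_lon=60, n_draws=1000), "runs/demo")
```

or equivalently, step by step with narrative output:

```
python analysis/01_generate_inputs.py
python analysis/02_exposure_summary.py
python analysis/03_burden_estimates.py
python analysis/04_sector_apportionment.py
python analysis/05_sensitivity_analyses.py
python analysis/06_model_evaluation.py
```

At the default configuration (0.5° India-like grid, 1.302 billion people,
1000 IER draws, seed 42) the drivers print:

```
Population-weighted annual-mean PM2.5 (control): 57.9 ug/m3
...
Residential energy use dominates: removing it lowers population-weighted
PM2.5 by 29.2 ug/m3 (50% of the control mean).

Premature mortality: 1,021,940 per year (95UI 350,623-1,517,447)
Years of life lost:  31,103,377 per year (95UI 10,671,418-46,184,445)
Urban share of mortality: 69%

Attribution/subtraction ratio for the major sectors: 1.9-2.8
(saturation of the exposure-response at high PM2.5).
Sector sums: subtraction 46% of control, attribution 100% of control
```

Reading this: almost everyone in the synthetic domain lives above the WHO
annual guideline; residential energy use accounts for half the
population-weighted exposure; and because the exposure–response flattens
above ~50 µg m⁻³, the mortality attributable to a sector is roughly twice
the mortality that removing the sector would avert. Tables land under
`results/` (exposure summary, burden strata, sector apportionment,
sensitivities, evaluation metrics).

A `pm25burden` console script wraps the same pipeline
(`pm25burden run-all --seed 42 --out runs/demo`, with `--cap`,
`--coarsen` and `--sensitivity` toggles for the sensitivity analyses).

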