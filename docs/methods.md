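# Methods

## Scope and data flow

The package implements the health-impact half of a source-apportionment
study: it starts from annual-mean surface PM2.5 fields (one control, seven
sector-off), a population raster, exposure–response parameters, baseline
mortality rates and a life table, and produces burden tables, sector
apportionments, uncertainty intervals and model-evaluation statistics.
The atmospheric simulation that would produce the PM2.5 fields is out of
scope; the synthetic module stands in for it and for the licensed health
inputs.

## Grids and exposure metrics

Fields live on a regular latitude/longitude grid (default 60×60 cells over
6–36° N, 68–98° E, i.e. 0.5° ≈ the 30 km resolution class of regional
models). Cell areas follow the spherical strip formula, so area decreases
with |latitude|. Choosing a regular lat/lon grid rather than a conformal
projection keeps every exposure operation exactly testable and changes
nothing in the health arithmetic, which only consumes per-cell values and
areas.

Population-weighted mean exposure is Σ(c·P)/ΣP over cells; cells with zero
population drop out. Threshold exceedance is the population fraction in
cells strictly above a concentration. Two sensitivity transforms are
provided:

* **coarsening** by an integer factor — area-weighted mean for
  concentrations, block sum for population (counts conserved exactly;
  non-divisible shapes are padded and the padding masked out);
* **capping** — a hard clip `min(c, cap)` per cell. A proportional
  rescaling would also keep means below the cap, but only a clip
  guarantees the stated ceiling in every cell, so the clip reading is
  used; this is a genuinely open interpretive choice and is flagged here.

Printed percentages use half-up integer rounding, matching how such
tables are typeset.

## The IER and its ensemble

The IER form `RR = 1 + α(1 − exp(−β(c − TMREL)^γ))` above the TMREL and 1
below it is evaluated on each cell's annual mean (long-term exposure; no
sub-annual averaging). Uncertainty intervals are empirical 2.5/97.5
percentiles over an ensemble of joint parameter draws — the standard
convention, requiring no distributional assumption. TMREL is drawn
uniformly on [2.4, 5.9] µg m⁻³ per draw. Age dependence enters at the
parameter level: ischaemic heart disease and cerebrovascular disease carry
one parameter stratum per 5-year adult age group (excess risk attenuating
with age); the other endpoints share one stratum. Lookups fall back to the
shared stratum, so user-supplied CSV ensembles with either layout work.

The synthetic ensemble uses lognormal marginals (α: σ=0.25, β: σ=0.30, γ:
σ=0.10) around per-disease medians chosen to give curve shapes in the
plausible range for ambient studies — RR ≈ 1.5–1.9 at 60 µg m⁻³,
saturating above ~50 µg m⁻³. It is a stand-in with the right shape and
skew, **not** a reproduction of any published parameter set; real
parameter tables can be supplied via `IERParameterEnsemble.from_csv`.

## Burden accounting

Mean burden uses the ensemble-mean RR per cell and the mean baseline
rates; per-stratum lower/upper columns carry only the baseline-rate
bounds, while the national 95UI is assembled by quadrature (below). A
single national age composition applies in every cell (gridded age
structure is not available at this resolution). Urban cells are those with
population density ≥ 400 persons km⁻²; a cell is wholly urban or wholly
rural. Region masks come from GeoJSON polygons rasterised by cell-centre
containment, ties resolved to the first-listed feature, which makes
regional totals exactly additive. The state sensitivity multiplies COPD,
IHD and cerebrovascular baseline rates (mean and bounds alike) by
region-to-nation ratios, leaving lung cancer and ALRI at national values.

## Sector apportionment

Subtraction recomputes the full burden on each sector-off field and
differences; attribution scales the control burden by the sector's
fractional reduction of the national population-weighted mean. The
aggregate (national) level is used for the headline tables because the
method is defined on aggregate quantities there; a per-cell attribution
field is available for mapping. Neither method's sector sum is forced to
close: attribution sums to Σ fractions of the control burden (which can
exceed 100% when sector contributions overlap), subtraction sums lower
wherever the IER is concave. Tiny negative subtraction results (floating
noise) are clamped to zero with a warning; materially negative values
raise.

## Uncertainty

Fractional errors per side are combined as √(Σf²) and applied
multiplicatively to the mean. Components:

* population: ±2%;
* PM2.5: per cell, ±2 sample standard deviations (ddof=1) of the 52
  weekly concentrations relative to the annual mean, aggregated to one
  national fraction by population weighting (the aggregation weight is an
  open choice; population weighting matches how the exposure metric
  itself is formed);
* exposure–response: the ensemble RR interval evaluated at the national
  population-weighted concentration per disease, with the PM2.5 fraction
  folded in by evaluating the lower bound at c·(1−f) and the upper at
  c·(1+f); per-disease fractions are averaged with burden-share weights
  on the attributable-fraction scale (which is what enters the burden);
* baseline mortality: the table's bounds, burden-share weighted.

Sides are kept separate throughout, so intervals are asymmetric. Sector
estimates reuse the control burden's fractional errors, consistent with
relative uncertainty being nearly constant across sectors. Full
Monte-Carlo propagation through every stratum is deliberately not done;
quadrature is the method being implemented.

## Synthetic inputs: what they emulate, what they do not

* **PM2.5 control**: background (25 µg m⁻³) plus a Gaussian-in-latitude
  band (amplitude 120, centre 27° N, width 2°) modulated by correlated
  lognormal noise (smoothed-white-noise field, kernel 3 cells, σ=0.15) —
  a high-concentration northern band exceeding 100 µg m⁻³ over a cleaner
  south, and a population-weighted mean near 57 µg m⁻³, the condition the
  analysis is run at. Weekly fields are the annual mean times lognormal
  noise at CV 0.3 (strong seasonality), renormalised per cell so the
  52-week mean equals the annual mean exactly.
* **Sector-off fields**: control × (1 − f), f per cell around the
  configured sector means (defaults: the population-weighted shares
  0.35%, 2.8%, 0.02%, 21%, 16.3%, 51.6%, 10.3% for AGR/BBU/DUS/ENE/IND/
  RES/TRA). Individual fractions must lie in [0,1]; their sum may
  slightly exceed 1 (as overlapping zero-out contributions do), with a
  warning above 1.05.
* **Population**: correlated lognormal base tilted toward the polluted
  band (as the dense northern plains are), 5% of cells boosted 40× into
  urban densities, integerised by largest-remainder so the total (default
  1.302 billion) is conserved exactly.
* **Health tables**: deterministic baseline rates (adult diseases rising
  log-linearly with age between plausible anchors, ALRI concentrated in
  infancy, ±15% bounds), a strictly decreasing reference life table, and
  an India-like age pyramid.
* **Observations**: bilinear samples of the annual/seasonal fields at 45
  random sites plus Gaussian noise (SD 10 µg m⁻³).

Not emulated: atmospheric chemistry and meteorology, emission inventories,
sub-cell population structure, spatial correlation between urban cells and
pollution peaks beyond the shared band, any real file formats beyond the
generic NetCDF/CSV schemas. Passing tests therefore demonstrate the
correctness and qualitative behaviour of the *method* (saturation gap
between apportionment methods, resolution and capping responses,
conservation and determinism), not agreement with any real monitoring or
census data.

## Numerical and design choices

* Ensemble-mean RR is computed exactly per cell (vectorised draws ×
  cells), not interpolated from a curve, so brute-force oracles agree to
  1e-9.
* Empirical percentiles use linear interpolation between order statistics.
* Degenerate inputs fail fast: zero total population, mismatched grids,
  RR < 1, non-monotone life tables, fractions outside [0,1].
* Problem sizes: the analysis drivers use a 60×60 grid with 1000 draws
  (~seconds per driver); tests use 8×8–30×30 grids and 60–1000 draws,
  sizes at which every brute-force oracle is exact and fast.
* Determinism: all randomness flows from one seed through
  `numpy.random.SeedSequence` substreams; rerunning any driver or the
  pipeline with the same seed reproduces every table byte-for-byte.

## Known limitations

* The IER parameter stand-ins shape-match published ambient-range curves
  but are not fitted to cohort data; absolute burden numbers from the
  synthetic configuration are illustrative, not estimates for any real
  population.
* No indoor/household exposure, no morbidity endpoints, no partial
  (sub-100%) sector reductions.
* The quadrature UI treats components as independent; correlations (e.g.
  between baseline rates and age structure) are ignored by construction.
* NetCDF output uses the NETCDF3_CLASSIC format for portability.
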