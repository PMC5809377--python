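"""Sensitivity of the mortality estimate to resolution, capping, baseline
rates and life table.

Re-runs the burden calculation with (a) the concentration and population
grids coarsened 10x, (b) concentrations capped at 80 and at 50 ug m^-3,
(c) region-specific baseline-mortality scaling, and (d) a lower life
table (YLL only), and reports each change relative to the reference run.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np
import pandas as pd

from common import RESULTS, SEED, ensure_dirs, get_bundle
from pm25burden.burden import (
    LifeTable,
    apply_state_scaling,
    compute_burden,
    total_burden,
    total_yll,
)
from pm25burden.exposure import cap_concentrations, coarsen, population_weighted_mean
from pm25burden.regions import rasterize_regions


def burden_on(conc, pop, b, lt=None, region_masks=None, bm_by_region=None):
    return compute_burden(
        conc, pop, b["ages"], b["baseline_mortality"], b["ensemble"],
        lt or b["life_table"], region_masks=region_masks,
        bm_by_region=bm_by_region, urban_split=False,
    )


def main() -> None:
    ensure_dirs()
    b = get_bundle()
    control, pop = b["control"], b["population"]

    bt_ref = burden_on(control, pop, b)
    m_ref = total_burden(bt_ref)
    y_ref = total_yll(bt_ref)
    pwm_ref = population_weighted_mean(control, pop)
    rows = [{"case": "reference", "pwm": pwm_ref, "mortality": m_ref,
             "delta_pwm_pct": 0.0, "delta_mortality_pct": 0.0}]

    # (a) resolution degradation: 10x coarser grids
    conc_c = coarsen(control, 10, "concentration")
    pop_c = coarsen(pop, 10, "population")
    m = total_burden(burden_on(conc_c, pop_c, b))
    pwm = population_weighted_mean(conc_c, pop_c)
    rows.append({"case": "coarsen_10x", "pwm": pwm, "mortality": m,
                 "delta_pwm_pct": 100 * (pwm / pwm_ref - 1),
                 "delta_mortality_pct": 100 * (m / m_ref - 1)})

    # (b) concentration caps
    for cap in (80.0, 50.0):
        capped = cap_concentrations(control, cap)
        m = total_burden(burden_on(capped, pop, b))
        pwm = population_weighted_mean(capped, pop)
        rows.append({"case": f"cap_{cap:.0f}", "pwm": pwm, "mortality": m,
                     "delta_pwm_pct": 100 * (pwm / pwm_ref - 1),
                     "delta_mortality_pct": 100 * (m / m_ref - 1)})

    # (c) region-specific baseline mortality (ratios around 1)
    masks = rasterize_regions(b["regions_geojson"], control.spec)
    rng = np.random.default_rng(SEED)
    ratios = {name: float(np.exp(rng.normal(0.0, 0.15))) for name in masks}
    bm_by_region = apply_state_scaling(b["baseline_mortality"], ratios)
    bt = burden_on(control, pop, b, region_masks=masks, bm_by_region=bm_by_region)
    m = sum(total_burden(bt, region=r) for r in masks)
    rows.append({"case": "state_baseline_rates", "pwm": pwm_ref, "mortality": m,
                 "delta_pwm_pct": 0.0,
                 "delta_mortality_pct": 100 * (m / m_ref - 1)})

    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "sensitivity_mortality.csv", index=False)

    # (d) alternative (lower) life table: affects YLL only
    frame = b["life_table"].to_frame()
    alt_lt = LifeTable(dict(zip(frame["age_group"], 0.4 * frame["le_remaining"])))
    y_alt = total_yll(burden_on(control, pop, b, lt=alt_lt))
    pd.DataFrame(
        [{"case": "reference", "yll": y_ref},
         {"case": "lower_life_table", "yll": y_alt,
          "delta_yll_pct": 100 * (y_alt / y_ref - 1)}]
    ).to_csv(RESULTS / "sensitivity_yll.csv", index=False)

    print(table.to_string(index=False))
    coarse = table.set_index("case").loc["coarsen_10x"]
    print(
        f"\nCoarsening changes population-weighted PM2.5 by "
        f"{coarse['delta_pwm_pct']:+.0f}% but mortality by only "
        f"{coarse['delta_mortality_pct']:+.0f}% — the saturating "
        "exposure-response damps the burden response to losing the peak."
    )
    print(f"Lower life table: YLL {100 * (y_alt / y_ref - 1):.0f}% vs reference.")


if __name__ == "__main__":
    main()
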