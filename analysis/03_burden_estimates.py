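"""Premature mortality and years of life lost with 95% uncertainty intervals.

Computes the disease/age/region burden tables on the control scenario,
assembles the national 95UI by combining population, exposure-response
(with PM2.5 variability folded in) and baseline-mortality fractional
errors in quadrature, and reports the urban/rural and disease splits.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from common import RESULTS, ensure_dirs, get_bundle
from pm25burden.burden import compute_burden, total_burden, total_yll
from pm25burden.exposure import population_weighted_mean
from pm25burden.regions import rasterize_regions
from pm25burden.uncertainty import (
    POPULATION_FRACTIONAL_ERROR,
    baseline_fractional_errors,
    combine_burden_ui,
    pm25_fractional_error,
    rr_fractional_errors,
)


def main() -> None:
    ensure_dirs()
    b = get_bundle()
    control, pop = b["control"], b["population"]
    masks = rasterize_regions(b["regions_geojson"], control.spec)

    bt = compute_burden(
        control, pop, b["ages"], b["baseline_mortality"], b["ensemble"],
        b["life_table"], region_masks=masks,
    )
    bt.to_csv(RESULTS / "burden_by_stratum.csv", index=False)

    pwm = population_weighted_mean(control, pop)
    pm_frac = pm25_fractional_error(b["weekly"], pop)
    sel = bt[(bt["region"] == "India") & (bt["class"] == "total")]
    weights = sel.groupby("disease")["mortality_mean"].sum()
    rr_lo, rr_hi = rr_fractional_errors(
        b["ensemble"], pwm, weights.to_dict(), pm_fraction=pm_frac
    )
    base_lo, base_hi = baseline_fractional_errors(b["baseline_mortality"], bt)
    components = {
        "population": POPULATION_FRACTIONAL_ERROR,
        "rr": (rr_lo, rr_hi),
        "baseline": (base_lo, base_hi),
    }
    m_ui = combine_burden_ui(total_burden(bt), components)
    y_ui = combine_burden_ui(total_yll(bt), components)

    urban_share = total_burden(bt, klass="urban") / m_ui.mean
    shares = (weights / weights.sum()).round(3)
    totals = pd.DataFrame(
        [
            {"quantity": "mortality", "mean": m_ui.mean,
             "lower_95": m_ui.lower_95, "upper_95": m_ui.upper_95},
            {"quantity": "yll", "mean": y_ui.mean,
             "lower_95": y_ui.lower_95, "upper_95": y_ui.upper_95},
        ]
    )
    totals.to_csv(RESULTS / "burden_totals.csv", index=False)
    shares.rename("share").to_csv(RESULTS / "disease_shares.csv")

    print(
        f"Premature mortality: {m_ui.mean:,.0f} per year "
        f"(95UI {m_ui.lower_95:,.0f}-{m_ui.upper_95:,.0f})"
    )
    print(
        f"Years of life lost:  {y_ui.mean:,.0f} per year "
        f"(95UI {y_ui.lower_95:,.0f}-{y_ui.upper_95:,.0f})"
    )
    print(f"Urban share of mortality: {urban_share:.0%}")
    print("Disease shares of the burden:")
    print(shares.to_string())
    print(
        "\nComponent fractional errors (low/high): "
        f"population {POPULATION_FRACTIONAL_ERROR:.2f}, "
        f"exposure-response {rr_lo:.2f}/{rr_hi:.2f} (PM2.5 folded in), "
        f"baseline {base_lo:.2f}/{base_hi:.2f}"
    )


if __name__ == "__main__":
    main()
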