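"""Sector-specific mortality by the subtraction and attribution methods.

Runs both apportionment methods over all seven zero-out scenarios and
contrasts them: because the exposure-response saturates at the high
concentrations of the polluted band, the attribution estimate exceeds
the subtraction (averted-mortality) estimate for every major sector.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import RESULTS, ensure_dirs, get_bundle
from pm25burden.apportion import apportion_all


def main() -> None:
    ensure_dirs()
    b = get_bundle()
    table = apportion_all(
        b["scenarios"], b["population"], b["ages"], b["baseline_mortality"],
        b["ensemble"], b["life_table"],
    )
    table.to_csv(RESULTS / "sector_apportionment.csv", index=False)

    m_all = table.attrs["m_all"]
    body = table[table["sector"] != "TOTAL"].set_index("sector")
    total = table[table["sector"] == "TOTAL"].iloc[0]

    print(f"Control-scenario premature mortality: {m_all:,.0f} per year\n")
    show = body[["pm_reduction", "m_subtraction", "percent_subtraction",
                 "m_attribution", "percent_attribution"]].copy()
    show["m_subtraction"] = show["m_subtraction"].round(0)
    show["m_attribution"] = show["m_attribution"].round(0)
    print(show.to_string())

    major = body.loc[["ENE", "IND", "RES", "TRA"]]
    ratios = major["m_attribution"] / major["m_subtraction"]
    print(
        f"\nAttribution/subtraction ratio for the major sectors: "
        f"{ratios.min():.1f}-{ratios.max():.1f} "
        "(saturation of the exposure-response at high PM2.5)."
    )
    print(
        f"Sector sums: subtraction {total['percent_subtraction']:.0f}% of control, "
        f"attribution {total['percent_attribution']:.0f}% of control "
        "(neither method is forced to close at 100%)."
    )


if __name__ == "__main__":
    main()
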