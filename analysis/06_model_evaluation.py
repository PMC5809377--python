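"""Evaluate the (synthetic) model PM2.5 fields against site observations.

Samples the annual and seasonal mean fields at the monitoring-site
locations and reports normalised mean bias, Pearson correlation and the
OLS best-fit slope per season.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import RESULTS, ensure_dirs, get_bundle
from pm25burden.evaluation import evaluation_report, week_seasons


def main() -> None:
    ensure_dirs()
    b = get_bundle()
    control, weekly = b["control"], b["weekly"]

    labels = week_seasons(weekly.shape[0])
    fields = {"annual": control}
    for season in ("DJF", "MAM", "JJA", "SON"):
        fields[season] = control.copy_with(weekly[labels == season].mean(axis=0))

    report = evaluation_report(fields, b["observations"])
    report.to_csv(RESULTS / "evaluation_metrics.csv", index=False)
    print(report.to_string(index=False))
    annual = report.set_index("season").loc["annual"]
    print(
        f"\nAnnual means: NMB {annual['nmb']:+.2f}, r {annual['pearson_r']:.2f}, "
        f"slope {annual['slope']:.2f} over {annual['n_sites']:.0f} sites "
        "(site values are field samples plus observation noise, so the "
        "statistics mainly reflect the configured noise level)."
    )


if __name__ == "__main__":
    main()
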