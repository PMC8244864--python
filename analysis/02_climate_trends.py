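#!/usr/bin/env python
"""Yearly climate trends in the 15-year synthetic series.

Regresses yearly rainfall totals, storm counts and mean diurnal temperature
range on year (OLS).  With the generator's 3%/year rainfall decline and
constant storm frequency, rainfall should trend significantly downward
while storms stay flat -- the regime in which an ever larger share of the
rain arrives as storms.  Writes results/climate_trends.csv.
"""

from pathlib import Path

import pandas as pd
import statsmodels.api as sm

from nestdecay.climate import aggregate_climate, read_climate_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def trend(series: pd.Series) -> dict:
    X = sm.add_constant(series.index.astype(float))
    fit = sm.OLS(series.to_numpy(), X).fit()
    return {"slope": fit.params[1], "r_squared": fit.rsquared,
            "p_value": fit.pvalues[1]}


def main():
    clim = read_climate_table(ROOT / "study" / "climate_15y.csv")
    yearly = aggregate_climate(clim, by="year")
    yearly["period"] = yearly["period"].astype(int)
    yearly = yearly.set_index("period")

    rows = []
    for col, label in [("total_rain_mm", "yearly rainfall (mm)"),
                       ("n_storms", "yearly storm count"),
                       ("mean_diff_temp_c", "diurnal temperature range (C)")]:
        t = trend(yearly[col])
        rows.append({"quantity": label, **t})
        print(f"{label:34s} slope {t['slope']:+9.3f}/yr  "
              f"R2 {t['r_squared']:.3f}  p {t['p_value']:.4f}")
    out = ROOT / "climate_trends.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    yearly.to_csv(ROOT / "climate_yearly.csv")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
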