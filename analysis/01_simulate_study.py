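#!/usr/bin/env python
"""Generate the synthetic study all later analysis steps consume.

Produces, under results/study/:
  climate_15y.csv  -- 15 years of daily climate with a 3%/year rainfall
                      decline (for the trend analysis);
  climate.csv      -- the two monitoring years of climate;
  nests.csv        -- a ~1,500-nest monitored cohort (weekly visits,
                      censored at study end);
  design.csv       -- the generator's truth category table;
  surveys.csv      -- two survey windows splitting the cohort;
  truth.json       -- every latent value the generator committed to.
"""

import dataclasses
import datetime as dt
import json
from pathlib import Path

from nestdecay.climate import CLIMATE_COLUMNS
from nestdecay.core import write_nest_table
from nestdecay.simulate import (ClimateSimConfig, CohortSimConfig,
                                simulate_climate, simulate_cohort)

SEED = 20160701
OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    long_cfg = ClimateSimConfig(start=dt.date(2003, 1, 1),
                                end=dt.date(2017, 12, 31),
                                yearly_trend=0.97, seed=SEED)
    simulate_climate(long_cfg)[CLIMATE_COLUMNS].to_csv(
        OUT / "climate_15y.csv", index=False)

    clim_cfg = ClimateSimConfig(seed=SEED + 1)
    clim = simulate_climate(clim_cfg)
    clim[CLIMATE_COLUMNS].to_csv(OUT / "climate.csv", index=False)

    cohort_cfg = CohortSimConfig(seed=SEED + 2)
    records, design, truth = simulate_cohort(cohort_cfg, climate=clim)
    write_nest_table(records, OUT / "nests.csv")
    design.to_csv(OUT / "design.csv", index=False)
    (OUT / "surveys.csv").write_text(
        "label,start_date,end_date\n"
        "S4,2016-07-01,2017-06-30\nS5,2017-07-01,2018-06-30\n")
    with open(OUT / "truth.json", "w") as fh:
        json.dump({
            "seed": SEED,
            "theta": truth["theta"],
            "base": truth["base"],
            "coefficients": truth["coefficients"],
            "overall_mean_mu": truth["overall_mean_mu"],
            "overall_mean_observed": truth["overall_mean_observed"],
            "censored_fraction": truth["censored_fraction"],
            "n_nests": len(records),
        }, fh, indent=2)

    print(f"study written to {OUT}")
    print(f"  {len(records)} nests in {cohort_cfg.n_groups} groups; "
          f"true mean decay {truth['overall_mean_mu']:.1f} days "
          f"(expected observed {truth['overall_mean_observed']:.1f}); "
          f"{100 * truth['censored_fraction']:.1f}% censored")


if __name__ == "__main__":
    main()
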