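"""Marginally standardised mortality rates by calendar period and by age.

Per-cause Poisson models (exposure, age + age², sex, period, time after
entry, exposure interactions; log person-time offset) are standardised by
g-computation to the exposed cohort's own profile, giving rates per 100 000
person-years — the trend and age-profile tables.  Also reports the
drug-poisoning share of all-cause mortality by age.
Writes results/rates_period.csv and results/rates_age.csv.
"""

from pathlib import Path

import pandas as pd

from opiomort import io
from opiomort.causes import NCD_CAUSES
from opiomort.lexis import read_cells
from opiomort.projection import percent_change
from opiomort.ratemodel import RateModelSpec, cause_fraction, fit_cells, marginal_rates
from opiomort.smr import ALL_CAUSE
from opiomort.timeaxes import PERIOD_LABELS

RESULTS = Path(__file__).resolve().parents[1] / "results"

CAUSES = {"all": ALL_CAUSE, "drug_poisoning": "drug_poisoning",
          "non_communicable": NCD_CAUSES}


def main():
    cells = read_cells(RESULTS / "cells.csv")
    exposed = cells[cells["exposed"]]
    periods = [p for p in PERIOD_LABELS if p in set(exposed["period_bin"])]
    ages = list(range(20, 61, 5))

    period_tabs, age_tabs, age_series = [], [], {}
    for label, cause in CAUSES.items():
        f = fit_cells(cells, RateModelSpec(cause=cause))
        sp = marginal_rates(f, "period_bin", periods, exposed)
        sp.table.insert(0, "cause", label)
        period_tabs.append(sp.table)
        sa = marginal_rates(f, "age_years", ages, exposed)
        age_series[label] = sa
        sa_t = sa.table.copy()
        sa_t.insert(0, "cause", label)
        age_tabs.append(sa_t)

    period_df = pd.concat(period_tabs, ignore_index=True)
    age_df = pd.concat(age_tabs, ignore_index=True)
    io.write_table(period_df, RESULTS / "rates_period.csv")
    io.write_table(age_df, RESULTS / "rates_age.csv")

    print("standardised rates per 100 000 py by period (exposed profile):")
    print(period_df.round(1).to_string(index=False))
    dp = period_df[period_df["cause"] == "drug_poisoning"].set_index("period_bin")["rate"]
    print(f"\ndrug poisoning {dp['2010-12']:.0f} -> {dp['2016-18']:.0f} per 100k: "
          f"{percent_change(dp, '2010-12', '2016-18'):+.0f}% from 2010-12 to 2016-18")

    frac = cause_fraction(age_series["all"], age_series["drug_poisoning"])
    print("\ndrug-poisoning share of all-cause mortality by age:")
    print(frac.round(1).to_string())


if __name__ == "__main__":
    main()
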