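"""Population-ageing counterfactual: hold age-specific rates fixed and let
only the population age structure drift.

The synthetic age structure interpolates the under-40 anchors (89% in 2001,
52% in 2018).  Applying the modelled age-specific rates to it isolates how
much of each cause's trend ageing alone would produce.  Writes
results/age_structure.csv and results/projection.csv.
"""

from pathlib import Path

import pandas as pd

from opiomort import io
from opiomort.causes import NCD_CAUSES
from opiomort.lexis import read_cells
from opiomort.projection import (
    percent_change,
    project,
    synth_age_structure,
    write_age_structure,
)
from opiomort.ratemodel import RateModelSpec, fit_cells, marginal_rates

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    cells = read_cells(RESULTS / "cells.csv")
    exposed = cells[cells["exposed"]]
    structure = synth_age_structure((2001, 2018))
    write_age_structure(structure, RESULTS / "age_structure.csv")
    print(f"age structure: under-40 share {structure.under_40(2001):.0%} (2001) "
          f"-> {structure.under_40(2018):.0%} (2018)")

    ages = sorted(set(structure.table["age"]))
    rows = []
    for label, cause in (("drug_poisoning", "drug_poisoning"),
                         ("non_communicable", NCD_CAUSES)):
        f = fit_cells(cells, RateModelSpec(cause=cause))
        series = project(marginal_rates(f, "age_years", ages, exposed), structure)
        for year, rate in series.items():
            rows.append({"cause": label, "year": year, "rate": rate})
        print(f"{label}: {series[2010]:.0f} -> {series[2018]:.0f} per 100k, "
              f"{percent_change(series, 2010, 2018):+.0f}% 2010->2018 "
              f"({percent_change(series, 2001, 2018):+.0f}% 2001->2018) "
              "from ageing alone")
    io.write_table(pd.DataFrame(rows), RESULTS / "projection.csv")


if __name__ == "__main__":
    main()
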