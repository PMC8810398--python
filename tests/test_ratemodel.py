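import datetime as dt
import logging

import numpy as np
import pandas as pd
import pytest

from opiomort.ratemodel import (
    RateModelSpec,
    build_design,
    cause_fraction,
    fit,
    fit_cells,
    marginal_rates,
)
from opiomort.causes import EXCLUSIVE_LABELS


def _cells(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "member_id", "exposed", "match_set_id", "sex", "period_bin",
            "age_years", "tse_band", "person_time", "cause_exclusive",
        ],
    )


def _stratum(exposed, sex, period, deaths, py, age=35, tse=0):
    """Cells realising a stratum with the given death count and person-time."""
    rows = []
    for k in range(deaths):
        rows.append((0, exposed, 0, sex, period, age, tse, py / (deaths + 1), "x"))
    rows.append((0, exposed, 0, sex, period, age, tse, py / (deaths + 1), None))
    return rows


class TestClosedForms:
    def test_single_stratum_intercept_is_log_rate(self):
        cells = _cells(_stratum(True, "F", "2001-03", deaths=3, py=12.0))
        f = fit_cells(cells, RateModelSpec(cause="all", terms=()))
        assert f.params["const"] == pytest.approx(np.log(3 / 12.0), abs=1e-8)

    def test_two_strata_exposure_coefficient_is_log_rate_ratio(self):
        cells = _cells(
            _stratum(True, "F", "2001-03", deaths=8, py=10.0)
            + _stratum(False, "F", "2001-03", deaths=2, py=20.0)
        )
        f = fit_cells(cells, RateModelSpec(cause="all", terms=("exposed",)))
        assert f.params["exposed"] == pytest.approx(np.log(8.0), abs=1e-6)

    def test_aggregation_invariance(self):
        """Splitting cells into slices with identical covariates leaves the
        fitted coefficients unchanged (likelihood invariance)."""
        base = _cells(
            _stratum(True, "F", "2001-03", 8, 10.0)
            + _stratum(False, "M", "2004-06", 2, 20.0, age=50, tse=1)
        )
        quarter = base.assign(person_time=base["person_time"] / 4)
        sliced = pd.concat(
            [quarter] + [quarter.assign(cause_exclusive=None)] * 3
        ).reset_index(drop=True)
        spec = RateModelSpec(cause="all", terms=("exposed", "age", "sex"))
        f1, f2 = fit_cells(base, spec), fit_cells(sliced, spec)
        assert np.allclose(f1.params, f2.params, atol=1e-8)


def test_rank_deficient_levels_dropped_with_warning(caplog):
    # no exposed person-time in 2004-06 -> exposed:period interaction level
    # for that bin is empty and must be dropped
    cells = _cells(
        _stratum(True, "F", "2001-03", 2, 10.0)
        + _stratum(False, "F", "2001-03", 1, 10.0)
        + _stratum(False, "F", "2004-06", 1, 10.0)
    )
    spec = RateModelSpec(cause="all", terms=("exposed", "period", "exposed:period"))
    with caplog.at_level(logging.WARNING, logger="opiomort.ratemodel"):
        design = build_design(cells, spec)
    assert "exposed:period_2004-06" not in design.X.columns
    assert "rank-deficient" in caplog.text
    fit(spec, design)  # still fits


def test_zero_person_time_rejected():
    cells = _cells([(0, True, 0, "F", "2001-03", 35, 0, 0.0, None)])
    with pytest.raises(ValueError, match="person_time"):
        build_design(cells, RateModelSpec())


class TestMarginalRates:
    def test_saturated_model_equals_direct_standardisation(self):
        """On exact multiplicative data, g-computation reproduces the
        directly standardised rate."""
        # rates: F/M = 0.01/0.02 in p1, tripled in p2; py weights 30/10
        py = {("F", "2001-03"): 300.0, ("M", "2001-03"): 100.0,
              ("F", "2004-06"): 300.0, ("M", "2004-06"): 100.0}
        rate = {("F", "2001-03"): 0.01, ("M", "2001-03"): 0.02,
                ("F", "2004-06"): 0.03, ("M", "2004-06"): 0.06}
        rows = []
        for (sex, period), t in py.items():
            d = int(round(rate[(sex, period)] * t))
            rows += _stratum(True, sex, period, d, t)
        cells = _cells(rows)
        spec = RateModelSpec(cause="all", terms=("sex", "period"))
        f = fit_cells(cells, spec)
        series = marginal_rates(f, "period_bin", ["2001-03", "2004-06"], cells)
        # direct standardisation over the sex distribution (3:1 person-time)
        for period, got in zip(["2001-03", "2004-06"], series.table["rate"]):
            direct = 1e5 * (0.75 * rate[("F", period)] + 0.25 * rate[("M", period)])
            assert got == pytest.approx(direct, rel=1e-7)

    def test_constant_model_marginal_is_intercept_rate(self):
        cells = _cells(
            _stratum(True, "F", "2001-03", 4, 20.0)
            + _stratum(True, "M", "2004-06", 4, 20.0, age=50)
        )
        f = fit_cells(cells, RateModelSpec(cause="all", terms=()))
        series = marginal_rates(f, "age_years", [20, 40, 60], cells)
        expect = 1e5 * np.exp(f.params["const"])
        assert np.allclose(series.table["rate"], expect, rtol=1e-10)
        assert (series.table["ci_low"] <= series.table["rate"]).all()
        assert (series.table["rate"] <= series.table["ci_high"]).all()

    def test_target_outside_support_rejected(self, demo_study):
        cells = demo_study["cells"]
        f = fit_cells(cells, RateModelSpec(cause="all"))
        with pytest.raises(ValueError, match="support"):
            marginal_rates(f, "period_bin", ["1998-00"], cells[cells["exposed"]])


class TestRecovery:
    def test_exposure_coefficient_recovery(self):
        """Interaction-free exposure coefficient recovers the simulated
        log rate ratio within 3 SE."""
        from opiomort.cohort import build_cohort
        from opiomort.lexis import expand_cohort
        from opiomort.synthetic import HazardSpec, PopulationConfig, simulate_population

        rr = 3.0
        cfg = PopulationConfig(
            n_individuals=8000,
            exposure_prevalence=0.25,
            hazards=(HazardSpec("any", np.log(0.006), exposure_log_rr=np.log(rr)),),
            seed=21,
        )
        registry, _ = simulate_population(cfg)
        members, _ = build_cohort(registry, seed=22)
        cells = expand_cohort(members, registry, cause_col="cause_label")
        f = fit_cells(
            cells,
            RateModelSpec(cause="all", terms=("exposed", "age", "sex", "period", "tse")),
            cause_col="event_cause",
        )
        se = float(np.sqrt(f.cov.loc["exposed", "exposed"]))
        assert abs(f.params["exposed"] - np.log(rr)) < 3 * se

    def test_wald_coverage_of_exposure_coefficient(self):
        """95% Wald intervals for the exposure log rate ratio cover the truth
        between 90% and 99% of the time over 100 small replicates."""
        from opiomort.lexis import expand_cohort
        from opiomort.synthetic import HazardSpec, PopulationConfig, simulate_population
        from opiomort.timeaxes import WASHOUT_DAYS

        truth = np.log(2.0)
        cover = 0
        n_rep = 100
        for rep in range(n_rep):
            cfg = PopulationConfig(
                n_individuals=1500,
                exposure_prevalence=0.5,
                birth_year_range=(1950, 1980),
                registration_window=(dt.date(1995, 1, 1), dt.date(1999, 1, 1)),
                exposure_onset_window=(dt.date(1998, 1, 1), dt.date(2000, 12, 31)),
                hazards=(HazardSpec("any", np.log(0.02), exposure_log_rr=truth),),
                study_end=dt.date(2007, 12, 31),
                seed=1000 + rep,
            )
            registry, _ = simulate_population(cfg)
            # entry/exit without matching: the invariant concerns the GLM
            entry = (
                pd.to_datetime(registry["registration_date"])
                + pd.Timedelta(days=WASHOUT_DAYS)
            ).clip(lower=pd.Timestamp("2001-01-01"))
            exit_ = pd.to_datetime(registry["death_date"]).fillna(
                pd.Timestamp("2007-12-31")
            )
            members = pd.DataFrame(
                {
                    "person_id": registry["person_id"],
                    "exposed": registry["exposure_date"].notna(),
                    "entry_date": entry,
                    "exit_date": exit_,
                    "match_set_id": 0,
                }
            )
            members = members[members["entry_date"] < members["exit_date"]]
            cells = expand_cohort(members, registry, cause_col="cause_label")
            f = fit_cells(
                cells,
                RateModelSpec(cause="all", terms=("exposed",)),
                cause_col="event_cause",
            )
            se = float(np.sqrt(f.cov.loc["exposed", "exposed"]))
            est = float(f.params["exposed"])
            if est - 1.96 * se <= truth <= est + 1.96 * se:
                cover += 1
        assert 90 <= cover <= 99


def test_cause_specific_fitted_counts_sum_to_all_cause(demo_study):
    """Fitted expected death counts of the mutually exclusive causes sum to
    within 2% of the all-cause fitted count (competing-risk approximation)."""
    cells = demo_study["cells"]
    spec_terms = ("exposed", "age", "age2", "sex", "period", "tse")
    total = 0.0
    for cause in EXCLUSIVE_LABELS:
        f = fit_cells(cells, RateModelSpec(cause=cause, terms=spec_terms))
        d = f.design
        total += float(np.exp(d.X.to_numpy() @ f.params.to_numpy() + d.offset).sum())
    f_all = fit_cells(cells, RateModelSpec(cause="all", terms=spec_terms))
    d = f_all.design
    fitted_all = float(np.exp(d.X.to_numpy() @ f_all.params.to_numpy() + d.offset).sum())
    assert total == pytest.approx(fitted_all, rel=0.02)


def test_cause_fraction_percentages():
    from opiomort.ratemodel import StandardizedRateSeries

    mk = lambda cause, rates: StandardizedRateSeries(
        cause, "age_years",
        pd.DataFrame({"age_years": [25, 50], "rate": rates,
                      "ci_low": rates, "ci_high": rates}),
    )
    frac = cause_fraction(mk("all", [582.0, 2223.0]), mk("dp", [348.0, 1155.0]))
    assert frac[25] == pytest.approx(59.8, abs=0.05)
    assert frac[50] == pytest.approx(52.0, abs=0.05)
    same = cause_fraction(mk("all", [100.0, 100.0]), mk("c", [100.0, 100.0]))
    assert np.allclose(same, 100.0)
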