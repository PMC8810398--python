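"""Standardised mortality ratios with matched-set bootstrap intervals.

Expected deaths come from age-band × sex × calendar-period mortality rates
in the comparison group applied to the exposed person-time, stratum by
stratum; the SMR is observed / expected.  Confidence intervals are
percentile bootstrap: matched sets (one exposed member plus their sampled
comparators) are resampled with replacement, the comparison rates and
expected deaths are recomputed on each resample, and the 2.5% / 97.5%
quantiles of the resampled SMRs are reported.  The conventional Poisson-SE
interval assumes the expected count is error-free and is deliberately not
offered.

Strata with exposed person-time but no comparison person-time contribute
zero expected deaths; the uncovered person-time is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALL_CAUSE = "all"
DEFAULT_AGE_BAND_WIDTH = 5
_MIN_AGE = 18

__all__ = [
    "ALL_CAUSE",
    "DEFAULT_AGE_BAND_WIDTH",
    "StratumRateTable",
    "SMRResult",
    "age_band",
    "comparison_rates",
    "expected_deaths",
    "bootstrap_smr",
]


def age_band(age_years, width: int = DEFAULT_AGE_BAND_WIDTH) -> np.ndarray:
    """Lower bound of the age band containing each completed age
    (width 5 gives 18–22, 23–27, …)."""
    a = np.asarray(age_years)
    return _MIN_AGE + width * ((a - _MIN_AGE) // width)


@dataclass
class StratumRateTable:
    """Comparison-group deaths, person-time and rates by stratum.

    ``person_time`` is a Series indexed by (age_band, sex, period_bin);
    ``deaths`` a DataFrame on the same index with one column per cause plus
    :data:`ALL_CAUSE`.  Rates are undefined (NaN), not zero, where the
    person-time is zero.
    """

    person_time: pd.Series
    deaths: pd.DataFrame
    age_band_width: int = DEFAULT_AGE_BAND_WIDTH

    def rate(self, cause: str) -> pd.Series:
        if cause not in self.deaths.columns:
            return pd.Series(0.0, index=self.person_time.index)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.deaths[cause] / self.person_time
        return r.where(self.person_time > 0)

    @property
    def causes(self) -> list:
        return [c for c in self.deaths.columns if c != ALL_CAUSE]


def _stratum_frame(cells: pd.DataFrame, width: int, cause_col: str) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "age_band": age_band(cells["age_years"].to_numpy(), width),
            "sex": cells["sex"].to_numpy(),
            "period_bin": cells["period_bin"].to_numpy(),
            "person_time": cells["person_time"].to_numpy(),
            "cause": cells[cause_col].to_numpy(),
        }
    )
    return df


def comparison_rates(
    cells: pd.DataFrame,
    age_band_width: int = DEFAULT_AGE_BAND_WIDTH,
    cause_col: str = "cause_exclusive",
) -> StratumRateTable:
    """Aggregate comparison-group cells into a stratum rate table."""
    if cells["exposed"].any():
        raise ValueError("comparison_rates requires comparison-group cells only")
    df = _stratum_frame(cells, age_band_width, cause_col)
    keys = ["age_band", "sex", "period_bin"]
    pt = df.groupby(keys)["person_time"].sum()
    events = df[df["cause"].notna()]
    deaths = (
        events.groupby(keys + ["cause"]).size().unstack("cause", fill_value=0)
    )
    deaths = deaths.reindex(pt.index, fill_value=0)
    deaths[ALL_CAUSE] = events.groupby(keys).size().reindex(pt.index, fill_value=0)
    n_empty = int((pt <= 0).sum())
    if n_empty:
        logger.warning("%d strata have zero comparison person-time", n_empty)
    return StratumRateTable(pt, deaths, age_band_width)


def expected_deaths(
    exposed_cells: pd.DataFrame,
    rates: StratumRateTable,
    cause_col: str = "cause_exclusive",
) -> pd.Series:
    """Expected deaths per cause: Σ over strata of exposed person-time times
    the comparison rate.  Returns a Series indexed by cause (including
    :data:`ALL_CAUSE`).  Exposed strata with no defined comparison rate
    contribute zero and the uncovered person-time is logged."""
    df = _stratum_frame(exposed_cells, rates.age_band_width, cause_col)
    pt = df.groupby(["age_band", "sex", "period_bin"])["person_time"].sum()
    defined = rates.person_time > 0
    out = {}
    for cause in list(rates.deaths.columns):
        aligned = rates.rate(cause).reindex(pt.index)
        out[cause] = float((pt * aligned).sum(skipna=True))
    uncovered = float(pt[~pt.index.isin(rates.person_time.index[defined])].sum())
    if uncovered > 0:
        logger.warning(
            "%.2f exposed person-years fall in strata with no comparison rate",
            uncovered,
        )
    return pd.Series(out, name="expected")


@dataclass
class SMRResult:
    cause: str
    observed: int
    expected: float
    smr: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_degenerate: int = 0


def _set_matrices(cells: pd.DataFrame, cause: str, width: int, cause_col: str):
    """Per-set stratum matrices for the bootstrap.

    Returns (set_ids, Texp, Dexp, Tcmp, Dcmp) where T* are (n_sets, n_strata)
    person-time matrices, Dexp the exposed death count per set for ``cause``,
    and Dcmp the comparison death counts per (set, stratum).
    """
    df = _stratum_frame(cells, width, cause_col)
    df["set"] = cells["match_set_id"].to_numpy()
    df["exposed"] = cells["exposed"].to_numpy()
    s_codes, strata = pd.factorize(
        pd.MultiIndex.from_frame(df[["age_band", "sex", "period_bin"]]), sort=True
    )
    df["s"] = s_codes
    g_codes, set_ids = pd.factorize(df["set"].to_numpy(), sort=True)
    df["g"] = g_codes
    G, S = len(set_ids), len(strata)

    if isinstance(cause, str) and cause == ALL_CAUSE:
        is_event = df["cause"].notna().to_numpy()
    elif isinstance(cause, (tuple, list, set, frozenset)):
        is_event = df["cause"].isin(list(cause)).to_numpy()
    else:
        is_event = (df["cause"] == cause).fillna(False).to_numpy()
    exp_m = df["exposed"].to_numpy()

    def accumulate(mask, values):
        m = np.zeros((G, S))
        np.add.at(m, (df["g"].to_numpy()[mask], df["s"].to_numpy()[mask]), values[mask])
        return m

    pt = df["person_time"].to_numpy()
    ones = np.ones(len(df))
    Texp = accumulate(exp_m, pt)
    Tcmp = accumulate(~exp_m, pt)
    Dcmp = accumulate(~exp_m & is_event, ones)
    Dexp = np.zeros(G)
    np.add.at(Dexp, df["g"].to_numpy()[exp_m & is_event], 1.0)
    return set_ids, Texp, Dexp, Tcmp, Dcmp


def bootstrap_smr(
    sets: pd.DataFrame,
    cells: pd.DataFrame,
    cause: str = ALL_CAUSE,
    n_boot: int = 1000,
    seed: int = 0,
    age_band_width: int = DEFAULT_AGE_BAND_WIDTH,
    cause_col: str = "cause_exclusive",
) -> SMRResult:
    """Point SMR and percentile bootstrap CI, resampling matched sets.

    The resampling unit is the matched set: an exposed member and their
    comparators always move together, so correlation induced by matching is
    respected.  Quantiles use linear interpolation.  Resamples with zero
    expected deaths are excluded from the quantiles with a warning; if every
    resample is degenerate an error names the cause.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if len(sets) < 1:
        raise ValueError("bootstrap requires at least one matched set")
    set_ids, Texp, Dexp, Tcmp, Dcmp = _set_matrices(
        cells, cause, age_band_width, cause_col
    )
    G = len(set_ids)

    def smr_from_weights(w: np.ndarray):
        # w: (reps, G) multiplicity of each matched set
        tc = w @ Tcmp
        dc = w @ Dcmp
        te = w @ Texp
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(tc > 0, dc / np.where(tc > 0, tc, 1.0), np.nan)
        expected = np.nansum(np.where(tc > 0, te * r, np.nan), axis=1)
        observed = w @ Dexp
        return observed, expected

    obs0, exp0 = smr_from_weights(np.ones((1, G)))
    observed, expected = float(obs0[0]), float(exp0[0])
    if expected <= 0:
        raise ValueError(f"no expected deaths for cause {cause!r}")
    point = observed / expected

    rng = np.random.default_rng(seed)
    smrs = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(2e8 // max(G, 1) // 8)))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        draws = rng.integers(0, G, size=(b, G))
        w = np.stack([np.bincount(d, minlength=G) for d in draws]).astype(float)
        o, e = smr_from_weights(w)
        with np.errstate(invalid="ignore", divide="ignore"):
            smrs[done : done + b] = np.where(e > 0, o / np.where(e > 0, e, 1.0), np.nan)
        done += b
    degenerate = int(np.isnan(smrs).sum())
    valid = smrs[~np.isnan(smrs)]
    if len(valid) == 0:
        raise ValueError(f"all bootstrap resamples degenerate for cause {cause!r}")
    if degenerate:
        logger.warning(
            "%d of %d resamples had zero expected deaths for cause %r",
            degenerate,
            n_boot,
            cause,
        )
    lo, hi = np.quantile(valid, [0.025, 0.975])  # inclusive linear interpolation
    return SMRResult(
        cause=cause,
        observed=int(observed),
        expected=expected,
        smr=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        n_degenerate=degenerate,
    )


def smr_table(
    sets: pd.DataFrame,
    cells: pd.DataFrame,
    causes,
    n_boot: int = 1000,
    seed: int = 0,
    age_band_width: int = DEFAULT_AGE_BAND_WIDTH,
    cause_col: str = "cause_exclusive",
) -> pd.DataFrame:
    """One SMR row per cause (machine-readable analogue of a cause-of-death
    forest plot)."""
    rows = []
    for k, cause in enumerate(causes):
        try:
            res = bootstrap_smr(
                sets, cells, cause, n_boot, seed + k, age_band_width, cause_col
            )
        except ValueError as err:
            # a cause can be too rare for any expected deaths at this sample
            # size; report the observed count and leave the SMR undefined
            logger.warning("SMR undefined for cause %r: %s", cause, err)
            observed = int(
                (
                    cells.loc[cells["exposed"], cause_col].notna()
                    if cause == ALL_CAUSE
                    else cells.loc[cells["exposed"], cause_col].eq(cause)
                ).sum()
            )
            rows.append(
                {
                    "cause": cause,
                    "observed": observed,
                    "expected": 0.0,
                    "smr": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "n_boot": 0,
                }
            )
            continue
        rows.append(
            {
                "cause": res.cause,
                "observed": res.observed,
                "expected": res.expected,
                "smr": res.smr,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_boot": res.n_boot,
            }
        )
    return pd.DataFrame(rows)
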