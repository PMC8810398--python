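"""Log-linear Poisson rate models on Lexis cells, and marginally
standardised rates per 100 000 person-years.

The model for each cause has death counts as the response, an offset for
log person-time, and terms for exposure, age (linear and quadratic, centred
at 35), sex, calendar period, time-after-entry band, and the interactions
of exposure with period and with time after entry.  Cells are aggregated by
covariate pattern before fitting — aggregation leaves the Poisson
likelihood unchanged — and the optimisation is delegated to statsmodels
GLM.

Marginal (g-computation) standardisation: predictions are averaged over the
exposed cohort's person-time-weighted covariate distribution with one axis
variable (period, or age) overridden to a target value, giving rates in a
cohort of 100 000 people with the cohort's own profile.  Confidence
intervals use the delta method on the weighted mean of predicted rates,
applied on the log scale so the bounds stay positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .smr import ALL_CAUSE
from .timeaxes import PERIOD_LABELS

logger = logging.getLogger(__name__)

AGE_CENTER = 35.0
PER = 100_000.0

DEFAULT_TERMS = (
    "exposed",
    "age",
    "age2",
    "sex",
    "period",
    "tse",
    "exposed:period",
    "exposed:tse",
)

__all__ = [
    "AGE_CENTER",
    "DEFAULT_TERMS",
    "RateModelSpec",
    "Design",
    "RateModelFit",
    "StandardizedRateSeries",
    "build_design",
    "fit",
    "fit_cells",
    "marginal_rates",
    "cause_fraction",
]


@dataclass(frozen=True)
class RateModelSpec:
    """Which cause to model and which terms enter the linear predictor."""

    cause: str = ALL_CAUSE
    terms: tuple = DEFAULT_TERMS
    age_center: float = AGE_CENTER


@dataclass
class Design:
    y: np.ndarray  # death counts per covariate pattern
    X: pd.DataFrame  # design matrix (named columns)
    offset: np.ndarray  # log person-time
    patterns: pd.DataFrame  # one row per aggregated covariate pattern
    spec: RateModelSpec
    period_levels: tuple = ()
    tse_levels: tuple = ()


def _pattern_table(cells: pd.DataFrame, cause: str, cause_col: str) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "exposed": cells["exposed"].to_numpy().astype(bool),
            "age_years": cells["age_years"].to_numpy(),
            "sex": cells["sex"].to_numpy(),
            "period_bin": cells["period_bin"].to_numpy(),
            "tse_band": cells["tse_band"].to_numpy(),
            "person_time": cells["person_time"].to_numpy(),
        }
    )
    if isinstance(cause, str) and cause == ALL_CAUSE:
        ev = cells[cause_col].notna()
    elif isinstance(cause, (tuple, list, set, frozenset)):
        ev = cells[cause_col].isin(list(cause))
    else:
        ev = cells[cause_col].eq(cause)
    df["deaths"] = ev.to_numpy().astype(np.int64)
    keys = ["exposed", "age_years", "sex", "period_bin", "tse_band"]
    agg = df.groupby(keys, sort=True, as_index=False).agg(
        deaths=("deaths", "sum"), person_time=("person_time", "sum")
    )
    return agg


def _design_matrix(
    patterns: pd.DataFrame,
    spec: RateModelSpec,
    period_levels,
    tse_levels,
) -> pd.DataFrame:
    X = pd.DataFrame(index=patterns.index)
    X["const"] = 1.0
    t = set(spec.terms)
    exposed = patterns["exposed"].astype(float)
    if "exposed" in t:
        X["exposed"] = exposed
    if "age" in t:
        X["age_c"] = patterns["age_years"].astype(float) - spec.age_center
    if "age2" in t:
        X["age_c2"] = (patterns["age_years"].astype(float) - spec.age_center) ** 2
    if "sex" in t:
        X["sex_M"] = (patterns["sex"] == "M").astype(float)
    if "period" in t:
        for lev in period_levels[1:]:
            X[f"period_{lev}"] = (patterns["period_bin"] == lev).astype(float)
    if "tse" in t:
        for lev in tse_levels[1:]:
            X[f"tse_{lev}"] = (patterns["tse_band"] == lev).astype(float)
    if "exposed:period" in t:
        for lev in period_levels[1:]:
            X[f"exposed:period_{lev}"] = exposed * (
                patterns["period_bin"] == lev
            ).astype(float)
    if "exposed:tse" in t:
        for lev in tse_levels[1:]:
            X[f"exposed:tse_{lev}"] = exposed * (patterns["tse_band"] == lev).astype(
                float
            )
    return X


def _drop_deficient(X: pd.DataFrame) -> pd.DataFrame:
    """Drop empty or collinear columns (with a warning) so the design has
    full column rank on the fitted data."""
    keep = [c for c in X.columns if c == "const" or X[c].abs().sum() > 0]
    dropped = [c for c in X.columns if c not in keep]
    X = X[keep]
    # greedy rank check via QR on the remaining columns
    q, r = np.linalg.qr(X.to_numpy())
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if len(diag) else 1.0)
    collinear = [c for c, d in zip(X.columns, diag) if d <= tol]
    if collinear:
        X = X.drop(columns=collinear)
        dropped += collinear
    if dropped:
        logger.warning("dropped rank-deficient design columns: %s", dropped)
    return X


def build_design(
    cells: pd.DataFrame,
    spec: RateModelSpec = RateModelSpec(),
    cause_col: str = "cause_exclusive",
) -> Design:
    """Aggregate cells by covariate pattern and build the design matrix."""
    if len(cells) == 0:
        raise ValueError("no cells to fit")
    if (cells["person_time"] <= 0).any():
        raise ValueError("cells must have positive person_time")
    patterns = _pattern_table(cells, spec.cause, cause_col)
    if patterns["person_time"].sum() <= 0:
        raise ValueError("zero total person-time")
    period_levels = tuple(
        p for p in PERIOD_LABELS if p in set(patterns["period_bin"])
    )
    tse_levels = tuple(sorted(patterns["tse_band"].unique()))
    X = _drop_deficient(_design_matrix(patterns, spec, period_levels, tse_levels))
    return Design(
        y=patterns["deaths"].to_numpy().astype(float),
        X=X,
        offset=np.log(patterns["person_time"].to_numpy()),
        patterns=patterns,
        spec=spec,
        period_levels=period_levels,
        tse_levels=tse_levels,
    )


@dataclass
class RateModelFit:
    spec: RateModelSpec
    params: pd.Series
    cov: pd.DataFrame
    design: Design
    converged: bool
    deviance: float

    def predict_rate(self, patterns: pd.DataFrame) -> np.ndarray:
        """Predicted rate (deaths per person-year) for covariate patterns."""
        X = _design_matrix(
            patterns, self.spec, self.design.period_levels, self.design.tse_levels
        )
        self._check_support(patterns)
        X = X.reindex(columns=self.params.index, fill_value=0.0)
        return np.exp(X.to_numpy() @ self.params.to_numpy())

    def _check_support(self, patterns: pd.DataFrame) -> None:
        t = set(self.spec.terms)
        if "period" in t:
            unseen = set(patterns["period_bin"]) - set(self.design.period_levels)
            if unseen:
                raise ValueError(f"period bins outside fitted support: {unseen}")
        if "tse" in t:
            unseen = set(patterns["tse_band"]) - set(self.design.tse_levels)
            if unseen:
                raise ValueError(f"tse bands outside fitted support: {unseen}")


def fit(spec: RateModelSpec, design: Design) -> RateModelFit:
    """Maximum-likelihood Poisson fit with log person-time offset
    (statsmodels GLM does the optimisation)."""
    model = sm.GLM(
        design.y,
        design.X.to_numpy(),
        family=sm.families.Poisson(),
        offset=design.offset,
    )
    res = model.fit(maxiter=200)
    if not res.converged:
        raise RuntimeError(
            f"Poisson fit did not converge for cause {spec.cause!r} "
            f"after {res.fit_history['iteration']} iterations"
        )
    cols = design.X.columns
    return RateModelFit(
        spec=spec,
        params=pd.Series(res.params, index=cols),
        cov=pd.DataFrame(res.cov_params(), index=cols, columns=cols),
        design=design,
        converged=bool(res.converged),
        deviance=float(res.deviance),
    )


def fit_cells(
    cells: pd.DataFrame,
    spec: RateModelSpec = RateModelSpec(),
    cause_col: str = "cause_exclusive",
) -> RateModelFit:
    return fit(spec, build_design(cells, spec, cause_col))


@dataclass
class StandardizedRateSeries:
    """Marginally standardised rates per 100 000 person-years along one axis
    (calendar period or single year of age)."""

    cause: str
    axis: str  # "period_bin" or "age_years"
    table: pd.DataFrame  # columns: axis value, rate, ci_low, ci_high
    reference: str = "person-time-weighted exposed cohort profile"


def marginal_rates(
    fit: RateModelFit,
    axis: str,
    targets,
    reference_cells: pd.DataFrame,
    exposed: bool = True,
) -> StandardizedRateSeries:
    """G-computation: for every reference cell predict the rate with ``axis``
    overridden to each target (exposure fixed), then average weighted by cell
    person-time and scale to 100 000 person-years."""
    if axis not in ("period_bin", "age_years"):
        raise ValueError("axis must be 'period_bin' or 'age_years'")
    # only the covariate pattern and its person-time weight matter here
    keys = ["age_years", "sex", "period_bin", "tse_band"]
    ref = (
        reference_cells.groupby(keys, sort=True, as_index=False)["person_time"].sum()
    )
    ref["exposed"] = bool(exposed)
    w = ref["person_time"].to_numpy()
    rows = []
    beta = fit.params.to_numpy()
    V = fit.cov.to_numpy()
    for target in targets:
        prof = ref.copy()
        prof[axis] = target
        if axis == "age_years":
            prof["age_years"] = float(target)
        X = _design_matrix(
            prof, fit.spec, fit.design.period_levels, fit.design.tse_levels
        )
        fit._check_support(prof)
        X = X.reindex(columns=fit.params.index, fill_value=0.0).to_numpy()
        mu = np.exp(X @ beta)
        mean = float(np.average(mu, weights=w))
        grad = (w[:, None] * mu[:, None] * X).sum(axis=0) / w.sum()
        var = float(grad @ V @ grad)
        se_log = np.sqrt(var) / mean
        with np.errstate(over="ignore"):  # a tiny mean gives an honest inf bound
            rows.append(
                {
                    axis: target,
                    "rate": PER * mean,
                    "ci_low": PER * mean * np.exp(-1.96 * se_log),
                    "ci_high": PER * mean * np.exp(1.96 * se_log),
                }
            )
    return StandardizedRateSeries(fit.spec.cause, axis, pd.DataFrame(rows))


def cause_fraction(
    series_all: StandardizedRateSeries, series_cause: StandardizedRateSeries
) -> pd.Series:
    """Cause-specific share of the all-cause rate, in percent, per axis
    point (undefined where the all-cause rate is zero)."""
    if series_all.axis != series_cause.axis:
        raise ValueError("series must share an axis")
    a = series_all.table.set_index(series_all.axis)["rate"]
    c = series_cause.table.set_index(series_cause.axis)["rate"]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = 100.0 * c / a
    frac = frac.where(a > 0)
    if frac.isna().any():
        logger.warning("all-cause rate is zero at some axis points")
    frac.name = "pct_of_all_cause"
    return frac
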