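"""Subgroup (effect-modification) analyses and the yearly-trend procedure.

Subgroup fits repeat the full analysis independently within each level of a
partition (age group, sex, period, region, or combinations): nothing is
pooled and every nuisance parameter is re-estimated per subgroup.  Because
strata are built per admission record, restricting the pooled stratum table
to a subgroup's records is exactly equivalent to re-running the pipeline on
that subgroup alone.

The yearly-trend procedure fits the fully adjusted model separately per
calendar year, draws ``n_draws`` values of the % risk change per degC from
each year's posterior, fits one ordinary-least-squares line of effect on
year per draw, and summarises the resulting slope distribution (median and
95% credible interval, in percentage points per year).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError
from .inference import FitResult, ModelSpec, fit_model, percent_change
from .design import build_design_matrix

logger = logging.getLogger(__name__)


@dataclass
class SubgroupResult:
    label: dict  # e.g. {"sex": "M", "age_group": "16-64"}
    n_events: int
    fit: FitResult | None  # None when the subgroup was skipped (too small)

    @property
    def skipped(self) -> bool:
        return self.fit is None


def subgroup_fit(
    strata: pd.DataFrame,
    by: list[str] | tuple[str, ...],
    spec: ModelSpec | None = None,
    min_events: int = 50,
) -> list[SubgroupResult]:
    """Re-fit the model independently within each level of a partition.

    ``by`` lists stratum-table columns (e.g. ``["sex", "age_group"]``).
    Subgroups with fewer than ``min_events`` admissions are skipped with a
    logged warning rather than crashing.  An empty ``by`` is the identity
    partition and reproduces the pooled fit exactly.
    """
    spec = spec or ModelSpec()
    by = list(by)
    for c in by:
        if c not in strata.columns:
            raise DataError(f"partition column {c!r} not in stratum table")
    if not by:
        groups = [((), strata)]
    else:
        groups = list(strata.groupby(by, sort=True, observed=True))

    results = []
    for key, sub in groups:
        if not isinstance(key, tuple):
            key = (key,)
        label = dict(zip(by, key))
        n_events = sub["stratum_id"].nunique()
        if n_events < min_events:
            logger.warning(
                "subgroup %s skipped: %d events < min_events=%d",
                label, n_events, min_events,
            )
            results.append(SubgroupResult(label, n_events, None))
            continue
        design = build_design_matrix(sub, adjusted=spec.adjusted)
        results.append(SubgroupResult(label, n_events, fit_model(design, spec)))
    return results


@dataclass
class TrendResult:
    """Posterior temporal trend of the temperature effect.

    ``pct_draws[i, k]`` is draw ``k`` of the % change per degC in year
    ``years[i]``; ``slopes[k]`` is the OLS slope (percentage points of risk
    change per calendar year) fitted to draw ``k`` across years.
    """

    years: np.ndarray
    pct_draws: np.ndarray  # (n_years, n_draws)
    slopes: np.ndarray  # (n_draws,)
    slope_median: float
    slope_lo: float
    slope_hi: float
    omitted_years: list
    per_year: pd.DataFrame  # per-year % change median and 95% CrI

    def to_frame(self) -> pd.DataFrame:
        return self.per_year.copy()


def slope_draws(
    years: np.ndarray,
    pct_draws: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """OLS slope of effect on calendar year, one slope per posterior draw.

    ``pct_draws`` is (n_years, n_draws); returns (n_draws,).  Equivariant:
    adding a constant to every year's effect leaves the slopes unchanged.
    """
    years = np.asarray(years, dtype=float)
    w = np.ones(len(years)) if weights is None else np.asarray(weights, float)
    yc = years - np.average(years, weights=w)
    return (w * yc) @ np.atleast_2d(pct_draws) / (w @ (yc * yc))


def yearly_trend(
    strata: pd.DataFrame,
    spec: ModelSpec | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    min_events: int = 50,
    weighted: bool = False,
) -> TrendResult:
    """Posterior-draw trend of the yearly temperature effect.

    Fits the model per calendar year, propagates posterior uncertainty by
    drawing ``n_draws`` effects per year, and regresses each draw vector on
    year (unweighted OLS by default; ``weighted=True`` uses inverse-variance
    weights).  Years with fewer than ``min_events`` admissions are omitted
    from the regression and reported in ``omitted_years``.
    """
    spec = spec or ModelSpec()
    if "year" not in strata.columns:
        raise DataError("stratum table lacks a 'year' column")
    rng = np.random.default_rng(seed)

    years, draws, variances, omitted, rows = [], [], [], [], []
    for year, sub in strata.groupby("year", sort=True):
        n_events = sub["stratum_id"].nunique()
        if n_events < min_events:
            logger.warning("year %s omitted from trend: %d events", year, n_events)
            omitted.append(int(year))
            continue
        design = build_design_matrix(sub, adjusted=spec.adjusted)
        f = fit_model(design, spec)
        beta = f.sample_coef("x_lag", n_draws, rng)
        pct = percent_change(beta)
        years.append(int(year))
        draws.append(pct)
        j = f._active.index("x_lag")
        variances.append(float(f._cov[j, j]))
        rows.append(
            (int(year), n_events, f.percent_change["median"],
             f.percent_change["lo"], f.percent_change["hi"])
        )

    if len(years) < 3:
        raise DataError(f"trend needs >= 3 usable years, got {len(years)}")

    years_arr = np.array(years, dtype=float)
    pct_draws = np.vstack(draws)  # (n_years, n_draws)
    w = 1.0 / np.asarray(variances) if weighted else None
    slopes = slope_draws(years_arr, pct_draws, w)
    med, lo, hi = np.percentile(slopes, [50, 2.5, 97.5])

    per_year = pd.DataFrame(
        rows, columns=["year", "n_events", "pct_median", "pct_lo", "pct_hi"]
    )
    return TrendResult(
        years=years_arr.astype(int),
        pct_draws=pct_draws,
        slopes=slopes,
        slope_median=float(med),
        slope_lo=float(lo),
        slope_hi=float(hi),
        omitted_years=omitted,
        per_year=per_year,
    )


def trend_by_age(
    strata: pd.DataFrame,
    spec: ModelSpec | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    min_events: int = 50,
) -> dict[str, TrendResult]:
    """Yearly trend per age group plus the pooled ("total") trend."""
    out: dict[str, TrendResult] = {}
    seq = np.random.SeedSequence(seed)
    groups = list(strata.groupby("age_group", sort=True, observed=True))
    seeds = seq.generate_state(len(groups) + 1) % (2**31)
    for (label, sub), s in zip(groups, seeds):
        try:
            out[str(label)] = yearly_trend(sub, spec, n_draws, int(s), min_events)
        except DataError as err:
            logger.warning("trend skipped for age group %s: %s", label, err)
    out["total"] = yearly_trend(strata, spec, n_draws, int(seeds[-1]), min_events)
    return out


def subgroup_table(results: list[SubgroupResult]) -> pd.DataFrame:
    """Tidy one-row-per-subgroup summary (for forest plots / CSV export)."""
    rows = []
    for r in results:
        base = dict(r.label)
        base["n_events"] = r.n_events
        if r.skipped:
            base.update({"pct_median": np.nan, "pct_lo": np.nan,
                         "pct_hi": np.nan, "skipped": True})
        else:
            base.update(
                {
                    "pct_median": r.fit.percent_change["median"],
                    "pct_lo": r.fit.percent_change["lo"],
                    "pct_hi": r.fit.percent_change["hi"],
                    "skipped": False,
                }
            )
        rows.append(base)
    return pd.DataFrame(rows)
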