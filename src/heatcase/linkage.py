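"""Record cleaning and exposure/confounder linkage.

Implements the ordered exclusion cascade (duplicates, geography, season,
age, missingness), daily mean temperature, residential-location fuzzing,
grid-cell assignment, lag-averaged exposure, and same-day confounder and
holiday linkage, together with age-group and study-period labelling.

Conventions
-----------
* "Lags 0-3" means the admission day (lag 0) plus the three preceding days,
  i.e. a four-day average; the window is configurable per call.
* Confounders enter at lag 0 (same day) only.
* The holiday indicator is 1 on a holiday, 0 otherwise.
* Grid cells are half-open squares: a point on a shared boundary belongs to
  the lower/left cell.  Points pushed outside the extent by fuzzing are
  clamped back to the nearest interior point — fuzzing is a privacy device
  and must never create exclusions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import EmptyCohortError, LinkageError
from .synthetic import RECORD_COLUMNS, DEFAULT_PERIODS, period_label

SUMMER_MONTHS = (6, 7, 8)
MIN_AGE = 5
DEFAULT_LAGS = (0, 1, 2, 3)

#: cascade rules in the order they are applied (each record counted once)
EXCLUSION_RULES = (
    "duplicate",
    "outside_extent",
    "non_summer",
    "under_age",
    "missing",
)


@dataclass
class ExclusionReport:
    """Per-rule removal tallies, in application order."""

    n_input: int
    removed: dict = field(default_factory=dict)
    n_retained: int = 0

    def __post_init__(self):
        for rule in EXCLUSION_RULES:
            self.removed.setdefault(rule, 0)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def check(self) -> None:
        assert self.n_input == self.n_retained + self.n_removed

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "n_removed": self.n_removed,
            "n_retained": self.n_retained,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def __str__(self) -> str:  # human-readable log block
        lines = [f"records received            {self.n_input:>10d}"]
        labels = {
            "duplicate": "duplicate records",
            "outside_extent": "residence outside extent",
            "non_summer": "outside June-August",
            "under_age": f"aged < {MIN_AGE} years",
            "missing": "missing sex or age",
        }
        for rule in EXCLUSION_RULES:
            lines.append(f"- {labels[rule]:<26}{self.removed[rule]:>10d}")
        lines.append(f"records retained            {self.n_retained:>10d}")
        return "\n".join(lines)


def _extent_of(surface_or_extent) -> tuple[float, float]:
    if isinstance(surface_or_extent, xr.Dataset):
        return (
            float(surface_or_extent.attrs["extent_x"]),
            float(surface_or_extent.attrs["extent_y"]),
        )
    ex, ey = surface_or_extent
    return float(ex), float(ey)


def apply_exclusions(
    records: pd.DataFrame,
    extent,
    min_age: int = MIN_AGE,
    summer_months=SUMMER_MONTHS,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Run the exclusion cascade and return (retained records, report).

    Rules are applied in a fixed order — duplicates, residence outside the
    grid extent, admission outside June-August, age below ``min_age``,
    missing sex or age — so each defective record is tallied exactly once,
    under the first rule it violates.  Duplicates are detected by full-field
    equality on the canonical record schema (the conservative definition).
    """
    ex, ey = _extent_of(extent)
    df = records.copy()
    report = ExclusionReport(n_input=len(df))

    dup = df.duplicated(subset=RECORD_COLUMNS, keep="first")
    report.removed["duplicate"] = int(dup.sum())
    df = df[~dup]

    inside = (
        (df["x"] >= 0) & (df["x"] < ex) & (df["y"] >= 0) & (df["y"] < ey)
    )
    report.removed["outside_extent"] = int((~inside).sum())
    df = df[inside]

    months = pd.DatetimeIndex(df["date"]).month
    summer = pd.Series(np.isin(months, summer_months), index=df.index)
    report.removed["non_summer"] = int((~summer).sum())
    df = df[summer]

    young = df["age"] < min_age  # NaN ages fall through to the missing rule
    report.removed["under_age"] = int(young.sum())
    df = df[~young]

    missing = df["age"].isna() | df["sex"].isna() | (df["sex"] == "")
    report.removed["missing"] = int(missing.sum())
    df = df[~missing]

    report.n_retained = len(df)
    report.check()
    if report.n_retained == 0:
        raise EmptyCohortError("no records remain after the exclusion cascade")
    return df.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# exposure
# ---------------------------------------------------------------------------

def compute_daily_mean(surface: xr.Dataset) -> xr.DataArray:
    """Daily mean temperature: (Tmin + Tmax) / 2, elementwise.

    Missing cell-days propagate as NaN; nothing is imputed.
    """
    tmean = (surface["tmin"] + surface["tmax"]) / 2.0
    return tmean.rename("tmean")


def lag_average_field(tmean: xr.DataArray, lag_set=DEFAULT_LAGS) -> xr.DataArray:
    """Lag-averaged exposure anchored at every available day.

    For each day ``d`` on the time axis, the mean of ``tmean`` over
    ``{d - L : L in lag_set}``.  Days whose window reaches outside the
    surface (or hits a missing day) are NaN, never partially averaged.
    """
    times = pd.DatetimeIndex(tmean["time"].values)
    acc = None
    for L in lag_set:
        shifted = tmean.reindex(time=times - pd.Timedelta(days=int(L)))
        shifted = shifted.assign_coords(time=times)
        acc = shifted if acc is None else acc + shifted
    return (acc / len(lag_set)).rename("x_lag")


def lagged_mean_exposure(
    date,
    cell: tuple[int, int],
    tmean: xr.DataArray,
    lag_set=DEFAULT_LAGS,
) -> float:
    """Lag-averaged exposure for one record (row ``iy``, column ``ix``).

    Raises :class:`LinkageError` naming the first missing date rather than
    averaging over a partial window.
    """
    date = pd.Timestamp(date)
    iy, ix = cell
    times = pd.DatetimeIndex(tmean["time"].values)
    vals = []
    for L in sorted(lag_set):
        day = date - pd.Timedelta(days=int(L))
        if day not in times:
            raise LinkageError(f"no temperature for {day.date()} (lag {L})")
        v = float(tmean.sel(time=day).values[iy, ix])
        if np.isnan(v):
            raise LinkageError(f"temperature missing for {day.date()} (lag {L})")
        vals.append(v)
    return float(np.mean(vals))


def fuzz_locations(
    xy: np.ndarray, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Displace each point uniformly on the disc of the given radius.

    ``radius`` is in the grid's length unit (km); the governance-style
    100 m fuzz is ``radius=0.1``.
    """
    xy = np.asarray(xy, dtype=float)
    if radius < 0:
        raise LinkageError("fuzz radius must be >= 0")
    if radius == 0:
        return xy.copy()
    n = len(xy)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    theta = rng.uniform(0, 2 * np.pi, n)
    return xy + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def clamp_to_extent(xy: np.ndarray, extent, eps: float = 1e-9) -> np.ndarray:
    """Clamp points to the half-open extent [0, ex) x [0, ey)."""
    ex, ey = _extent_of(extent)
    out = np.asarray(xy, dtype=float).copy()
    out[:, 0] = np.clip(out[:, 0], 0.0, ex - eps)
    out[:, 1] = np.clip(out[:, 1], 0.0, ey - eps)
    return out


def assign_cells(xy: np.ndarray, surface: xr.Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Map points to (row iy, column ix) of the fine grid.

    Cells are half-open squares [i, i+1) x [j, j+1) in units of
    ``cell_size``, so a point on a shared boundary belongs to the
    lower/left cell.  Points outside the extent raise :class:`LinkageError`.
    """
    cell = float(surface.attrs["cell_size"])
    ex, ey = _extent_of(surface)
    xy = np.asarray(xy, dtype=float)
    bad = (
        (xy[:, 0] < 0) | (xy[:, 0] >= ex) | (xy[:, 1] < 0) | (xy[:, 1] >= ey)
    )
    if bad.any():
        i = int(np.argmax(bad))
        raise LinkageError(
            f"point ({xy[i, 0]:.3f}, {xy[i, 1]:.3f}) outside grid extent"
        )
    ix = np.floor(xy[:, 0] / cell).astype(int)
    iy = np.floor(xy[:, 1] / cell).astype(int)
    return iy, ix


def age_group_of(ages) -> pd.Categorical:
    """Age bands: 5-15, 16-64, 65+ (integer years, inclusive bounds)."""
    return pd.cut(
        np.asarray(ages, dtype=float),
        bins=[5, 16, 65, np.inf],
        right=False,
        labels=["5-15", "16-64", "65+"],
    )


def link_records(
    records: pd.DataFrame,
    temp: xr.Dataset,
    cov: xr.Dataset,
    holidays,
    lag_set=DEFAULT_LAGS,
    fuzz_radius: float = 0.1,
    seed: int = 0,
    periods=DEFAULT_PERIODS,
) -> pd.DataFrame:
    """Attach exposure, confounders and analysis labels to retained records.

    Adds fuzzed coordinates, fine-cell indices, region, lag-averaged mean
    temperature ``x_lag``, same-day rainfall/humidity/wind from the coarse
    grid, the holiday indicator (1 = holiday), age group, calendar year and
    study period.  Pure given the seed: identical inputs yield identical
    output.
    """
    rng = np.random.default_rng(seed)
    df = records.copy().reset_index(drop=True)

    xy = fuzz_locations(df[["x", "y"]].values, fuzz_radius, rng)
    xy = clamp_to_extent(xy, temp)
    iy, ix = assign_cells(xy, temp)
    df["x_fuzz"], df["y_fuzz"] = xy[:, 0], xy[:, 1]
    df["cell_iy"], df["cell_ix"] = iy, ix
    df["region"] = temp["region"].values[iy, ix]

    tmean = compute_daily_mean(temp)
    xlag = lag_average_field(tmean, lag_set)
    times = pd.DatetimeIndex(temp["time"].values)
    tpos = pd.Series(np.arange(len(times)), index=times)
    dates = pd.DatetimeIndex(df["date"])
    missing_days = ~dates.isin(times)
    if missing_days.any():
        raise LinkageError(
            f"no temperature surface for {dates[missing_days][0].date()}"
        )
    ti = tpos.loc[dates].values
    df["x_lag"] = xlag.values[ti, iy, ix]
    if df["x_lag"].isna().any():
        bad = df.loc[df["x_lag"].isna(), "date"].iloc[0]
        raise LinkageError(f"incomplete lag window for admission on {bad}")

    f = int(cov.attrs["coarse_factor"])
    icy, icx = iy // f, ix // f
    for var in ("rain", "humidity", "wind"):
        vals = cov[var].values[ti, icy, icx]
        if np.isnan(vals).any():
            raise LinkageError(f"missing coarse {var} value")
        df[var] = vals

    hol = frozenset(holidays)
    df["holiday"] = np.array([d.date() in hol for d in dates], dtype=int)

    df["age_group"] = age_group_of(df["age"]).astype(str)
    df["year"] = dates.year
    df["period"] = [period_label(int(y), periods) for y in df["year"]]
    return df
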