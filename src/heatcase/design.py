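"""Time-stratified case-crossover strata and design matrices.

Each admission defines one stratum: the event day plus every other date in
the same calendar month and year falling on the same weekday (3 or 4
referents, depending on whether the month holds four or five such weekdays).
Strata defined this way are disjoint across events — the property that
removes overlap bias — and absorb weekday, within-summer seasonality and
long-term trend by construction.

Exposure at a referent day re-anchors the full lag window at that day, and
confounders are linked at lag 0, exactly as for the event day.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import DataError, DesignError
from .linkage import DEFAULT_LAGS, compute_daily_mean, lag_average_field

CONFOUNDER_COLUMNS = ("rain", "humidity", "wind", "holiday")


def stratum_dates(event_date) -> list[pd.Timestamp]:
    """All dates in the event's month/year sharing its weekday (event included)."""
    d = pd.Timestamp(event_date)
    n_days = calendar.monthrange(d.year, d.month)[1]
    first = pd.Timestamp(d.year, d.month, 1)
    offset = (d.weekday() - first.weekday()) % 7
    days = range(1 + offset, n_days + 1, 7)
    return [pd.Timestamp(d.year, d.month, day) for day in days]


def referent_dates(event_date) -> list[pd.Timestamp]:
    """The stratum's non-event days."""
    d = pd.Timestamp(event_date)
    return [t for t in stratum_dates(d) if t != d]


@dataclass
class Stratum:
    """One admission with its referent days and linked exposures."""

    stratum_id: int
    record_id: int
    patient_id: int
    days: pd.DataFrame  # columns: date, case, x_lag, rain, humidity, wind, holiday

    def validate(self) -> None:
        if int(self.days["case"].sum()) != 1:
            raise DesignError(f"stratum {self.stratum_id}: not exactly one case day")
        n_ref = len(self.days) - 1
        if n_ref not in (3, 4):
            raise DesignError(
                f"stratum {self.stratum_id}: {n_ref} referents (expected 3 or 4)"
            )
        dates = pd.DatetimeIndex(self.days["date"])
        keys = set(zip(dates.weekday, dates.month, dates.year))
        if len(keys) != 1:
            raise DesignError(
                f"stratum {self.stratum_id}: days do not share weekday/month/year"
            )
        if self.days[["x_lag", "rain", "humidity", "wind"]].isna().any().any():
            raise DesignError(f"stratum {self.stratum_id}: missing exposure")


def build_stratum(
    linked_record: pd.Series,
    temp: xr.Dataset,
    cov: xr.Dataset,
    holidays,
    lag_set=DEFAULT_LAGS,
) -> Stratum:
    """Build one stratum for a linked record (single-record reference path).

    The vectorised :func:`build_strata` is the pipeline path; this function
    exists for inspection and testing of individual strata.
    """
    one = linked_record.to_frame().T
    one = one.astype({"cell_iy": int, "cell_ix": int, "record_id": int,
                      "patient_id": int})
    strata = build_strata(one, temp, cov, holidays, lag_set)
    days = strata[
        ["date", "case", "x_lag", "rain", "humidity", "wind", "holiday"]
    ].reset_index(drop=True)
    s = Stratum(
        stratum_id=int(strata["stratum_id"].iloc[0]),
        record_id=int(linked_record["record_id"]),
        patient_id=int(linked_record["patient_id"]),
        days=days,
    )
    s.validate()
    return s


def build_strata(
    linked: pd.DataFrame,
    temp: xr.Dataset,
    cov: xr.Dataset,
    holidays,
    lag_set=DEFAULT_LAGS,
) -> pd.DataFrame:
    """Expand linked records into long-format stratum-days with exposures.

    Returns one row per stratum-day with columns ``stratum_id`` (one stratum
    per admission record), ``record_id``, ``patient_id``, subgroup labels,
    ``date``, ``case`` and the exposure/confounder columns.  Raises
    :class:`DesignError` if any stratum day lacks a computable exposure.
    """
    if len(linked) == 0:
        raise DesignError("no records to build strata from")
    df = linked.reset_index(drop=True).copy()
    df["stratum_id"] = np.arange(len(df))

    event_dates = pd.DatetimeIndex(df["date"])
    mapping = {d: stratum_dates(d) for d in event_dates.unique()}

    carry = [
        c
        for c in (
            "stratum_id", "record_id", "patient_id", "cell_iy", "cell_ix",
            "region", "age_group", "sex", "period", "year", "age",
        )
        if c in df.columns
    ]
    long = df[carry + ["date"]].copy()
    long["stratum_day"] = [mapping[d] for d in event_dates]
    long = long.explode("stratum_day", ignore_index=True)
    long["case"] = (long["stratum_day"] == long["date"]).astype(int)
    long = long.drop(columns=["date"]).rename(columns={"stratum_day": "date"})

    # exposures at every stratum day, lag window re-anchored per day
    tmean = compute_daily_mean(temp)
    xlag = lag_average_field(tmean, lag_set)
    times = pd.DatetimeIndex(temp["time"].values)
    tpos = pd.Series(np.arange(len(times)), index=times)
    dates = pd.DatetimeIndex(long["date"])
    if not dates.isin(times).all():
        missing = sorted(set(dates[~dates.isin(times)].date))
        raise DesignError(f"no temperature surface for stratum days {missing}")
    ti = tpos.loc[dates].values
    iy = long["cell_iy"].values.astype(int)
    ix = long["cell_ix"].values.astype(int)
    long["x_lag"] = xlag.values[ti, iy, ix]
    if long["x_lag"].isna().any():
        bad = sorted(set(pd.DatetimeIndex(long.loc[long["x_lag"].isna(), "date"]).date))
        raise DesignError(f"incomplete lag window on stratum days {bad}")

    f = int(cov.attrs["coarse_factor"])
    icy, icx = iy // f, ix // f
    for var in ("rain", "humidity", "wind"):
        vals = cov[var].values[ti, icy, icx]
        if np.isnan(vals).any():
            raise DesignError(f"missing coarse {var} on a stratum day")
        long[var] = vals
    hol = frozenset(holidays)
    long["holiday"] = np.array([d.date() in hol for d in dates], dtype=int)
    return long


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Model-ready arrays grouped by stratum.

    ``X`` holds the covariate columns in ``columns`` order; ``y`` is the
    case indicator; ``stratum_starts`` are the row offsets of each stratum
    in the (stratum-sorted) arrays.  ``x_lag`` keeps the raw exposure per
    row for non-linear (binned) temperature terms.  The holiday column is
    coded 1 = holiday; analyses using the opposite convention flip only the
    holiday coefficient's sign.
    """

    frame: pd.DataFrame
    columns: list[str]
    X: np.ndarray
    y: np.ndarray
    stratum_starts: np.ndarray
    stratum_sizes: np.ndarray
    x_lag: np.ndarray
    patient_ids: np.ndarray

    @property
    def n_strata(self) -> int:
        return len(self.stratum_starts)

    def validate(self) -> None:
        cases = np.add.reduceat(self.y, self.stratum_starts)
        if not np.all(cases == 1):
            bad = int(np.argmax(cases != 1))
            raise DataError(
                f"stratum at offset {self.stratum_starts[bad]} has "
                f"{int(cases[bad])} case rows (expected 1)"
            )
        if not np.isfinite(self.X).all():
            raise DataError("design matrix contains non-finite entries")


def build_design_matrix(
    strata: pd.DataFrame,
    adjusted: bool = True,
    extra_columns: tuple[str, ...] = (),
) -> DesignMatrix:
    """Assemble the conditional-Poisson design matrix from stratum-days.

    ``adjusted=False`` emits the temperature column only; ``adjusted=True``
    appends rainfall, humidity, wind and the holiday indicator, in that
    (documented) order.  ``extra_columns`` appends further columns present
    in ``strata`` (used e.g. to test invariance to stratum-constant terms).
    """
    cols = ["x_lag"]
    if adjusted:
        cols += list(CONFOUNDER_COLUMNS)
    for c in extra_columns:
        if c not in strata.columns:
            raise DesignError(f"unknown design column {c!r}")
        cols.append(c)

    frame = strata.sort_values(["stratum_id", "date"], kind="stable").reset_index(
        drop=True
    )
    sid = frame["stratum_id"].values
    starts = np.flatnonzero(np.r_[True, sid[1:] != sid[:-1]])
    sizes = np.diff(np.r_[starts, len(sid)])

    dm = DesignMatrix(
        frame=frame,
        columns=cols,
        X=frame[cols].to_numpy(dtype=float),
        y=frame["case"].to_numpy(dtype=int),
        stratum_starts=starts,
        stratum_sizes=sizes,
        x_lag=frame["x_lag"].to_numpy(dtype=float),
        patient_ids=frame["patient_id"].to_numpy()
        if "patient_id" in frame.columns
        else np.zeros(len(frame), dtype=int),
    )
    dm.validate()
    return dm


def strata_to_csv(strata: pd.DataFrame, path) -> None:
    """Serialize stratum-days to long-format CSV (round-trippable)."""
    strata.to_csv(path, index=False)


def strata_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    return df
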