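"""Synthetic study generator.

Emulates, with known ground truth, every input the real analysis obtained
from restricted sources:

* a fine planar grid of daily minimum/maximum temperatures over the summers
  of the configured years (with late-May spill-over so lagged exposures exist
  for early-June events), partitioned into administrative regions;
* a coarse grid of daily rainfall, relative humidity and wind speed,
  optionally correlated with temperature so that confounding adjustment is
  testable;
* a patient register (age, sex, home location, region);
* admission records drawn from a log-linear daily Poisson rate with a known
  temperature coefficient, weekday/month/year baseline, holiday effect and
  patient-level random effects (recurrent admissions);
* deliberately injected defective records (duplicates, out-of-extent,
  non-summer, under-5, missing fields) to exercise the exclusion cascade.

The temperature field is the sum of a smooth spatial gradient, a per-year
offset, a sinusoidal within-summer seasonal term and an AR(1) day-to-day
term shared across the grid, plus small independent cell-day noise.  This is
deliberately simple: it is cheap, fully controllable, and provides the
within-stratum day-to-day exposure variation that the case-crossover design
needs.

All randomness flows from ``SimulationConfig.seed`` through a
``numpy.random.SeedSequence`` split per stage, so identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import calendar
import datetime as dt
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .exceptions import ConfigurationError, GenerationError

#: canonical admission-record schema (the ``defect`` tag is bookkeeping for
#: tests and is never part of record identity)
RECORD_COLUMNS = [
    "record_id",
    "patient_id",
    "date",
    "age",
    "sex",
    "x",
    "y",
    "icd10",
]

AGE_GROUP_LABELS = ("5-15", "16-64", "65+")
DEFAULT_PERIODS = ((2002, 2007), (2008, 2013), (2014, 2019))

#: days of pre-June spill-over in the temperature surface, enough for the
#: longest supported lag window (lag 5 anchored on June 1 reaches May 27)
SUMMER_PAD_DAYS = 6


def period_label(year: int, periods=DEFAULT_PERIODS) -> str:
    for a, b in periods:
        if a <= year <= b:
            return f"{a}-{b}"
    return "other"


@dataclass(frozen=True)
class CascadeNoise:
    """How many defective records to inject, per defect type."""

    n_duplicates: int = 0
    n_outside_extent: int = 0
    n_non_summer: int = 0
    n_under_age: int = 0
    n_missing: int = 0

    @property
    def total(self) -> int:
        return (
            self.n_duplicates
            + self.n_outside_extent
            + self.n_non_summer
            + self.n_under_age
            + self.n_missing
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one synthetic study.

    Effect parameters are on the log-rate scale: ``beta_temp`` is the change
    in log admission rate per 1 degC of lag-averaged mean temperature, so the
    ground-truth percent risk change per degC is ``100*(exp(beta_temp)-1)``.
    ``modifiers`` multiply ``beta_temp`` for subgroups, keyed by partition
    name ("age_group", "sex", "period", "region", "year") then by level.
    """

    seed: int = 0
    years: tuple[int, ...] = (2002, 2003, 2004)
    n_patients: int = 2000
    grid_shape: tuple[int, int] = (33, 33)  # (rows, cols) of 1 km fine cells
    coarse_factor: int = 11
    n_regions: int = 9

    # --- admission-rate model (ground truth) ---
    beta_temp: float = math.log(1.02)  # 2% per degC
    temp_threshold: float | None = None  # piecewise-linear exposure response
    beta_above: float | None = None  # slope above the threshold
    gamma: dict = field(
        default_factory=lambda: {
            "rain": -0.010,  # per mm
            "humidity": 0.002,  # per % RH
            "wind": -0.010,  # per m/s
            "holiday": -0.15,  # internal coding: 1 = holiday
        }
    )
    sigma_patient: float = 0.25
    baseline_log_rate: float = -4.8
    expected_events: int | None = None  # if set, intercept is solved exactly
    weekday_effects: tuple[float, ...] = (0.02, 0.01, 0.0, -0.01, 0.0, -0.03, -0.02)
    month_effects: dict = field(default_factory=lambda: {6: 0.0, 7: 0.03, 8: -0.02})
    year_effect_sd: float = 0.05  # baseline (not exposure) year wobble
    modifiers: dict = field(default_factory=dict)
    log_rate_cap: float = 4.0

    # --- temperature field ---
    constant_temperature: float | None = None
    temp_mean: float = 15.5
    temp_gradient: tuple[float, float] = (0.06, 0.04)  # degC per km in (x, y)
    temp_year_sd: float = 0.6
    temp_season_amp: float = 2.5
    temp_ar_rho: float = 0.7
    temp_ar_sd: float = 2.2  # stationary SD of the shared daily AR(1) term
    temp_cell_sd: float = 0.3
    diurnal_half_range_mean: float = 4.0
    diurnal_half_range_sd: float = 1.0

    # --- coarse covariate field ---
    cov_corr: dict = field(
        default_factory=lambda: {"humidity": -0.3, "rain": -0.2, "wind": 0.0}
    )
    humidity_mean: float = 70.0
    humidity_sd: float = 10.0
    rain_loc: float = 0.5
    rain_sd: float = 2.0
    wind_mean: float = 3.5
    wind_sd: float = 1.3

    # --- population ---
    age_group_probs: tuple[float, float, float] = (0.25, 0.55, 0.20)
    sex_probs: tuple[float, float] = (0.49, 0.51)

    # --- calendar / exposure definition used by the generator ---
    lag_set: tuple[int, ...] = (0, 1, 2, 3)
    periods: tuple = DEFAULT_PERIODS
    extra_holidays_per_year: int = 1

    noise: CascadeNoise = field(default_factory=CascadeNoise)

    # ------------------------------------------------------------------
    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ny, nx = self.grid_shape
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        r1, r2 = _region_block_shape(self.n_regions)
        if ny % r1 or nx % r2:
            raise ConfigurationError(
                f"grid_shape {self.grid_shape} cannot be partitioned into "
                f"{self.n_regions} regions ({r1}x{r2} blocks)"
            )
        if ny % self.coarse_factor or nx % self.coarse_factor:
            raise ConfigurationError(
                f"grid_shape {self.grid_shape} is not divisible by "
                f"coarse_factor {self.coarse_factor}"
            )
        if self.sigma_patient < 0:
            raise ConfigurationError("sigma_patient must be >= 0")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not self.years:
            raise ConfigurationError("years must be non-empty")
        if any(l < 0 for l in self.lag_set) or not self.lag_set:
            raise ConfigurationError("lag_set must be non-empty, non-negative")
        if max(self.lag_set) > SUMMER_PAD_DAYS + 5:
            raise ConfigurationError("lag_set exceeds the pre-summer spill-over")
        if (self.temp_threshold is None) != (self.beta_above is None):
            raise ConfigurationError(
                "temp_threshold and beta_above must be set together"
            )

    # geometry helpers -------------------------------------------------
    @property
    def cell_size(self) -> float:
        return 1.0  # km

    @property
    def extent(self) -> tuple[float, float]:
        """(x_max, y_max) in km; the grid occupies [0, x_max) x [0, y_max)."""
        ny, nx = self.grid_shape
        return nx * self.cell_size, ny * self.cell_size

    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise"] = asdict(self.noise)
        return d


def _region_block_shape(n_regions: int) -> tuple[int, int]:
    """Most-square factor pair (rows, cols) of ``n_regions``."""
    best = (1, n_regions)
    for r in range(1, int(math.isqrt(n_regions)) + 1):
        if n_regions % r == 0:
            best = (r, n_regions // r)
    return best


# ---------------------------------------------------------------------------
# calendar
# ---------------------------------------------------------------------------

def summer_dates(year: int, pad_days: int = SUMMER_PAD_DAYS) -> pd.DatetimeIndex:
    """June 1 .. Aug 31 plus ``pad_days`` of late-May spill-over."""
    start = pd.Timestamp(year, 6, 1) - pd.Timedelta(days=pad_days)
    return pd.date_range(start, pd.Timestamp(year, 8, 31), freq="D")


def event_dates(year: int) -> pd.DatetimeIndex:
    """Days on which admissions can occur: June 1 .. Aug 31."""
    return pd.date_range(pd.Timestamp(year, 6, 1), pd.Timestamp(year, 8, 31), freq="D")


def _last_monday_of_august(year: int) -> dt.date:
    last = max(
        week[calendar.MONDAY]
        for week in calendar.monthcalendar(year, 8)
        if week[calendar.MONDAY]
    )
    return dt.date(year, 8, last)


def make_holidays(config: SimulationConfig) -> frozenset[dt.date]:
    """National-holiday calendar: the late-August bank holiday each year plus
    ``extra_holidays_per_year`` seeded random June/July weekdays.

    Purely synthetic (no real holiday calendar is consulted); all dates fall
    inside the simulated summers.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[0])
    days: set[dt.date] = set()
    for year in config.years:
        days.add(_last_monday_of_august(year))
        pool = pd.date_range(f"{year}-06-01", f"{year}-07-31", freq="D")
        pool = pool[pool.weekday < 5]
        for d in rng.choice(pool.to_pydatetime(), size=config.extra_holidays_per_year,
                            replace=False):
            days.add(pd.Timestamp(d).date())
    return frozenset(days)


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def region_field(config: SimulationConfig) -> np.ndarray:
    """Integer region id per fine cell: a block partition of the grid."""
    ny, nx = config.grid_shape
    r1, r2 = _region_block_shape(config.n_regions)
    iy, ix = np.mgrid[0:ny, 0:nx]
    return (iy // (ny // r1)) * r2 + (ix // (nx // r2))


def make_temperature_surface(config: SimulationConfig) -> xr.Dataset:
    """Fine-grid daily Tmin/Tmax field covering every simulated summer.

    Returns an :class:`xarray.Dataset` with variables ``tmin``/``tmax`` on
    dims ``(time, y, x)`` and an integer ``region`` field on ``(y, x)``;
    ``x``/``y`` coordinates are cell centres in km.
    """
    config.validate()
    ny, nx = config.grid_shape
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    times = pd.DatetimeIndex(
        np.concatenate([summer_dates(y).values for y in config.years])
    )
    nT = len(times)
    xc = (np.arange(nx) + 0.5) * config.cell_size
    yc = (np.arange(ny) + 0.5) * config.cell_size

    if config.constant_temperature is not None:
        tmean = np.full((nT, ny, nx), float(config.constant_temperature))
        half = np.zeros((nT, ny, nx))
    else:
        gx, gy = config.temp_gradient
        spatial = gx * xc[None, :] + gy * yc[:, None]
        spatial = spatial - spatial.mean()

        year_eff = dict(
            zip(config.years, rng.normal(0.0, config.temp_year_sd, len(config.years)))
        )
        # seasonal + AR(1) time series, built per year so no gap leakage
        tseries = np.empty(nT)
        pos = 0
        for y in config.years:
            n = len(summer_dates(y))
            frac = np.arange(n) / max(n - 1, 1)
            season = config.temp_season_amp * np.sin(np.pi * frac)
            innov_sd = config.temp_ar_sd * math.sqrt(1 - config.temp_ar_rho**2)
            ar = np.empty(n)
            ar[0] = rng.normal(0.0, config.temp_ar_sd)
            shocks = rng.normal(0.0, innov_sd, n - 1)
            for t in range(1, n):
                ar[t] = config.temp_ar_rho * ar[t - 1] + shocks[t - 1]
            tseries[pos : pos + n] = year_eff[y] + season + ar
            pos += n

        cell_noise = rng.normal(0.0, config.temp_cell_sd, (nT, ny, nx))
        tmean = config.temp_mean + tseries[:, None, None] + spatial[None] + cell_noise
        half = np.abs(
            rng.normal(
                config.diurnal_half_range_mean,
                config.diurnal_half_range_sd,
                (nT, ny, nx),
            )
        )

    ds = xr.Dataset(
        {
            "tmin": (("time", "y", "x"), tmean - half),
            "tmax": (("time", "y", "x"), tmean + half),
            "region": (("y", "x"), region_field(config).astype(np.int32)),
        },
        coords={"time": times, "y": yc, "x": xc},
        attrs={
            "cell_size": config.cell_size,
            "coarse_factor": config.coarse_factor,
            "extent_x": nx * config.cell_size,
            "extent_y": ny * config.cell_size,
        },
    )
    return ds


def make_covariate_surfaces(config: SimulationConfig, temp: xr.Dataset) -> xr.Dataset:
    """Coarse-grid daily rainfall (mm), relative humidity (%) and wind (m/s).

    Each covariate is built from a standard-normal field that carries the
    configured correlation with the coarse-cell mean temperature, then mapped
    to its physical scale.  Humidity is a clipped affine map (the clip almost
    never binds at the default mean/SD, so the configured correlation is
    preserved); rainfall and wind are truncated at zero, which attenuates
    their correlations somewhat — humidity is therefore the covariate to use
    when a precise correlation is required.
    """
    f = config.coarse_factor
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])

    tmean = (temp["tmin"] + temp["tmax"]) / 2.0
    tcoarse = tmean.coarsen(x=f, y=f).mean()
    z = (tcoarse - tcoarse.mean()) / max(float(tcoarse.std()), 1e-12)
    z = z.values
    shape = z.shape

    def mix(corr: float) -> np.ndarray:
        return corr * z + math.sqrt(max(1 - corr**2, 0.0)) * rng.normal(0, 1, shape)

    c = config.cov_corr
    humidity = np.clip(
        config.humidity_mean + config.humidity_sd * mix(c.get("humidity", 0.0)), 0, 100
    )
    rain = np.maximum(0.0, config.rain_loc + config.rain_sd * mix(c.get("rain", 0.0)))
    wind = np.maximum(0.0, config.wind_mean + config.wind_sd * mix(c.get("wind", 0.0)))

    ds = xr.Dataset(
        {
            "rain": (("time", "y", "x"), rain),
            "humidity": (("time", "y", "x"), humidity),
            "wind": (("time", "y", "x"), wind),
        },
        coords={
            "time": temp["time"].values,
            "y": tcoarse["y"].values,
            "x": tcoarse["x"].values,
        },
        attrs={
            "cell_size": config.cell_size * f,
            "coarse_factor": f,
            "extent_x": temp.attrs["extent_x"],
            "extent_y": temp.attrs["extent_y"],
        },
    )
    return ds


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def make_patients(config: SimulationConfig, temp: xr.Dataset) -> pd.DataFrame:
    """Patient register: id, age (>=5), sex, home location, region."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    n = config.n_patients
    groups = rng.choice(3, size=n, p=np.asarray(config.age_group_probs))
    lows, highs = np.array([5, 16, 65]), np.array([16, 65, 95])
    ages = rng.integers(lows[groups], highs[groups])
    sexes = rng.choice(np.array(["M", "F"]), size=n, p=np.asarray(config.sex_probs))
    ex, ey = config.extent
    x = rng.uniform(0, ex, n)
    y = rng.uniform(0, ey, n)
    regions = temp["region"].values[
        np.minimum((y / config.cell_size).astype(int), config.grid_shape[0] - 1),
        np.minimum((x / config.cell_size).astype(int), config.grid_shape[1] - 1),
    ]
    return pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "age": ages,
            "sex": sexes,
            "x": x,
            "y": y,
            "region": regions,
        }
    )


def _age_group_of(ages: np.ndarray) -> np.ndarray:
    out = np.where(ages >= 65, "65+", np.where(ages >= 16, "16-64", "5-15"))
    return out


def _modifier_vector(modifiers: dict, key: str, levels: np.ndarray) -> np.ndarray:
    table = modifiers.get(key, {})
    if not table:
        return np.ones(len(levels))
    return np.array([float(table.get(l, 1.0)) for l in levels])


# ---------------------------------------------------------------------------
# admissions
# ---------------------------------------------------------------------------

def simulate_admissions(
    config: SimulationConfig,
    temp: xr.Dataset,
    cov: xr.Dataset,
    holidays: frozenset,
    patients: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Draw admission records from the ground-truth conditional-Poisson law.

    For every patient-day in June-August the admission count is Poisson with

    ``log rate = intercept + weekday + month + year + beta_p * X_lag
                 + gamma . (rain, humidity, wind, holiday) + b_patient``

    where ``X_lag`` is the lag-averaged daily mean temperature at the
    patient's fine cell, ``b_patient ~ N(0, sigma_patient^2)`` is drawn once
    per patient, and ``beta_p`` is ``beta_temp`` times the product of the
    subgroup modifiers that apply to that patient-day.  Returns the records
    and a ground-truth dictionary.
    """
    from .linkage import compute_daily_mean, lag_average_field

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])

    tmean = compute_daily_mean(temp)
    xlag = lag_average_field(tmean, config.lag_set)  # (time, y, x), NaN if short

    times = pd.DatetimeIndex(temp["time"].values)
    ev_dates = pd.DatetimeIndex(
        np.concatenate([event_dates(y).values for y in config.years])
    )
    tpos = pd.Series(np.arange(len(times)), index=times)
    ev_idx = tpos.loc[ev_dates].values

    cell = config.cell_size
    ny, nx = config.grid_shape
    iy = np.minimum((patients["y"].values / cell).astype(int), ny - 1)
    ix = np.minimum((patients["x"].values / cell).astype(int), nx - 1)
    f = config.coarse_factor
    icy, icx = iy // f, ix // f

    # exposure matrix: patients x event-days
    xlag_v = xlag.values[ev_idx]  # (D, ny, nx)
    if np.isnan(xlag_v).any():
        raise GenerationError("lag-averaged exposure undefined on an event day")
    X = xlag_v[:, iy, ix].T  # (n_pat, D)

    covv = {k: cov[k].values[ev_idx] for k in ("rain", "humidity", "wind")}
    Z = {k: v[:, icy, icx].T for k, v in covv.items()}  # (n_pat, D)

    hol = np.array([d.date() in holidays for d in ev_dates], dtype=float)

    # day-level baseline
    wd = np.asarray(config.weekday_effects)[ev_dates.weekday]
    mon = np.array([config.month_effects.get(m, 0.0) for m in ev_dates.month])
    year_eff = dict(
        zip(config.years, rng.normal(0.0, config.year_effect_sd, len(config.years)))
    )
    yr = np.array([year_eff[y] for y in ev_dates.year])

    # exposure coefficient per patient-day
    age_group = _age_group_of(patients["age"].values)
    m_pat = (
        _modifier_vector(config.modifiers, "age_group", age_group)
        * _modifier_vector(config.modifiers, "sex", patients["sex"].values)
        * _modifier_vector(config.modifiers, "region", patients["region"].values)
    )
    day_periods = np.array([period_label(y, config.periods) for y in ev_dates.year])
    m_day = _modifier_vector(
        config.modifiers, "period", day_periods
    ) * _modifier_vector(config.modifiers, "year", ev_dates.year.values)
    beta = config.beta_temp * m_pat[:, None] * m_day[None, :]

    temp_term = beta * X
    if config.temp_threshold is not None:
        temp_term = temp_term + (config.beta_above - config.beta_temp) * (
            m_pat[:, None] * m_day[None, :]
        ) * np.maximum(X - config.temp_threshold, 0.0)

    b_pat = rng.normal(0.0, config.sigma_patient, config.n_patients)

    g = config.gamma
    eta = (
        temp_term
        + g.get("rain", 0.0) * Z["rain"]
        + g.get("humidity", 0.0) * Z["humidity"]
        + g.get("wind", 0.0) * Z["wind"]
        + g.get("holiday", 0.0) * hol[None, :]
        + (wd + mon + yr)[None, :]
        + b_pat[:, None]
    )

    if config.expected_events is not None:
        from scipy.special import logsumexp

        intercept = math.log(config.expected_events) - logsumexp(eta)
    else:
        intercept = config.baseline_log_rate
    eta = eta + intercept

    if eta.max() > config.log_rate_cap:
        p, d = np.unravel_index(np.argmax(eta), eta.shape)
        raise GenerationError(
            f"log admission rate {eta.max():.2f} exceeds cap "
            f"{config.log_rate_cap} (patient {p}, day {ev_dates[d].date()}); "
            "lower baseline_log_rate or beta_temp/modifiers"
        )

    counts = rng.poisson(np.exp(eta))
    pat_i, day_i = np.nonzero(counts)
    reps = counts[pat_i, day_i]
    pat_i = np.repeat(pat_i, reps)
    day_i = np.repeat(day_i, reps)

    icd = rng.choice(np.array(["J45", "J46"]), size=len(pat_i), p=[0.95, 0.05])
    records = pd.DataFrame(
        {
            "record_id": np.arange(len(pat_i)),
            "patient_id": patients["patient_id"].values[pat_i],
            "date": ev_dates[day_i],
            "age": patients["age"].values[pat_i].astype(float),
            "sex": patients["sex"].values[pat_i],
            "x": patients["x"].values[pat_i],
            "y": patients["y"].values[pat_i],
            "icd10": icd,
        }
    )
    records["defect"] = ""

    truth = {
        "beta_temp": config.beta_temp,
        "pct_per_degC": 100.0 * math.expm1(config.beta_temp),
        "temp_threshold": config.temp_threshold,
        "beta_above": config.beta_above,
        "gamma": dict(config.gamma),
        "sigma_patient": config.sigma_patient,
        "intercept": float(intercept),
        "expected_events": float(np.exp(eta).sum()),
        "year_effects": {int(k): float(v) for k, v in year_eff.items()},
        "modifiers": config.modifiers,
        "lag_set": list(config.lag_set),
        "n_events": int(len(records)),
    }
    return records, truth


# ---------------------------------------------------------------------------
# cascade noise
# ---------------------------------------------------------------------------

def inject_cascade_noise(
    records: pd.DataFrame,
    config: SimulationConfig,
    noise: CascadeNoise | None = None,
) -> pd.DataFrame:
    """Append deliberately defective records, tagged by defect type.

    Duplicates are byte-identical copies of existing records *including* the
    record id (duplicated source records share content); every other injected
    record receives a fresh id.  The ``defect`` column carries the defect
    type so tests can verify the exclusion cascade's bookkeeping.
    """
    noise = noise if noise is not None else config.noise
    if noise.total == 0:
        return records.copy()
    if len(records) == 0:
        raise GenerationError("cannot inject noise into an empty record set")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[0])
    ex, ey = config.extent
    next_id = int(records["record_id"].max()) + 1
    chunks = [records.copy()]

    def sample(n: int) -> pd.DataFrame:
        idx = rng.choice(len(records), size=n, replace=n > len(records))
        return records.iloc[idx].copy()

    dup = sample(noise.n_duplicates)
    dup["defect"] = "duplicate"
    chunks.append(dup)

    out = sample(noise.n_outside_extent)
    out["x"] = ex + 5.0 + rng.uniform(0, 5, len(out))
    out["record_id"] = np.arange(next_id, next_id + len(out))
    next_id += len(out)
    out["defect"] = "outside_extent"
    chunks.append(out)

    season = sample(noise.n_non_summer)
    season["date"] = [
        pd.Timestamp(int(y), int(rng.choice([5, 9])), 15)
        for y in pd.DatetimeIndex(season["date"]).year
    ]
    season["record_id"] = np.arange(next_id, next_id + len(season))
    next_id += len(season)
    season["defect"] = "non_summer"
    chunks.append(season)

    young = sample(noise.n_under_age)
    young["age"] = rng.integers(0, 5, len(young)).astype(float)
    young["record_id"] = np.arange(next_id, next_id + len(young))
    next_id += len(young)
    young["defect"] = "under_age"
    chunks.append(young)

    miss = sample(noise.n_missing)
    drop_sex = np.arange(len(miss)) % 2 == 0
    miss.loc[drop_sex, "sex"] = None
    miss.loc[~drop_sex, "age"] = np.nan
    miss["record_id"] = np.arange(next_id, next_id + len(miss))
    miss["defect"] = "missing"
    chunks.append(miss)

    return pd.concat([c for c in chunks if len(c)], ignore_index=True)


# ---------------------------------------------------------------------------
# one-call bundle + serialization
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    config: SimulationConfig
    temperature: xr.Dataset
    covariates: xr.Dataset
    holidays: frozenset
    patients: pd.DataFrame
    records: pd.DataFrame  # includes injected defects, if any
    truth: dict


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate every study input in one call (deterministic given the seed)."""
    temp = make_temperature_surface(config)
    cov = make_covariate_surfaces(config, temp)
    holidays = make_holidays(config)
    patients = make_patients(config, temp)
    records, truth = simulate_admissions(config, temp, cov, holidays, patients)
    records = inject_cascade_noise(records, config)
    return SyntheticStudy(config, temp, cov, holidays, patients, records, truth)


def save_study(study: SyntheticStudy, outdir) -> None:
    """Write the study to flat text files (long-format CSV + YAML sidecar)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.records.to_csv(outdir / "admissions.csv", index=False)
    study.patients.to_csv(outdir / "patients.csv", index=False)
    for name, ds in (("temperature", study.temperature), ("covariates", study.covariates)):
        df = ds.to_dataframe().reset_index()
        df.to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "holidays.csv", "w") as fh:
        fh.write("date\n")
        for d in sorted(study.holidays):
            fh.write(f"{d.isoformat()}\n")
    with open(outdir / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(_yamlable(study.truth), fh, sort_keys=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(_yamlable(study.config.to_dict()), fh, sort_keys=False)


def load_study(indir) -> SyntheticStudy:
    """Read a study previously written by :func:`save_study`."""
    from pathlib import Path

    indir = Path(indir)
    with open(indir / "config.yaml") as fh:
        config = config_from_dict(yaml.safe_load(fh))
    records = pd.read_csv(indir / "admissions.csv", parse_dates=["date"])
    records["defect"] = records.get("defect", pd.Series(dtype=str)).fillna("")
    patients = pd.read_csv(indir / "patients.csv")

    def grid_from_csv(path, variables, cell_size):
        df = pd.read_csv(path, parse_dates=["time"])
        ds = df.set_index(["time", "y", "x"]).to_xarray()
        out = xr.Dataset({v: ds[v] for v in variables})
        out.attrs.update(
            cell_size=cell_size,
            coarse_factor=config.coarse_factor,
            extent_x=config.extent[0],
            extent_y=config.extent[1],
        )
        return out

    temp = grid_from_csv(indir / "temperature.csv", ("tmin", "tmax"),
                         config.cell_size)
    # region broadcasts over time in the long CSV; collapse it back
    region_df = pd.read_csv(indir / "temperature.csv", parse_dates=["time"])
    region = (
        region_df.set_index(["time", "y", "x"])["region"].to_xarray().isel(time=0)
    )
    temp["region"] = (("y", "x"), region.values.astype(np.int32))
    cov = grid_from_csv(indir / "covariates.csv", ("rain", "humidity", "wind"),
                        config.cell_size * config.coarse_factor)

    hol_df = pd.read_csv(indir / "holidays.csv", parse_dates=["date"])
    holidays = frozenset(d.date() for d in hol_df["date"])
    with open(indir / "ground_truth.yaml") as fh:
        truth = yaml.safe_load(fh)
    return SyntheticStudy(config, temp, cov, holidays, patients, records, truth)


def _yamlable(obj):
    if isinstance(obj, dict):
        return {str(k): _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_from_dict(d: dict) -> SimulationConfig:
    """Rebuild a SimulationConfig from ``to_dict`` output (e.g. YAML)."""
    d = dict(d)
    if "noise" in d and isinstance(d["noise"], dict):
        d["noise"] = CascadeNoise(**d["noise"])
    for key in ("years", "grid_shape", "weekday_effects", "lag_set",
                "age_group_probs", "sex_probs", "temp_gradient"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    if "month_effects" in d:
        d["month_effects"] = {int(k): v for k, v in d["month_effects"].items()}
    if "periods" in d:
        d["periods"] = tuple(tuple(p) for p in d["periods"])
    return SimulationConfig(**d)
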