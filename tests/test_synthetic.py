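"""Generator tests: determinism, field structure, generative law recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heatcase.exceptions import ConfigurationError, GenerationError
from heatcase.synthetic import (
    CascadeNoise,
    SimulationConfig,
    inject_cascade_noise,
    make_covariate_surfaces,
    make_holidays,
    make_patients,
    make_temperature_surface,
    simulate_admissions,
    simulate_study,
    RECORD_COLUMNS,
)
from heatcase.linkage import compute_daily_mean, lag_average_field

from conftest import NOISE


def _null_config(**kw) -> SimulationConfig:
    """All baseline structure off: i.i.d. Poisson counts given exposure."""
    base = dict(
        seed=9,
        beta_temp=0.0,
        gamma={},
        sigma_patient=0.0,
        weekday_effects=(0.0,) * 7,
        month_effects={},
        year_effect_sd=0.0,
        baseline_log_rate=-4.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_seed_determinism_end_to_end():
    a = simulate_study(SimulationConfig(seed=3, expected_events=500, noise=NOISE))
    b = simulate_study(SimulationConfig(seed=3, expected_events=500, noise=NOISE))
    assert a.temperature.identical(b.temperature)
    assert a.covariates.identical(b.covariates)
    assert a.holidays == b.holidays
    pd.testing.assert_frame_equal(a.patients, b.patients)
    pd.testing.assert_frame_equal(a.records, b.records)
    assert a.truth == b.truth


def test_constant_field_option():
    cfg = SimulationConfig(seed=0, constant_temperature=15.0)
    temp = make_temperature_surface(cfg)
    assert float(temp["tmin"].min()) == 15.0
    assert float(temp["tmax"].max()) == 15.0


def test_temperature_surface_structure():
    cfg = SimulationConfig(seed=2)
    temp = make_temperature_surface(cfg)
    # Tmin <= Tmax everywhere; every cell in exactly one of 9 regions
    assert ((temp["tmax"] - temp["tmin"]) >= 0).all()
    assert set(np.unique(temp["region"].values)) == set(range(9))
    # spill-over: at least lag-5 coverage before every June 1
    times = pd.DatetimeIndex(temp["time"].values)
    for year in cfg.years:
        assert pd.Timestamp(year, 5, 27) in times
    # summer means land in a plausible band for the default parameters
    tmean = compute_daily_mean(temp)
    for year in cfg.years:
        sel = tmean.sel(time=str(year))
        assert 10.0 < float(sel.mean()) < 22.0


def test_temperature_day_to_day_autocorrelation():
    temp = make_temperature_surface(SimulationConfig(seed=4))
    tmean = compute_daily_mean(temp).mean(dim=("x", "y")).values
    # grid-average series within one year should be positively autocorrelated
    x = tmean[:98]
    r = np.corrcoef(x[:-1], x[1:])[0, 1]
    assert r > 0.3


def test_coarse_grid_geometry():
    cfg = SimulationConfig(seed=0)
    temp = make_temperature_surface(cfg)
    cov = make_covariate_surfaces(cfg, temp)
    # 33x33 fine cells at coarse_factor 11 -> 3x3 coarse cells of 121 fine each
    assert cov["rain"].shape[1:] == (3, 3)
    assert cfg.coarse_factor**2 == 121
    assert float(cov["humidity"].min()) >= 0
    assert float(cov["humidity"].max()) <= 100
    assert float(cov["rain"].min()) >= 0
    assert float(cov["wind"].min()) >= 0


@pytest.mark.parametrize("corr,band", [(0.0, (-0.1, 0.1)), (-0.5, (-0.6, -0.4))])
def test_covariate_temperature_correlation(corr, band):
    # a denser coarse grid so the sample correlation has >= 10k cell-days
    cfg = SimulationConfig(
        seed=8,
        grid_shape=(32, 32),
        coarse_factor=4,
        n_regions=4,
        cov_corr={"humidity": corr, "rain": 0.0, "wind": 0.0},
    )
    temp = make_temperature_surface(cfg)
    cov = make_covariate_surfaces(cfg, temp)
    tmean = compute_daily_mean(temp).coarsen(x=4, y=4).mean().values.ravel()
    hum = cov["humidity"].values.ravel()
    assert hum.size >= 10_000
    r = np.corrcoef(tmean, hum)[0, 1]
    assert band[0] < r < band[1]


def test_null_model_counts_are_poisson():
    """beta=0, gamma=0, sigma=0, flat baseline: daily totals i.i.d. Poisson."""
    cfg = _null_config()
    study = simulate_study(cfg)
    daily = study.records.groupby("date").size()
    daily = daily.reindex(
        pd.DatetimeIndex(
            np.concatenate(
                [pd.date_range(f"{y}-06-01", f"{y}-08-31").values for y in cfg.years]
            )
        ),
        fill_value=0,
    ).values
    # index-of-dispersion test: (n-1) s^2 / mean ~ chi2(n-1) under Poisson
    n = len(daily)
    stat = (n - 1) * daily.var(ddof=1) / daily.mean()
    lo, hi = stats.chi2.ppf([0.001, 0.999], df=n - 1)
    assert lo < stat < hi


def _empirical_log_rate_slope(study, config):
    """Monte-Carlo slope of log(admission rate) on exposure, computed from
    patient-day counts and exposures reconstructed independently of the
    generator's internals (Poisson regression closed form via WLS)."""
    tmean = compute_daily_mean(study.temperature)
    xlag = lag_average_field(tmean, config.lag_set)
    times = pd.DatetimeIndex(study.temperature["time"].values)
    ev = pd.DatetimeIndex(
        np.concatenate(
            [pd.date_range(f"{y}-06-01", f"{y}-08-31").values for y in config.years]
        )
    )
    tpos = pd.Series(np.arange(len(times)), index=times).loc[ev].values
    iy = study.patients["y"].values.astype(int)
    ix = study.patients["x"].values.astype(int)
    X = xlag.values[tpos][:, iy, ix].T.ravel()  # patient-day exposures
    counts = np.zeros((len(study.patients), len(ev)))
    pid = pd.Series(np.arange(len(study.patients)),
                    index=study.patients["patient_id"].values)
    rows = pid.loc[study.records["patient_id"]].values
    cols = pd.Series(np.arange(len(ev)), index=ev).loc[
        pd.DatetimeIndex(study.records["date"])].values
    np.add.at(counts, (rows, cols), 1)
    y = counts.ravel()
    # Poisson ML for log-linear model with intercept: one Newton step suffices
    # from the moment estimator; use statsmodels-free IRLS (few iterations)
    b0, b1 = math.log(max(y.mean(), 1e-12)), 0.0
    for _ in range(25):
        mu = np.exp(b0 + b1 * X)
        g = np.array([(y - mu).sum(), ((y - mu) * X).sum()])
        H = -np.array([[mu.sum(), (mu * X).sum()],
                       [(mu * X).sum(), (mu * X * X).sum()]])
        step = np.linalg.solve(-H, g)
        b0, b1 = b0 + step[0], b1 + step[1]
        if np.abs(g).max() < 1e-8:
            break
    return b1


def test_exposure_coefficient_recovered_by_monte_carlo():
    cfg = _null_config(seed=13, beta_temp=math.log(1.02), baseline_log_rate=-3.1)
    study = simulate_study(cfg)
    assert len(study.records) > 30_000
    slope = _empirical_log_rate_slope(study, cfg)
    # rate ratio per +1 degC approaches 1.02
    assert 1.012 < math.exp(slope) < 1.028


def test_subgroup_modifier_halves_female_effect():
    cfg = _null_config(
        seed=14,
        beta_temp=math.log(1.04),
        baseline_log_rate=-3.1,
        modifiers={"sex": {"F": 0.5}},
    )
    study = simulate_study(cfg)
    slopes = {}
    for sex in ("M", "F"):
        pats = study.patients[study.patients["sex"] == sex].reset_index(drop=True)
        recs = study.records[study.records["sex"] == sex]
        sub = type(study)(
            config=cfg, temperature=study.temperature, covariates=study.covariates,
            holidays=study.holidays, patients=pats, records=recs, truth=study.truth,
        )
        slopes[sex] = _empirical_log_rate_slope(sub, cfg)
    assert math.exp(slopes["M"]) == pytest.approx(1.04, abs=0.012)
    assert math.exp(slopes["F"]) == pytest.approx(math.exp(math.log(1.04) / 2),
                                                  abs=0.012)


def test_cascade_noise_bookkeeping_and_identity():
    cfg = SimulationConfig(seed=5, expected_events=400)
    study = simulate_study(cfg)  # zero-noise default
    clean = study.records
    assert (clean["defect"] == "").all()

    noisy = inject_cascade_noise(clean, cfg, NOISE)
    assert len(noisy) == len(clean) + NOISE.total
    assert noisy["defect"].value_counts().to_dict() == {
        "": len(clean), "duplicate": 5, "outside_extent": 2,
        "non_summer": 10, "under_age": 3, "missing": 1,
    }
    # zero-noise config: output identical to input
    same = inject_cascade_noise(clean, cfg, CascadeNoise())
    pd.testing.assert_frame_equal(same, clean)


def test_injected_duplicate_is_field_identical():
    cfg = SimulationConfig(seed=6, expected_events=300)
    study = simulate_study(cfg)
    noisy = inject_cascade_noise(study.records, cfg, CascadeNoise(n_duplicates=3))
    dups = noisy[noisy["defect"] == "duplicate"]
    originals = noisy[noisy["defect"] == ""].set_index("record_id")
    for _, row in dups.iterrows():
        src = originals.loc[row["record_id"]]
        for col in RECORD_COLUMNS:
            if col == "record_id":
                continue
            assert row[col] == src[col]


def test_rate_overflow_raises_naming_parameter():
    cfg = _null_config(seed=1, baseline_log_rate=6.0)
    temp = make_temperature_surface(cfg)
    cov = make_covariate_surfaces(cfg, temp)
    hol = make_holidays(cfg)
    pats = make_patients(cfg, temp)
    with pytest.raises(GenerationError, match="baseline_log_rate"):
        simulate_admissions(cfg, temp, cov, hol, pats)


@pytest.mark.parametrize(
    "kw",
    [
        {"grid_shape": (10, 10), "n_regions": 9, "coarse_factor": 5},
        {"grid_shape": (33, 32)},  # not divisible by coarse_factor 11
        {"n_regions": 0},
        {"sigma_patient": -1.0},
        {"lag_set": ()},
        {"temp_threshold": 20.0},  # beta_above missing
    ],
)
def test_invalid_configurations_rejected(kw):
    with pytest.raises(ConfigurationError):
        SimulationConfig(seed=0, **kw)


def test_holidays_inside_simulated_range():
    cfg = SimulationConfig(seed=7)
    hols = make_holidays(cfg)
    assert len(hols) >= len(cfg.years)
    for d in hols:
        assert d.year in cfg.years
        assert d.month in (6, 7, 8)
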