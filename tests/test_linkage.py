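"""Exclusion-cascade and exposure-linkage tests."""

import numpy as np
import pandas as pd
import pytest

from heatcase.exceptions import EmptyCohortError, LinkageError
from heatcase.linkage import (
    apply_exclusions,
    assign_cells,
    clamp_to_extent,
    compute_daily_mean,
    fuzz_locations,
    lag_average_field,
    lagged_mean_exposure,
    link_records,
    age_group_of,
)
from heatcase.synthetic import SimulationConfig, simulate_study, period_label

from conftest import NOISE, toy_surface


# ---------------------------------------------------------------------------
# exclusion cascade
# ---------------------------------------------------------------------------

def test_clean_input_passes_through(medium_chain):
    study, retained, report, _, _ = medium_chain
    assert report.n_input == len(study.records)
    assert report.n_retained == len(study.records)
    assert all(v == 0 for v in report.removed.values())


def test_injected_defects_reproduced_exactly(small_chain):
    study, retained, report, _, _ = small_chain
    assert report.removed == {
        "duplicate": 5, "outside_extent": 2, "non_summer": 10,
        "under_age": 3, "missing": 1,
    }
    assert report.n_input == report.n_retained + report.n_removed
    # retained records are exactly the clean ones
    assert (retained["defect"] == "").all()
    assert report.n_retained == (study.records["defect"] == "").sum()


def test_cascade_is_idempotent(small_chain):
    study, retained, _, _, _ = small_chain
    again, report2 = apply_exclusions(retained, study.temperature)
    assert report2.n_removed == 0
    pd.testing.assert_frame_equal(again, retained)


def test_rule_order_counts_first_violation():
    """A non-summer 4-year-old is tallied under non-summer, not age."""
    base = dict(patient_id=1, age=4.0, sex="F", x=1.0, y=1.0, icd10="J45")
    records = pd.DataFrame(
        [
            {"record_id": 0, "date": pd.Timestamp("2002-05-15"), **base},
            {"record_id": 1, "date": pd.Timestamp("2002-07-15"), **base},
            {"record_id": 2, "date": pd.Timestamp("2002-07-20"), **{**base, "age": 30.0}},
        ]
    )
    retained, report = apply_exclusions(records, (10.0, 10.0))
    assert report.removed["non_summer"] == 1
    assert report.removed["under_age"] == 1
    assert report.n_retained == 1


def test_empty_cohort_raises():
    records = pd.DataFrame(
        [{"record_id": 0, "patient_id": 1, "date": pd.Timestamp("2002-01-01"),
          "age": 30.0, "sex": "M", "x": 1.0, "y": 1.0, "icd10": "J45"}]
    )
    with pytest.raises(EmptyCohortError):
        apply_exclusions(records, (10.0, 10.0))


def test_report_serialization(small_chain):
    _, _, report, _, _ = small_chain
    d = report.to_dict()
    assert d["n_input"] == d["n_retained"] + d["n_removed"]
    text = str(report)
    assert "records retained" in text and str(report.n_retained) in text


# ---------------------------------------------------------------------------
# daily mean
# ---------------------------------------------------------------------------

def test_daily_mean_arithmetic():
    surf = toy_surface({pd.Timestamp("2002-06-01"): 0.0})
    surf["tmin"].values[:] = 10.0
    surf["tmax"].values[:] = 20.0
    assert float(compute_daily_mean(surf).values.mean()) == 15.0
    surf["tmin"].values[:] = 7.5
    surf["tmax"].values[:] = 7.5
    assert float(compute_daily_mean(surf).values.mean()) == 7.5


def test_daily_mean_matches_brute_force_scan():
    temp = simulate_study(SimulationConfig(seed=11, expected_events=100)).temperature
    tmean = compute_daily_mean(temp).values
    brute = (temp["tmin"].values + temp["tmax"].values) / 2.0
    assert np.allclose(tmean, brute)
    assert np.isclose(tmean.mean(), brute.mean())


# ---------------------------------------------------------------------------
# fuzzing and cell assignment
# ---------------------------------------------------------------------------

def test_fuzz_zero_radius_is_identity():
    rng = np.random.default_rng(0)
    xy = np.array([[1.0, 2.0], [3.0, 4.0]])
    assert np.array_equal(fuzz_locations(xy, 0.0, rng), xy)


def test_fuzz_respects_radius_bound():
    rng = np.random.default_rng(1)
    xy = np.zeros((10_000, 2))
    out = fuzz_locations(xy, 0.1, rng)
    dist = np.hypot(out[:, 0], out[:, 1])
    assert (dist <= 0.1 + 1e-12).all()


def test_fuzz_mean_squared_displacement():
    # uniform on a disc of radius r: E[d^2] = r^2 / 2
    rng = np.random.default_rng(2)
    out = fuzz_locations(np.zeros((10_000, 2)), 0.1, rng)
    msd = (out**2).sum(axis=1).mean()
    assert msd == pytest.approx(0.1**2 / 2, rel=0.05)


def test_assign_cells_centre_and_boundary():
    surf = toy_surface({pd.Timestamp("2002-06-01"): 15.0}, shape=(6, 6))
    iy, ix = assign_cells(np.array([[3.5, 4.5]]), surf)  # centre of cell (4,3)
    assert (iy[0], ix[0]) == (4, 3)
    # a point exactly on a shared boundary belongs to the lower/left cell
    iy, ix = assign_cells(np.array([[3.0, 2.0]]), surf)
    assert (iy[0], ix[0]) == (2, 3)
    with pytest.raises(LinkageError):
        assign_cells(np.array([[6.0, 1.0]]), surf)  # on the outer edge


def test_assign_cells_agrees_with_brute_force_containment():
    surf = toy_surface({pd.Timestamp("2002-06-01"): 15.0}, shape=(5, 7))
    rng = np.random.default_rng(3)
    pts = np.column_stack([rng.uniform(0, 7, 500), rng.uniform(0, 5, 500)])
    iy, ix = assign_cells(pts, surf)
    for k in range(len(pts)):
        hits = [
            (i, j)
            for i in range(5)
            for j in range(7)
            if j <= pts[k, 0] < j + 1 and i <= pts[k, 1] < i + 1
        ]
        assert hits == [(iy[k], ix[k])]


def test_clamp_keeps_fuzzed_points_linkable():
    surf = toy_surface({pd.Timestamp("2002-06-01"): 15.0}, shape=(4, 4))
    xy = np.array([[-0.05, 2.0], [4.2, 3.9999]])
    clamped = clamp_to_extent(xy, surf)
    assign_cells(clamped, surf)  # must not raise


# ---------------------------------------------------------------------------
# lagged exposure
# ---------------------------------------------------------------------------

def test_lagged_mean_constant_field():
    days = pd.date_range("2002-06-01", "2002-06-10")
    surf = toy_surface({d: 15.0 for d in days})
    tmean = compute_daily_mean(surf)
    for lags in [(0,), (0, 1, 2, 3), (2,)]:
        assert lagged_mean_exposure("2002-06-08", (0, 0), tmean, lags) == 15.0


def test_lagged_mean_hand_computed_window():
    vals = {pd.Timestamp("2002-06-05"): 10.0, pd.Timestamp("2002-06-06"): 12.0,
            pd.Timestamp("2002-06-07"): 14.0, pd.Timestamp("2002-06-08"): 16.0}
    tmean = compute_daily_mean(toy_surface(vals))
    assert lagged_mean_exposure("2002-06-08", (0, 0), tmean, (0, 1, 2, 3)) == 13.0


def test_lag_window_reaches_into_late_may():
    days = pd.date_range("2002-05-26", "2002-06-03")
    vals = {d: float(i) for i, d in enumerate(days)}  # May 26 -> 0, ...
    tmean = compute_daily_mean(toy_surface(vals))
    got = lagged_mean_exposure("2002-06-01", (0, 0), tmean, tuple(range(6)))
    brute = np.mean([vals[pd.Timestamp("2002-06-01") - pd.Timedelta(days=L)]
                     for L in range(6)])
    assert got == brute  # pulls May 27-31 plus June 1


def test_missing_lag_day_raises_naming_date():
    days = pd.date_range("2002-06-01", "2002-06-05")
    tmean = compute_daily_mean(toy_surface({d: 1.0 for d in days}))
    with pytest.raises(LinkageError, match="2002-05-31"):
        lagged_mean_exposure("2002-06-03", (0, 0), tmean, (0, 1, 2, 3))


def test_lag_average_field_matches_scalar_path(medium_chain):
    study, _, _, _, _ = medium_chain
    tmean = compute_daily_mean(study.temperature)
    field = lag_average_field(tmean, (0, 1, 2, 3))
    t = pd.Timestamp("2003-07-10")
    ti = list(pd.DatetimeIndex(tmean["time"].values)).index(t)
    assert field.values[ti, 4, 7] == pytest.approx(
        lagged_mean_exposure(t, (4, 7), tmean, (0, 1, 2, 3))
    )


# ---------------------------------------------------------------------------
# covariate linkage and labels
# ---------------------------------------------------------------------------

def test_linked_records_schema_and_ranges(medium_chain):
    study, retained, _, linked, _ = medium_chain
    assert len(linked) == len(retained)
    for col in ("x_lag", "rain", "humidity", "wind", "holiday", "age_group",
                "period", "region", "cell_iy", "cell_ix"):
        assert col in linked.columns
    assert linked["x_lag"].notna().all()
    assert set(linked["holiday"].unique()) <= {0, 1}
    # holiday flag consistent with the calendar
    hol = set(study.holidays)
    expect = [d.date() in hol for d in pd.DatetimeIndex(linked["date"])]
    assert (linked["holiday"].values == np.array(expect, dtype=int)).all()


def test_x_lag_within_window_envelope(medium_chain):
    """Each record's lag-averaged exposure lies inside the min/max of its
    own window, checked directly against the surface."""
    study, _, _, linked, _ = medium_chain
    tmean = compute_daily_mean(study.temperature)
    times = pd.DatetimeIndex(tmean["time"].values)
    tpos = pd.Series(np.arange(len(times)), index=times)
    sub = linked.sample(n=200, random_state=0)
    for _, row in sub.iterrows():
        idx = [tpos[pd.Timestamp(row["date"]) - pd.Timedelta(days=L)]
               for L in (0, 1, 2, 3)]
        window = tmean.values[idx, int(row["cell_iy"]), int(row["cell_ix"])]
        assert window.min() - 1e-9 <= row["x_lag"] <= window.max() + 1e-9


def test_linkage_is_pure_given_seed(medium_chain):
    study, retained, _, linked, _ = medium_chain
    again = link_records(retained, study.temperature, study.covariates,
                         study.holidays, seed=1)
    pd.testing.assert_frame_equal(again, linked)


def test_age_group_boundaries():
    groups = age_group_of([5, 15, 16, 64, 65, 90]).astype(str).tolist()
    assert groups == ["5-15", "5-15", "16-64", "16-64", "65+", "65+"]


def test_period_boundaries():
    assert period_label(2007) == "2002-2007"
    assert period_label(2008) == "2008-2013"
    assert period_label(2013) == "2008-2013"
    assert period_label(2014) == "2014-2019"
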