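"""Window tables, the Matérn kernel and the spatial logistic GLMM."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from carnivisit import recurrence as rc
from conftest import lattice_cells

UTC = dt.timezone.utc
START = dt.datetime(2023, 7, 1, tzinfo=UTC)


def at_day(make_record, day, **kw):
    return make_record(ts=START + dt.timedelta(days=day, hours=12), **kw)


# ---------------------------------------------------------------------------
# window table

def test_window_table_definition(make_record):
    """Reports only in window 2 of four 30-day windows: the predictor row
    of window 1 sees outcome 1, window 2 carries the count, window 3 is
    all zero."""
    cells = lattice_cells(1, 1, lon0=22.0, lat0=49.3)
    recs = [at_day(make_record, 40, lon=22.005, lat=49.305)]
    wt = rc.build_window_table(recs, cells, start=START,
                               end=START + dt.timedelta(days=120))
    assert len(wt) == 3
    assert wt["n_all_prev"].tolist() == [0, 1, 0]
    assert wt["outcome_next"].tolist() == [1, 0, 0]
    assert wt["window_index"].tolist() == [1, 2, 3]


def test_window_table_no_records(make_record):
    cells = lattice_cells(2, 1, lon0=22.0, lat0=49.3)
    wt = rc.build_window_table([], cells, start=START,
                               end=START + dt.timedelta(days=90))
    assert (wt[["n_all_prev", "n_feeding_prev", "n_damage_prev",
                "outcome_next"]] == 0).all().all()


def test_row_count_is_cells_times_windows_minus_one(make_record):
    cells = lattice_cells(3, 2, lon0=22.0, lat0=49.3)
    recs = [at_day(make_record, d, lon=22.005, lat=49.305) for d in (3, 35, 80)]
    wt = rc.build_window_table(recs, cells, start=START,
                               end=START + dt.timedelta(days=360))
    assert len(wt) == len(cells) * (12 - 1)


def test_partial_final_window_dropped(make_record):
    cells = lattice_cells(1, 1, lon0=22.0, lat0=49.3)
    wt = rc.build_window_table([at_day(make_record, 5, lon=22.005, lat=49.305)],
                               cells, start=START,
                               end=START + dt.timedelta(days=75))
    assert len(wt) == 1  # two complete windows -> one predictor row


def test_short_period_rejected(make_record):
    cells = lattice_cells(1, 1, lon0=22.0, lat0=49.3)
    with pytest.raises(ValueError, match="window"):
        rc.build_window_table([at_day(make_record, 1, lon=22.005, lat=49.305)],
                              cells, start=START,
                              end=START + dt.timedelta(days=45))


def test_feeding_classification(make_record):
    """Successful anthropogenic foraging counts as feeding; 'other' does
    not; depredation counts as both feeding and damage by construction."""
    cells = lattice_cells(1, 1, lon0=22.0, lat0=49.3)
    recs = [
        at_day(make_record, 10, lon=22.005, lat=49.305,
               event_type="foraging_anthropogenic", attractants=("waste",),
               foraging_success="success"),
        at_day(make_record, 11, lon=22.005, lat=49.305,
               event_type="foraging_anthropogenic", attractants=("waste",),
               foraging_success="failure"),
        at_day(make_record, 12, lon=22.005, lat=49.305, event_type="other"),
        at_day(make_record, 13, lon=22.005, lat=49.305,
               event_type="depredation_domestic", attractants=("livestock",),
               foraging_success="success"),
    ]
    wt = rc.build_window_table(recs, cells, start=START,
                               end=START + dt.timedelta(days=90))
    first = wt[wt["window_index"] == 1].iloc[0]
    assert first["n_all_prev"] == 4
    assert first["n_feeding_prev"] == 2   # successful foraging + depredation
    assert first["n_damage_prev"] == 1    # depredation only


# ---------------------------------------------------------------------------
# Matérn kernel

@pytest.mark.parametrize("nu", [0.5, 1.5, 2.5])
def test_matern_is_one_at_zero_and_non_increasing(nu):
    d = np.linspace(0, 0.5, 200)
    c = rc.matern_correlation(d, rho=25.0, nu=nu)
    assert c[0] == pytest.approx(1.0)
    assert np.all(np.diff(c) <= 1e-12)
    assert np.all((c >= 0) & (c <= 1))


def test_matern_half_is_exponential():
    d = np.linspace(0, 0.3, 50)
    np.testing.assert_allclose(rc.matern_correlation(d, rho=25.0, nu=0.5),
                               np.exp(-25.0 * d), rtol=1e-12)


def test_matern_requires_positive_rho():
    with pytest.raises(ValueError):
        rc.matern_correlation(0.1, rho=0.0)


# ---------------------------------------------------------------------------
# spatial logistic fit

def test_lambda_zero_equals_plain_logistic():
    df = rc.simulate_recurrence_data(n_cols=8, n_rows=5, n_windows=8, seed=3)
    f0 = rc.fit_spatial_logistic(df, lambda_fixed=0.0)
    fsmall = rc.fit_spatial_logistic(df, lambda_fixed=1e-8,
                                     compute_covariance_ses=False)
    np.testing.assert_allclose(fsmall.estimates, f0.estimates, atol=1e-4)


def test_laplace_objective_converges_to_logistic_loglik():
    df = rc.simulate_recurrence_data(n_cols=6, n_rows=4, n_windows=6, seed=9)
    f0 = rc.fit_spatial_logistic(df, lambda_fixed=0.0)
    ll = rc.laplace_marginal_loglik(df, f0.estimates, rho=25.0, lam=1e-8)
    assert ll == pytest.approx(f0.log_marginal, abs=1e-4)


def test_single_replicate_parameter_recovery():
    """Fitting data simulated from the model recovers the generating
    parameters within two standard errors (one seeded replicate; the
    50-replicate coverage study lives in the acceptance suite)."""
    df = rc.simulate_recurrence_data(seed=0)
    fit = rc.fit_spatial_logistic(df, predictor="all")
    assert fit.converged and not fit.boundary_lambda
    assert abs(fit.estimates[0] - (-1.4)) <= 2 * fit.standard_errors[0]
    assert abs(fit.estimates[1] - 0.3) <= 2 * fit.standard_errors[1]
    assert abs(np.log(fit.rho / 25.0)) <= 2 * fit.se_log_rho
    assert abs(np.log(fit.lam / 0.3)) <= 2 * fit.se_log_lambda


def test_aicc_and_invariants():
    df = rc.simulate_recurrence_data(n_cols=8, n_rows=5, n_windows=8, seed=4)
    fit = rc.fit_spatial_logistic(df)
    assert fit.lam >= 0 and fit.rho > 0
    assert np.all((fit.p_values >= 0) & (fit.p_values <= 1))
    p = 4  # two fixed effects + two covariance parameters
    n = fit.n_obs
    expected = -2 * fit.log_marginal + 2 * p + 2 * p * (p + 1) / (n - p - 1)
    assert fit.aicc == pytest.approx(expected, rel=1e-9)


def test_two_cells_required():
    df = rc.simulate_recurrence_data(n_cols=1, n_rows=1, n_windows=8, seed=0)
    with pytest.raises(ValueError, match="two distinct cells"):
        rc.fit_spatial_logistic(df)


# ---------------------------------------------------------------------------
# prediction

def _fake_fit(beta0, beta1):
    return rc.SpatialGlmmFit(
        terms=["intercept", "n_all_prev"],
        estimates=np.array([beta0, beta1]),
        standard_errors=np.array([0.1, 0.1]),
        z_values=np.zeros(2), p_values=np.zeros(2), rho=25.0, lam=0.3,
        nu=0.5, aicc=0.0, log_marginal=0.0, n_obs=100, n_cells=10,
        converged=True)


def test_flat_slope_gives_constant_probability():
    fit = _fake_fit(-1.0, 0.0)
    probs = rc.predict_recurrence(fit, np.arange(10))
    np.testing.assert_allclose(probs, expit(-1.0))


def test_probability_at_zero_previous_reports():
    # inverse-logit of the intercept alone
    fit = _fake_fit(-1.39, 0.28)
    assert rc.predict_recurrence(fit, 0) == pytest.approx(0.199, abs=5e-4)


def test_probability_strictly_increasing_to_one():
    fit = _fake_fit(-1.39, 0.28)
    ks = np.arange(0, 60)
    probs = rc.predict_recurrence(fit, ks)
    assert np.all(np.diff(probs) > 0)
    assert probs[-1] > 0.999


def test_negative_k_rejected():
    with pytest.raises(ValueError):
        rc.predict_recurrence(_fake_fit(-1.0, 0.3), -1)
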