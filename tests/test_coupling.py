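"""Rank correlations, stepwise selection, amplitude fits and lag
estimation against independent oracles and constructed signals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stemflux import estimate_lag, fit_log_amplitude, spearman, stepwise_regression
from stemflux.coupling import (
    ENV_VARIABLES,
    correlation_table,
    significance_stars,
)
from stemflux.errors import (
    CollinearityError,
    DataQuantityError,
    EstimationError,
    ValidationError,
)
from tests.conftest import make_trace_series
from tests.oracles import brute_spearman, brute_stepwise


# ---------------------------------------------------------------------------
# spearman
# ---------------------------------------------------------------------------

def test_spearman_monotone():
    assert spearman([1, 2, 3, 4, 5], [1, 4, 9, 16, 25]).rho == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]).rho == pytest.approx(-1.0)


def test_spearman_ties_match_oracle():
    x = [1.0, 2.0, 2.0, 3.0, 4.0]
    y = [1.0, 3.0, 2.0, 4.0, 4.0]
    assert spearman(x, y).rho == pytest.approx(brute_spearman(x, y), abs=1e-12)


def test_spearman_oracle_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = rng.integers(5, 15)
        x = rng.integers(0, 6, n).astype(float)  # heavy ties
        y = rng.integers(0, 6, n).astype(float) + 0.5 * x
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        assert spearman(x, y).rho == pytest.approx(brute_spearman(x, y), abs=1e-10)


def test_spearman_pairwise_deletion_and_errors():
    x = [1.0, 2.0, np.nan, 3.0, 4.0, 5.0, 6.0, 7.0]
    y = [2.0, 4.0, 1.0, 6.0, 8.0, np.nan, 9.0, 11.0]
    assert spearman(x, y).n == 6
    with pytest.raises(DataQuantityError):
        spearman([1, 2, 3], [1, 2, 3])
    with pytest.raises(EstimationError):
        spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(-100, 100), min_size=6, max_size=20, unique=True))
def test_spearman_monotone_transform_invariance(xs):
    """exp is strictly increasing, so ranks (and rho) are unchanged."""
    xs = np.asarray(xs, dtype=float)
    rng = np.random.default_rng(7)
    ys = rng.permutation(len(xs)).astype(float)
    base = spearman(xs, ys).rho
    transformed = spearman(np.exp(xs / 50.0), ys).rho
    assert transformed == pytest.approx(base, abs=1e-12)


def test_significance_stars():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.2) == ""


# ---------------------------------------------------------------------------
# correlation table
# ---------------------------------------------------------------------------

def _daily_tables(n=60, seed=0):
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2019-05-01", periods=n, freq="D")
    clim = pd.DataFrame(
        {v: rng.normal(0, 1, n) for v in ENV_VARIABLES}, index=dates
    )
    rad = pd.DataFrame(
        {
            "daily_max": clim["t_max"].to_numpy(),   # exact copy
            "daily_mean": rng.normal(0, 1, n),
            "daily_min": rng.normal(0, 1, n),
            "amplitude": rng.normal(5, 1, n),
        },
        index=dates,
    )
    return rad, clim


def test_correlation_table_exact_copy_cell():
    rad, clim = _daily_tables()
    table = correlation_table(rad, clim)
    cell = table[(table.response == "Xyl_max") & (table.predictor == "t_max")]
    assert cell["rho"].iloc[0] == pytest.approx(1.0)


def test_correlation_table_consistent_with_spearman():
    rad, clim = _daily_tables(seed=3)
    table = correlation_table(rad, clim)
    cell = table[(table.response == "Xyl_mean") & (table.predictor == "vpd_max")]
    direct = spearman(rad["daily_mean"], clim["vpd_max"])
    assert cell["rho"].iloc[0] == pytest.approx(direct.rho)
    assert cell["n"].iloc[0] == direct.n


def test_correlation_table_empty_mask():
    rad, clim = _daily_tables()
    with pytest.raises(ValidationError):
        correlation_table(rad, clim, np.zeros(len(rad), dtype=bool))


def test_correlation_table_null_calibration():
    """Permuted response: correlations stay small at n = 500."""
    rng = np.random.default_rng(9)
    n = 500
    dates = pd.date_range("2019-01-01", periods=n, freq="D")
    clim = pd.DataFrame({v: rng.normal(0, 1, n) for v in ENV_VARIABLES}, index=dates)
    rad = pd.DataFrame(
        {"daily_max": rng.permutation(clim["t_max"].to_numpy()),
         "daily_mean": rng.normal(0, 1, n),
         "daily_min": rng.normal(0, 1, n)},
        index=dates,
    )
    table = correlation_table(rad, clim)
    assert (table["rho"].abs() < 0.2).mean() >= 0.95


# ---------------------------------------------------------------------------
# stepwise regression
# ---------------------------------------------------------------------------

def test_stepwise_empty_pool():
    y = pd.Series(np.random.default_rng(0).normal(0, 1, 30))
    model = stepwise_regression(y, pd.DataFrame(index=y.index))
    assert model.predictors == []
    assert model.adj_r2 == 0.0


def test_stepwise_recovers_generative_model():
    rng = np.random.default_rng(1)
    n = 100
    x1 = rng.normal(0, 1, n)
    x2 = rng.normal(0, 1, n)
    y = 2.0 * x1 + rng.normal(0, 0.1, n)
    pool = pd.DataFrame({"x1": x1, "x2": x2})
    model = stepwise_regression(pd.Series(y), pool)
    assert model.predictors == ["x1"]
    assert model.coefficients["x1"] == pytest.approx(2.0, rel=0.05)


def test_stepwise_matches_bruteforce_oracle():
    rng = np.random.default_rng(2)
    for rep in range(20):
        n = 80
        k = int(rng.integers(2, 6))
        pool = rng.normal(0, 1, (n, k))
        true = rng.integers(0, 2, k)
        y = pool @ (true * rng.normal(1.0, 0.5, k)) + rng.normal(0, 1.0, n)
        names = [f"x{j}" for j in range(k)]
        model = stepwise_regression(
            pd.Series(y), pd.DataFrame(pool, columns=names)
        )
        oracle_sel, oracle_coeffs = brute_stepwise(y, pool, names)
        assert set(model.predictors) == oracle_sel
        for name, val in oracle_coeffs.items():
            assert model.coefficients[name] == pytest.approx(val, abs=1e-8)


def test_stepwise_order_invariance():
    rng = np.random.default_rng(3)
    n = 90
    pool = pd.DataFrame({f"x{j}": rng.normal(0, 1, n) for j in range(4)})
    y = pd.Series(1.5 * pool["x2"] - 0.8 * pool["x0"] + rng.normal(0, 0.5, n))
    a = stepwise_regression(y, pool)
    b = stepwise_regression(y, pool[list(pool.columns)[::-1]])
    assert set(a.predictors) == set(b.predictors)
    assert a.adj_r2 == pytest.approx(b.adj_r2)


def test_stepwise_collinearity_error():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 60)
    pool = pd.DataFrame({"a": x, "b": 2.0 * x})
    with pytest.raises(CollinearityError):
        stepwise_regression(pd.Series(rng.normal(0, 1, 60)), pool)


def test_stepwise_data_quantity_guard():
    rng = np.random.default_rng(5)
    pool = pd.DataFrame({f"x{j}": rng.normal(0, 1, 30) for j in range(4)})
    with pytest.raises(DataQuantityError):
        stepwise_regression(pd.Series(rng.normal(0, 1, 30)), pool)


# ---------------------------------------------------------------------------
# log amplitude fit
# ---------------------------------------------------------------------------

def test_log_fit_exact():
    vpd = pd.Series(np.linspace(0.2, 4.0, 40))
    amp = 2.0 + 3.0 * np.log(vpd)
    fit = fit_log_amplitude(amp, vpd)
    assert fit.a == pytest.approx(2.0, abs=1e-9)
    assert fit.b == pytest.approx(3.0, abs=1e-9)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)


def test_log_fit_null():
    rng = np.random.default_rng(6)
    vpd = pd.Series(np.linspace(0.2, 4.0, 200))
    amp = pd.Series(rng.normal(5, 1, 200))
    fit = fit_log_amplitude(amp, vpd)
    assert abs(fit.b) < 2 * fit.se_b
    assert fit.r2 < 0.05


def test_log_fit_guards():
    vpd = pd.Series(np.full(20, 0.01))
    amp = pd.Series(np.ones(20))
    with pytest.raises(DataQuantityError):
        fit_log_amplitude(amp, vpd)


# ---------------------------------------------------------------------------
# lag estimation
# ---------------------------------------------------------------------------

def _diurnal(n_days=6, phase=0.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n_days * 48) * 0.5
    vals = np.sin(2 * np.pi * (t - phase) / 24.0) + noise * rng.normal(0, 1, len(t))
    return make_trace_series(vals)


def test_lag_zero_for_identical():
    x = _diurnal()
    assert estimate_lag(x, x.copy()) == pytest.approx(0.0, abs=0.05)


def test_lag_constructed_shift():
    x = _diurnal(8)
    y = x.shift(4)  # 4 samples = 2 h later
    assert estimate_lag(x, y) == pytest.approx(2.0, abs=0.26)


def test_lag_antisymmetry():
    x = _diurnal(8, noise=0.05, seed=1)
    y = _diurnal(8, phase=3.0, noise=0.05, seed=2)
    assert estimate_lag(x, y) == pytest.approx(-estimate_lag(y, x), abs=0.3)


def test_lag_errors():
    short = _diurnal(2)
    with pytest.raises(EstimationError):
        estimate_lag(short, short)
    flat = make_trace_series(np.zeros(5 * 48))
    with pytest.raises(EstimationError):
        estimate_lag(flat, flat)


def test_lag_simulator_truth(sim_clean):
    from stemflux.preprocess import PreprocessConfig, decompose_inner_bark, thermal_correct
    from stemflux.synthetic import implied_lag_hours

    ob, xy, truth = sim_clean
    t_air = truth.artifact_x / truth.params.alpha_x
    ob_c = thermal_correct(ob, t_air, PreprocessConfig())
    xy_c = thermal_correct(xy, t_air, PreprocessConfig())
    inner = decompose_inner_bark(ob_c, xy_c)
    lag = estimate_lag(xy_c.radius, inner.radius)
    assert lag == pytest.approx(implied_lag_hours(truth.params), abs=0.5)
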