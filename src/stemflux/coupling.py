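"""Xylem–phloem coupling and environmental-control statistics.

Rank correlations (Spearman ρ with the t approximation for p), a Table-2
style correlation matrix between daily xylem metrics and environmental
variables, forward stepwise regression with backward elimination, the
logarithmic amplitude–VPD fit, and cross-correlation lag estimation
between the 30-min xylem and inner-bark signals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    CollinearityError,
    DataQuantityError,
    EstimationError,
    ValidationError,
)
from .traces import RECORDS_PER_DAY

ENV_VARIABLES = [
    "t_max", "t_mean", "t_min",
    "vpd_max", "vpd_mean", "vpd_min",
    "rh_max", "rh_mean", "rh_min",
    "p_sum", "swc_mean",
]

RESPONSES = {"Xyl_max": "daily_max", "Xyl_mean": "daily_mean", "Xyl_min": "daily_min"}


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    n: int


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with average ranks and the t approximation.

    Missing values are removed pairwise; at least 5 complete pairs are
    required.  ρ is the Pearson correlation of average ranks; p comes from
    t = ρ·√((n−2)/(1−ρ²)) with n−2 degrees of freedom (p = 0 at |ρ| = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 5:
        raise DataQuantityError(f"spearman needs >= 5 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise EstimationError("correlation undefined for an all-tied input")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-14:
        return SpearmanResult(float(np.sign(rho)), 0.0, n)
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return SpearmanResult(rho, p, n)


def correlation_table(
    daily_radius: pd.DataFrame,
    daily_climate: pd.DataFrame,
    season_mask=None,
) -> pd.DataFrame:
    """Spearman ρ between daily xylem metrics and environmental variables.

    Returns a tidy table with one row per (response, predictor) pair:
    ``rho``, ``p``, ``n`` and significance ``stars`` (* / ** / *** at
    0.05 / 0.01 / 0.001).  ``season_mask`` restricts the dates (e.g. the
    April–September growing season).
    """
    joined = daily_radius.join(daily_climate, how="inner")
    if season_mask is not None:
        mask = np.asarray(season_mask)
        if mask.dtype != bool:
            raise ValidationError("season_mask must be boolean")
        if len(mask) != len(joined):
            mask = pd.Series(season_mask, index=daily_radius.index).reindex(joined.index).fillna(False).to_numpy(dtype=bool)
        joined = joined[mask]
    if joined.empty:
        raise ValidationError("correlation_table: empty seasonal selection")
    rows = []
    for resp_label, resp_col in RESPONSES.items():
        for env in ENV_VARIABLES:
            res = spearman(joined[resp_col], joined[env])
            rows.append(
                {
                    "response": resp_label,
                    "predictor": env,
                    "rho": res.rho,
                    "p": res.p,
                    "n": res.n,
                    "stars": significance_stars(res.p),
                }
            )
    return pd.DataFrame(rows)


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy correlation table into the responses × predictors
    matrix layout (ρ values)."""
    return table.pivot(index="response", columns="predictor", values="rho")[ENV_VARIABLES]


# ---------------------------------------------------------------------------
# stepwise regression
# ---------------------------------------------------------------------------

@dataclass
class StepwiseModel:
    """Result of a forward-with-elimination stepwise OLS fit."""

    predictors: list[str]
    coefficients: dict[str, float]    # includes "const"; non-standardized
    std_errors: dict[str, float]
    p_values: dict[str, float]
    adj_r2: float
    f_value: float
    df_model: int
    df_resid: int
    n: int

    def to_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "p_values": self.p_values,
            "adj_r2": self.adj_r2,
            "f_value": self.f_value,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "n": self.n,
        }


def _fit(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def _check_collinearity(pool: pd.DataFrame) -> None:
    cols = list(pool.columns)
    arr = pool.to_numpy(dtype=float)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            xi, xj = arr[:, i], arr[:, j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            if abs(r) > 1.0 - 1e-12:
                raise CollinearityError(
                    f"predictors {cols[i]!r} and {cols[j]!r} are perfectly collinear"
                )


def stepwise_regression(
    y: pd.Series,
    pool: pd.DataFrame,
    alpha_in: float = 0.05,
    alpha_out: float = 0.10,
) -> StepwiseModel:
    """Forward selection with backward elimination on partial-F p-values.

    At each iteration the candidate with the smallest partial-F p-value
    (equivalently, the two-sided t-test of its coefficient) enters if
    p < ``alpha_in``; any selected predictor whose p-value exceeds
    ``alpha_out`` is then removed (worst first).  Iterates to a fixed
    point.  Coefficients are non-standardized.
    """
    data = pd.concat([y.rename("__y__"), pool], axis=1).dropna()
    n = len(data)
    if pool.shape[1] > 0 and n < 10 * pool.shape[1]:
        raise DataQuantityError(
            f"stepwise needs >= 10 rows per pooled predictor ({10 * pool.shape[1]}), got {n}"
        )
    if pool.shape[1] > 0:
        _check_collinearity(data[pool.columns])
    yv = data["__y__"].to_numpy(dtype=float)

    selected: list[str] = []
    seen: set[frozenset] = set()
    while True:
        changed = False
        # forward step
        candidates = [c for c in pool.columns if c not in selected]
        best_p, best_c = None, None
        for c in candidates:
            fit = _fit(yv, data[selected + [c]])
            p = fit.pvalues[c]
            if np.isnan(p):
                continue
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < alpha_in:
            selected.append(best_c)
            changed = True
        # backward step(s)
        while selected:
            fit = _fit(yv, data[selected])
            pvals = fit.pvalues[selected]
            worst = pvals.idxmax()
            if pvals[worst] > alpha_out:
                selected.remove(worst)
                changed = True
            else:
                break
        key = frozenset(selected)
        if not changed or key in seen:
            break
        seen.add(key)

    fit = _fit(yv, data[selected]) if selected else sm.OLS(
        yv, np.ones((n, 1))
    ).fit()
    if selected:
        coeffs = {k: float(v) for k, v in fit.params.items()}
        ses = {k: float(v) for k, v in fit.bse.items()}
        ps = {k: float(v) for k, v in fit.pvalues.items()}
        adj_r2 = float(fit.rsquared_adj)
        f_value = float(fit.fvalue)
        df_model, df_resid = int(fit.df_model), int(fit.df_resid)
    else:
        coeffs = {"const": float(np.mean(yv))}
        ses = {"const": float(np.std(yv, ddof=1) / np.sqrt(n))}
        ps = {"const": float("nan")}
        adj_r2 = 0.0
        f_value = float("nan")
        df_model, df_resid = 0, n - 1
    return StepwiseModel(
        predictors=selected,
        coefficients=coeffs,
        std_errors=ses,
        p_values=ps,
        adj_r2=adj_r2,
        f_value=f_value,
        df_model=df_model,
        df_resid=df_resid,
        n=n,
    )


# ---------------------------------------------------------------------------
# amplitude–environment fits
# ---------------------------------------------------------------------------

@dataclass
class LogAmplitudeFit:
    """Least-squares fit amplitude = a + b·ln(VPD_max), with the linear
    fit's R² on the same days for comparison."""

    a: float
    b: float
    r2: float
    se_a: float
    se_b: float
    n: int
    linear_r2: float

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "r2": self.r2,
            "se_a": self.se_a, "se_b": self.se_b,
            "n": self.n, "linear_r2": self.linear_r2,
        }


VPD_LOG_GUARD_KPA = 0.05


def fit_log_amplitude(amplitude: pd.Series, vpd_max: pd.Series) -> LogAmplitudeFit:
    """Fit the saturating amplitude–VPD relationship a + b·ln(VPD_max).

    Days with VPD_max ≤ 0.05 kPa are excluded (log guard); at least 10
    valid days are required.
    """
    df = pd.concat([amplitude.rename("amp"), vpd_max.rename("vpd")], axis=1).dropna()
    df = df[df["vpd"] > VPD_LOG_GUARD_KPA]
    if len(df) < 10:
        raise DataQuantityError(f"log fit needs >= 10 valid days, got {len(df)}")
    fit = _fit(df["amp"].to_numpy(), pd.DataFrame({"lnvpd": np.log(df["vpd"])}))
    lin = _fit(df["amp"].to_numpy(), pd.DataFrame({"vpd": df["vpd"].to_numpy()}))
    return LogAmplitudeFit(
        a=float(fit.params["const"]),
        b=float(fit.params["lnvpd"]),
        r2=float(fit.rsquared),
        se_a=float(fit.bse["const"]),
        se_b=float(fit.bse["lnvpd"]),
        n=int(len(df)),
        linear_r2=float(lin.rsquared),
    )


def amplitude_environment_correlations(
    amplitude: pd.Series, daily_climate: pd.DataFrame
) -> pd.DataFrame:
    """Spearman ρ between the daily amplitude and each environmental
    variable (the linear panel of the amplitude–environment figure)."""
    rows = []
    joined = daily_climate.join(amplitude.rename("amp"), how="inner")
    for env in ENV_VARIABLES:
        res = spearman(joined["amp"], joined[env])
        rows.append({"predictor": env, "rho": res.rho, "p": res.p, "n": res.n,
                     "stars": significance_stars(res.p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lag estimation
# ---------------------------------------------------------------------------

def _longest_common_run(valid: np.ndarray) -> tuple[int, int]:
    best_start = best_len = cur_start = cur_len = 0
    for i, ok in enumerate(valid):
        if ok:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_len = 0
    return best_start, best_len


def remove_daily_means(series: pd.Series) -> pd.Series:
    """High-pass a 30-min series by subtracting each calendar day's mean."""
    days = series.index.normalize()
    return series - series.groupby(days).transform("mean")


def remove_rolling_daily_mean(series: pd.Series) -> pd.Series:
    """High-pass a 30-min series by subtracting a centred 24-h rolling mean.

    Unlike calendar-day demeaning this also removes within-day drift (soil
    drying, growth), which otherwise leaks a zero-lag common component into
    both signals and biases cross-correlation lags toward zero.
    """
    rolling = series.rolling(RECORDS_PER_DAY, center=True, min_periods=RECORDS_PER_DAY // 2).mean()
    return series - rolling


def estimate_lag(
    x: pd.Series,
    y: pd.Series,
    max_lag_hours: float = 12.0,
    highpass: bool = True,
) -> float:
    """Bark-behind-xylem lag from the cross-correlation of two 30-min series.

    Finds the lag (in hours, ±``max_lag_hours``) maximising the normalised
    cross-correlation of ``y`` against ``x`` over their longest common
    gapless window (≥ 3 days required), after removing a centred 24-h
    rolling mean from each series (``highpass=False`` if the inputs are
    already detrended).  Positive values mean ``y`` lags ``x``.  The
    discrete peak is refined by parabolic interpolation.
    """
    if not x.index.equals(y.index):
        common = x.index.intersection(y.index)
        x, y = x.reindex(common), y.reindex(common)
    valid = (~x.isna() & ~y.isna()).to_numpy()
    start, length = _longest_common_run(valid)
    if length < 3 * RECORDS_PER_DAY:
        raise EstimationError(
            "estimate_lag needs a common gapless window of at least 3 days"
        )
    xs = x.iloc[start:start + length]
    ys = y.iloc[start:start + length]
    if highpass:
        xs = remove_rolling_daily_mean(xs)
        ys = remove_rolling_daily_mean(ys)
    xv = xs.to_numpy(dtype=float)
    yv = ys.to_numpy(dtype=float)
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise EstimationError("estimate_lag: flat series")
    max_lag = int(round(max_lag_hours * 2))
    lags = np.arange(-max_lag, max_lag + 1)
    corrs = np.empty(len(lags))
    for i, k in enumerate(lags):
        if k >= 0:
            a, b = xv[: len(xv) - k], yv[k:]
        else:
            a, b = xv[-k:], yv[: len(yv) + k]
        if np.std(a) == 0 or np.std(b) == 0:
            corrs[i] = -np.inf
            continue
        corrs[i] = np.corrcoef(a, b)[0, 1]
    kbest = int(np.argmax(corrs))
    khat = float(lags[kbest])
    if 0 < kbest < len(lags) - 1 and np.isfinite(corrs[kbest - 1:kbest + 2]).all():
        c_m, c_0, c_p = corrs[kbest - 1], corrs[kbest], corrs[kbest + 1]
        denom = c_m - 2 * c_0 + c_p
        if denom < 0:
            khat += 0.5 * (c_m - c_p) / denom
    return khat * 0.5  # samples → hours


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class CouplingReport:
    """Bundle of every coupling statistic the pipeline produces."""

    residual_coupling: SpearmanResult
    correlation_table: pd.DataFrame = field(repr=False)
    stepwise_models: dict[str, StepwiseModel] = field(repr=False)
    amplitude_fit: LogAmplitudeFit
    amplitude_correlations: pd.DataFrame = field(repr=False)
    lag_hours: float

    def to_dict(self) -> dict:
        return {
            "residual_coupling": {
                "rho": self.residual_coupling.rho,
                "p": self.residual_coupling.p,
                "n": self.residual_coupling.n,
            },
            "correlation_table": self.correlation_table.to_dict(orient="records"),
            "stepwise_models": {k: m.to_dict() for k, m in self.stepwise_models.items()},
            "amplitude_fit": self.amplitude_fit.to_dict(),
            "amplitude_correlations": self.amplitude_correlations.to_dict(orient="records"),
            "lag_hours": self.lag_hours,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
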