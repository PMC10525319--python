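"""Synthetic weather and stem-hydraulics generator with known ground truth.

The stem is modelled as a two-compartment resistance–capacitance network:
transpiration E pulls water through the soil–xylem resistance ``r_soil``
and, via the exchange resistance ``r_stor``, dehydrates an elastic storage
compartment (the inner bark) of capacitance ``c_stor``.  The xylem water
potential is quasi-steady (its own capacitance is negligible on a 30-min
step), so each step solves the node balance

    (Ψ_soil − Ψ_x)/r_soil + (Ψ_s − Ψ_x)/r_stor = E

for Ψ_x, then updates storage water with explicit Euler,
W ← W − q·Δt with q = (Ψ_s − Ψ_x)/r_stor and Ψ_s = Ψ_s0 + (W − W0)/c_stor.

Radii follow the potentials elastically: the lignified xylem moves by
``eps_x`` µm MPa⁻¹ and the soft inner bark by ``eps_b`` (about ten times
larger), on top of a Gompertz seasonal growth curve for the bark.
Measured traces add thermal artifacts proportional to air temperature,
Gaussian sensor noise, and random gaps.

The storage compartment relaxes toward its hydraulic environment with time
constant τ_s = (r_soil + r_stor)·c_stor, so for a diurnal (24 h) forcing
the bark signal trails the xylem signal by the first-order phase delay

    lag = (P/2π) · arctan(2π τ_s / P),  P = 24 h,

which :func:`implied_lag_hours` reports as the ground truth for lag
recovery tests.  Transpiration saturates with VPD through a canopy
conductance decline, E = g_max · s(SR) · VPD / (1 + VPD/vpd_sat), which is
what makes the daily amplitude–VPD relationship logarithmic rather than
linear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NumericalError, ValidationError
from .preprocess import compute_vpd
from .traces import ClimateTrace, SensorTrace, RECORDS_PER_DAY

DT_HOURS = 0.5


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class WeatherConfig:
    """Diurnal/seasonal weather generator settings.

    Defaults emulate a dry inner-alpine growing season: seasonal mean air
    temperature around 14 °C peaking in late July, 8 °C diurnal range,
    humidity anticorrelated with temperature, ~390 mm of growing-season
    rain, and a soil bucket spanning 5–33 vol %.
    """

    start_date: str = "2019-04-01"
    n_days: int = 183
    t_seasonal_mean: float = 11.0
    t_seasonal_amplitude: float = 8.0
    t_diurnal_amplitude: float = 10.0
    rh_base: float = 70.0
    rh_t_slope: float = 2.5
    sr_peak: float = 900.0
    cloud_fraction: float = 0.35
    rain_event_rate: float = 0.45
    rain_event_mean: float = 4.7
    swc_max: float = 33.0
    swc_min: float = 5.0
    swc_drain_rate: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "start_date":
                continue
            if not np.isfinite(v):
                raise ConfigurationError(f"WeatherConfig.{f.name} is not finite")
        if self.n_days < 1:
            raise ConfigurationError("WeatherConfig.n_days must be >= 1")
        if not 0.0 <= self.cloud_fraction <= 1.0:
            raise ConfigurationError("WeatherConfig.cloud_fraction must be in [0, 1]")
        for name in ("t_diurnal_amplitude", "sr_peak", "rain_event_rate",
                     "rain_event_mean", "swc_drain_rate", "rh_t_slope"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"WeatherConfig.{name} must be >= 0")
        if self.swc_max <= self.swc_min:
            raise ConfigurationError("WeatherConfig.swc_max must exceed swc_min")
        if not 0.0 <= self.rh_base <= 100.0:
            raise ConfigurationError("WeatherConfig.rh_base must be in [0, 100]")


@dataclass
class HydraulicParams:
    """Two-compartment stem model parameters.

    Units: potentials in MPa, radii in µm, water in arbitrary "unit water"
    (only potentials and radii are physical), fluxes in unit water per hour,
    resistances in MPa per unit flux, capacitance in unit water per MPa.

    ``r_stor · c_stor`` is the storage time constant τ that sets how far the
    bark trails the xylem; with the default r_soil = r_stor/10 and τ = 2 h
    the diurnal phase lag is almost exactly 2 h.  ``eps_b/eps_x`` sets the
    bark:xylem amplitude ratio (default 10).  ``growth_total`` defaults to
    the ~0.7 mm of radial growth a slow-growing drought-limited pine puts on
    in one season, following a Gompertz curve over day of year.
    """

    g_max: float = 5.0
    vpd_sat: float = 1.2
    sr_sat: float = 150.0
    r_soil: float = 0.1
    r_stor: float = 1.0
    c_stor: float = 2.0
    eps_x: float = 25.0
    eps_b: float = 250.0
    k_soilpsi: float = 0.02
    growth_total: float = 700.0
    growth_midpoint_doy: float = 170.0
    growth_rate: float = 0.035
    alpha_x: float = 1.08
    alpha_b: float = 0.2
    noise_sd: float = 0.5
    gap_fraction: float = 0.01
    seed: int = 0
    swc_ref: float | None = None

    def validate(self) -> None:
        for name in ("r_soil", "r_stor", "c_stor", "eps_x", "eps_b"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"HydraulicParams.{name} must be > 0")
        for name in ("g_max", "vpd_sat", "sr_sat", "k_soilpsi", "growth_total",
                     "growth_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"HydraulicParams.{name} must be >= 0")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ConfigurationError("HydraulicParams.gap_fraction must be in [0, 1)")

    @property
    def tau_hours(self) -> float:
        """Storage time constant r_stor·c_stor (hours)."""
        return self.r_stor * self.c_stor


def implied_lag_hours(params: HydraulicParams, period_hours: float = 24.0) -> float:
    """Ground-truth bark-behind-xylem lag for a sinusoidal forcing.

    The storage potential is a first-order low-pass of its hydraulic
    environment with τ_s = (r_soil + r_stor)·c_stor, so at forcing period P
    the phase delay is (P/2π)·arctan(2π τ_s/P).
    """
    tau_s = (params.r_soil + params.r_stor) * params.c_stor
    return period_hours / (2 * math.pi) * math.atan(2 * math.pi * tau_s / period_hours)


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def _day_length_hours(doy: np.ndarray) -> np.ndarray:
    # 8–16 h photoperiod over the year, longest near the summer solstice
    return 12.0 + 4.0 * np.sin(2 * math.pi * (doy - 80.0) / 365.25)


def generate_weather(config: WeatherConfig) -> ClimateTrace:
    """Generate a 30-min microclimate record from a seasonal/diurnal model.

    Temperature is a seasonal sinusoid (peaking late July) plus an AR(1)
    day-to-day anomaly and a diurnal sinusoid peaking at 15:00, damped on
    cloudy days.  RH is anticorrelated with temperature and pushed toward
    saturation during rain.  Solar radiation follows a half-sine photoperiod
    shape, zero at night.  Rain events arrive as a daily Poisson process
    with exponential amounts.  Soil water content follows a bucket: rain
    fills it, exponential drainage empties it, and drainage is increased on
    high-VPD days (evaporative demand).  Identical seed ⇒ identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_steps = config.n_days * RECORDS_PER_DAY
    index = pd.date_range(config.start_date, periods=n_steps, freq="30min")
    doy = index.dayofyear.to_numpy().astype(float)
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    day_of_run = np.arange(n_steps) // RECORDS_PER_DAY

    # --- temperature ---
    t_seasonal = config.t_seasonal_mean + config.t_seasonal_amplitude * np.cos(
        2 * math.pi * (doy - 200.0) / 365.25
    )
    anomaly = np.empty(config.n_days)
    phi, sd = 0.7, 3.5  # synoptic day-to-day variability
    anomaly[0] = rng.normal(0.0, sd)
    for d in range(1, config.n_days):
        anomaly[d] = phi * anomaly[d - 1] + rng.normal(0.0, sd * math.sqrt(1 - phi**2))
    cloudy = rng.random(config.n_days) < config.cloud_fraction

    # --- rain (daily Poisson events with exponential amounts) ---
    p = np.zeros(n_steps)
    n_events = rng.poisson(config.rain_event_rate, size=config.n_days)
    for d in range(config.n_days):
        for _ in range(n_events[d]):
            slot = rng.integers(0, RECORDS_PER_DAY)
            p[d * RECORDS_PER_DAY + slot] += rng.exponential(config.rain_event_mean)
    rainy_day = n_events > 0
    cloudy = cloudy | rainy_day  # rain implies cloud

    diurnal_damp = np.where(cloudy, 0.4, 1.0)[day_of_run]
    t_air = (
        t_seasonal
        + anomaly[day_of_run]
        + 0.5 * config.t_diurnal_amplitude * diurnal_damp
        * np.cos(2 * math.pi * (hour - 15.0) / 24.0)
    )

    # --- humidity (anticorrelated with T; saturated during rain) ---
    rh = (
        config.rh_base
        - config.rh_t_slope * (t_air - config.t_seasonal_mean)
        + np.where(cloudy, 8.0, 0.0)[day_of_run]
        + rng.normal(0.0, 2.0, n_steps)
    )
    rh = np.where(p > 0, np.maximum(rh, 97.0), rh)
    rh = np.clip(rh, 5.0, 100.0)

    # --- solar radiation (half-sine photoperiod, zero at night) ---
    day_len = _day_length_hours(doy)
    sunrise = 12.0 - day_len / 2.0
    phase = (hour - sunrise) / day_len
    shape = np.where((phase > 0) & (phase < 1), np.sin(math.pi * np.clip(phase, 0, 1)), 0.0)
    sr = config.sr_peak * shape ** 1.2
    sr *= np.where(cloudy, 0.25, 1.0)[day_of_run]
    sr = np.where(p > 0, sr * 0.5, sr)
    sr = np.maximum(sr, 0.0)

    vpd = compute_vpd(t_air, rh)

    # --- soil bucket ---
    daily_vpd = np.array(
        [vpd[d * RECORDS_PER_DAY:(d + 1) * RECORDS_PER_DAY].mean() for d in range(config.n_days)]
    )
    demand = 1.0 + 0.5 * np.minimum(daily_vpd, 2.0)
    swc = np.empty(n_steps)
    s = config.swc_min + 0.85 * (config.swc_max - config.swc_min)
    drain_per_step = config.swc_drain_rate / RECORDS_PER_DAY
    for i in range(n_steps):
        s += 0.6 * p[i]
        s -= drain_per_step * demand[day_of_run[i]] * (s - config.swc_min)
        s = min(max(s, config.swc_min), config.swc_max)
        swc[i] = s

    data = pd.DataFrame(
        {
            "t_air_c": t_air,
            "rh_pct": rh,
            "sr_wm2": sr,
            "p_mm": p,
            "swc_volpct": swc,
            "vpd_kpa": vpd,
        },
        index=index,
    )
    return ClimateTrace(data)


# ---------------------------------------------------------------------------
# stem simulation
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Unobserved states of a simulation run, for parameter-recovery tests.

    All series share the climate grid.  ``water`` is storage water relative
    to its initial value (arbitrary units); ``q`` is the storage→xylem
    exchange flow per step, positive when storage is being depleted.
    """

    psi_x: pd.Series
    psi_s: pd.Series
    psi_soil: pd.Series
    water: pd.Series
    q: pd.Series
    e: pd.Series
    growth: pd.Series
    r_x_true: pd.Series
    bark_true: pd.Series
    artifact_x: pd.Series
    artifact_b: pd.Series
    params: HydraulicParams = field(repr=False)

    def water_balance_error(self) -> float:
        """|W(end) − W(0) + Σ q·Δt| relative to total turnover.

        ``water[i]`` is the state at the *start* of step i, so the final
        state is water[-1] − q[-1]·Δt.
        """
        turnover = float(np.abs(self.q.to_numpy()).sum() * DT_HOURS)
        w_end = float(self.water.iloc[-1] - self.q.iloc[-1] * DT_HOURS)
        closure = float(
            w_end - self.water.iloc[0] + self.q.to_numpy().sum() * DT_HOURS
        )
        if turnover == 0.0:
            return abs(closure)
        return abs(closure) / turnover


def gompertz_growth(index: pd.DatetimeIndex, params: HydraulicParams) -> pd.Series:
    """Cumulative intra-annual radial growth G(t) in µm.

    Each calendar year contributes a Gompertz sigmoid over day of year,
    G_year(doy) = growth_total · exp(−exp(−growth_rate·(doy − midpoint))),
    and completed years carry their full total forward.
    """
    doy = index.dayofyear.to_numpy().astype(float) + (
        index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    ) / 24.0
    year = index.year.to_numpy()
    within = params.growth_total * np.exp(
        -np.exp(-params.growth_rate * (doy - params.growth_midpoint_doy))
    )
    completed = (year - year[0]).astype(float) * params.growth_total
    return pd.Series(within + completed - within[0], index=index, name="growth_um")


def transpiration(climate: ClimateTrace, params: HydraulicParams) -> pd.Series:
    """Transpiration rate E (unit water h⁻¹) with canopy-conductance
    saturation: E = g_max · s(SR) · VPD / (1 + VPD/vpd_sat), where
    s = SR/sr_sat clipped to [0, 1] is the light response of canopy
    conductance.  ``sr_sat`` is the saturating irradiance (conductance
    saturates well below full sun), so E is zero at night and
    light-limited only in deep shade or at dawn/dusk."""
    vpd = climate.vpd.to_numpy()
    sr = climate.sr.to_numpy()
    s = np.clip(sr / max(params.sr_sat, 1e-9), 0.0, 1.0)
    if params.vpd_sat > 0:
        e = params.g_max * s * vpd / (1.0 + vpd / params.vpd_sat)
    else:
        e = params.g_max * s * vpd
    return pd.Series(e, index=climate.index, name="e")


def simulate_stem(
    climate: ClimateTrace, params: HydraulicParams
) -> tuple[SensorTrace, SensorTrace, SimTruth]:
    """Run the two-compartment stem model over a gapless climate record.

    Returns the measured over-bark trace, the measured on-xylem trace and
    the full ground truth.  Measured traces include thermal artifacts
    (α·T), Gaussian noise and random gaps; the truth series carry none of
    these.  The same ``params.seed`` reproduces noise and gap placement
    bitwise.
    """
    params.validate()
    from .preprocess import ensure_vpd

    climate = ensure_vpd(climate)
    if climate.has_gaps() or climate.vpd.isna().any():
        raise ValidationError("simulate_stem requires a gapless climate record")

    index = climate.index
    n = len(index)
    t_air = climate.t_air.to_numpy()
    swc = climate.swc.to_numpy()
    swc_ref = params.swc_ref if params.swc_ref is not None else float(swc.max())
    psi_soil = -params.k_soilpsi * (swc_ref - swc)

    e = transpiration(climate, params).to_numpy()
    r_soil, r_stor, c_stor = params.r_soil, params.r_stor, params.c_stor
    g_total = 1.0 / r_soil + 1.0 / r_stor

    psi_x = np.empty(n)
    psi_s = np.empty(n)
    water = np.empty(n)
    q = np.empty(n)

    psi_s_now = psi_soil[0]
    w_now = 0.0
    psi_x_prev = None
    for i in range(n):
        psi_x_now = (psi_soil[i] / r_soil + psi_s_now / r_stor - e[i]) / g_total
        if psi_x_prev is not None and abs(psi_x_now - psi_x_prev) > 1.0:
            raise NumericalError(
                "explicit Euler unstable (|ΔΨ_x| > 1 MPa per step); "
                "use a smaller time step or larger resistances"
            )
        q_now = (psi_s_now - psi_x_now) / r_stor
        psi_x[i], psi_s[i], water[i], q[i] = psi_x_now, psi_s_now, w_now, q_now
        w_now = w_now - q_now * DT_HOURS
        psi_s_now = psi_soil[0] + w_now / c_stor
        psi_x_prev = psi_x_now

    growth = gompertz_growth(index, params)
    r_x_true = params.eps_x * (psi_x - psi_x[0])
    bark_true = growth.to_numpy() + params.eps_b * (psi_s - psi_s[0])

    rng = np.random.default_rng(params.seed)
    artifact_x = params.alpha_x * t_air
    artifact_b = params.alpha_b * t_air
    noise_x = rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else np.zeros(n)
    noise_ob = rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else np.zeros(n)
    gaps_x = rng.random(n) < params.gap_fraction
    gaps_ob = rng.random(n) < params.gap_fraction

    measured_x = r_x_true + artifact_x + noise_x
    measured_ob = r_x_true + bark_true + artifact_b + noise_ob
    measured_x[gaps_x] = np.nan
    measured_ob[gaps_ob] = np.nan

    truth = SimTruth(
        psi_x=pd.Series(psi_x, index=index, name="psi_x_mpa"),
        psi_s=pd.Series(psi_s, index=index, name="psi_s_mpa"),
        psi_soil=pd.Series(psi_soil, index=index, name="psi_soil_mpa"),
        water=pd.Series(water, index=index, name="water"),
        q=pd.Series(q, index=index, name="q"),
        e=pd.Series(e, index=index, name="e"),
        growth=growth,
        r_x_true=pd.Series(r_x_true, index=index, name="r_x_true_um"),
        bark_true=pd.Series(bark_true, index=index, name="bark_true_um"),
        artifact_x=pd.Series(artifact_x, index=index, name="artifact_x_um"),
        artifact_b=pd.Series(artifact_b, index=index, name="artifact_b_um"),
        params=params,
    )

    tree = f"sim{params.seed}"
    overbark = SensorTrace(tree, "overbark", pd.Series(measured_ob, index=index))
    xylem = SensorTrace(tree, "xylem", pd.Series(measured_x, index=index))
    return overbark, xylem, truth


def simulate_stand(
    climate: ClimateTrace, params: HydraulicParams, n_trees: int, seed: int
) -> tuple[list[SensorTrace], list[SimTruth]]:
    """Simulate several trees sharing hydraulic parameters but independent
    noise and gap realisations (per-tree seeds derived from ``seed``)."""
    if n_trees < 1:
        raise ConfigurationError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    tree_seeds = rng.integers(0, 2**31 - 1, size=n_trees)
    traces: list[SensorTrace] = []
    truths: list[SimTruth] = []
    for k, s in enumerate(tree_seeds, start=1):
        p = replace(params, seed=int(s))
        ob, xy, truth = simulate_stem(climate, p)
        tree = f"tree{k}"
        traces.append(SensorTrace(tree, "overbark", ob.radius))
        traces.append(SensorTrace(tree, "xylem", xy.radius))
        truths.append(truth)
    return traces, truths
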