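"""End-to-end pipeline orchestration with stable file contracts.

Each stage reads its inputs from the output directory (or the configured
input CSVs), writes plain CSV/JSON intermediates, and can therefore be
re-run in isolation with identical results.  ``run_pipeline`` chains the
stages and writes a ``manifest.json`` with the configuration echo, row
counts and seed.  All randomness flows from the single run seed through
per-stage derived seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coupling import (
    CouplingReport,
    amplitude_environment_correlations,
    correlation_table,
    estimate_lag,
    fit_log_amplitude,
    spearman,
    stepwise_regression,
    ENV_VARIABLES,
    RESPONSES,
)
from .daily import daily_climate, daily_radius_stats, growing_season_mask, growing_season_summary
from .detrend import residualize
from .errors import ConfigurationError, ValidationError
from .preprocess import (
    PreprocessConfig,
    aggregate_trees,
    decompose_inner_bark,
    ensure_vpd,
    thermal_correct,
)
from .synthetic import HydraulicParams, WeatherConfig, generate_weather, simulate_stand
from .traces import (
    read_climate_csv,
    read_dendro_csv,
    write_climate_csv,
    write_dendro_csv,
)

logger = logging.getLogger("stemflux")


@dataclass
class RunConfig:
    """Full pipeline configuration.

    Exactly one of ``inputs`` (paths to dendrometer and climate CSVs) or
    ``simulate`` (weather + hydraulic parameter blocks) must be present.
    """

    out_dir: str = "stemflux_out"
    seed: int = 0
    log_level: str = "INFO"
    inputs: dict | None = None                 # {dendro_csv, climate_csv}
    simulate: dict | None = None               # {weather: {...}, hydraulics: {...}, n_trees}
    preprocess: dict = field(default_factory=dict)   # PreprocessConfig fields + skip_thermal
    metrics: dict = field(default_factory=dict)      # {min_coverage}
    detrend: dict = field(default_factory=dict)      # {cutoff_days: [10, 25]}
    stats: dict = field(default_factory=dict)        # {alpha_in, alpha_out, max_lag_hours}

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigurationError(
                "exactly one of 'inputs' and 'simulate' must be configured"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def cutoff_days(self) -> list[int]:
        return list(self.detrend.get("cutoff_days", [10, 25]))

    @property
    def min_coverage(self) -> float:
        return float(self.metrics.get("min_coverage", 0.9))


def default_simulation_config(seed: int = 0, out_dir: str = "stemflux_out") -> RunConfig:
    """Two growing seasons of the default simulated stand of four trees."""
    return RunConfig(
        out_dir=out_dir,
        seed=seed,
        simulate={"weather": {"n_days": 549}, "hydraulics": {}, "n_trees": 4},
    )


def _stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    return {
        "weather": int(rng.integers(0, 2**31 - 1)),
        "stand": int(rng.integers(0, 2**31 - 1)),
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, out_dir: Path) -> None:
    """Generate weather and a simulated stand; write climate.csv,
    dendro.csv and truth.json."""
    if config.simulate is None:
        raise ConfigurationError("no 'simulate' block configured")
    seeds = _stage_seeds(config.seed)
    weather_kwargs = dict(config.simulate.get("weather", {}))
    weather_kwargs.setdefault("seed", seeds["weather"])
    wcfg = WeatherConfig(**weather_kwargs)
    hyd_kwargs = dict(config.simulate.get("hydraulics", {}))
    params = HydraulicParams(**hyd_kwargs)
    n_trees = int(config.simulate.get("n_trees", 4))

    climate = generate_weather(wcfg)
    traces, truths = simulate_stand(climate, params, n_trees, seeds["stand"])
    write_climate_csv(climate, out_dir / "climate.csv")
    write_dendro_csv(traces, out_dir / "dendro.csv")

    truth_summary = {
        "weather_config": dataclasses.asdict(wcfg),
        "hydraulic_params": dataclasses.asdict(params),
        "n_trees": n_trees,
        "water_balance_error": [t.water_balance_error() for t in truths],
        "growth_total_um": float(truths[0].growth.iloc[-1]),
        "psi_x_range_mpa": [float(truths[0].psi_x.min()), float(truths[0].psi_x.max())],
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_summary, fh, indent=2, sort_keys=True)
    logger.info("simulate: %d trees, %d climate records", n_trees, len(climate.index))


def _load_raw(config: RunConfig, out_dir: Path):
    if config.simulate is not None:
        dendro_path = out_dir / "dendro.csv"
        climate_path = out_dir / "climate.csv"
    else:
        dendro_path = Path(config.inputs["dendro_csv"])
        climate_path = Path(config.inputs["climate_csv"])
    return read_dendro_csv(dendro_path), read_climate_csv(climate_path)


def stage_preprocess(config: RunConfig, out_dir: Path) -> None:
    """Thermal-correct raw traces, derive inner bark, aggregate trees;
    write corrected.csv (per-tree and tree-mean rows)."""
    traces, climate = _load_raw(config, out_dir)
    climate = ensure_vpd(climate)
    skip_thermal = bool(config.preprocess.get("skip_thermal", False))
    pp_kwargs = {
        k: v for k, v in config.preprocess.items()
        if k in ("coeff_bark", "coeff_xylem", "reference_temperature", "reference_value")
    }
    ppcfg = PreprocessConfig(**pp_kwargs)

    by_tree: dict[str, dict[str, object]] = {}
    for t in traces:
        by_tree.setdefault(t.tree_id, {})[t.position] = t
    corrected = []
    for tree_id, positions in sorted(by_tree.items()):
        if "overbark" not in positions or "xylem" not in positions:
            raise ValidationError(f"tree {tree_id}: need both overbark and xylem traces")
        ob, xy = positions["overbark"], positions["xylem"]
        if not skip_thermal:
            t_ob = climate.t_air.reindex(ob.index)
            t_xy = climate.t_air.reindex(xy.index)
            ob = thermal_correct(ob, t_ob, ppcfg)
            xy = thermal_correct(xy, t_xy, ppcfg)
        else:
            ob = ob.with_radius(ob.radius, corrected=True)
            xy = xy.with_radius(xy.radius, corrected=True)
        inner = decompose_inner_bark(ob, xy)
        corrected.extend([ob, xy, inner])

    out = list(corrected)
    for position in ("xylem", "innerbark"):
        group = [t for t in corrected if t.position == position]
        if len(group) >= 2:
            agg = aggregate_trees(group)
            out.append(agg.mean)
    write_dendro_csv(out, out_dir / "corrected.csv")
    logger.info("preprocess: %d corrected traces (incl. tree means)", len(out))


def stage_daily(config: RunConfig, out_dir: Path) -> None:
    """Daily radius metrics and climate aggregates; write daily_radius.csv,
    daily_climate.csv and table1.csv (growing-season summary)."""
    traces = read_dendro_csv(out_dir / "corrected.csv")
    _, climate = _load_raw(config, out_dir)
    climate = ensure_vpd(climate)
    frames = []
    for t in traces:
        if t.position == "overbark":
            continue
        stats = daily_radius_stats(t, config.min_coverage)
        frames.append(stats.reset_index())
    radius_daily = pd.concat(frames, ignore_index=True)
    radius_daily.to_csv(out_dir / "daily_radius.csv", index=False, na_rep="NA",
                        float_format="%.6f")
    clim_daily = daily_climate(climate)
    clim_daily.reset_index().to_csv(out_dir / "daily_climate.csv", index=False,
                                    na_rep="NA", float_format="%.6f")
    growing_season_summary(clim_daily).reset_index().to_csv(
        out_dir / "table1.csv", index=False, na_rep="NA", float_format="%.3f"
    )
    logger.info("daily: %d radius rows, %d climate days", len(radius_daily), len(clim_daily))


def _read_daily_radius(out_dir: Path) -> pd.DataFrame:
    df = pd.read_csv(out_dir / "daily_radius.csv", na_values=["NA"], parse_dates=["date"])
    return df


def stage_detrend(config: RunConfig, out_dir: Path) -> None:
    """FFT low-pass detrending of the tree-mean daily series at each
    configured cutoff; write residuals.csv."""
    df = _read_daily_radius(out_dir)
    rows = []
    for cutoff in config.cutoff_days:
        for position in ("xylem", "innerbark"):
            sub = df[(df["tree_id"] == "mean") & (df["position"] == position)]
            if sub.empty:
                continue
            series = sub.set_index("date")["daily_mean"]
            det = residualize(series, cutoff)
            rows.append(
                pd.DataFrame(
                    {
                        "date": det.original.index,
                        "position": position,
                        "original_um": det.original.to_numpy(),
                        "smooth_um": det.smooth.to_numpy(),
                        "residual_um": det.residual.to_numpy(),
                        "cutoff_days": cutoff,
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True)
    out.to_csv(out_dir / "residuals.csv", index=False, na_rep="NA", float_format="%.6f")
    logger.info("detrend: %d residual rows", len(out))


def stage_couple(config: RunConfig, out_dir: Path) -> CouplingReport:
    """Coupling statistics on the pipeline intermediates; write
    coupling_report.json, table2.csv, table3.csv and fig6_fits.csv."""
    alpha_in = float(config.stats.get("alpha_in", 0.05))
    alpha_out = float(config.stats.get("alpha_out", 0.10))
    max_lag_hours = float(config.stats.get("max_lag_hours", 12.0))
    primary_cutoff = config.cutoff_days[0]

    radius_daily = _read_daily_radius(out_dir)
    clim_daily = pd.read_csv(out_dir / "daily_climate.csv", na_values=["NA"],
                             parse_dates=["date"]).set_index("date")
    residuals = pd.read_csv(out_dir / "residuals.csv", na_values=["NA"],
                            parse_dates=["date"])

    # residual coupling (growing season, primary cutoff, tree-mean series)
    res = residuals[residuals["cutoff_days"] == primary_cutoff]
    rx = res[res["position"] == "xylem"].set_index("date")["residual_um"]
    rb = res[res["position"] == "innerbark"].set_index("date")["residual_um"]
    joined = pd.concat([rx.rename("x"), rb.rename("b")], axis=1)
    joined = joined[growing_season_mask(joined.index)]
    residual_coupling = spearman(joined["x"], joined["b"])

    # Table 2: correlations on the tree-mean xylem metrics
    xyl = radius_daily[(radius_daily["tree_id"] == "mean")
                       & (radius_daily["position"] == "xylem")].set_index("date")
    season = growing_season_mask(xyl.index)
    corr_table = correlation_table(xyl, clim_daily, season)

    # Table 3: stepwise models per response over the full environmental pool
    merged = xyl.join(clim_daily, how="inner")
    merged = merged[growing_season_mask(merged.index)]
    models = {}
    for label, col in RESPONSES.items():
        models[label] = stepwise_regression(
            merged[col], merged[ENV_VARIABLES], alpha_in, alpha_out
        )

    # amplitude fits (log vs linear) and per-variable correlations
    amp_fit = fit_log_amplitude(merged["amplitude"], merged["vpd_max"])
    amp_corr = amplitude_environment_correlations(
        merged["amplitude"], clim_daily
    )

    # lag from the 30-min tree-mean traces
    traces = read_dendro_csv(out_dir / "corrected.csv")
    mean_traces = {t.position: t for t in traces if t.tree_id == "mean"}
    lag = estimate_lag(
        mean_traces["xylem"].radius,
        mean_traces["innerbark"].radius,
        max_lag_hours=max_lag_hours,
    )

    report = CouplingReport(
        residual_coupling=residual_coupling,
        correlation_table=corr_table,
        stepwise_models=models,
        amplitude_fit=amp_fit,
        amplitude_correlations=amp_corr,
        lag_hours=lag,
    )
    report.to_json(out_dir / "coupling_report.json")
    corr_table.to_csv(out_dir / "table2.csv", index=False, float_format="%.6f")
    t3 = []
    for label, m in models.items():
        row = {"response": label, "adj_r2": m.adj_r2, "f_value": m.f_value,
               "df_model": m.df_model, "df_resid": m.df_resid, "n": m.n}
        for k, v in m.coefficients.items():
            row[f"coef_{k}"] = v
            row[f"se_{k}"] = m.std_errors[k]
        t3.append(row)
    pd.DataFrame(t3).to_csv(out_dir / "table3.csv", index=False, float_format="%.6f")
    fig6 = amp_corr.copy()
    fig6.to_csv(out_dir / "fig6_fits.csv", index=False, float_format="%.6f")
    logger.info("couple: residual rho=%.3f, lag=%.2f h", residual_coupling.rho, lag)
    return report


STAGES = ("simulate", "preprocess", "daily", "detrend", "couple")


def run_pipeline(config: RunConfig) -> CouplingReport:
    """Run every stage in order and write manifest.json.

    With a ``simulate`` block the raw data are generated first; with
    ``inputs`` the simulate stage is skipped.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None:
        stage_simulate(config, out_dir)
    stage_preprocess(config, out_dir)
    stage_daily(config, out_dir)
    stage_detrend(config, out_dir)
    report = stage_couple(config, out_dir)

    radius_daily = _read_daily_radius(out_dir)
    mean_xyl = radius_daily[(radius_daily["tree_id"] == "mean")
                            & (radius_daily["position"] == "xylem")]
    config_echo = dataclasses.asdict(config)
    config_echo.pop("out_dir", None)  # path-independent bundles stay comparable
    manifest = {
        "config": config_echo,
        "version": __version__,
        "seed": config.seed,
        "row_counts": {
            "daily_radius": int(len(radius_daily)),
            "mean_xylem_days": int(len(mean_xyl)),
            "mean_xylem_valid_days": int(mean_xyl["daily_mean"].notna().sum()),
            "coverage_dropped_days": int(mean_xyl["daily_mean"].isna().sum()),
        },
        "residual_coupling_rho": report.residual_coupling.rho,
        "lag_hours": report.lag_hours,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report
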