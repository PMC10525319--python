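import numpy as np
import pandas as pd
import pytest

from stemflux import (
    HydraulicParams,
    WeatherConfig,
    default_simulation_config,
    generate_weather,
    run_pipeline,
    simulate_stem,
)


@pytest.fixture(scope="session")
def climate_90():
    """90 growing-season days of default weather."""
    return generate_weather(WeatherConfig(n_days=90, seed=3))


@pytest.fixture(scope="session")
def climate_120():
    return generate_weather(WeatherConfig(n_days=120, seed=3))


@pytest.fixture(scope="session")
def clean_params():
    """No noise, no gaps; thermal artifacts at their default coefficients."""
    return HydraulicParams(noise_sd=0.0, gap_fraction=0.0)


@pytest.fixture(scope="session")
def sim_clean(climate_120, clean_params):
    """Noiseless gapless simulation (overbark, xylem, truth)."""
    return simulate_stem(climate_120, clean_params)


@pytest.fixture(scope="session")
def pipeline_dir(tmp_path_factory):
    """Full default two-season pipeline run (4 noisy trees), seed 1."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = default_simulation_config(seed=1, out_dir=str(out))
    report = run_pipeline(cfg)
    return out, report


def make_trace_series(values, start="2019-06-01"):
    idx = pd.date_range(start, periods=len(values), freq="30min")
    return pd.Series(np.asarray(values, dtype=float), index=idx)
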