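"""Preprocessing of raw records: VPD derivation, thermal-expansion
correction, inner-bark decomposition, and tree averaging.

The vapour pressure deficit is derived with the Magnus form of the
saturation vapour pressure curve,

    e_s(T) = 0.6108 · exp(17.27 T / (T + 237.3))   [kPa, T in °C]
    VPD    = e_s(T) · (1 − RH/100)

which agrees with other common parameterisations to well under 1 % over
0–40 °C.

Thermal correction removes the apparent radius change caused by expansion
of the sensor hardware: a warmer screw and sensor body inflate the raw
reading, so the artifact is *subtracted*.  The over-bark sensor carries the
sensor-body coefficient (0.2 µm °C⁻¹); the on-xylem sensor additionally
carries the steel screw, lumped into a single 1.08 µm °C⁻¹ coefficient
taken as a given constant.  Only variations matter downstream, so the
reference temperature merely fixes an additive offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConfigurationError,
    IdentityError,
    StateError,
    ValidationError,
)
from .traces import ClimateTrace, SensorTrace, require_aligned

#: Magnus constants (kPa, dimensionless, °C).
MAGNUS_A = 0.6108
MAGNUS_B = 17.27
MAGNUS_C = 237.3

#: Material constants recorded for documentation only; the lumped per-sensor
#: coefficients below are what the correction actually uses.
STEEL_EXPANSION_PER_C = 13.9e-6
MOIST_WOOD_EXPANSION_PER_C = 7.9e-6
SENSOR_EXPANSION_UM_PER_C = 0.2


@dataclass
class PreprocessConfig:
    """Thermal-correction settings.

    ``coeff_bark`` applies to the over-bark sensor (sensor body only) and
    ``coeff_xylem`` to the on-xylem sensor (sensor body + steel screw,
    lumped).  ``reference_temperature`` is either ``first_observation`` or
    ``fixed_value`` (then ``reference_value`` is used).
    """

    coeff_bark: float = 0.2
    coeff_xylem: float = 1.08
    reference_temperature: str = "first_observation"
    reference_value: float = 0.0

    def __post_init__(self) -> None:
        if self.coeff_bark < 0 or self.coeff_xylem < 0:
            raise ConfigurationError("thermal coefficients must be >= 0")
        if self.reference_temperature not in ("first_observation", "fixed_value"):
            raise ConfigurationError(
                "reference_temperature must be 'first_observation' or 'fixed_value'"
            )


def saturation_vapour_pressure(t_air):
    """Saturation vapour pressure e_s (kPa) for air temperature in °C."""
    t = np.asarray(t_air, dtype=float)
    return MAGNUS_A * np.exp(MAGNUS_B * t / (t + MAGNUS_C))


def compute_vpd(t_air, rh):
    """Vapour pressure deficit (kPa) from 30-min T (°C) and RH (%).

    Elementwise Magnus evaluation; exactly zero at RH = 100.  RH outside
    [0, 100] raises :class:`ValidationError` listing offending timestamps.
    """
    t = np.asarray(t_air, dtype=float)
    r = np.asarray(rh, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (r < 0) | (r > 100)
    if bad.any():
        if isinstance(rh, pd.Series):
            stamps = list(rh.index[bad][:5])
            raise ValidationError(f"RH outside [0, 100] at timestamps {stamps}")
        raise ValidationError(f"RH outside [0, 100] at {int(bad.sum())} positions")
    if (t <= -MAGNUS_C).any():
        raise ValidationError("air temperature below the Magnus validity range")
    vpd = saturation_vapour_pressure(t) * (1.0 - r / 100.0)
    vpd = np.where(np.isnan(vpd), np.nan, np.maximum(vpd, 0.0))
    if isinstance(t_air, pd.Series):
        return pd.Series(vpd, index=t_air.index, name="vpd_kpa")
    return vpd


def ensure_vpd(climate: ClimateTrace) -> ClimateTrace:
    """Return a climate trace with the derived ``vpd_kpa`` column present."""
    if "vpd_kpa" in climate.data.columns:
        return climate
    data = climate.data.copy()
    data["vpd_kpa"] = compute_vpd(climate.t_air, climate.rh)
    return ClimateTrace(data)


def thermal_correct(
    trace: SensorTrace, t_air: pd.Series, config: PreprocessConfig | None = None
) -> SensorTrace:
    """Remove the thermal-expansion artifact from a raw sensor trace.

    corrected = raw − coeff · (T − T_ref), with the coefficient chosen by
    sensor position.  Missing radii stay missing; records with missing T
    cannot be corrected and become missing too.
    """
    config = config or PreprocessConfig()
    if trace.corrected:
        raise StateError(
            f"{trace.tree_id}/{trace.position} already thermally corrected"
        )
    if trace.position == "innerbark":
        raise StateError("correct over-bark and xylem traces before decomposition")
    if not isinstance(t_air.index, pd.DatetimeIndex) or not t_air.index.equals(trace.index):
        raise AlignmentError("temperature series is not aligned to the trace grid")
    coeff = config.coeff_bark if trace.position == "overbark" else config.coeff_xylem
    if config.reference_temperature == "first_observation":
        valid = t_air.dropna()
        if valid.empty:
            raise ValidationError("temperature series has no valid observations")
        t_ref = float(valid.iloc[0])
    else:
        t_ref = float(config.reference_value)
    corrected = trace.radius - coeff * (t_air - t_ref)
    return trace.with_radius(corrected, corrected=True)


def decompose_inner_bark(overbark: SensorTrace, xylem: SensorTrace) -> SensorTrace:
    """Derive the inner-bark series as over-bark minus on-xylem radius.

    The inner bark (living phloem, cambial zone, parenchyma) is what remains
    of the whole-stem radius once the xylem contribution is removed; the
    result is missing wherever either input is missing.
    """
    if overbark.tree_id != xylem.tree_id:
        raise IdentityError(
            f"tree mismatch: {overbark.tree_id!r} vs {xylem.tree_id!r}"
        )
    if overbark.position != "overbark" or xylem.position != "xylem":
        raise ValidationError("expected an over-bark and an on-xylem trace")
    if not (overbark.corrected and xylem.corrected):
        raise StateError("both traces must be thermally corrected before decomposition")
    require_aligned(overbark.index, xylem.index, "decompose_inner_bark")
    inner = overbark.radius - xylem.radius
    return SensorTrace(overbark.tree_id, "innerbark", inner, corrected=True)


@dataclass
class AggregatedTrace:
    """Per-timestamp mean over trees with its standard error and count."""

    mean: SensorTrace
    se: pd.Series
    n: pd.Series


def aggregate_trees(traces: list[SensorTrace]) -> AggregatedTrace:
    """Average re-zeroed traces over trees, with per-timestamp SE.

    Each trace is first re-zeroed to its first valid reading so that trees
    with different absolute offsets contribute only their variation.  The
    standard error is the sample SD over trees divided by √n, using the
    trees with data present at each timestamp.
    """
    if not traces:
        raise ValidationError("aggregate_trees: empty input")
    positions = {t.position for t in traces}
    if len(positions) != 1:
        raise ValidationError(f"aggregate_trees: mixed positions {sorted(positions)}")
    if len(traces) < 2:
        raise ValidationError("aggregate_trees: need at least 2 traces")
    index = traces[0].index
    for t in traces[1:]:
        require_aligned(index, t.index, "aggregate_trees")
    cols = {}
    for t in traces:
        valid = t.radius.dropna()
        if valid.empty:
            raise ValidationError(f"aggregate_trees: trace {t.tree_id} has no data")
        cols[t.tree_id] = t.radius - float(valid.iloc[0])
    wide = pd.DataFrame(cols)
    n = wide.count(axis=1)
    mean = wide.mean(axis=1)
    se = wide.std(axis=1, ddof=1) / np.sqrt(n.where(n > 0))
    mean_trace = SensorTrace(
        "mean", traces[0].position, mean, corrected=traces[0].corrected
    )
    return AggregatedTrace(mean_trace, se.rename("se_um"), n.rename("n_trees"))
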