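"""In-memory containers for 30-minute dendrometer and microclimate records.

Both containers keep their data on a strictly regular 30-minute
:class:`pandas.DatetimeIndex` (local standard time, no DST shifts).  Gaps are
represented as NaN values on the grid, never as missing rows, which makes
alignment between sensors trivial and keeps every downstream operation a
plain vectorised pandas expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError

STEP = pd.Timedelta(minutes=30)
RECORDS_PER_DAY = 48

#: Valid dendrometer mounting positions.  ``overbark`` is the sensor on the
#: living phloem surface, ``xylem`` the sensor bearing on the sapwood via an
#: inserted screw, and ``innerbark`` the derived difference of the two.
POSITIONS = ("overbark", "xylem", "innerbark")

CLIMATE_COLUMNS = ("t_air_c", "rh_pct", "sr_wm2", "p_mm", "swc_volpct")


def _check_grid(index: pd.DatetimeIndex, what: str) -> None:
    if not isinstance(index, pd.DatetimeIndex):
        raise ValidationError(f"{what}: index must be a DatetimeIndex")
    if len(index) == 0:
        raise ValidationError(f"{what}: empty series")
    if len(index) > 1:
        deltas = np.unique(np.diff(index.asi8))
        if deltas.size != 1 or deltas[0] != STEP.value:
            raise ValidationError(
                f"{what}: timestamps must be strictly increasing with exact "
                f"30-min spacing (gaps are NaN values, not missing rows)"
            )


@dataclass
class SensorTrace:
    """One point-dendrometer radius series (µm) for one tree and position.

    Parameters
    ----------
    tree_id
        Label of the tree the sensor is mounted on.
    position
        One of ``overbark``, ``xylem`` or ``innerbark``.
    radius
        Radius variation in µm on a regular 30-min grid; NaN marks missing
        records.
    corrected
        Whether the thermal-expansion correction has been applied.
    """

    tree_id: str
    position: str
    radius: pd.Series
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValidationError(
                f"position must be one of {POSITIONS}, got {self.position!r}"
            )
        _check_grid(self.radius.index, f"SensorTrace({self.tree_id}/{self.position})")
        values = np.asarray(self.radius, dtype=float)
        if np.isinf(values).any():
            raise ValidationError("radius values must be finite where present")
        self.radius = pd.Series(values, index=self.radius.index, name="radius_um")

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.radius.index

    def with_radius(self, radius: pd.Series, *, corrected: bool | None = None) -> "SensorTrace":
        """Return a copy with a new radius series (same identity)."""
        out = replace(self, radius=radius)
        if corrected is not None:
            out.corrected = corrected
        return out


@dataclass
class ClimateTrace:
    """30-minute microclimate record.

    Columns: air temperature ``t_air_c`` (°C), relative humidity ``rh_pct``
    (%), solar radiation ``sr_wm2`` (W m⁻²), precipitation ``p_mm`` (mm per
    30-min interval) and volumetric soil water content ``swc_volpct``
    (vol %).  A derived ``vpd_kpa`` column may be present.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CLIMATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"climate table missing columns: {missing}")
        _check_grid(self.data.index, "ClimateTrace")
        rh = self.data["rh_pct"]
        bad = rh[(rh < 0) | (rh > 100)].dropna()
        if len(bad):
            raise ValidationError(
                f"RH outside [0, 100] at {len(bad)} timestamps, first: {bad.index[0]}"
            )
        p = self.data["p_mm"]
        if (p.dropna() < 0).any():
            raise ValidationError("precipitation must be non-negative")
        if "vpd_kpa" in self.data.columns and (self.data["vpd_kpa"].dropna() < 0).any():
            raise ValidationError("VPD must be non-negative")

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def t_air(self) -> pd.Series:
        return self.data["t_air_c"]

    @property
    def rh(self) -> pd.Series:
        return self.data["rh_pct"]

    @property
    def sr(self) -> pd.Series:
        return self.data["sr_wm2"]

    @property
    def p(self) -> pd.Series:
        return self.data["p_mm"]

    @property
    def swc(self) -> pd.Series:
        return self.data["swc_volpct"]

    @property
    def vpd(self) -> pd.Series:
        if "vpd_kpa" not in self.data.columns:
            raise ValidationError("VPD not derived yet; call preprocess.ensure_vpd")
        return self.data["vpd_kpa"]

    def has_gaps(self) -> bool:
        return bool(self.data[list(CLIMATE_COLUMNS)].isna().any().any())


def require_aligned(a: pd.Index, b: pd.Index, what: str) -> None:
    """Raise :class:`AlignmentError` unless two indexes are identical."""
    if not a.equals(b):
        raise AlignmentError(f"{what}: timestamp grids differ (exact join, no interpolation)")


# ---------------------------------------------------------------------------
# CSV interchange (long dendrometer format; wide climate format)
# ---------------------------------------------------------------------------

def _full_grid(index: pd.DatetimeIndex) -> pd.DatetimeIndex:
    return pd.date_range(index.min(), index.max(), freq="30min")


def read_dendro_csv(path) -> list[SensorTrace]:
    """Read a long-format dendrometer CSV.

    Columns: ``timestamp`` (ISO 8601), ``tree_id``, ``position``
    (overbark|xylem), ``radius_um``.  Missing values empty or ``NA``.  Each
    tree/position series is re-indexed onto the complete 30-min grid spanning
    its own range so that gaps become NaN values.
    """
    df = pd.read_csv(path, na_values=["NA"], parse_dates=["timestamp"])
    required = {"timestamp", "tree_id", "position", "radius_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"dendrometer CSV missing columns: {sorted(missing)}")
    traces = []
    for (tree, pos), grp in df.groupby(["tree_id", "position"], sort=True):
        if grp["timestamp"].duplicated().any():
            raise ValidationError(f"duplicate timestamps for {tree}/{pos}")
        series = grp.set_index("timestamp")["radius_um"].sort_index()
        series = series.reindex(_full_grid(series.index))
        corrected = False
        if "corrected" in grp.columns:
            corrected = bool(grp["corrected"].iloc[0])
        traces.append(SensorTrace(str(tree), str(pos), series, corrected=corrected))
    return traces


def write_dendro_csv(traces: list[SensorTrace], path) -> None:
    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": t.index,
                    "tree_id": t.tree_id,
                    "position": t.position,
                    "radius_um": t.radius.to_numpy(),
                    "corrected": t.corrected,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, na_rep="NA", float_format="%.6f")


def read_climate_csv(path) -> ClimateTrace:
    """Read a wide climate CSV (``timestamp, t_air_c, rh_pct, sr_wm2, p_mm,
    swc_volpct`` plus optional ``vpd_kpa``)."""
    df = pd.read_csv(path, na_values=["NA"], parse_dates=["timestamp"])
    df = df.set_index("timestamp").sort_index()
    df = df.reindex(_full_grid(df.index))
    return ClimateTrace(df)


def write_climate_csv(climate: ClimateTrace, path) -> None:
    out = climate.data.copy()
    out.insert(0, "timestamp", out.index)
    out.to_csv(path, index=False, na_rep="NA", float_format="%.6f")
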