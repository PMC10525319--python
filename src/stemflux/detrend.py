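"""FFT low-pass smoothing of daily series and residual extraction.

The seasonal trend of a daily radius series is estimated with a hard
spectral low-pass: the mean is removed, the series is mirror-padded to
twice its length (which makes the padded signal continuous at both ends
and the filter symmetric under time reversal), every Fourier component
with period shorter than ``cutoff_days`` is zeroed, and the inverse
transform is truncated back to the original length.  Residuals (original −
smooth) are then free of the seasonal trend; with a 10-day cutoff they
carry the synoptic-scale variation, with a 25-day cutoff only sub-monthly
variation is removed.

Internal gaps of up to 10 % are linearly bridged for the transform only
and re-masked on output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataQualityError, ParameterError, ValidationError

MAX_GAP_FRACTION = 0.10


@dataclass
class DetrendedSeries:
    """A daily series split into a low-frequency smooth and residuals."""

    original: pd.Series
    smooth: pd.Series
    residual: pd.Series
    cutoff_days: int


def _validate_daily(series: pd.Series) -> pd.Series:
    if not isinstance(series.index, pd.DatetimeIndex):
        raise ValidationError("fft_lowpass expects a DatetimeIndex daily series")
    full = pd.date_range(series.index.min(), series.index.max(), freq="D")
    series = series.reindex(full)
    return series


def fft_lowpass(series: pd.Series, cutoff_days: int) -> pd.Series:
    """Hard spectral low-pass of a daily series.

    Components with period < ``cutoff_days`` (frequency > 1/cutoff_days per
    day) are zeroed; the component at exactly the cutoff period is kept.
    Output is aligned to the input dates and masked wherever the input was
    missing.
    """
    series = _validate_daily(series)
    n = len(series)
    if cutoff_days < 2 or cutoff_days >= n:
        raise ParameterError(
            f"cutoff_days must be in [2, series length); got {cutoff_days} for n={n}"
        )
    x = series.to_numpy(dtype=float)
    mask = np.isnan(x)
    if mask.all():
        raise DataQualityError("series has no valid observations")
    if mask.mean() > MAX_GAP_FRACTION:
        raise DataQualityError(
            f"gap fraction {mask.mean():.1%} exceeds {MAX_GAP_FRACTION:.0%}"
        )
    filled = pd.Series(x).interpolate(limit_direction="both").to_numpy()
    mu = filled.mean()
    y = filled - mu
    padded = np.concatenate([y, y[::-1]])
    spectrum = np.fft.rfft(padded)
    freqs = np.fft.rfftfreq(2 * n, d=1.0)
    spectrum[freqs > 1.0 / cutoff_days + 1e-12] = 0.0
    smooth = np.fft.irfft(spectrum, 2 * n)[:n] + mu
    smooth[mask] = np.nan
    return pd.Series(smooth, index=series.index, name="smooth_um")


def residualize(series: pd.Series, cutoff_days: int) -> DetrendedSeries:
    """Split a daily series into smooth trend and residuals.

    residual + smooth reconstructs the original wherever it is present.
    """
    aligned = _validate_daily(series)
    smooth = fft_lowpass(aligned, cutoff_days)
    residual = aligned - smooth
    return DetrendedSeries(
        original=aligned.rename("original_um"),
        smooth=smooth,
        residual=residual.rename("residual_um"),
        cutoff_days=cutoff_days,
    )
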