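"""Median-frequency (MDF) computation and fatigue trend detection.

MDF is the frequency splitting the in-band power of a window's periodogram
into equal halves; it drifts downward as a muscle fatigues.  The spectrum
estimator is a single-taper (Hann) periodogram per analysis window,
restricted to the 15-450 Hz analysis band before bisection.  MDF windows
default to 1 s -- longer than the 200 ms envelope window -- because a 200 ms
window only gives 5 Hz bins, too coarse near typical MDF values of
80-120 Hz.

A window with no power returns NaN (the "no-power" sentinel) and is
excluded from trend fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal, stats

from . import _intervals
from .features import frame_count
from .io_formats import ChannelMeta, Recording

#: analysis band used to bound the cumulative-power bisection, Hz
DEFAULT_BAND = (15.0, 450.0)

#: sentinel for windows with no spectral power
NO_POWER = np.nan


@dataclass
class MdfSeries:
    """Per-channel median-frequency track on a window-center time grid."""

    times: np.ndarray
    mdf_hz: np.ndarray  # (n_channels, n_windows); NaN = no power
    spectrum_band: tuple[float, float]
    channels: list[ChannelMeta]


@dataclass(frozen=True)
class FatigueTrend:
    slope_hz_per_s: float
    intercept_hz: float
    p_value: float

    @property
    def fatigue_flagged(self) -> bool:
        return self.slope_hz_per_s < 0 and self.p_value < 0.05


def median_frequency(window_samples: np.ndarray, fs: float,
                     band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Median frequency of one window via Hann-periodogram bisection.

    Returns the frequency where cumulative in-band power reaches half the
    total, linearly interpolated between bins.  When the half-power level
    falls on a plateau of the cumulative spectrum (e.g. two equal spectral
    lines), the midpoint of the plateau is returned, so an equal-power
    mixture of 50 and 150 Hz tones yields ~100 Hz.
    """
    x = np.asarray(window_samples, dtype=float)
    if x.size < 16:
        raise ValueError("median_frequency needs at least 16 samples")
    freqs, power = signal.periodogram(x, fs=fs, window="hann", detrend=False)
    lo, hi = band
    keep = (freqs >= lo) & (freqs <= min(hi, fs / 2.0))
    freqs, power = freqs[keep], power[keep]
    total = power.sum()
    if not np.isfinite(total) or total <= 0:
        return NO_POWER
    cum = np.cumsum(power)
    half = 0.5 * total
    tol = 1e-9 * total

    k = int(np.searchsorted(cum, half - tol, side="left"))
    k = min(k, len(cum) - 1)
    c_prev = cum[k - 1] if k > 0 else 0.0
    f_prev = freqs[k - 1] if k > 0 else max(0.0, freqs[0] - (freqs[1] - freqs[0]))
    dc = cum[k] - c_prev
    frac = float(np.clip((half - c_prev) / dc, 0.0, 1.0)) if dc > 0 else 1.0
    f_low = f_prev + frac * (freqs[k] - f_prev)

    m = int(np.searchsorted(cum, half + tol, side="right"))
    if m > k and m < len(freqs):
        # plateau: negligible power between bins k and m
        return 0.5 * (f_low + freqs[m])
    return float(f_low)


def mdf_series(rec: Recording, window_s: float = 1.0, step_s: float = 0.05,
               band: tuple[float, float] = DEFAULT_BAND) -> MdfSeries:
    """Windowed MDF per channel; windowing mirrors the envelope framing."""
    fs = rec.sample_rate
    window = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if window < 16:
        raise ValueError("MDF window must cover at least 16 samples")
    n_win = frame_count(rec.n_samples, window, step)
    mdf = np.full((rec.n_channels, n_win), NO_POWER)
    for ci in range(rec.n_channels):
        for w in range(n_win):
            seg = rec.data[ci, w * step: w * step + window]
            mdf[ci, w] = median_frequency(seg, fs, band)
    times = rec.t0 + (np.arange(n_win) * step + window / 2.0) / fs
    return MdfSeries(times=times, mdf_hz=mdf, spectrum_band=band,
                     channels=list(rec.channels))


def fatigue_trend(mdf: MdfSeries, interval: tuple[float, float],
                  channel: int = 0) -> FatigueTrend:
    """OLS line through (time, MDF) inside ``interval`` with a slope test.

    Fatigue is flagged when the slope is negative with p < 0.05.  Windows
    carrying the no-power sentinel are excluded; at least 5 valid windows
    are required.
    """
    lo, hi = interval
    mask = (mdf.times >= lo) & (mdf.times <= hi) & np.isfinite(mdf.mdf_hz[channel])
    if mask.sum() < 5:
        raise ValueError(
            f"need >= 5 valid MDF windows in ({lo}, {hi}) s; got {int(mask.sum())}"
        )
    x = mdf.times[mask]
    y = mdf.mdf_hz[channel, mask]
    if np.ptp(y) == 0:
        # perfectly flat track: zero slope, nothing to flag
        return FatigueTrend(slope_hz_per_s=0.0, intercept_hz=float(y[0]), p_value=1.0)
    fit = stats.linregress(x, y)
    return FatigueTrend(slope_hz_per_s=float(fit.slope),
                        intercept_hz=float(fit.intercept),
                        p_value=float(fit.pvalue))
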