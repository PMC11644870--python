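"""Raw-signal conditioning: the 15-450 Hz bandpass stage and an optional
powerline notch.

The bandpass is a Butterworth design (default order 4) applied either
forward-backward (``zero_phase``, no group delay; the offline default) or
forward only (``causal``, for simulated real-time replay).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal

from .io_formats import Recording


class FilterConfigError(ValueError):
    """Filter parameters incompatible with the recording (e.g. Nyquist)."""


@dataclass(frozen=True)
class FilterSpec:
    low_hz: float = 15.0
    high_hz: float = 450.0
    order: int = 4
    mode: str = "zero_phase"  # or "causal"
    notch_hz: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 2 or self.order % 2:
            raise ValueError("order must be a positive even integer")
        if self.mode not in ("zero_phase", "causal"):
            raise ValueError("mode must be 'zero_phase' or 'causal'")


def _bandpass_sos(spec: FilterSpec, fs: float):
    nyq = fs / 2.0
    if spec.high_hz >= nyq:
        raise FilterConfigError(
            f"bandpass upper edge {spec.high_hz} Hz requires sample_rate > "
            f"{2 * spec.high_hz} Hz (Nyquist violation at fs={fs} Hz)"
        )
    return signal.butter(spec.order, [spec.low_hz, spec.high_hz],
                         btype="bandpass", fs=fs, output="sos")


def _apply(sos, data: np.ndarray, mode: str) -> np.ndarray:
    if mode == "zero_phase":
        return signal.sosfiltfilt(sos, data, axis=-1)
    return signal.sosfilt(sos, data, axis=-1)


def bandpass(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Apply the analysis bandpass per channel; shape and clock unchanged."""
    sos = _bandpass_sos(spec, rec.sample_rate)
    out = _apply(sos, rec.data, spec.mode)
    filtered = Recording(sample_rate=rec.sample_rate, channels=list(rec.channels),
                         data=out, t0=rec.t0)
    if spec.notch_hz is not None:
        filtered = notch(filtered, notch_hz=spec.notch_hz, mode=spec.mode)
    return filtered


def notch(rec: Recording, notch_hz: float = 60.0, q: float = 30.0,
          mode: str = "zero_phase") -> Recording:
    """Attenuate a narrow powerline band around ``notch_hz``."""
    nyq = rec.sample_rate / 2.0
    if not (0 < notch_hz < nyq):
        raise FilterConfigError(f"notch frequency {notch_hz} Hz is not below Nyquist {nyq} Hz")
    b, a = signal.iirnotch(notch_hz, q, fs=rec.sample_rate)
    if mode == "zero_phase":
        out = signal.filtfilt(b, a, rec.data, axis=-1)
    else:
        out = signal.lfilter(b, a, rec.data, axis=-1)
    return Recording(sample_rate=rec.sample_rate, channels=list(rec.channels),
                     data=out, t0=rec.t0)
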