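"""Sliding-window envelope features (RMS, MAV, peak-to-peak) and the
threshold-normalized training-load summary.

Windows are 200 ms by default with a 10 ms step (the fine end of the
10-50 ms range; 50 ms suits constrained hardware).  The first window starts
at ``t0``; window-center times are reported; a trailing partial window is
dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from . import _intervals
from .io_formats import AnnotationTrack, ChannelMeta, FormatError, Recording
from .preprocess import FilterSpec

#: step-size range supported by the acquisition chain, seconds
STEP_RANGE_S = (0.010, 0.050)


class WindowConfigError(ValueError):
    """Window/step configuration that cannot tile the recording."""


@dataclass
class EnvelopeSeries:
    """Per-channel windowed envelope features on a common time grid.

    ``rms_mv``, ``mav_mv`` and ``ptp_mv`` have shape ``(n_channels, n_windows)``
    and align with ``times`` (window centers, seconds).
    """

    window_s: float
    step_s: float
    times: np.ndarray
    channels: list[ChannelMeta]
    rms_mv: np.ndarray
    mav_mv: np.ndarray
    ptp_mv: np.ndarray
    filter_spec: Optional[FilterSpec] = None

    @property
    def n_windows(self) -> int:
        return len(self.times)

    def channel_index(self, label: str) -> int:
        for i, c in enumerate(self.channels):
            if c.label == label:
                return i
        raise KeyError(f"no channel labelled {label!r}")


def frame_count(n_samples: int, window: int, step: int) -> int:
    """Number of full windows of ``window`` samples advancing by ``step``."""
    if n_samples < window:
        return 0
    return (n_samples - window) // step + 1


def sliding_features(rec: Recording, window_s: float = 0.200,
                     step_s: float = 0.010, *, allow_any_step: bool = False,
                     filter_spec: Optional[FilterSpec] = None) -> EnvelopeSeries:
    """Compute RMS/MAV/PTP for every full sliding window of each channel."""
    fs = rec.sample_rate
    window = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if window < 2:
        raise WindowConfigError(f"window of {window_s} s is under 2 samples at fs={fs}")
    if step < 1:
        raise WindowConfigError(f"step of {step_s} s is under 1 sample at fs={fs}")
    if step > window:
        raise WindowConfigError(
            f"step {step_s} s exceeds window {window_s} s; windows must tile without gaps"
        )
    if not allow_any_step and not (STEP_RANGE_S[0] - 1e-12 <= step_s <= STEP_RANGE_S[1] + 1e-12):
        raise WindowConfigError(
            f"step {step_s} s outside the supported {STEP_RANGE_S} s range "
            "(pass allow_any_step=True to override)"
        )
    n = rec.n_samples
    if n < window:
        warnings.warn("recording shorter than one window; returning empty series")
        empty = np.zeros((rec.n_channels, 0))
        return EnvelopeSeries(window_s=window_s, step_s=step_s,
                              times=np.zeros(0), channels=list(rec.channels),
                              rms_mv=empty, mav_mv=empty.copy(), ptp_mv=empty.copy(),
                              filter_spec=filter_spec)
    views = sliding_window_view(rec.data, window, axis=1)[:, ::step, :]
    rms = np.sqrt(np.mean(views ** 2, axis=-1))
    mav = np.mean(np.abs(views), axis=-1)
    ptp = np.max(views, axis=-1) - np.min(views, axis=-1)
    n_win = rms.shape[1]
    starts = np.arange(n_win) * step
    times = rec.t0 + (starts + window / 2.0) / fs
    return EnvelopeSeries(window_s=window_s, step_s=step / fs, times=times,
                          channels=list(rec.channels), rms_mv=rms, mav_mv=mav,
                          ptp_mv=ptp, filter_spec=filter_spec)


def training_load(env: EnvelopeSeries, isometric_threshold_mv: float,
                  track: AnnotationTrack,
                  active_kinds: Sequence[str] = ("set", "walk")) -> np.ndarray:
    """Threshold-normalized activity-seconds per channel.

    ``load = step_s * sum(rms / threshold)`` over windows whose start times
    fall inside the annotated active (set or walk) intervals, so a
    contraction held exactly at the isometric threshold for T seconds
    scores T.
    """
    if isometric_threshold_mv <= 0:
        raise ValueError("isometric_threshold_mv must be > 0")
    session_end = float(env.times[-1] + env.window_s) if env.n_windows else None
    intervals: list[tuple[float, float]] = []
    for kind in active_kinds:
        intervals.extend(track.intervals(kind, session_end=session_end))
    if not intervals:
        warnings.warn("no active (set/walk) intervals annotated; training load is 0")
        return np.zeros(len(env.channels))
    starts = env.times - env.window_s / 2.0
    mask = _intervals.centers_inside(starts, intervals)
    return env.step_s * env.rms_mv[:, mask].sum(axis=1) / isometric_threshold_mv


def write_envelope(env: EnvelopeSeries, path) -> None:
    """Write an EnvelopeSeries CSV: ``time_s,<label>_rms_mv,<label>_mav_mv,...``."""
    cols: dict[str, np.ndarray] = {"time_s": env.times}
    for i, ch in enumerate(env.channels):
        cols[f"{ch.label}_rms_mv"] = env.rms_mv[i]
        cols[f"{ch.label}_mav_mv"] = env.mav_mv[i]
        cols[f"{ch.label}_ptp_mv"] = env.ptp_mv[i]
    with open(path, "w", encoding="utf-8", newline="\n") as f:
        f.write(f"# window_s={env.window_s!r} step_s={env.step_s!r}\n")
        pd.DataFrame(cols).to_csv(f, index=False, float_format="%.17g",
                                  lineterminator="\n")


def read_envelope(path) -> EnvelopeSeries:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as f:
        meta = f.readline().strip()
        parts = dict(p.split("=") for p in meta.lstrip("# ").split())
        try:
            window_s = float(parts["window_s"])
            step_s = float(parts["step_s"])
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: bad envelope metadata line {meta!r}") from exc
        df = pd.read_csv(f, float_precision="round_trip")
    labels: list[str] = []
    for col in df.columns[1:]:
        if col.endswith("_rms_mv"):
            labels.append(col[: -len("_rms_mv")])
    channels = [ChannelMeta.from_label(lbl) for lbl in labels]
    rms = np.vstack([df[f"{l}_rms_mv"].to_numpy(float) for l in labels])
    mav = np.vstack([df[f"{l}_mav_mv"].to_numpy(float) for l in labels])
    ptp = np.vstack([df[f"{l}_ptp_mv"].to_numpy(float) for l in labels])
    return EnvelopeSeries(window_s=window_s, step_s=step_s,
                          times=df["time_s"].to_numpy(float), channels=channels,
                          rms_mv=rms, mav_mv=mav, ptp_mv=ptp)
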