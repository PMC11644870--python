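"""Sustained envelope-drop (FOG precursor) detection and evaluation.

The detector watches the windowed RMS envelope of each channel.  The RMS
track is first smoothed with a centered moving average spanning roughly two
gait cycles (default 2.2 s), which cancels stride-periodic burst ripple
while leaving the multi-second precursor drop intact.  A causal rolling
median over the trailing ``baseline_window_s`` (excluding windows already
inside a candidate drop, so the drop cannot drag its own baseline down)
tracks normal activity.  A candidate opens when the smoothed envelope falls
below ``drop_fraction`` of baseline and closes, with hysteresis, when it
recovers above ``drop_fraction + 0.1``.  Candidates separated by less than
``refractory_s`` are merged and only those persisting at least
``min_duration_s`` (default 3 s) are kept.

Each kept event's start is then refined by backtracking to the end of the
last stretch of normal-amplitude activity.  The in-event burst peaks set
the attenuated scale (their 90th percentile); walking backwards on a
lightly smoothed (``onset_smooth_s``) RMS track, the onset is placed just
after the last burst exceeding ``onset_margin`` (default 1.3) times that
scale -- a level between the attenuated and the normal burst-peak scales.
Because a drop beginning between two strides is unobservable until the
next (attenuated) burst, this last-normal-evidence convention is
deliberately early: by at most about one stride, and late by no more than
about one analysis window.  That is the right bias for an alerting
application.  Lead time is the gap from that start to the matched
annotated FOG onset.

Detection runs per channel; a session-level event requires co-occurring
drops on at least two thigh channels (quadriceps + hamstring), the
consistent signature; single-channel mode is available.
"""

from __future__ import annotations

import bisect
import warnings
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import _intervals
from .features import EnvelopeSeries
from .io_formats import AnnotationTrack, ChannelMeta

#: muscles whose co-occurring drops define a session-level event
THIGH_MUSCLES = frozenset({"quadriceps", "hamstring"})


@dataclass(frozen=True)
class DetectorConfig:
    drop_fraction: float = 0.5
    min_duration_s: float = 3.0
    baseline_window_s: float = 10.0
    baseline_stat: str = "median"  # or "trimmed_mean"
    refractory_s: float = 2.0
    smooth_s: float = 2.2
    hysteresis: float = 0.1
    onset_margin: float = 1.3
    onset_smooth_s: float = 0.3
    fusion_min_channels: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.drop_fraction < 1):
            raise ValueError("drop_fraction must be in (0, 1)")
        if self.min_duration_s <= 0:
            raise ValueError("min_duration_s must be > 0")
        if self.baseline_stat not in ("median", "trimmed_mean"):
            raise ValueError("baseline_stat must be 'median' or 'trimmed_mean'")
        if not (self.drop_fraction + self.hysteresis < 1):
            raise ValueError("drop_fraction + hysteresis must stay below 1")
        if self.onset_margin <= 1:
            raise ValueError("onset_margin must exceed 1")


@dataclass(frozen=True)
class PrecursorEvent:
    """A detected sustained envelope drop, optionally matched to a FOG onset."""

    channel: Optional[ChannelMeta]
    start_s: float
    end_s: float
    baseline_mv: float
    floor_mv: float
    fold_drop: float
    matched_fog_onset_s: Optional[float] = None
    lead_s: Optional[float] = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class DetectionReport:
    events: list[PrecursorEvent]
    n_onsets: int
    n_matched: int
    sensitivity: Optional[float]
    false_alarms_per_min: float
    lead_stats: Optional[tuple[float, float, float]]  # (min, mean, max)

    def to_dict(self) -> dict:
        return {
            "events": [
                {
                    "channel": e.channel.label if e.channel else None,
                    "start_s": e.start_s,
                    "end_s": e.end_s,
                    "baseline_mv": e.baseline_mv,
                    "floor_mv": e.floor_mv,
                    "fold_drop": e.fold_drop,
                    "matched_fog_onset_s": e.matched_fog_onset_s,
                    "lead_s": e.lead_s,
                }
                for e in self.events
            ],
            "n_onsets": self.n_onsets,
            "n_matched": self.n_matched,
            "sensitivity": self.sensitivity,
            "false_alarms_per_min": self.false_alarms_per_min,
            "lead_stats": None if self.lead_stats is None else list(self.lead_stats),
        }


class _TrailingBuffer:
    """Sorted buffer of accepted (index, value) samples for rolling statistics."""

    def __init__(self) -> None:
        self._idx: deque[int] = deque()
        self._val: deque[float] = deque()
        self._sorted: list[float] = []

    def __len__(self) -> int:
        return len(self._sorted)

    def push(self, i: int, v: float) -> None:
        self._idx.append(i)
        self._val.append(v)
        bisect.insort(self._sorted, v)

    def trim(self, i_now: int, span: int) -> None:
        while self._idx and self._idx[0] <= i_now - span:
            self._idx.popleft()
            v = self._val.popleft()
            del self._sorted[bisect.bisect_left(self._sorted, v)]

    def stat(self, kind: str) -> float:
        s = self._sorted
        k = len(s)
        if kind == "median":
            return 0.5 * (s[(k - 1) // 2] + s[k // 2])
        # 20%-trimmed mean
        cut = k // 5
        core = s[cut: k - cut] or s
        return float(np.mean(core))


def smooth_envelope(values: np.ndarray, step_s: float, smooth_s: float) -> np.ndarray:
    """Centered moving average with edge-count correction; identity when the
    smoothing span does not exceed one step."""
    k = int(round(smooth_s / step_s))
    if k <= 1:
        return np.asarray(values, dtype=float)
    kernel = np.ones(k)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones(len(values)), kernel, mode="same")
    return num / den


def _scan(values: np.ndarray, step_s: float, cfg: DetectorConfig,
          active: Optional[np.ndarray] = None) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """One causal pass: rolling baseline with in-drop exclusion plus raw
    hysteresis candidate intervals ``[open, close)`` in window indices."""
    n = len(values)
    if active is None:
        active = np.ones(n, dtype=bool)
    n_base = max(1, int(round(cfg.baseline_window_s / step_s)))
    act_vals = values[active]
    seed = float(np.median(act_vals)) if act_vals.size else 0.0
    baseline = np.full(n, np.nan)
    buf = _TrailingBuffer()
    intervals: list[tuple[int, int]] = []
    in_drop = False
    open_i = 0
    b_prev = seed
    seen_active = 0
    for i in range(n):
        if not active[i]:
            if in_drop:
                intervals.append((open_i, i))
                in_drop = False
            continue
        buf.trim(i, n_base)
        if seen_active < n_base:
            b = seed  # warm-up: global active-period median
        elif len(buf):
            b = buf.stat(cfg.baseline_stat)
        else:
            b = b_prev  # drop outlasted the buffer: freeze the last baseline
        v = values[i]
        if in_drop:
            if v >= (cfg.drop_fraction + cfg.hysteresis) * b:
                intervals.append((open_i, i))
                in_drop = False
        else:
            if v < cfg.drop_fraction * b:
                in_drop = True
                open_i = i
        if not in_drop:
            buf.push(i, v)
        baseline[i] = b
        b_prev = b
        seen_active += 1
    if in_drop:
        intervals.append((open_i, n))
    return baseline, intervals


def rolling_baseline(env: EnvelopeSeries, cfg: DetectorConfig = DetectorConfig(),
                     channel: int = 0,
                     active_intervals: Optional[Sequence[tuple[float, float]]] = None
                     ) -> np.ndarray:
    """Per-window baseline estimate (NaN outside the active intervals)."""
    if env.n_windows == 0:
        return np.zeros(0)
    smoothed = smooth_envelope(env.rms_mv[channel], env.step_s, cfg.smooth_s)
    active = None
    if active_intervals is not None:
        active = _intervals.centers_inside(env.times, active_intervals)
    baseline, _ = _scan(smoothed, env.step_s, cfg, active)
    return baseline


def detect_precursors(env: EnvelopeSeries, cfg: DetectorConfig = DetectorConfig(),
                      channels: Optional[Sequence[int]] = None,
                      active_intervals: Optional[Sequence[tuple[float, float]]] = None
                      ) -> list[PrecursorEvent]:
    """Detect sustained envelope drops per channel (see module docstring)."""
    if env.n_windows == 0:
        return []
    step = env.step_s
    active = None
    if active_intervals is not None:
        active = _intervals.centers_inside(env.times, active_intervals)
    gap = max(1, int(round(cfg.refractory_s / step)))
    min_len = int(round(cfg.min_duration_s / step))
    cap = max(1, int(round(2.0 * cfg.smooth_s / step)))
    events: list[PrecursorEvent] = []
    idx = range(env.rms_mv.shape[0]) if channels is None else channels
    for ci in idx:
        raw_rms = env.rms_mv[ci]
        smoothed = smooth_envelope(raw_rms, step, cfg.smooth_s)
        mini = smooth_envelope(raw_rms, step, cfg.onset_smooth_s)
        baseline, raw = _scan(smoothed, step, cfg, active)
        merged: list[list[int]] = []
        for o, c in raw:
            if merged and o - merged[-1][1] <= gap:
                merged[-1][1] = c
            else:
                merged.append([o, c])
        for o, c in merged:
            if c - o < min_len:
                continue
            b = float(baseline[o])
            floor = float(np.mean(smoothed[o:c]))
            # backtrack to the end of the last normal-amplitude stretch:
            # the level sits above the in-drop burst-peak scale but below
            # normal burst peaks (early by <= ~one stride, never late)
            onset_level = cfg.onset_margin * float(np.percentile(raw_rms[o:c], 90))
            j = o
            while (j > 0 and o - j < cap and mini[j - 1] < onset_level
                   and (active is None or active[j - 1])):
                j -= 1
            start = float(env.times[j])
            end = float(env.times[c - 1] + step) if c >= env.n_windows else float(env.times[c])
            fold = b / floor if floor > 0 else np.inf
            events.append(PrecursorEvent(channel=env.channels[ci], start_s=start,
                                         end_s=end, baseline_mv=b, floor_mv=floor,
                                         fold_drop=fold))
    events.sort(key=lambda e: e.start_s)
    return events


def fuse_events(events: Sequence[PrecursorEvent], min_channels: int = 2,
                muscles: Optional[frozenset] = THIGH_MUSCLES) -> list[PrecursorEvent]:
    """Merge per-channel events into session-level events.

    Events overlapping in time on at least ``min_channels`` distinct channels
    (restricted to ``muscles`` when given) form one fused event spanning the
    union of the member intervals.
    """
    pool = [e for e in events
            if muscles is None or e.channel is None or e.channel.muscle in muscles]
    pool = sorted(pool, key=lambda e: e.start_s)
    fused: list[PrecursorEvent] = []
    cluster: list[PrecursorEvent] = []

    def _flush() -> None:
        chans = {e.channel.label for e in cluster if e.channel is not None}
        if len(chans) >= min_channels:
            b = float(np.mean([e.baseline_mv for e in cluster]))
            floor = float(np.mean([e.floor_mv for e in cluster]))
            fused.append(PrecursorEvent(
                channel=None,
                start_s=min(e.start_s for e in cluster),
                end_s=max(e.end_s for e in cluster),
                baseline_mv=b, floor_mv=floor,
                fold_drop=b / floor if floor > 0 else np.inf))

    for e in pool:
        if cluster and e.start_s <= max(x.end_s for x in cluster):
            cluster.append(e)
        else:
            if cluster:
                _flush()
            cluster = [e]
    if cluster:
        _flush()
    return fused


def match_events(events: Sequence[PrecursorEvent], track: AnnotationTrack,
                 horizon_s: float = 10.0) -> list[PrecursorEvent]:
    """Assign each event the earliest unclaimed FOG onset in
    ``(start_s, start_s + horizon_s]``; earlier events win contested onsets."""
    onsets = [e.start_s for e in track.labelled("fog_onset")]
    taken: set[float] = set()
    out: list[PrecursorEvent] = []
    for ev in sorted(events, key=lambda e: e.start_s):
        candidates = [o for o in onsets
                      if ev.start_s < o <= ev.start_s + horizon_s and o not in taken]
        if candidates:
            o = min(candidates)
            taken.add(o)
            out.append(replace(ev, matched_fog_onset_s=o, lead_s=o - ev.start_s))
        else:
            out.append(ev)
    return out


def fold_change(env: EnvelopeSeries, event: PrecursorEvent, track: AnnotationTrack,
                channel: int = 0,
                exclude: Optional[Sequence[PrecursorEvent]] = None,
                active_kinds: Sequence[str] = ("walk", "set")) -> float:
    """Mean RMS over normal-activity reference windows divided by mean RMS
    inside the event.

    Reference windows are the active (walking/set) intervals with every
    precursor span in ``exclude`` (default: just this event) and every
    annotated FOG interval removed.  Returns NaN with a warning when no
    reference windows remain.
    """
    session_end = float(env.times[-1] + env.window_s)
    active: list[tuple[float, float]] = []
    for kind in active_kinds:
        active.extend(track.intervals(kind, session_end=session_end))
    if not active:
        active = [(float(env.times[0] - env.window_s), session_end)]
    cut = [(e.start_s, e.end_s) for e in (exclude if exclude is not None else [event])]
    cut.extend(track.intervals("fog", session_end=session_end))
    reference = _intervals.subtract(active, cut)
    ref_mask = _intervals.windows_inside(env.times, env.window_s, reference)
    ev_mask = _intervals.windows_inside(env.times, env.window_s,
                                        [(event.start_s, event.end_s)])
    if not ref_mask.any() or not ev_mask.any():
        warnings.warn("fold_change undefined: no reference or event windows")
        return float("nan")
    return float(np.mean(env.rms_mv[channel, ref_mask])
                 / np.mean(env.rms_mv[channel, ev_mask]))


def evaluate(events: Sequence[PrecursorEvent], truth: AnnotationTrack,
             session_length_s: float) -> DetectionReport:
    """Sensitivity, false-alarm rate and lead statistics versus annotations."""
    onsets = truth.labelled("fog_onset")
    matched = [e for e in events if e.matched_fog_onset_s is not None]
    unmatched = len(events) - len(matched)
    active_s = _intervals.total(truth.intervals("walk", session_end=session_length_s))
    if active_s <= 0:
        active_s = session_length_s
    leads = [e.lead_s for e in matched]
    n_onsets = len(onsets)
    return DetectionReport(
        events=list(events),
        n_onsets=n_onsets,
        n_matched=len(matched),
        sensitivity=None if n_onsets == 0 else len({e.matched_fog_onset_s for e in matched}) / n_onsets,
        false_alarms_per_min=unmatched / (active_s / 60.0),
        lead_stats=None if not leads else (float(np.min(leads)), float(np.mean(leads)),
                                           float(np.max(leads))),
    )
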