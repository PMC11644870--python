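"""Activity-state statistics: classical one-way fixed-effects ANOVA between
labelled window populations (active vs pause, normal vs pre-FOG).

The sampling unit is configurable: individual envelope windows
(``unit="window"``) or per-interval aggregates (``unit="episode"``, one mean
RMS per annotated interval), since window counts and interval counts imply
very different effective sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sp_stats

from . import _intervals
from .features import EnvelopeSeries
from .fog_detect import PrecursorEvent
from .io_formats import AnnotationTrack


@dataclass
class StateSamples:
    """Labelled groups of per-window (or per-episode) RMS values in mV."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for name, vals in self.groups.items():
            if vals.size < 2:
                raise ValueError(f"group {name!r} needs at least 2 values")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    degenerate: bool = False


@dataclass(frozen=True)
class StateComparison:
    samples: StateSamples
    anova: AnovaResult
    mean_ratio: float  # mean of first state over mean of second


def one_way_anova(samples: StateSamples) -> AnovaResult:
    """Classical one-way ANOVA: F = MS_between / MS_within, p from F(k-1, N-k).

    When every group has zero internal variance the statistic is degenerate:
    the result carries ``degenerate=True`` with p = 0 (or p = 1 if the group
    means coincide as well).
    """
    groups = list(samples.groups.values())
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(F=0.0, p=1.0, df_between=df_b, df_within=df_w,
                               degenerate=True)
        return AnovaResult(F=np.inf, p=0.0, df_between=df_b, df_within=df_w,
                           degenerate=True)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sp_stats.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), p=p, df_between=df_b, df_within=df_w)


def resolve_state_intervals(track: AnnotationTrack, state: str,
                            session_end: float,
                            events: Optional[Sequence[PrecursorEvent]] = None
                            ) -> list[tuple[float, float]]:
    """Time intervals occupied by a named activity state.

    ``precursor`` requires detected events; ``normal`` is active time with
    precursor and FOG spans removed.
    """
    if state in ("walk", "set", "pause", "fog"):
        return track.intervals(state, session_end=session_end)
    if state == "active":
        return _intervals.merge(track.intervals("walk", session_end=session_end)
                                + track.intervals("set", session_end=session_end))
    if state == "precursor":
        if not events:
            raise ValueError("state 'precursor' needs detected precursor events")
        return _intervals.merge([(e.start_s, e.end_s) for e in events])
    if state == "normal":
        active = resolve_state_intervals(track, "active", session_end)
        cut = track.intervals("fog", session_end=session_end)
        if events:
            cut = cut + [(e.start_s, e.end_s) for e in events]
        return _intervals.subtract(active, cut)
    raise ValueError(f"unknown state {state!r}")


def state_comparison(env: EnvelopeSeries, track: AnnotationTrack,
                     states: tuple[str, str] = ("active", "pause"),
                     channel: int = 0, unit: str = "window",
                     events: Optional[Sequence[PrecursorEvent]] = None
                     ) -> StateComparison:
    """ANOVA between two activity states plus the ratio of their mean RMS.

    Windows straddling a state boundary are excluded.  ``unit="episode"``
    aggregates each state interval to its mean RMS first.
    """
    if unit not in ("window", "episode"):
        raise ValueError("unit must be 'window' or 'episode'")
    session_end = float(env.times[-1] + env.window_s)
    rms = env.rms_mv[channel]
    groups: dict[str, np.ndarray] = {}
    for state in states:
        intervals = resolve_state_intervals(track, state, session_end, events)
        if unit == "window":
            mask = _intervals.windows_inside(env.times, env.window_s, intervals)
            vals = rms[mask]
        else:
            vals = np.array([
                rms[m].mean()
                for iv in intervals
                if (m := _intervals.windows_inside(env.times, env.window_s, [iv])).any()
            ])
        if vals.size < 2:
            raise ValueError(f"state {state!r} has fewer than 2 {unit} samples")
        groups[state] = vals
    samples = StateSamples(groups=groups)
    anova = one_way_anova(samples)
    ratio = float(groups[states[0]].mean() / groups[states[1]].mean())
    return StateComparison(samples=samples, anova=anova, mean_ratio=ratio)
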