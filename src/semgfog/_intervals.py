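"""Half-open time-interval arithmetic shared by the analysis modules."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

Interval = tuple[float, float]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping/touching intervals; drop empty ones."""
    iv = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in iv:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(base: Sequence[Interval], cut: Sequence[Interval]) -> list[Interval]:
    """Return ``base`` with every span of ``cut`` removed."""
    base = merge(base)
    cut = merge(cut)
    out: list[Interval] = []
    for s, e in base:
        lo = s
        for cs, ce in cut:
            if ce <= lo or cs >= e:
                continue
            if cs > lo:
                out.append((lo, cs))
            lo = max(lo, ce)
            if lo >= e:
                break
        if lo < e:
            out.append((lo, e))
    return out


def total(intervals: Sequence[Interval]) -> float:
    return float(sum(e - s for s, e in merge(intervals)))


def centers_inside(times: np.ndarray, intervals: Sequence[Interval]) -> np.ndarray:
    """Boolean mask of window-center times falling inside any interval."""
    mask = np.zeros(len(times), dtype=bool)
    for s, e in merge(intervals):
        mask |= (times >= s) & (times < e)
    return mask


def windows_inside(times: np.ndarray, window_s: float, intervals: Sequence[Interval]) -> np.ndarray:
    """Mask of windows (centers ``times``, width ``window_s``) fully contained
    in some interval; windows straddling a boundary are excluded."""
    half = 0.5 * window_s
    mask = np.zeros(len(times), dtype=bool)
    for s, e in merge(intervals):
        mask |= (times - half >= s) & (times + half <= e)
    return mask
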