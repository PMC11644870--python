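"""CSV dialects for sEMG recordings and event annotations, plus clock helpers.

A :class:`Recording` holds uniformly sampled multi-channel surface EMG in
millivolts on a session clock (seconds, starting at ``t0``).  An
:class:`AnnotationTrack` holds timestamped study events (walk boundaries,
freeze-of-gait onsets/ends, exercise set/pause boundaries), optionally with
the video frame index they were scored from.  Both are stored as small,
human-readable CSV files:

Recording CSV
    line 1: ``# fs_hz=<float> t0_s=<float>``
    line 2: ``time_s,<label1>,<label2>,...``
    data rows: time in seconds followed by per-channel amplitudes in mV.

Annotation CSV
    header ``label,start_s,end_s,frame_index``; empty cells mean "none".

Floats are written with 17 significant digits so a write/read round trip
reproduces the in-memory arrays bit for bit.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MUSCLES = ("quadriceps", "hamstring", "tibialis_anterior", "gastrocnemius", "biceps")
SIDES = ("left", "right")
EVENT_LABELS = (
    "walk_start",
    "walk_end",
    "fog_onset",
    "fog_end",
    "pause_start",
    "pause_end",
    "set_start",
    "set_end",
)
#: video frame rate used to score events from the session recording
DEFAULT_VIDEO_FPS = 33.0

_META_RE = re.compile(r"#\s*fs_hz=(\S+)\s+t0_s=(\S+)\s*$")


class FormatError(ValueError):
    """The file does not conform to the recording/annotation dialect."""


class DataError(ValueError):
    """The file parsed but contains an invalid (non-numeric or NaN) cell."""


@dataclass(frozen=True)
class ChannelMeta:
    """Identity of one sEMG channel: muscle group, body side, free-text label."""

    muscle: str
    side: str
    label: str

    def __post_init__(self) -> None:
        if self.muscle not in MUSCLES:
            raise ValueError(f"unknown muscle {self.muscle!r}; expected one of {MUSCLES}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}; expected one of {SIDES}")
        if not self.label:
            raise ValueError("channel label must be non-empty")

    @classmethod
    def from_label(cls, label: str) -> "ChannelMeta":
        """Recover muscle/side from a ``<muscle>_<side>[_suffix]`` column label."""
        for muscle in MUSCLES:
            for side in SIDES:
                prefix = f"{muscle}_{side}"
                if label == prefix or label.startswith(prefix + "_"):
                    return cls(muscle=muscle, side=side, label=label)
        raise FormatError(
            f"channel label {label!r} does not encode '<muscle>_<side>'"
        )


@dataclass
class Recording:
    """Uniformly sampled multi-channel sEMG, amplitudes in mV.

    ``data`` has shape ``(n_channels, n_samples)``; sample ``k`` of every
    channel is taken at session time ``t0 + k / sample_rate``.
    """

    sample_rate: float
    channels: list[ChannelMeta]
    data: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if len(self.channels) == 0:
            raise FormatError("a Recording must have at least one channel")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channels but data has {self.data.shape[0]} rows"
            )
        if not (np.isfinite(self.sample_rate) and self.sample_rate > 0):
            raise ValueError("sample_rate must be a positive finite number")
        if not np.isfinite(self.t0):
            raise ValueError("t0 must be finite")
        if not np.all(np.isfinite(self.data)):
            raise DataError("recording data contains NaN or infinite values")
        keys = [(c.muscle, c.side, c.label) for c in self.channels]
        if len(set(keys)) != len(keys):
            raise ValueError("(muscle, side, label) must be unique per channel")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    def channel_index(self, label: str) -> int:
        for i, c in enumerate(self.channels):
            if c.label == label:
                return i
        raise KeyError(f"no channel labelled {label!r}")


@dataclass(frozen=True)
class Event:
    """One annotated study event on the session clock."""

    label: str
    start_s: float
    end_s: Optional[float] = None
    frame_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label not in EVENT_LABELS:
            raise FormatError(f"unknown event label {self.label!r}")
        if not np.isfinite(self.start_s):
            raise ValueError("event start_s must be finite")
        if self.end_s is not None and self.end_s < self.start_s:
            raise ValueError(f"event end_s {self.end_s} precedes start_s {self.start_s}")
        if self.frame_index is not None and self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


@dataclass
class AnnotationTrack:
    """Sorted list of :class:`Event` sharing the recording's session clock."""

    events: list[Event]
    video_fps: float = DEFAULT_VIDEO_FPS

    def __post_init__(self) -> None:
        if self.video_fps <= 0:
            raise ValueError("video_fps must be positive")
        self.events = sorted(self.events, key=lambda e: e.start_s)
        # freeze episodes must close after they open
        open_onset: Optional[float] = None
        for e in self.events:
            if e.label == "fog_onset":
                open_onset = e.start_s
            elif e.label == "fog_end":
                if open_onset is None or e.start_s < open_onset:
                    raise ValueError(
                        f"fog_end at {e.start_s} s has no preceding fog_onset"
                    )
                open_onset = None

    def labelled(self, label: str) -> list[Event]:
        return [e for e in self.events if e.label == label]

    def intervals(self, kind: str, session_end: Optional[float] = None) -> list[tuple[float, float]]:
        """Pair ``<kind>_start``/``<kind>_end`` (or fog_onset/fog_end) events.

        An unclosed interval is closed at ``session_end`` when given,
        otherwise dropped.
        """
        if kind == "fog":
            open_label, close_label = "fog_onset", "fog_end"
        elif kind in ("walk", "set", "pause"):
            open_label, close_label = f"{kind}_start", f"{kind}_end"
        else:
            raise ValueError(f"unknown interval kind {kind!r}")
        out: list[tuple[float, float]] = []
        start: Optional[float] = None
        for e in self.events:
            if e.label == open_label:
                start = e.start_s
            elif e.label == close_label and start is not None:
                out.append((start, e.start_s))
                start = None
        if start is not None and session_end is not None and session_end > start:
            out.append((start, session_end))
        return out

    def shifted(self, offset_s: float) -> "AnnotationTrack":
        events = [
            replace(
                e,
                start_s=e.start_s + offset_s,
                end_s=None if e.end_s is None else e.end_s + offset_s,
            )
            for e in self.events
        ]
        return AnnotationTrack(events=events, video_fps=self.video_fps)


def read_recording(path) -> Recording:
    """Parse a recording CSV (dialect in the module docstring)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as f:
        first = f.readline().rstrip("\n")
        m = _META_RE.match(first)
        if m is None:
            raise FormatError(
                f"{path}: first line must be '# fs_hz=<float> t0_s=<float>', got {first!r}"
            )
        sample_rate = float(m.group(1))
        t0 = float(m.group(2))
        df = pd.read_csv(f, dtype=str, keep_default_na=False)
    if df.shape[1] < 2 or df.columns[0] != "time_s":
        raise FormatError(f"{path}: header must be 'time_s,<label>,...'")
    numeric = {}
    for col in df.columns:
        probe = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=np.float64)
        bad = np.flatnonzero(~np.isfinite(probe))
        if bad.size:
            raise DataError(
                f"{path}: non-numeric or NaN value at data row {bad[0] + 1}, column {col!r}"
            )
        # numpy's string conversion is correctly rounded, so a write/read
        # round trip reproduces the stored doubles bit for bit
        numeric[col] = df[col].to_numpy(dtype=np.float64)
    times = numeric["time_s"]
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise FormatError(f"{path}: time_s column must be strictly increasing")
    channels = [ChannelMeta.from_label(c) for c in df.columns[1:]]
    data = np.vstack([numeric[c] for c in df.columns[1:]])
    return Recording(sample_rate=sample_rate, channels=channels, data=data, t0=t0)


def write_recording(rec: Recording, path) -> None:
    """Write ``rec`` in the recording CSV dialect (17-digit floats)."""
    path = Path(path)
    times = rec.times()
    with open(path, "w", encoding="utf-8", newline="\n") as f:
        f.write(f"# fs_hz={rec.sample_rate!r} t0_s={rec.t0!r}\n")
        f.write("time_s," + ",".join(c.label for c in rec.channels) + "\n")
        table = np.column_stack([times, rec.data.T])
        np.savetxt(f, table, fmt="%.17g", delimiter=",", newline="\n")


def read_annotations(path, video_fps: float = DEFAULT_VIDEO_FPS) -> AnnotationTrack:
    """Parse an annotation CSV; events are sorted on read."""
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as f:
        reader = csv.reader(f)
        header = next(reader, None)
        if header != ["label", "start_s", "end_s", "frame_index"]:
            raise FormatError(
                f"{path}: header must be 'label,start_s,end_s,frame_index'"
            )
        events = []
        for i, row in enumerate(reader):
            if not row:
                continue
            if len(row) != 4:
                raise FormatError(f"{path}: row {i + 1} has {len(row)} cells, expected 4")
            label, start_s, end_s, frame = row
            try:
                events.append(
                    Event(
                        label=label,
                        start_s=float(start_s),
                        end_s=float(end_s) if end_s != "" else None,
                        frame_index=int(frame) if frame != "" else None,
                    )
                )
            except (ValueError, FormatError) as exc:
                if isinstance(exc, FormatError):
                    raise
                raise DataError(f"{path}: row {i + 1}: {exc}") from exc
    return AnnotationTrack(events=events, video_fps=video_fps)


def write_annotations(track: AnnotationTrack, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as f:
        f.write("label,start_s,end_s,frame_index\n")
        for e in track.events:
            end = "" if e.end_s is None else repr(e.end_s)
            frame = "" if e.frame_index is None else str(e.frame_index)
            f.write(f"{e.label},{e.start_s!r},{end},{frame}\n")


def frame_to_seconds(frame_index: int, fps: float = DEFAULT_VIDEO_FPS) -> float:
    """Convert a video frame index to seconds on the video clock."""
    if frame_index < 0:
        raise ValueError("frame_index must be >= 0")
    if fps <= 0:
        raise ValueError("fps must be positive")
    return frame_index / fps


def align_clocks(track: AnnotationTrack, offset_s: float) -> AnnotationTrack:
    """Shift all event times by ``offset_s`` (sensor/video latency reconciliation)."""
    if not np.isfinite(offset_s):
        raise ValueError("offset_s must be finite")
    return track.shifted(offset_s)
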