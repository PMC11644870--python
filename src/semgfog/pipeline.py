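"""End-to-end orchestration: simulate/load -> bandpass -> envelope ->
detect/match -> fatigue -> state statistics, as one reproducible run.

``analyze_session`` is the in-memory workhorse; ``run_pipeline`` wraps it
with file I/O, config hashing and logging for the command line.
``analyze_cohort`` runs the fixed three-session demonstration cohort and
aggregates episode-level metrics (fold change, lead times, sensitivity,
false alarms).
"""

from __future__ import annotations

import hashlib
import json
import shutil
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import _intervals
from .fatigue import MdfSeries, mdf_series
from .features import EnvelopeSeries, sliding_features, write_envelope
from .fog_detect import (DetectionReport, DetectorConfig, PrecursorEvent,
                         detect_precursors, evaluate, fold_change, fuse_events,
                         match_events)
from .io_formats import (AnnotationTrack, ChannelMeta, Recording,
                         read_annotations, read_recording, write_annotations,
                         write_recording)
from .preprocess import FilterSpec, bandpass
from .stats import StateComparison, state_comparison
from .synth import FogEpisodeSpec, SessionSpec, default_cohort, generate_session


@dataclass
class SessionAnalysis:
    """Everything the pipeline derives from one session."""

    recording: Recording
    annotations: AnnotationTrack
    filtered: Recording
    envelope: EnvelopeSeries
    channel_events: list[PrecursorEvent]
    events: list[PrecursorEvent]  # fused (or per-channel) and matched
    report: DetectionReport
    folds: list[float]  # one per matched event, averaged over channels
    event_p95_mv: list[float]  # 95th pct |filtered| inside each matched event


@dataclass
class CohortReport:
    n_episodes: int
    n_matched: int
    n_false_alarms: int
    sensitivity: float
    false_alarms_per_min: float
    folds: list[float]
    mean_fold: float
    leads: list[float]
    lead_min: float
    lead_mean: float
    lead_max: float
    event_p95_mv: list[float]
    mean_event_p95_mv: float


def analyze_session(rec: Recording, track: AnnotationTrack,
                    filter_spec: FilterSpec = FilterSpec(),
                    window_s: float = 0.200, step_s: float = 0.010,
                    detector: DetectorConfig = DetectorConfig(),
                    horizon_s: float = 10.0, fuse: bool = True) -> SessionAnalysis:
    """Run the full detection chain on one session."""
    filtered = bandpass(rec, filter_spec)
    env = sliding_features(filtered, window_s, step_s, filter_spec=filter_spec)
    walk = track.intervals("walk", session_end=rec.t0 + rec.duration_s)
    channel_events = detect_precursors(env, detector,
                                       active_intervals=walk or None)
    if fuse:
        events = fuse_events(channel_events, detector.fusion_min_channels)
    else:
        events = list(channel_events)
    events = match_events(events, track, horizon_s=horizon_s)
    report = evaluate(events, track, session_length_s=rec.duration_s)
    folds: list[float] = []
    p95s: list[float] = []
    t = filtered.times()
    for ev in events:
        if ev.matched_fog_onset_s is None:
            continue
        per_chan = [fold_change(env, ev, track, channel=ci, exclude=events)
                    for ci in range(len(env.channels))]
        folds.append(float(np.nanmean(per_chan)))
        sel = (t >= ev.start_s) & (t < ev.end_s)
        p95s.append(float(np.mean(
            [np.percentile(np.abs(filtered.data[ci, sel]), 95)
             for ci in range(filtered.n_channels)])))
    return SessionAnalysis(recording=rec, annotations=track, filtered=filtered,
                           envelope=env, channel_events=channel_events,
                           events=events, report=report, folds=folds,
                           event_p95_mv=p95s)


def analyze_cohort(sessions: Optional[Sequence[tuple[Recording, AnnotationTrack]]] = None,
                   **kwargs) -> CohortReport:
    """Analyze each cohort session and aggregate episode-level metrics."""
    if sessions is None:
        sessions = default_cohort()
    folds: list[float] = []
    leads: list[float] = []
    p95s: list[float] = []
    n_onsets = n_matched = n_false = 0
    active_s = 0.0
    for rec, track in sessions:
        res = analyze_session(rec, track, **kwargs)
        folds.extend(res.folds)
        p95s.extend(res.event_p95_mv)
        leads.extend(e.lead_s for e in res.events if e.lead_s is not None)
        n_onsets += res.report.n_onsets
        n_matched += res.report.n_matched
        n_false += len(res.events) - res.report.n_matched
        active_s += _intervals.total(track.intervals("walk", session_end=rec.duration_s))
    return CohortReport(
        n_episodes=n_onsets, n_matched=n_matched, n_false_alarms=n_false,
        sensitivity=n_matched / n_onsets if n_onsets else float("nan"),
        false_alarms_per_min=n_false / (active_s / 60.0) if active_s else float("nan"),
        folds=folds, mean_fold=float(np.mean(folds)) if folds else float("nan"),
        leads=leads,
        lead_min=float(np.min(leads)) if leads else float("nan"),
        lead_mean=float(np.mean(leads)) if leads else float("nan"),
        lead_max=float(np.max(leads)) if leads else float("nan"),
        event_p95_mv=p95s,
        mean_event_p95_mv=float(np.mean(p95s)) if p95s else float("nan"),
    )


@dataclass
class RunConfig:
    """Parameterization of one reproducible pipeline run."""

    out_dir: str
    seed: int = 0
    session: Optional[SessionSpec] = None  # simulate when set...
    recording_path: Optional[str] = None   # ...else load these files
    annotations_path: Optional[str] = None
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    window_s: float = 0.200
    step_s: float = 0.010
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    mdf_window_s: float = 1.0
    mdf_step_s: float = 0.05
    comparison: Optional[tuple[str, str]] = ("normal", "precursor")
    comparison_unit: str = "window"
    horizon_s: float = 10.0

    def validate(self) -> None:
        if self.step_s > self.window_s:
            raise ValueError("step_s must not exceed window_s")
        if (self.session is None) == (self.recording_path is None):
            raise ValueError("configure exactly one of 'session' or input paths")
        if self.recording_path is not None:
            if self.annotations_path is None:
                raise ValueError("annotations_path required with recording_path")
            for p in (self.recording_path, self.annotations_path):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        if self.session is not None:
            self.session.validate()

    def to_dict(self) -> dict:
        d = {
            # out_dir deliberately excluded: reruns into a different directory
            # must hash (and serialize) identically
            "seed": self.seed,
            "recording_path": self.recording_path,
            "annotations_path": self.annotations_path,
            "filter": asdict(self.filter_spec),
            "window_s": self.window_s,
            "step_s": self.step_s,
            "detector": asdict(self.detector),
            "mdf_window_s": self.mdf_window_s,
            "mdf_step_s": self.mdf_step_s,
            "comparison": list(self.comparison) if self.comparison else None,
            "comparison_unit": self.comparison_unit,
            "horizon_s": self.horizon_s,
        }
        if self.session is not None:
            s = asdict(self.session)
            s["channels"] = [c["label"] for c in s["channels"]]
            d["session"] = s
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def session_spec_from_dict(d: dict) -> SessionSpec:
    d = dict(d)
    if "channels" in d:
        d["channels"] = [ChannelMeta.from_label(lbl) for lbl in d["channels"]]
    if "episodes" in d:
        d["episodes"] = [FogEpisodeSpec(**ep) for ep in d["episodes"]]
    return SessionSpec(**d)


def run_config_from_yaml(path, out_dir: Optional[str] = None) -> RunConfig:
    with open(path, "r", encoding="utf-8") as f:
        raw = yaml.safe_load(f) or {}
    kwargs: dict = {}
    if "session" in raw:
        kwargs["session"] = session_spec_from_dict(raw.pop("session"))
    if "filter" in raw:
        kwargs["filter_spec"] = FilterSpec(**raw.pop("filter"))
    if "detector" in raw:
        kwargs["detector"] = DetectorConfig(**raw.pop("detector"))
    if "comparison" in raw and raw["comparison"] is not None:
        raw["comparison"] = tuple(raw["comparison"])
    kwargs.update(raw)
    if out_dir is not None:
        kwargs["out_dir"] = out_dir
    return RunConfig(**kwargs)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute simulate/load -> filter -> features -> detect -> fatigue ->
    stats, writing every artifact (stamped with the config hash) to
    ``cfg.out_dir``.  Deterministic for a fixed config; partial outputs are
    removed on failure."""
    cfg.validate()
    out = Path(cfg.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} [{stage}] {msg}")

    stage = "setup"
    try:
        meta = {"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
                "seed": cfg.seed}
        stage = "input"
        if cfg.session is not None:
            spec = cfg.session
            if spec.seed != cfg.seed:
                spec = SessionSpec(**{**asdict_spec(spec), "seed": cfg.seed})
            rec, track = generate_session(spec)
            write_recording(rec, out / "recording.csv")
            write_annotations(track, out / "annotations.csv")
            log(stage, f"simulated session seed={cfg.seed}")
        else:
            rec = read_recording(cfg.recording_path)
            track = read_annotations(cfg.annotations_path)
            log(stage, f"loaded {cfg.recording_path}")

        stage = "analysis"
        res = analyze_session(rec, track, filter_spec=cfg.filter_spec,
                              window_s=cfg.window_s, step_s=cfg.step_s,
                              detector=cfg.detector, horizon_s=cfg.horizon_s)
        write_recording(res.filtered, out / "filtered.csv")
        write_envelope(res.envelope, out / "envelope.csv")
        log(stage, f"{len(res.events)} session-level events, "
                   f"{res.report.n_matched}/{res.report.n_onsets} onsets matched")

        stage = "fatigue"
        mdf = mdf_series(res.filtered, cfg.mdf_window_s, cfg.mdf_step_s)
        _write_mdf(mdf, out / "mdf.csv")
        log(stage, f"{mdf.mdf_hz.shape[1]} MDF windows")

        stage = "detection-report"
        detection = dict(meta)
        detection.update(res.report.to_dict())
        detection["fold_changes"] = res.folds
        detection["event_p95_mv"] = res.event_p95_mv
        _write_json(detection, out / "detection.json")

        stage = "stats"
        if cfg.comparison is not None:
            try:
                comp = state_comparison(res.envelope, track, states=cfg.comparison,
                                        unit=cfg.comparison_unit, events=res.events)
                stats_out = dict(meta)
                stats_out.update({
                    "states": list(cfg.comparison),
                    "unit": cfg.comparison_unit,
                    "F": comp.anova.F, "p": comp.anova.p,
                    "df": [comp.anova.df_between, comp.anova.df_within],
                    "degenerate": comp.anova.degenerate,
                    "mean_ratio": comp.mean_ratio,
                    "group_sizes": {k: int(v.size) for k, v in comp.samples.groups.items()},
                })
                _write_json(stats_out, out / "stats.json")
                log(stage, f"F={comp.anova.F:.3g} p={comp.anova.p:.3g}")
            except ValueError as exc:
                log(stage, f"comparison skipped: {exc}")

        (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        return out
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def asdict_spec(spec: SessionSpec) -> dict:
    d = asdict(spec)
    d["channels"] = [ChannelMeta(**c) for c in d["channels"]]
    d["episodes"] = [FogEpisodeSpec(**e) for e in d["episodes"]]
    return d


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def _write_mdf(mdf: MdfSeries, path: Path) -> None:
    import pandas as pd

    cols = {"time_s": mdf.times}
    for i, ch in enumerate(mdf.channels):
        cols[f"{ch.label}_mdf_hz"] = mdf.mdf_hz[i]
    with open(path, "w", encoding="utf-8", newline="\n") as f:
        f.write(f"# band_hz={mdf.spectrum_band[0]!r}-{mdf.spectrum_band[1]!r}\n")
        pd.DataFrame(cols).to_csv(f, index=False, float_format="%.17g",
                                  lineterminator="\n")
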