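"""Detector mechanics on constructed envelopes plus recovery on synthetic
sessions."""

import numpy as np
import pytest

import semgfog as sf
from semgfog.fog_detect import (DetectorConfig, PrecursorEvent, fuse_events,
                                rolling_baseline)

#: detector with smoothing disabled, for hand-checkable toy envelopes
RAW_CFG = DetectorConfig(smooth_s=0.0, onset_smooth_s=0.0, baseline_window_s=10.0)


def make_env(rms: np.ndarray, step_s: float = 0.5, n_channels: int = 1) -> sf.EnvelopeSeries:
    rms = np.tile(np.asarray(rms, dtype=float), (n_channels, 1))
    labels = ["quadriceps_right", "hamstring_right"]
    channels = [sf.ChannelMeta.from_label(labels[i]) for i in range(n_channels)]
    times = (np.arange(rms.shape[1]) + 0.5) * step_s
    return sf.EnvelopeSeries(window_s=step_s, step_s=step_s, times=times,
                             channels=channels, rms_mv=rms, mav_mv=rms.copy(),
                             ptp_mv=rms.copy())


def test_baseline_constant_envelope():
    env = make_env(np.full(40, 3.0))
    base = rolling_baseline(env, RAW_CFG)
    np.testing.assert_allclose(base, 3.0)


def test_baseline_holds_through_step_drop():
    # 30-window toy: 3 mV for 20 windows then a drop to 1 mV; the exclusion
    # rule must keep the baseline at ~3 mV throughout the drop
    env = make_env(np.concatenate([np.full(20, 3.0), np.full(10, 1.0)]))
    base = rolling_baseline(env, RAW_CFG)
    np.testing.assert_allclose(base, 3.0)


def test_zero_envelope_no_events():
    env = make_env(np.zeros(50))
    base = rolling_baseline(env, RAW_CFG)
    np.testing.assert_allclose(base, 0.0)
    assert sf.detect_precursors(env, RAW_CFG) == []


def test_constant_envelope_no_events():
    env = make_env(np.full(60, 3.0))
    assert sf.detect_precursors(env, RAW_CFG) == []


def test_sustained_drop_detected_short_dip_ignored():
    # 4 s dip -> one event; 2 s dip -> filtered out by the persistence rule
    long_dip = np.full(80, 3.0)
    long_dip[40:48] = 1.0  # 8 windows x 0.5 s = 4 s
    events = sf.detect_precursors(make_env(long_dip), RAW_CFG)
    assert len(events) == 1
    assert events[0].duration_s >= RAW_CFG.min_duration_s
    assert events[0].fold_drop > 1.0

    short_dip = np.full(80, 3.0)
    short_dip[40:44] = 1.0  # 2 s < min_duration_s
    assert sf.detect_precursors(make_env(short_dip), RAW_CFG) == []


def test_event_invariants_on_synthetic_sessions():
    for seed in range(5):
        rec, track = sf.generate_session(sf.SessionSpec(
            duration_s=40.0, episodes=[sf.FogEpisodeSpec(25.0)], seed=700 + seed))
        env = sf.sliding_features(sf.bandpass(rec), 0.2, 0.01)
        for ev in sf.detect_precursors(env):
            assert ev.duration_s >= DetectorConfig().min_duration_s
            assert ev.fold_drop > 1.0
            assert ev.baseline_mv > ev.floor_mv >= 0.0


def test_stricter_drop_fraction_never_adds_events():
    rec, track = sf.generate_session(sf.SessionSpec(
        duration_s=60.0, episodes=[sf.FogEpisodeSpec(25.0), sf.FogEpisodeSpec(45.0)],
        seed=77))
    env = sf.sliding_features(sf.bandpass(rec), 0.2, 0.01)
    counts = []
    for frac in (0.6, 0.5, 0.4, 0.3):
        cfg = DetectorConfig(drop_fraction=frac)
        counts.append(len(sf.detect_precursors(env, cfg)))
    assert counts == sorted(counts, reverse=True)


def _event(start, end=None, channel=None):
    return PrecursorEvent(channel=channel, start_s=start,
                          end_s=end if end is not None else start + 5.0,
                          baseline_mv=3.0, floor_mv=1.0, fold_drop=3.0)


def test_match_simple_lead():
    track = sf.AnnotationTrack(events=[sf.Event("fog_onset", 13.5)])
    matched = sf.match_events([_event(10.0)], track)
    assert matched[0].matched_fog_onset_s == 13.5
    assert matched[0].lead_s == pytest.approx(3.5)


def test_match_outside_horizon_unmatched():
    track = sf.AnnotationTrack(events=[sf.Event("fog_onset", 25.0)])
    matched = sf.match_events([_event(10.0)], track, horizon_s=10.0)
    assert matched[0].matched_fog_onset_s is None


def test_match_earliest_event_wins():
    track = sf.AnnotationTrack(events=[sf.Event("fog_onset", 18.0)])
    matched = sf.match_events([_event(10.0), _event(16.0)], track)
    by_start = {e.start_s: e for e in matched}
    assert by_start[10.0].matched_fog_onset_s == 18.0
    assert by_start[16.0].matched_fog_onset_s is None


def test_fold_change_closed_form():
    # reference at 3 mV, event at 1 mV -> fold 3
    rms = np.full(100, 3.0)
    rms[60:80] = 1.0
    env = make_env(rms)
    track = sf.AnnotationTrack(events=[sf.Event("walk_start", 0.0),
                                       sf.Event("walk_end", 50.0)])
    ev = _event(30.0, 40.0)
    assert sf.fold_change(env, ev, track) == pytest.approx(3.0)


def test_fold_change_undefined_without_reference():
    env = make_env(np.full(20, 1.0))
    track = sf.AnnotationTrack(events=[sf.Event("walk_start", 0.0),
                                       sf.Event("walk_end", 10.0)])
    ev = _event(0.0, 10.0)
    with pytest.warns(UserWarning):
        assert np.isnan(sf.fold_change(env, ev, track))


def test_fold_recovery_attenuation_half():
    # fold_change must recover 1/attenuation = 2 within 15% over 20 seeds
    cfg = DetectorConfig(drop_fraction=0.65)
    folds = []
    for seed in range(400, 420):
        eps = [sf.FogEpisodeSpec(25.0, attenuation=0.5)]
        rec, track = sf.generate_session(sf.SessionSpec(duration_s=40.0,
                                                        episodes=eps, seed=seed))
        res = sf.analyze_session(rec, track, detector=cfg)
        folds.extend(res.folds)
    assert len(folds) >= 15
    assert np.mean(folds) == pytest.approx(2.0, rel=0.15)


def test_lead_recovery_within_half_second():
    # mean onset-timing error across 20 seeds stays within +-0.5 s
    errs = []
    for seed in range(100, 120):
        lead = float(np.random.default_rng(seed).uniform(3.0, 4.5))
        rec, track = sf.generate_session(sf.SessionSpec(
            duration_s=40.0,
            episodes=[sf.FogEpisodeSpec(25.0, precursor_lead_s=lead)], seed=seed))
        res = sf.analyze_session(rec, track)
        matched = [e for e in res.events if e.lead_s is not None]
        assert len(matched) == 1
        errs.append(matched[0].lead_s - lead)
    assert abs(np.mean(errs)) <= 0.5


def test_fusion_requires_two_thigh_channels():
    q = sf.ChannelMeta.from_label("quadriceps_right")
    h = sf.ChannelMeta.from_label("hamstring_right")
    g = sf.ChannelMeta.from_label("gastrocnemius_left")
    only_one = fuse_events([_event(10.0, channel=q), _event(30.0, channel=h)])
    assert only_one == []  # no temporal overlap
    both = fuse_events([_event(10.0, channel=q), _event(10.5, channel=h)])
    assert len(both) == 1
    assert both[0].start_s == 10.0 and both[0].end_s == 15.5
    calf = fuse_events([_event(10.0, channel=q), _event(10.5, channel=g)])
    assert calf == []  # calf channels do not count toward thigh co-occurrence


def test_evaluate_arithmetic():
    track = sf.AnnotationTrack(events=[sf.Event("fog_onset", 15.0),
                                       sf.Event("fog_onset", 40.0),
                                       sf.Event("walk_start", 0.0),
                                       sf.Event("walk_end", 60.0)])
    events = sf.match_events([_event(12.0), _event(50.0)], track)
    rep = sf.evaluate(events, track, session_length_s=60.0)
    assert rep.sensitivity == pytest.approx(0.5)   # 1 matched of 2 onsets
    assert rep.false_alarms_per_min == pytest.approx(1.0)  # 1 unmatched / 1 min
    assert rep.lead_stats == (3.0, 3.0, 3.0)

    empty = sf.evaluate([], track, session_length_s=60.0)
    assert empty.sensitivity == 0.0
    assert empty.lead_stats is None

    no_onsets = sf.AnnotationTrack(events=[sf.Event("walk_start", 0.0),
                                           sf.Event("walk_end", 60.0)])
    assert sf.evaluate([], no_onsets, session_length_s=60.0).sensitivity is None
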