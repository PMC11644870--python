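"""Envelope features against closed forms and a brute-force oracle."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import semgfog as sf
from semgfog.features import (WindowConfigError, frame_count, read_envelope,
                              sliding_features, write_envelope)

from conftest import make_recording


def brute_force_features(data, window, step):
    """Naive per-window loop; the independent oracle."""
    n = data.shape[1]
    rms, mav, ptp = [], [], []
    for start in range(0, n - window + 1, step):
        seg = data[:, start: start + window]
        rms.append(np.sqrt(np.mean(seg ** 2, axis=1)))
        mav.append(np.mean(np.abs(seg), axis=1))
        ptp.append(np.max(seg, axis=1) - np.min(seg, axis=1))
    return (np.array(rms).T, np.array(mav).T, np.array(ptp).T)


def test_constant_signal_closed_form():
    rec = make_recording(np.full((1, 1000), 2.0))
    env = sliding_features(rec, 0.2, 0.01)
    np.testing.assert_array_equal(env.rms_mv, 2.0)
    np.testing.assert_array_equal(env.mav_mv, 2.0)
    np.testing.assert_array_equal(env.ptp_mv, 0.0)


def test_window_count_ten_second_recording():
    rec = make_recording(np.zeros((1, 10_000)))
    env = sliding_features(rec, 0.2, 0.01)
    assert env.n_windows == 981  # floor((10 - 0.2) / 0.01) + 1
    assert frame_count(10_000, 200, 10) == 981


def test_matches_brute_force_exactly(rng):
    for _ in range(30):
        n = int(rng.integers(30, 300))
        window = int(rng.integers(2, 25))
        step = int(rng.integers(1, window + 1))
        data = rng.normal(size=(2, n))
        rec = make_recording(data, fs=100.0)
        env = sliding_features(rec, window / 100.0, step / 100.0, allow_any_step=True)
        rms, mav, ptp = brute_force_features(data, window, step)
        np.testing.assert_array_equal(env.rms_mv, rms)
        np.testing.assert_array_equal(env.mav_mv, mav)
        np.testing.assert_array_equal(env.ptp_mv, ptp)


def test_window_times_start_at_t0():
    rec = make_recording(np.zeros((1, 1000)), t0=5.0)
    env = sliding_features(rec, 0.2, 0.01)
    assert env.times[0] == pytest.approx(5.1)  # first window center = t0 + w/2
    assert np.allclose(np.diff(env.times), 0.01)


def test_step_larger_than_window_rejected():
    rec = make_recording(np.zeros((1, 1000)))
    with pytest.raises(WindowConfigError):
        sliding_features(rec, 0.02, 0.05)


def test_step_outside_supported_range_needs_override():
    rec = make_recording(np.zeros((1, 1000)))
    with pytest.raises(WindowConfigError):
        sliding_features(rec, 0.2, 0.005)
    env = sliding_features(rec, 0.2, 0.005, allow_any_step=True)
    assert env.n_windows > 0


def test_recording_shorter_than_window_warns_empty():
    rec = make_recording(np.zeros((1, 50)))
    with pytest.warns(UserWarning):
        env = sliding_features(rec, 0.2, 0.01)
    assert env.n_windows == 0


@given(hst.floats(min_value=-50, max_value=50).filter(lambda c: abs(c) > 1e-3))
@settings(max_examples=25, deadline=None)
def test_amplitude_equivariance(c):
    rng = np.random.default_rng(7)
    data = rng.normal(size=(1, 400))
    env1 = sliding_features(make_recording(data), 0.05, 0.01)
    env2 = sliding_features(make_recording(c * data), 0.05, 0.01)
    np.testing.assert_allclose(env2.rms_mv, abs(c) * env1.rms_mv, rtol=1e-12)
    np.testing.assert_allclose(env2.mav_mv, abs(c) * env1.mav_mv, rtol=1e-12)
    np.testing.assert_allclose(env2.ptp_mv, abs(c) * env1.ptp_mv, rtol=1e-12)


def test_rms_dominates_mav(rng):
    data = rng.normal(size=(3, 2000))
    env = sliding_features(make_recording(data), 0.2, 0.01)
    assert np.all(env.rms_mv >= env.mav_mv - 1e-15)
    assert np.all(env.mav_mv >= 0)
    assert np.all(env.ptp_mv >= 0)


def _track_with_set(start, end):
    return sf.AnnotationTrack(events=[sf.Event("set_start", start),
                                      sf.Event("set_end", end)])


def test_training_load_definition():
    # RMS pinned at the isometric threshold for 30 s of activity -> load 30
    rec = make_recording(np.full((1, 35_000), 1.7))
    env = sliding_features(rec, 0.2, 0.01)
    track = _track_with_set(0.0, 30.0)
    load = sf.training_load(env, isometric_threshold_mv=1.7, track=track)
    assert load[0] == pytest.approx(30.0, abs=0.02)
    halved = sf.training_load(env, isometric_threshold_mv=3.4, track=track)
    assert halved[0] == pytest.approx(load[0] / 2.0)


def test_training_load_no_active_intervals_warns_zero():
    rec = make_recording(np.full((1, 1000), 1.0))
    env = sliding_features(rec, 0.2, 0.01)
    track = sf.AnnotationTrack(events=[])
    with pytest.warns(UserWarning):
        load = sf.training_load(env, 1.0, track)
    assert load[0] == 0.0


def test_training_load_set_exceeds_pause():
    spec = sf.CurlProtocolSpec()
    rec, track = sf.generate_curl_session(spec, seed=2)
    env = sliding_features(rec, 0.2, 0.01)
    load_sets = sf.training_load(env, 1.0, track, active_kinds=("set",))
    # pauses via a rebuilt track whose "set" intervals are the pauses
    pause_track = sf.AnnotationTrack(events=[
        sf.Event("set_start", s) for s, _ in spec.pause_intervals()
    ] + [sf.Event("set_end", e) for _, e in spec.pause_intervals()])
    load_pauses = sf.training_load(env, 1.0, pause_track, active_kinds=("set",))
    assert load_sets[0] > 5.0 * load_pauses[0]


def test_envelope_csv_round_trip(tmp_path, rng):
    data = rng.normal(size=(2, 3000))
    env = sliding_features(make_recording(data), 0.2, 0.01)
    p = tmp_path / "env.csv"
    write_envelope(env, p)
    back = read_envelope(p)
    assert back.window_s == env.window_s
    assert back.step_s == env.step_s
    np.testing.assert_array_equal(back.rms_mv, env.rms_mv)
    np.testing.assert_array_equal(back.times, env.times)
    assert [c.label for c in back.channels] == [c.label for c in env.channels]
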