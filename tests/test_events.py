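"""Trace cleaning, velocity, saccade and fixation detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oculocog as oc
from oculocog.events import (CleanTrace, compute_velocity, detect_fixations,
                             detect_saccades, preprocess, rms_dispersion)
from oculocog.paradigm import SAMPLING_RATE
from oculocog.profiles import default_profiles
from oculocog.simulate import GazeTrial, _min_jerk, saccade_duration
from oculocog import paradigm

DT = 1.0 / SAMPLING_RATE


def _trace(x, y, excluded=None):
    n = len(x)
    return CleanTrace(t=np.arange(n) * DT, x=np.asarray(x, float),
                      y=np.asarray(y, float),
                      interpolated_mask=np.zeros(n, bool),
                      excluded_mask=(np.zeros(n, bool) if excluded is None
                                     else excluded))


def _gaze(t, x, y, valid=None):
    trial = paradigm.Trial(task="synthetic", condition="-",
                           events=(paradigm.TargetEvent(0, 0, 0, "fixation"),),
                           duration=float(t[-1]))
    return GazeTrial(trial=trial, t=t, x=x, y=y,
                     valid=np.ones(len(t), bool) if valid is None else valid)


# ---------------------------------------------------------------------------
# preprocess


def test_preprocess_clean_trace_has_no_flags():
    t = np.arange(60) * DT
    gt = _gaze(t, np.zeros(60), np.zeros(60))
    trace = preprocess(gt)
    assert not trace.interpolated_mask.any()
    assert not trace.excluded_mask.any()
    assert not trace.unusable
    assert np.allclose(trace.x, 0.0)


def test_preprocess_interpolates_short_gap_linearly():
    t = np.arange(30) * DT
    x = np.linspace(0.0, 5.0, 30)
    valid = np.ones(30, bool)
    valid[10:12] = False  # 2 samples = 33 ms
    gt = _gaze(t, x.copy(), np.zeros(30), valid)
    trace = preprocess(gt)
    assert trace.interpolated_mask[10:12].all()
    assert not trace.excluded_mask.any()
    # the raw (unsmoothed) channel is exactly the linear bridge
    assert np.allclose(trace.x_raw, x, atol=1e-9)


def test_preprocess_long_gap_excluded_and_unusable_threshold():
    t = np.arange(60) * DT
    valid = np.ones(60, bool)
    valid[20:30] = False  # 167 ms: too long to bridge
    trace = preprocess(_gaze(t, np.zeros(60), np.zeros(60), valid))
    assert trace.excluded_mask[20:30].all()
    assert not trace.unusable

    mostly_bad = np.ones(60, bool)
    mostly_bad[:36] = False  # 60% invalid
    trace2 = preprocess(_gaze(t, np.zeros(60), np.zeros(60), mostly_bad))
    assert trace2.unusable


def test_preprocess_rejects_tiny_trials():
    t = np.arange(5) * DT
    with pytest.raises(ValueError, match="too short"):
        preprocess(_gaze(t, np.zeros(5), np.zeros(5)))


# ---------------------------------------------------------------------------
# velocity


def test_velocity_constant_zero_and_linear_ramps():
    n = 40
    assert np.allclose(compute_velocity(_trace(np.zeros(n), np.zeros(n))), 0.0)
    t = np.arange(n) * DT
    v = compute_velocity(_trace(10 * t, np.zeros(n)))
    assert np.allclose(v[1:-1], 10.0)
    v2 = compute_velocity(_trace(np.zeros(n), 5 * t))
    assert np.allclose(v2[1:-1], 5.0)


def test_velocity_nan_around_exclusions():
    n = 40
    excluded = np.zeros(n, bool)
    excluded[20:23] = True
    v = compute_velocity(_trace(np.zeros(n), np.zeros(n), excluded))
    assert np.isnan(v[19:24]).all()
    assert np.isfinite(v[:19]).all()


# ---------------------------------------------------------------------------
# saccade detection


def _min_jerk_trace(amplitude, onset=0.5, n=90, noise_sd=0.0, rng=None):
    t = np.arange(n) * DT
    dur = saccade_duration(amplitude)
    x = amplitude * _min_jerk(t, onset, dur)
    y = np.zeros(n)
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, n)
        y = y + rng.normal(0, noise_sd, n)
    return preprocess(_gaze(t, x, y))


def test_single_saccade_detected_with_correct_amplitude():
    trace = _min_jerk_trace(9.7)
    events = detect_saccades(trace)
    assert len(events) == 1
    assert events[0].amplitude == pytest.approx(9.7, abs=0.1)
    assert events[0].direction[0] == pytest.approx(1.0, abs=1e-6)


def test_fixation_noise_alone_yields_no_events(rng):
    # brute-force check: default-scale fixational noise never crosses 30 deg/s
    n_events = 0
    for _ in range(300):
        t = np.arange(60) * DT
        trace = preprocess(_gaze(t, rng.normal(0, 0.1, 60),
                                 rng.normal(0, 0.1, 60)))
        n_events += len(detect_saccades(trace))
    assert n_events == 0


def test_two_separated_saccades_detected_in_order():
    t = np.arange(120) * DT
    x = 5.0 * _min_jerk(t, 0.4, saccade_duration(5.0))
    x = x + 5.0 * _min_jerk(t, 0.9, saccade_duration(5.0))
    events = detect_saccades(preprocess(_gaze(t, x, np.zeros(120))))
    assert len(events) == 2
    assert events[0].offset < events[1].onset
    assert all(e.amplitude == pytest.approx(5.0, abs=0.1) for e in events)


def test_saccades_never_overlap_exclusions_or_each_other():
    prof = default_profiles()["control"]
    gen = np.random.default_rng(8)
    for trial in oc.build_prosaccade_schedule(1).trials[:16]:
        gt = oc.simulate_gaze_trial(trial, prof, gen)
        trace = preprocess(gt)
        events = detect_saccades(trace)
        for a, b in zip(events, events[1:]):
            assert a.offset_index < b.onset_index
        for e in events:
            assert not trace.excluded_mask[e.onset_index:e.offset_index + 1].any()


def test_detection_sensitivity_on_generated_saccades():
    """>= 95% of injected primary saccades recovered at default noise."""
    prof = default_profiles()["control"]
    gen = np.random.default_rng(3)
    sched = oc.build_prosaccade_schedule(0)
    found, total = 0, 0
    for trial in sched.trials:
        gt = oc.simulate_gaze_trial(trial, prof, gen)
        trace = preprocess(gt)
        if trace.unusable:
            continue
        cue = next(e for e in trial.events if e.kind == "step")
        total += 1
        hits = [e for e in detect_saccades(trace)
                if e.onset > cue.onset and e.amplitude >= 2.0]
        found += bool(hits)
    assert total >= 50
    assert found / total >= 0.95


def test_latency_recovery_within_one_sample():
    """Detected onsets track injected latencies to within ~1 sample."""
    prof = default_profiles()["control"]
    gen = np.random.default_rng(5)
    sched = oc.build_prosaccade_schedule(0)
    errors = []
    for rep in range(8):  # 8 x 64 = 512 trials
        for trial in sched.trials:
            gt = oc.simulate_gaze_trial(trial, prof, gen)
            if gt.truth["anti_error"]:
                continue
            cue = next(e for e in trial.events if e.kind == "step")
            trace = preprocess(gt)
            hits = [e for e in detect_saccades(trace)
                    if e.onset > cue.onset and e.amplitude >= 2.0]
            if hits:
                errors.append(hits[0].onset - cue.onset - gt.truth["latency"])
    errors = np.asarray(errors)
    assert len(errors) > 400
    assert abs(errors.mean()) < DT / 2
    assert np.quantile(np.abs(errors), 0.95) <= DT + 1e-9


# ---------------------------------------------------------------------------
# fixations and dispersion


def test_whole_trial_fixation_single_epoch_zero_dispersion():
    n = 120
    trace = _trace(np.zeros(n), np.zeros(n))
    epochs = detect_fixations(trace, [])
    assert len(epochs) == 1
    assert epochs[0].dispersion == pytest.approx(0.0, abs=1e-12)


def test_alternating_unit_offsets_have_unit_dispersion():
    x = np.tile([1.0, -1.0], 30)
    assert rms_dispersion(x, np.zeros(60)) == pytest.approx(1.0)


def test_saccade_splits_trial_into_two_epochs():
    trace = _min_jerk_trace(9.7, onset=0.75)
    saccades = detect_saccades(trace)
    epochs = detect_fixations(trace, saccades)
    assert len(epochs) == 2
    assert epochs[0].centroid[0] == pytest.approx(0.0, abs=0.05)
    assert epochs[1].centroid[0] == pytest.approx(9.7, abs=0.05)


@settings(max_examples=25, deadline=None)
@given(dx=st.floats(-20, 20), dy=st.floats(-20, 20),
       theta=st.floats(0, 2 * np.pi))
def test_dispersion_invariant_under_translation_and_rotation(dx, dy, theta):
    gen = np.random.default_rng(99)
    x = gen.normal(0, 0.3, 80)
    y = gen.normal(0, 0.3, 80)
    base = rms_dispersion(x, y)
    xr = np.cos(theta) * x - np.sin(theta) * y + dx
    yr = np.sin(theta) * x + np.cos(theta) * y + dy
    assert rms_dispersion(xr, yr) == pytest.approx(base, rel=1e-9, abs=1e-9)


def test_saccades_frame_serialisation():
    from oculocog.events import saccades_frame
    trace = _min_jerk_trace(9.7)
    events = detect_saccades(trace)
    df = saccades_frame([("P1", "prosaccade_antisaccade", 0, events)])
    assert list(df.columns) == ["participant_id", "task", "trial_index",
                                "onset", "offset", "amplitude",
                                "peak_velocity"]
    assert len(df) == 1
    assert df.amplitude.iloc[0] == pytest.approx(9.7, abs=0.1)
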