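"""Behavioral biomarkers: predicates, definitions, degenerate inputs."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from startlekit import (
    baseline_regression,
    behavior_profile,
    mouth_metrics,
    postural_stability,
    pupil_range,
    read_session,
    side_eye,
    trial_event_fraction,
    write_session,
)
from startlekit.io import Frames, Session, StimulusSpec, Trial, default_layout
from conftest import flat_trial


def _session(trials):
    return Session(
        subject_id="s1", group="autism", age_years=7, sex="boy",
        co_occurring="none", trials_test1=trials, frame_rate_hz=60.0,
    )


def _edit(trial, index=None, **frame_cols):
    frames = dataclasses.replace(trial.frames, **frame_cols)
    return dataclasses.replace(trial, frames=frames, index=index or trial.index)


def test_zero_events_everywhere():
    sess = _session([dataclasses.replace(flat_trial(), index=i + 1) for i in range(4)])
    for kind in ("screen_avoidance", "headphone_touch", "vocalization", "head_rotation"):
        assert trial_event_fraction(sess, kind)["percent"] == 0.0


def test_event_fraction_arithmetic():
    trials = []
    for i in range(40):
        tr = flat_trial()
        if i < 4:
            v = np.zeros(len(tr.frames), dtype=bool)
            v[10:40] = True
            tr = _edit(tr, index=i + 1, vocalizing=v)
        else:
            tr = dataclasses.replace(tr, index=i + 1)
        trials.append(tr)
    sess = _session(trials)
    out = trial_event_fraction(sess, "vocalization")
    assert out["percent"] == pytest.approx(10.0)
    # 4 trials x 30 frames x 16.67 ms
    assert out["duration_ms"] == pytest.approx(4 * 30 * 1000 / 60.0, rel=1e-6)


def test_head_rotation_needs_sustained_excursion():
    tr = flat_trial()
    yaw = tr.frames.head_yaw_deg.copy()
    yaw[30:33] = 20.0  # 3 frames at 60 fps = 50 ms < 100 ms -> no event
    sess = _session([_edit(tr, head_yaw_deg=yaw)])
    assert trial_event_fraction(sess, "head_rotation")["percent"] == 0.0
    yaw[30:40] = 20.0  # 167 ms -> event
    sess = _session([_edit(tr, head_yaw_deg=yaw)])
    assert trial_event_fraction(sess, "head_rotation")["percent"] == 100.0


def test_postural_stability_values():
    tr = flat_trial()
    sess = _session([tr])
    assert postural_stability(sess) == 0.0
    bbox = np.tile([10.0, 14.0], len(tr.frames) // 2)
    sess = _session([_edit(tr, bbox=bbox)])
    n = len(bbox)
    assert postural_stability(sess) == pytest.approx(2.0 * np.sqrt(n / (n - 1)), rel=1e-9)


def test_mouth_metrics_constant_and_episode():
    tr = flat_trial()
    sess = _session([tr])
    mm = mouth_metrics(sess)
    assert mm["mean"] == pytest.approx(1.0)
    assert mm["open_durations_ms"] == []
    mouth = tr.frames.mouth_area.copy()
    mouth[60:78] = 5.0  # 18 frames = 300 ms above median+delta
    mm = mouth_metrics(_session([_edit(tr, mouth_area=mouth)]))
    assert len(mm["open_durations_ms"]) == 1
    assert mm["open_durations_ms"][0] == pytest.approx(300.0, rel=1e-6)


def test_pupil_range_definition():
    tr = flat_trial()
    assert pupil_range(_session([tr])) == 0.0
    px = tr.frames.pupil_x.copy()
    px[0], px[1] = -0.05, 0.05
    assert pupil_range(_session([_edit(tr, pupil_x=px)])) == pytest.approx(10.0)


def test_side_eye_rectified_definition():
    tr = flat_trial()
    assert side_eye(_session([tr])) == 0.0
    n = len(tr.frames)
    yaw = np.full(n, 20.0)
    assert side_eye(_session([_edit(tr, head_yaw_deg=yaw, pupil_x=np.full(n, -0.1))])) == pytest.approx(0.1)
    assert side_eye(_session([_edit(tr, head_yaw_deg=yaw, pupil_x=np.full(n, +0.1))])) == 0.0


def test_baseline_regression_identities():
    trials = [dataclasses.replace(flat_trial(), index=i + 1) for i in range(8)]
    intercept, resid_sd = baseline_regression(_session(trials))
    assert intercept == pytest.approx(0.0, abs=1e-9)
    assert resid_sd == pytest.approx(0.0, abs=1e-9)

    # v_t exactly linear in t -> zero residual SD, intercept = v at t=3
    rng = np.random.default_rng(0)
    trials = []
    for i in range(8):
        tr = flat_trial()
        v = (2.0 + 0.5 * (i + 1)) / 100.0
        nec = 0.3 + v * np.where(np.arange(len(tr.frames)) % 2 == 0, 1.0, -1.0)
        nec *= np.sqrt((len(tr.frames.t_ms[tr.frames.t_ms < 1000]) - 1) /
                       len(tr.frames.t_ms[tr.frames.t_ms < 1000]))
        trials.append(_edit(tr, index=i + 1, nec=np.clip(nec, 0, 1)))
    sess = _session(trials)
    intercept, resid_sd = baseline_regression(sess)
    assert resid_sd < 0.2
    assert intercept == pytest.approx(2.0 + 0.5 * 3.0, rel=0.05)


def test_baseline_regression_needs_six_trials():
    trials = [dataclasses.replace(flat_trial(), index=i + 1) for i in range(5)]
    intercept, resid_sd = baseline_regression(_session(trials))
    assert np.isnan(intercept) and np.isnan(resid_sd)


def test_profile_round_trip_stable(one_session, tmp_path):
    before = behavior_profile(one_session)
    back = read_session(write_session(one_session, tmp_path / "s.json"))
    after = behavior_profile(back)
    for k, v in vars(before).items():
        w = getattr(after, k)
        if isinstance(v, float):
            assert w == pytest.approx(v, abs=1e-9, nan_ok=True)
        else:
            assert w == v


def test_profile_bounds(small_cohort):
    sessions, _ = small_cohort
    for s in sessions[:6]:
        p = behavior_profile(s)
        for k in ("screen_avoidance_pct", "headphone_touch_pct", "vocalization_pct",
                  "head_rotation_pct"):
            assert 0.0 <= getattr(p, k) <= 100.0
        assert p.postural_sd >= 0 and p.baseline_sd >= 0 and p.side_eye >= 0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(1, 30), st.integers(0, 30))
def test_event_fraction_monotone(n_plain, n_flagged):
    """Adding a flagged trial never decreases the event fraction."""
    def build(k_flag, n_tot):
        trials = []
        for i in range(n_tot):
            tr = flat_trial()
            if i < k_flag:
                v = np.zeros(len(tr.frames), dtype=bool)
                v[0] = True
                tr = _edit(tr, index=i + 1, vocalizing=v)
            else:
                tr = dataclasses.replace(tr, index=i + 1)
            trials.append(tr)
        return _session(trials)

    base = trial_event_fraction(build(n_flagged, n_plain + n_flagged), "vocalization")["percent"]
    more = trial_event_fraction(
        build(n_flagged + 1, n_plain + n_flagged + 1), "vocalization"
    )["percent"]
    assert more >= base
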