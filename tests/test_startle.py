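"""Neurometric scoring: amplitudes, responder rule, %PPI, habituation, cumsum."""

import dataclasses

import numpy as np
import pytest

from startlekit import (
    classify_responder,
    cumsum_stats,
    longterm_habituation,
    ppi_percent,
    score_trial,
    shortterm_profile,
)
from startlekit.startle import RESPONDER_THRESHOLD, cumulative_trace
from conftest import flat_trial


def _with_nec(trial, nec):
    frames = dataclasses.replace(trial.frames, nec=np.asarray(nec, dtype=float))
    return dataclasses.replace(trial, frames=frames)


def test_flat_trace_scores_zero():
    out = score_trial(flat_trial(nec=0.1))
    assert out.amplitude == 0.0
    assert out.valid


def test_injected_peak_recovered():
    tr = flat_trial(nec=0.0)
    nec = np.zeros(len(tr.frames))
    t = tr.frames.t_ms
    inside = (t >= 1100) & (t < 1160)
    nec[inside] = 0.6
    out = score_trial(_with_nec(tr, nec))
    assert out.amplitude == pytest.approx(0.6, abs=1e-12)


def test_all_missing_frames_invalid():
    out = score_trial(flat_trial(detected=False))
    assert not out.valid
    assert all(not np.isfinite(a) for a in out.amplitudes)
    assert not np.isfinite(out.max_cumsum)


def test_partial_window_coverage_rule():
    tr = flat_trial(nec=0.1)
    det = tr.frames.face_detected.copy()
    # drop 60% of the startle-window frames -> window invalid
    win = tr.frames.in_window(tr.windows.startle_windows[0])
    idx = np.flatnonzero(win)
    det[idx[: int(0.6 * len(idx))]] = False
    frames = dataclasses.replace(tr.frames, face_detected=det)
    nec = frames.nec.copy()
    nec[~det] = np.nan
    frames = dataclasses.replace(frames, nec=nec)
    out = score_trial(dataclasses.replace(tr, frames=frames))
    assert not np.isfinite(out.amplitude)


@pytest.mark.parametrize(
    "amps,expect",
    [([0.02, 0.03, 0.05], False), ([0.075], True), ([0.074, 0.074, 0.074], False)],
)
def test_responder_rule(amps, expect):
    responder, med = classify_responder(amps)
    assert responder is expect
    assert med == pytest.approx(np.median(amps))


def test_responder_no_valid_trials():
    responder, med = classify_responder([np.nan, np.nan])
    assert responder is None and np.isnan(med)


@pytest.mark.parametrize(
    "pulse,pp,expect", [(0.4, 0.3, 25.0), (0.4, 0.4, 0.0), (0.4, 0.5, -25.0)]
)
def test_ppi_percent_arithmetic(pulse, pp, expect):
    assert ppi_percent(pulse, pp) == pytest.approx(expect)


def test_ppi_undefined_for_zero_pulse():
    assert np.isnan(ppi_percent(0.0, 0.2))


def test_longterm_perfect_decrease():
    slope, r = longterm_habituation([0.8, 0.7, 0.6, 0.5])
    assert r == pytest.approx(-1.0)
    assert slope == pytest.approx(-0.1)


def test_longterm_degenerate():
    slope, r = longterm_habituation([0.3, 0.3, 0.3, 0.3])
    assert slope == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(r)
    s2, r2 = longterm_habituation([0.3, 0.2])
    assert np.isnan(s2) and np.isnan(r2)


def test_shortterm_contrasts():
    from startlekit.startle import TrialOutcome

    outs = [
        TrialOutcome("s", "II", i, "rhythmic", [0.3] * 6, [0.1, 0.1], 1.0, True, True)
        for i in range(3)
    ]
    prof = shortterm_profile(outs, "rhythmic")
    assert np.allclose(prof["contrasts"], 0.0)
    assert prof["sensitized"] is False
    # one invalid window: that position drops out, others still scored
    outs[0].amplitudes[2] = np.nan
    prof = shortterm_profile(outs[:1], "rhythmic")
    assert np.isnan(prof["means"][2]) and np.isfinite(prof["means"][0])


def test_cumsum_stats_arithmetic():
    m, s = cumsum_stats([10.0, 20.0, 30.0])
    assert (m, s) == (20.0, 10.0)
    m, s = cumsum_stats([0.0, 0.0])
    assert (m, s) == (0.0, 0.0)
    m, s = cumsum_stats([5.0])
    assert m == 5.0 and np.isnan(s)


def test_cumsum_trace_monotone(one_session):
    for t in one_session.all_trials[:10]:
        _, cs = cumulative_trace(t)
        assert np.all(np.diff(cs) >= -1e-12)


def test_amplitude_frame_rate_invariance():
    """The same analytic waveform sampled at 30 vs 60 fps scores within the
    curvature of one frame period."""
    from startlekit.io import Frames, StimulusSpec, Trial, default_layout
    from startlekit.synth import startle_kernel

    stim = StimulusSpec(kind="pulse_only", onsets_ms=[1000.0])
    amps = {}
    for fps in (30.0, 60.0):
        n = int(2000 * fps / 1000)
        t = np.arange(n) / fps * 1000.0
        nec = 0.1 + 0.5 * startle_kernel(t - 1000.0)
        frames = Frames(
            t_ms=t, nec=nec, pupil_x=np.zeros(n), head_yaw_deg=np.zeros(n),
            bbox=np.full(n, 30.0), mouth_area=np.zeros(n),
            face_detected=np.ones(n, dtype=bool),
            vocalizing=np.zeros(n, dtype=bool), headphone_touch=np.zeros(n, dtype=bool),
        )
        trial = Trial(1, "I", stim, default_layout("I", stim), frames)
        amps[fps] = score_trial(trial).amplitude
    assert amps[30.0] == pytest.approx(amps[60.0], abs=0.02)
    assert amps[60.0] == pytest.approx(0.5, abs=0.01)
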