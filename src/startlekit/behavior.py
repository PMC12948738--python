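"""The 10 behavioral biomarkers, computed per subject over Tests I and II.

1. screen avoidance — % of trials with the face undetectable most of the trial
2. headphone touches — % of trials with a headphone-touch flag
3. non-syllabic vocalizations — % of trials with a vocalization flag (+duration)
4. anteroposterior postural stability — SD of the face bounding-box size
5. head rotations — % of trials with a sustained large head-yaw excursion
6. mouth openings — mean mouth surface area and open-episode durations
7. pupil range — mean horizontal pupil excursion per trial (% inter-ocular)
8. side eye — pupil deviation opposite to the head-turn direction
9. baseline regression intercept — baseline eyelid variability early in session
10. baseline regression SD — stability of that variability across the session

Event-predicate thresholds are configuration, not measurement: the defaults
(>50% missing-face frames, |yaw| > 15 deg sustained >= 100 ms, 5 deg
side-eye gate) are explicit reconstructions of common practice.
All SDs use the sample (n-1) convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Session, Trial

EVENT_KINDS = ("screen_avoidance", "headphone_touch", "vocalization", "head_rotation")


@dataclass
class BehaviorConfig:
    missing_face_frac: float = 0.5
    yaw_threshold_deg: float = 15.0
    yaw_sustain_ms: float = 100.0
    side_eye_gate_deg: float = 5.0
    mouth_open_delta: float = 1.5     # above the per-session median
    peri_window_ms: tuple = (-500.0, 1500.0)


DEFAULT_CONFIG = BehaviorConfig()


@dataclass
class BehaviorProfile:
    subject_id: str
    group: str
    screen_avoidance_pct: float = np.nan
    headphone_touch_pct: float = np.nan
    vocalization_pct: float = np.nan
    vocalization_duration_ms: float = np.nan
    postural_sd: float = np.nan
    head_rotation_pct: float = np.nan
    mouth_area_mean: float = np.nan
    mouth_open_duration_ms: float = np.nan
    pupil_range: float = np.nan
    side_eye: float = np.nan
    baseline_intercept: float = np.nan
    baseline_sd: float = np.nan


def _frame_period_ms(trial: Trial) -> float:
    t = trial.frames.t_ms
    return float(np.median(np.diff(t))) if t.size > 1 else np.nan


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of consecutive True values."""
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1) if edges.size else []
    stops = list(edges[~mask[edges + 1]] + 1) if edges.size else []
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        stops = stops + [mask.size]
    return list(zip(starts, stops))


def _trial_has_event(trial: Trial, kind: str, cfg: BehaviorConfig) -> bool:
    fr = trial.frames
    if kind == "screen_avoidance":
        return float((~fr.face_detected).mean()) > cfg.missing_face_frac
    if kind == "headphone_touch":
        return bool(fr.headphone_touch.any())
    if kind == "vocalization":
        return bool(fr.vocalizing.any())
    if kind == "head_rotation":
        period = _frame_period_ms(trial)
        if not np.isfinite(period):
            return False
        big = fr.face_detected & (np.abs(np.where(fr.face_detected, fr.head_yaw_deg, 0.0))
                                  > cfg.yaw_threshold_deg)
        need = int(np.ceil(cfg.yaw_sustain_ms / period))
        return any(stop - start >= need for start, stop in _runs(big))
    raise ValueError(f"unknown event kind {kind!r}")


def trial_event_fraction(
    session: Session, event_kind: str, cfg: BehaviorConfig = DEFAULT_CONFIG
) -> dict:
    """Percent of trials (both tests) meeting the event predicate.

    For vocalizations the summed flagged duration (ms) is also returned.
    """
    trials = session.all_trials
    if not trials:
        raise ValueError("session has no trials")
    hits = sum(_trial_has_event(t, event_kind, cfg) for t in trials)
    out = {"percent": 100.0 * hits / len(trials), "n_trials": len(trials)}
    if event_kind == "vocalization":
        dur = 0.0
        for t in trials:
            period = _frame_period_ms(t)
            if np.isfinite(period):
                dur += float(t.frames.vocalizing.sum()) * period
        out["duration_ms"] = dur
    return out


def postural_stability(session: Session) -> float:
    """Sample SD of the face bounding-box size over all detected frames."""
    vals = np.concatenate(
        [t.frames.bbox[t.frames.face_detected] for t in session.all_trials]
    ) if session.all_trials else np.array([])
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        return np.nan
    return float(vals.std(ddof=1))


def mouth_metrics(session: Session, cfg: BehaviorConfig = DEFAULT_CONFIG) -> dict:
    """Mean mouth area, open-episode durations, and the peri-stimulus trace.

    Open episodes are runs of mouth area above the per-session median plus
    ``cfg.mouth_open_delta``; the peri-stimulus trace averages the
    baseline-corrected mouth area around every pulse onset.
    """
    all_vals = np.concatenate(
        [t.frames.mouth_area[t.frames.face_detected] for t in session.all_trials]
    ) if session.all_trials else np.array([])
    all_vals = all_vals[np.isfinite(all_vals)]
    if all_vals.size == 0:
        return {"mean": np.nan, "open_durations_ms": [], "total_open_ms": np.nan,
                "peri_t_ms": np.array([]), "peri_trace": np.array([])}
    thresh = float(np.median(all_vals)) + cfg.mouth_open_delta

    durations = []
    traces = []
    peri_t = None
    for t in session.all_trials:
        period = _frame_period_ms(t)
        fr = t.frames
        above = fr.face_detected & (np.where(fr.face_detected, fr.mouth_area, -np.inf) > thresh)
        for start, stop in _runs(above):
            durations.append((stop - start) * period)
        lo, hi = cfg.peri_window_ms
        for o in t.stimulus.pulse_onsets_ms:
            sel = (fr.t_ms >= o + lo) & (fr.t_ms < o + hi) & fr.face_detected
            pre = (fr.t_ms >= o + lo) & (fr.t_ms < o) & fr.face_detected
            if sel.sum() < 3 or pre.sum() < 2:
                continue
            rel = fr.t_ms[sel] - o
            grid = lo + period * np.arange(int(round((hi - lo) / period)))
            tr = np.interp(grid, rel, fr.mouth_area[sel] - np.nanmean(fr.mouth_area[pre]))
            traces.append(tr)
            peri_t = grid
    peri = np.mean(traces, axis=0) if traces else np.array([])
    return {
        "mean": float(all_vals.mean()),
        "open_durations_ms": durations,
        "total_open_ms": float(np.sum(durations)) if durations else 0.0,
        "peri_t_ms": peri_t if peri_t is not None else np.array([]),
        "peri_trace": peri,
    }


def pupil_range(session: Session) -> float:
    """Mean per-trial horizontal pupil excursion, x100 (% inter-ocular distance)."""
    ranges = []
    for t in session.all_trials:
        v = t.frames.pupil_x[t.frames.face_detected]
        v = v[np.isfinite(v)]
        if v.size >= 2:
            ranges.append(float(v.max() - v.min()))
    if not ranges:
        return np.nan
    return 100.0 * float(np.mean(ranges))


def side_eye(session: Session, cfg: BehaviorConfig = DEFAULT_CONFIG) -> float:
    """Mean counter-rotation of the pupil on frames with a turned head.

    Over frames with |yaw| above the gate: ``max(0, -sign(yaw) * pupil_x)``
    (rectified, so pupil movement in the head's own direction scores zero);
    0.0 when no frame qualifies.
    """
    num, count = 0.0, 0
    for t in session.all_trials:
        fr = t.frames
        ok = fr.face_detected & np.isfinite(fr.head_yaw_deg) & np.isfinite(fr.pupil_x)
        sel = ok & (np.abs(np.where(ok, fr.head_yaw_deg, 0.0)) > cfg.side_eye_gate_deg)
        if sel.any():
            contrib = np.maximum(0.0, -np.sign(fr.head_yaw_deg[sel]) * fr.pupil_x[sel])
            num += float(contrib.sum())
            count += int(sel.sum())
    return num / count if count else 0.0


def baseline_regression(session: Session, min_trials: int = 6) -> tuple[float, float]:
    """Baseline eyelid-variability regression over the session.

    Per trial t, ``v_t`` = sample SD of NEC in the baseline window, x100.
    OLS fit ``v_t = a + b*t`` over all usable trials; returns the predicted
    value at the centre of trials 1-5 (``a + 3b``) and the SD of residuals.
    """
    v, tn = [], []
    for i, tr in enumerate(session.all_trials, start=1):
        mask = tr.frames.in_window(tr.windows.baseline_ms) & tr.frames.face_detected
        n_all = int(tr.frames.in_window(tr.windows.baseline_ms).sum())
        if n_all == 0 or mask.sum() < max(2, 0.5 * n_all):
            continue
        v.append(100.0 * float(tr.frames.nec[mask].std(ddof=1)))
        tn.append(float(i))
    if len(v) < min_trials:
        return np.nan, np.nan
    v_arr, t_arr = np.asarray(v), np.asarray(tn)
    b, a = np.polyfit(t_arr, v_arr, 1)
    resid = v_arr - (a + b * t_arr)
    return float(a + b * 3.0), float(resid.std(ddof=1))


def behavior_profile(session: Session, cfg: BehaviorConfig = DEFAULT_CONFIG) -> BehaviorProfile:
    """All 10 biomarkers for one subject."""
    prof = BehaviorProfile(subject_id=session.subject_id, group=session.group)
    prof.screen_avoidance_pct = trial_event_fraction(session, "screen_avoidance", cfg)["percent"]
    prof.headphone_touch_pct = trial_event_fraction(session, "headphone_touch", cfg)["percent"]
    voc = trial_event_fraction(session, "vocalization", cfg)
    prof.vocalization_pct = voc["percent"]
    prof.vocalization_duration_ms = voc.get("duration_ms", np.nan)
    prof.head_rotation_pct = trial_event_fraction(session, "head_rotation", cfg)["percent"]
    prof.postural_sd = postural_stability(session)
    mm = mouth_metrics(session, cfg)
    prof.mouth_area_mean = mm["mean"]
    prof.mouth_open_duration_ms = mm["total_open_ms"]
    prof.pupil_range = pupil_range(session)
    prof.side_eye = side_eye(session, cfg)
    prof.baseline_intercept, prof.baseline_sd = baseline_regression(session)
    return prof


def behavior_table(sessions: list[Session], cfg: BehaviorConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """One-row-per-subject biomarker table."""
    rows = []
    for sess in sessions:
        p = behavior_profile(sess, cfg)
        row = {k: getattr(p, k) for k in vars(p)}
        row["age_years"] = sess.age_years
        row["sex"] = sess.sex
        rows.append(row)
    return pd.DataFrame(rows)


def event_trial_table(
    sessions: list[Session], cfg: BehaviorConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Trial-level binary event table for multilevel logistic models."""
    rows = []
    for sess in sessions:
        for t in sess.all_trials:
            row = dict(
                subject_id=sess.subject_id, group=sess.group,
                age_years=sess.age_years, sex=sess.sex,
                test=t.test, trial=t.index,
            )
            for kind in EVENT_KINDS:
                row[kind] = int(_trial_has_event(t, kind, cfg))
            rows.append(row)
    return pd.DataFrame(rows)
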