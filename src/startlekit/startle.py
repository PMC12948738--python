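"""Neurometric outcome extraction.

From per-trial eyelid traces to subject-level summaries: acoustic startle
response (ASR) amplitudes, prepulse inhibition (%PPI), long-term and
short-term habituation, anticipatory eyeblinks (AEB) in observation
windows, and the cumulative sum of the eyelid amplitude in Test II trains.

Amplitude convention: baseline-corrected window maximum, i.e.
``max(NEC in window) - median(NEC in baseline)``, floored at zero — the
standard eyeblink estimator.  Windows with fewer than half their frames
face-detected are marked invalid.  Subjects whose median pulse-only
amplitude falls below ``RESPONDER_THRESHOLD`` are non-responders and are
excluded from %PPI summaries (the boundary value counts as a responder).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Session, Trial

RESPONDER_THRESHOLD = 0.075
MIN_WINDOW_COVERAGE = 0.5
PREPULSE_KINDS = ("pp5", "pp10", "pp25")


@dataclass
class TrialOutcome:
    subject_id: str
    test: str
    index: int
    condition: str
    amplitudes: list        # one per startle window (S1..S6 for Test II); NaN = invalid
    aeb: list               # one per observation window; NaN = invalid
    max_cumsum: float       # NEC-seconds; NaN if the trial is invalid
    baseline_valid: bool
    valid: bool

    @property
    def amplitude(self) -> float:
        """Single-window amplitude (Test I convenience accessor)."""
        return self.amplitudes[0] if self.amplitudes else np.nan


def _window_stats(trial: Trial, window) -> tuple[np.ndarray, bool]:
    mask = trial.frames.in_window(window)
    det = mask & trial.frames.face_detected
    n_all = int(mask.sum())
    ok = n_all > 0 and det.sum() >= MIN_WINDOW_COVERAGE * n_all and det.sum() >= 1
    return det, ok


def score_trial(trial: Trial, subject_id: str = "") -> TrialOutcome:
    """Score one trial: window amplitudes, anticipatory blinks, cumulative sum."""
    fr = trial.frames
    base_det, base_ok = _window_stats(trial, trial.windows.baseline_ms)
    base_med = float(np.median(fr.nec[base_det])) if base_ok else np.nan

    def corrected_max(window) -> float:
        det, ok = _window_stats(trial, window)
        if not (ok and base_ok):
            return np.nan
        return max(float(np.max(fr.nec[det])) - base_med, 0.0)

    amplitudes = [corrected_max(w) for w in trial.windows.startle_windows]
    aeb = [corrected_max(w) for w in trial.windows.observation_windows]

    if base_ok:
        det = fr.face_detected
        tt = fr.t_ms[det]
        corr = np.maximum(fr.nec[det] - base_med, 0.0)
        if tt.size >= 2:
            dt = np.diff(tt, prepend=tt[0] - np.median(np.diff(tt))) / 1000.0
            csum = np.cumsum(corr * dt)
            max_cumsum = float(csum[-1])  # integrand >= 0 => cumsum is non-decreasing
        else:
            max_cumsum = np.nan
    else:
        max_cumsum = np.nan

    return TrialOutcome(
        subject_id=subject_id,
        test=trial.test,
        index=trial.index,
        condition=trial.condition,
        amplitudes=amplitudes,
        aeb=aeb,
        max_cumsum=max_cumsum,
        baseline_valid=base_ok,
        valid=base_ok and any(np.isfinite(a) for a in amplitudes),
    )


def cumulative_trace(trial: Trial) -> tuple[np.ndarray, np.ndarray]:
    """(t_ms, cumulative NEC-seconds) over detected frames, baseline-corrected."""
    fr = trial.frames
    base_det, base_ok = _window_stats(trial, trial.windows.baseline_ms)
    if not base_ok:
        return np.array([]), np.array([])
    base_med = float(np.median(fr.nec[base_det]))
    det = fr.face_detected
    tt = fr.t_ms[det]
    corr = np.maximum(fr.nec[det] - base_med, 0.0)
    dt = np.diff(tt, prepend=tt[0] - np.median(np.diff(tt))) / 1000.0
    return tt, np.cumsum(corr * dt)


def score_session(session: Session) -> list[TrialOutcome]:
    return [score_trial(t, subject_id=session.subject_id) for t in session.all_trials]


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def amplitude_table(sessions: list[Session]) -> pd.DataFrame:
    """Long trial-level table: one row per scored startle/observation window."""
    rows = []
    for sess in sessions:
        meta = dict(
            subject_id=sess.subject_id, group=sess.group,
            age_years=sess.age_years, sex=sess.sex,
        )
        pulse_only_no = 0
        for out in score_session(sess):
            if out.test == "I" and out.condition == "pulse_only":
                pulse_only_no += 1
            for w, a in enumerate(out.amplitudes):
                rows.append(
                    dict(
                        meta, test=out.test, trial=out.index, condition=out.condition,
                        window=f"S{w + 1}", amplitude=a,
                        pulse_only_no=pulse_only_no if (out.test == "I" and out.condition == "pulse_only") else np.nan,
                    )
                )
            for w, a in enumerate(out.aeb):
                rows.append(
                    dict(
                        meta, test=out.test, trial=out.index, condition=out.condition,
                        window=f"OW{w + 1}", amplitude=a, pulse_only_no=np.nan,
                    )
                )
    return pd.DataFrame(rows)


def cumsum_table(sessions: list[Session]) -> pd.DataFrame:
    """One row per Test II trial with its maximum cumulative sum (NEC-seconds)."""
    rows = []
    for sess in sessions:
        for out in score_session(sess):
            if out.test != "II":
                continue
            rows.append(
                dict(
                    subject_id=sess.subject_id, group=sess.group,
                    age_years=sess.age_years, sex=sess.sex,
                    trial=out.index, condition=out.condition,
                    max_cumsum=out.max_cumsum,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subject-level summaries
# ---------------------------------------------------------------------------

def classify_responder(pulse_only_amplitudes) -> tuple[bool | None, float]:
    """Responder rule: median pulse-only amplitude >= 0.075 (boundary inclusive).

    Returns ``(None, nan)`` when no valid pulse-only trial exists; such a
    subject is excluded from %PPI summaries.
    """
    a = np.asarray(pulse_only_amplitudes, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return None, np.nan
    med = float(np.median(a))
    return med >= RESPONDER_THRESHOLD, med


def ppi_percent(median_pulse: float, median_prepulse: float) -> float:
    """%PPI = 100 x (1 - prepulse/pulse); negative values mean facilitation."""
    if not np.isfinite(median_pulse) or median_pulse <= 0:
        return np.nan
    return 100.0 * (1.0 - median_prepulse / median_pulse)


def longterm_habituation(amplitudes_in_order) -> tuple[float, float]:
    """OLS slope of amplitude on pulse-only trial number, plus Pearson r.

    Requires >= 3 valid trials; r is NaN (missing, not zero) when the
    amplitudes have no variance.
    """
    a = np.asarray(amplitudes_in_order, dtype=float)
    t = np.arange(1, a.size + 1, dtype=float)
    ok = np.isfinite(a)
    a, t = a[ok], t[ok]
    if a.size < 3:
        return np.nan, np.nan
    slope = float(np.polyfit(t, a, 1)[0])
    if np.std(a) < 1e-12 or np.std(t) < 1e-12:
        return slope, np.nan
    r = float(np.corrcoef(t, a)[0, 1])
    return slope, r


def shortterm_profile(trial_outcomes: list[TrialOutcome], pattern: str) -> dict:
    """Per-pulse-position mean amplitudes and S1-vs-Sk contrasts for one pattern."""
    trials = [o for o in trial_outcomes if o.test == "II" and o.condition == pattern]
    if not trials:
        return {"means": [np.nan] * 6, "contrasts": [np.nan] * 5, "sensitized": None}
    arr = np.array([o.amplitudes for o in trials], dtype=float)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(arr, axis=0)
    contrasts = [means[k] - means[0] for k in range(1, len(means))]
    sensitized = bool(np.nanmax(means[1:]) > means[0]) if np.isfinite(means[0]) else None
    return {"means": means.tolist(), "contrasts": contrasts, "sensitized": sensitized}


def cumsum_stats(max_cumsums) -> tuple[float, float]:
    """Mean and sample SD of the per-trial maximum cumulative sum (NaN SD if < 2)."""
    v = np.asarray(max_cumsums, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.nan, np.nan
    return float(v.mean()), float(v.std(ddof=1)) if v.size >= 2 else np.nan


@dataclass
class SubjectNeurometrics:
    subject_id: str
    group: str
    median_asr: float
    responder: bool | None
    mean_amp: dict = field(default_factory=dict)
    sd_amp: dict = field(default_factory=dict)
    ppi_percent: dict = field(default_factory=dict)
    longterm_slope: float = np.nan
    longterm_r: float = np.nan
    shortterm: dict = field(default_factory=dict)
    aeb_mean: dict = field(default_factory=dict)
    cumsum_mean: dict = field(default_factory=dict)
    cumsum_sd: dict = field(default_factory=dict)


def subject_neurometrics(session: Session) -> SubjectNeurometrics:
    """All neurometric summaries for one subject."""
    outs = score_session(session)
    t1 = [o for o in outs if o.test == "I"]

    by_cond: dict[str, list[float]] = {}
    for o in t1:
        by_cond.setdefault(o.condition, []).append(o.amplitude)
    pulse = np.asarray(by_cond.get("pulse_only", []), dtype=float)
    responder, med = classify_responder(pulse)

    mean_amp, sd_amp, medians = {}, {}, {}
    for c, vals in by_cond.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        mean_amp[c] = float(v.mean()) if v.size else np.nan
        sd_amp[c] = float(v.std(ddof=1)) if v.size >= 2 else np.nan
        medians[c] = float(np.median(v)) if v.size else np.nan

    ppi = {}
    for kind in PREPULSE_KINDS:
        if responder and kind in medians and med > 0:
            ppi[kind] = ppi_percent(med, medians[kind])
        else:
            ppi[kind] = np.nan

    slope, r = longterm_habituation(
        [o.amplitude for o in t1 if o.condition == "pulse_only"]
    )

    st = {p: shortterm_profile(outs, p) for p in ("rhythmic", "random")}
    aeb_mean, cmean, csd = {}, {}, {}
    for p in ("rhythmic", "random"):
        tr = [o for o in outs if o.test == "II" and o.condition == p]
        if tr:
            arr = np.array([o.aeb for o in tr], dtype=float)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ow = np.nanmean(arr, axis=0)
            for w, v in enumerate(ow):
                aeb_mean[(p, f"OW{w + 1}")] = float(v)
        m, s = cumsum_stats([o.max_cumsum for o in tr])
        cmean[p], csd[p] = m, s

    return SubjectNeurometrics(
        subject_id=session.subject_id,
        group=session.group,
        median_asr=med,
        responder=responder,
        mean_amp=mean_amp,
        sd_amp=sd_amp,
        ppi_percent=ppi,
        longterm_slope=slope,
        longterm_r=r,
        shortterm=st,
        aeb_mean=aeb_mean,
        cumsum_mean=cmean,
        cumsum_sd=csd,
    )


def neurometrics_table(sessions: list[Session]) -> pd.DataFrame:
    """Flat one-row-per-subject neurometrics table."""
    rows = []
    for sess in sessions:
        nm = subject_neurometrics(sess)
        row = dict(
            subject_id=nm.subject_id, group=nm.group,
            age_years=sess.age_years, sex=sess.sex,
            median_asr=nm.median_asr,
            responder=nm.responder,
            longterm_slope=nm.longterm_slope,
            longterm_r=nm.longterm_r,
        )
        for c in ("pulse_only",) + PREPULSE_KINDS:
            row[f"amp_{c}_mean"] = nm.mean_amp.get(c, np.nan)
            row[f"amp_{c}_sd"] = nm.sd_amp.get(c, np.nan)
        for kind in PREPULSE_KINDS:
            row[f"ppi_{kind}"] = nm.ppi_percent.get(kind, np.nan)
        for p in ("rhythmic", "random"):
            for k in range(6):
                row[f"st_{p}_s{k + 1}"] = nm.shortterm[p]["means"][k]
            row[f"cumsum_{p}_mean"] = nm.cumsum_mean.get(p, np.nan)
            row[f"cumsum_{p}_sd"] = nm.cumsum_sd.get(p, np.nan)
            for w in ("OW1", "OW2"):
                row[f"aeb_{p}_{w.lower()}"] = nm.aeb_mean.get((p, w), np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
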