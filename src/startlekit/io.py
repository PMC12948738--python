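"""Domain types, window arithmetic and session (de)serialization.

A *session* is one child's visit: up to two 15-minute tests delivered on a
smartphone while the front camera tracks facial landmarks.  Test I is a
prepulse-inhibition design (pulse-only trials interleaved with
prepulse+pulse trials at three prepulse intensities); Test II delivers
six-pulse trains with either a rhythmic (constant inter-onset interval) or
random (irregular) schedule, plus scheduled-but-omitted onsets used to score
anticipatory eyeblinks.

Conventions
-----------
* Time is milliseconds from trial start; all intervals are half-open
  ``[start, end)`` so frame binning is unambiguous.
* Frames carry a normalized eyelid closure (NEC) in ``[0, 1]``
  (0 = fully open, 1 = fully closed), a signed horizontal pupil offset
  (fraction of inter-ocular distance), signed head yaw in degrees, the face
  bounding-box size (percent of frame width), a mouth-opening surface area,
  and three boolean channels (face detected, vocalizing, headphone touch).
* Frames where the face was not detected carry non-finite trace values and
  are excluded from window statistics; they are never interpolated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1"

STIMULUS_KINDS = ("pulse_only", "pp5", "pp10", "pp25", "rhythmic", "random")
PREPULSE_FRACTIONS = {"pulse_only": 0.0, "pp5": 0.05, "pp10": 0.10, "pp25": 0.25}
GROUPS = ("autism", "neurotypical")
SEXES = ("girl", "boy")
CO_OCCURRING = ("none", "adhd", "id", "adhd_id", "unknown")

#: default timing parameters; overridable via :func:`default_layout` kwargs.
BASELINE_MS = 1000.0
TEST1_WINDOW = (20.0, 500.0)   # relative to pulse onset
TEST2_WINDOW = (20.0, 400.0)   # relative to each (scheduled) onset
PREPULSE_LEAD_MS = 120.0       # prepulse onset -> pulse onset


class SessionValidationError(ValueError):
    """A session or trial violates a structural invariant."""


class LayoutError(ValueError):
    """A window layout is inconsistent (overlap, ordering, coverage)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StimulusSpec:
    """One trial's auditory schedule.

    ``onsets_ms`` are the delivered stimulus onsets relative to trial start
    (for ``pp*`` kinds: ``[prepulse_onset, pulse_onset]``).
    ``omitted_onsets_ms`` are scheduled-but-omitted onsets (Test II only),
    around which anticipatory eyeblinks are scored.
    """

    kind: str
    onsets_ms: list[float]
    omitted_onsets_ms: list[float] = field(default_factory=list)
    pulse_duration_ms: float = 50.0
    prepulse_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise SessionValidationError(f"unknown stimulus kind {self.kind!r}")
        if self.pulse_duration_ms <= 0:
            raise SessionValidationError("pulse_duration_ms must be > 0")
        on = np.asarray(self.onsets_ms, dtype=float)
        if on.size == 0:
            raise SessionValidationError("stimulus has no onsets")
        if np.any(np.diff(on) <= 0):
            raise SessionValidationError("onsets_ms must be strictly increasing")
        if self.kind in ("pp5", "pp10", "pp25"):
            if len(self.onsets_ms) != 2:
                raise SessionValidationError(
                    f"{self.kind} requires exactly one prepulse onset before one pulse onset"
                )
            expect = PREPULSE_FRACTIONS[self.kind]
            if self.prepulse_fraction == 0.0:
                self.prepulse_fraction = expect
        if self.kind == "rhythmic" and len(self.onsets_ms) > 2:
            isi = np.diff(on)
            if not np.allclose(isi, isi[0]):
                raise SessionValidationError("rhythmic pattern requires a constant inter-onset interval")

    @property
    def pulse_onsets_ms(self) -> list[float]:
        """Onsets of startle-eliciting pulses (excludes the prepulse)."""
        if self.kind in ("pp5", "pp10", "pp25"):
            return [self.onsets_ms[-1]]
        return list(self.onsets_ms)


@dataclass
class WindowLayout:
    """Scoring intervals for one trial, all half-open ``[start, end)`` ms."""

    baseline_ms: tuple[float, float]
    startle_windows: list[tuple[float, float]]
    observation_windows: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.baseline_ms = tuple(float(x) for x in self.baseline_ms)
        self.startle_windows = [tuple(float(x) for x in w) for w in self.startle_windows]
        self.observation_windows = [tuple(float(x) for x in w) for w in self.observation_windows]
        for name, (a, b) in self.iter_windows():
            if not b > a:
                raise LayoutError(f"window {name} is empty or reversed: [{a}, {b})")
        wins = sorted(w for _, w in self.iter_windows())
        for (a0, b0), (a1, b1) in zip(wins, wins[1:]):
            if a1 < b0:
                raise LayoutError(
                    f"windows overlap: [{a0}, {b0}) and [{a1}, {b1})"
                )

    def iter_windows(self):
        yield "baseline", self.baseline_ms
        for i, w in enumerate(self.startle_windows):
            yield f"S{i + 1}", w
        for i, w in enumerate(self.observation_windows):
            yield f"OW{i + 1}", w

    @property
    def end_ms(self) -> float:
        return max(b for _, (_, b) in self.iter_windows())


@dataclass
class Frames:
    """Columnar per-frame traces of one trial (arrays share one length)."""

    t_ms: np.ndarray
    nec: np.ndarray
    pupil_x: np.ndarray
    head_yaw_deg: np.ndarray
    bbox: np.ndarray
    mouth_area: np.ndarray
    face_detected: np.ndarray
    vocalizing: np.ndarray
    headphone_touch: np.ndarray

    FLOAT_COLS = ("t_ms", "nec", "pupil_x", "head_yaw_deg", "bbox", "mouth_area")
    BOOL_COLS = ("face_detected", "vocalizing", "headphone_touch")
    COLS = FLOAT_COLS + BOOL_COLS

    def __post_init__(self) -> None:
        for c in self.FLOAT_COLS:
            setattr(self, c, np.asarray(getattr(self, c), dtype=float))
        for c in self.BOOL_COLS:
            setattr(self, c, np.asarray(getattr(self, c), dtype=bool))
        n = len(self.t_ms)
        for c in self.COLS:
            if len(getattr(self, c)) != n:
                raise SessionValidationError(f"frame column {c!r} length mismatch")

    def __len__(self) -> int:
        return len(self.t_ms)

    def validate(self, where: str = "") -> None:
        if np.any(np.diff(self.t_ms) < 0):
            raise SessionValidationError(f"{where}: t_ms not non-decreasing")
        det = self.face_detected
        nec = self.nec[det]
        if nec.size and (np.nanmin(nec) < 0 or np.nanmax(nec) > 1):
            raise SessionValidationError(f"{where}: nec out of [0,1]")
        for c in ("nec", "pupil_x", "head_yaw_deg", "bbox", "mouth_area"):
            v = getattr(self, c)
            if np.any(~np.isfinite(v) & det):
                raise SessionValidationError(
                    f"{where}: non-finite {c} on a face-detected frame"
                )

    def in_window(self, window: tuple[float, float]) -> np.ndarray:
        a, b = window
        return (self.t_ms >= a) & (self.t_ms < b)


@dataclass
class Trial:
    index: int
    test: str  # "I" or "II"
    stimulus: StimulusSpec
    windows: WindowLayout
    frames: Frames

    def validate(self, where: str = "") -> None:
        if self.test not in ("I", "II"):
            raise SessionValidationError(f"{where}: test must be 'I' or 'II'")
        self.frames.validate(where=f"{where} trial {self.index}")
        if len(self.frames):
            t0, t1 = self.frames.t_ms[0], self.frames.t_ms[-1]
            if t0 > self.windows.baseline_ms[0] or t1 < self.windows.end_ms - 1000.0 / 15:
                raise SessionValidationError(
                    f"{where} trial {self.index}: frame span [{t0}, {t1}] does not "
                    f"cover baseline through last window"
                )

    @property
    def condition(self) -> str:
        return self.stimulus.kind


@dataclass
class Session:
    subject_id: str
    group: str
    age_years: float
    sex: str
    co_occurring: str = "unknown"
    trials_test1: list[Trial] = field(default_factory=list)
    trials_test2: list[Trial] = field(default_factory=list)
    frame_rate_hz: float = 60.0

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise SessionValidationError(f"group must be one of {GROUPS}")
        if self.sex not in SEXES:
            raise SessionValidationError(f"sex must be one of {SEXES}")
        if self.co_occurring not in CO_OCCURRING:
            raise SessionValidationError(f"co_occurring must be one of {CO_OCCURRING}")
        if not (self.trials_test1 or self.trials_test2):
            raise SessionValidationError("session must contain at least one test")
        if not 3 <= self.age_years <= 12:
            import warnings

            warnings.warn(
                f"subject {self.subject_id}: age {self.age_years} outside the 3-12 y "
                f"range of comparable cohorts",
                stacklevel=2,
            )
        for name, trials in (("I", self.trials_test1), ("II", self.trials_test2)):
            idx = [t.index for t in trials]
            if len(idx) != len(set(idx)):
                raise SessionValidationError(f"duplicate trial index in test {name}")
            for t in trials:
                t.validate(where=f"subject {self.subject_id} test {name}")

    @property
    def all_trials(self) -> list[Trial]:
        return list(self.trials_test1) + list(self.trials_test2)


# ---------------------------------------------------------------------------
# window arithmetic
# ---------------------------------------------------------------------------

def default_layout(
    test: str,
    stimulus: StimulusSpec,
    *,
    baseline_ms: float = BASELINE_MS,
    test1_window: tuple[float, float] = TEST1_WINDOW,
    test2_window: tuple[float, float] = TEST2_WINDOW,
) -> WindowLayout:
    """Default scoring layout for a trial.

    Test I: one startle window ``[pulse+20, pulse+500)``.  Test II: one
    window per delivered pulse and one observation window per omitted onset,
    each ``[onset+20, onset+400)`` but truncated at the next scheduled onset
    so that windows never overlap even for short inter-onset intervals.
    """
    first = stimulus.onsets_ms[0]
    baseline = (first - baseline_ms, first)
    if test == "I":
        pulse = stimulus.pulse_onsets_ms[-1]
        a, b = test1_window
        return WindowLayout(baseline, [(pulse + a, pulse + b)])
    if test != "II":
        raise LayoutError(f"unknown test {test!r}")
    a, b = test2_window
    scheduled = sorted(list(stimulus.onsets_ms) + list(stimulus.omitted_onsets_ms))
    nxt = {o: scheduled[i + 1] if i + 1 < len(scheduled) else np.inf
           for i, o in enumerate(scheduled)}

    def win(o: float) -> tuple[float, float]:
        end = min(o + b, nxt[o])
        if end <= o + a:
            raise LayoutError(f"window at onset {o} truncated to nothing (ISI too short)")
        return (o + a, end)

    startle = [win(o) for o in stimulus.pulse_onsets_ms]
    obs = [win(o) for o in sorted(stimulus.omitted_onsets_ms)]
    return WindowLayout(baseline, startle, obs)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _floats_out(arr: np.ndarray) -> list:
    # NaN is not valid JSON; encode missing samples as null
    return [None if not np.isfinite(x) else float(x) for x in arr]


def _floats_in(vals: Sequence, key: str) -> np.ndarray:
    try:
        return np.array([np.nan if v is None else float(v) for v in vals], dtype=float)
    except (TypeError, ValueError) as e:
        raise SessionValidationError(f"cannot parse numeric array {key!r}: {e}") from e


def session_to_dict(session: Session) -> dict:
    def trial_out(t: Trial) -> dict:
        return {
            "index": t.index,
            "test": t.test,
            "stimulus": {
                "kind": t.stimulus.kind,
                "onsets_ms": list(map(float, t.stimulus.onsets_ms)),
                "omitted_onsets_ms": list(map(float, t.stimulus.omitted_onsets_ms)),
                "pulse_duration_ms": float(t.stimulus.pulse_duration_ms),
                "prepulse_fraction": float(t.stimulus.prepulse_fraction),
            },
            "windows": {
                "baseline_ms": list(t.windows.baseline_ms),
                "startle_windows": [list(w) for w in t.windows.startle_windows],
                "observation_windows": [list(w) for w in t.windows.observation_windows],
            },
            "frames": {
                **{c: _floats_out(getattr(t.frames, c)) for c in Frames.FLOAT_COLS},
                # booleans are serialized explicitly, never omitted
                **{c: [bool(v) for v in getattr(t.frames, c)] for c in Frames.BOOL_COLS},
            },
        }

    return {
        "schema_version": SCHEMA_VERSION,
        "subject_id": session.subject_id,
        "group": session.group,
        "age_years": float(session.age_years),
        "sex": session.sex,
        "co_occurring": session.co_occurring,
        "frame_rate_hz": float(session.frame_rate_hz),
        "trials": [trial_out(t) for t in session.all_trials],
    }


def session_from_dict(doc: dict) -> Session:
    for key in ("subject_id", "group", "age_years", "sex", "frame_rate_hz", "trials"):
        if key not in doc:
            raise SessionValidationError(f"missing required key {key!r}")
    t1, t2 = [], []
    for i, td in enumerate(doc["trials"]):
        for key in ("index", "test", "stimulus", "frames"):
            if key not in td:
                raise SessionValidationError(f"trial #{i}: missing key {key!r}")
        sd = td["stimulus"]
        stim = StimulusSpec(
            kind=sd["kind"],
            onsets_ms=[float(x) for x in sd["onsets_ms"]],
            omitted_onsets_ms=[float(x) for x in sd.get("omitted_onsets_ms", [])],
            pulse_duration_ms=float(sd.get("pulse_duration_ms", 50.0)),
            prepulse_fraction=float(sd.get("prepulse_fraction", 0.0)),
        )
        if "windows" in td:
            wd = td["windows"]
            layout = WindowLayout(
                tuple(wd["baseline_ms"]),
                [tuple(w) for w in wd["startle_windows"]],
                [tuple(w) for w in wd.get("observation_windows", [])],
            )
        else:
            layout = default_layout(td["test"], stim)
        fd = td["frames"]
        frames = Frames(
            **{c: _floats_in(fd[c], c) for c in Frames.FLOAT_COLS},
            **{c: np.asarray(fd[c], dtype=bool) for c in Frames.BOOL_COLS},
        )
        order = np.argsort(frames.t_ms, kind="stable")
        if not np.all(order == np.arange(len(order))):
            frames = Frames(**{c: getattr(frames, c)[order] for c in Frames.COLS})
        trial = Trial(int(td["index"]), td["test"], stim, layout, frames)
        (t1 if trial.test == "I" else t2).append(trial)
    sess = Session(
        subject_id=str(doc["subject_id"]),
        group=doc["group"],
        age_years=float(doc["age_years"]),
        sex=doc["sex"],
        co_occurring=doc.get("co_occurring", "unknown"),
        trials_test1=t1,
        trials_test2=t2,
        frame_rate_hz=float(doc["frame_rate_hz"]),
    )
    sess.validate()
    return sess


def read_session(path: str | Path) -> Session:
    """Read and validate a session JSON file."""
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise SessionValidationError(f"{path}: malformed JSON: {e}") from e
    return session_from_dict(doc)


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session to JSON; ``read_session`` round-trips losslessly."""
    session.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(session_to_dict(session), fh, allow_nan=False)
    return path


def session_to_long_frame(session: Session) -> pd.DataFrame:
    """Long-format per-frame export (one row per frame)."""
    recs = []
    for test, trials in (("I", session.trials_test1), ("II", session.trials_test2)):
        for t in trials:
            df = pd.DataFrame({c: getattr(t.frames, c) for c in Frames.COLS})
            df.insert(0, "condition", t.condition)
            df.insert(0, "trial", t.index)
            df.insert(0, "test", test)
            df.insert(0, "subject_id", session.subject_id)
            recs.append(df)
    return pd.concat(recs, ignore_index=True)


def sessions_equal(a: Session, b: Session, tol: float = 1e-9) -> bool:
    """Field-by-field equality (numeric tolerance ``tol``, exact labels/bools)."""
    da, db = session_to_dict(a), session_to_dict(b)

    def eq(x, y):
        if isinstance(x, dict):
            return isinstance(y, dict) and x.keys() == y.keys() and all(eq(x[k], y[k]) for k in x)
        if isinstance(x, list):
            return isinstance(y, list) and len(x) == len(y) and all(eq(u, v) for u, v in zip(x, y))
        if isinstance(x, bool) or isinstance(y, bool):
            return x is y or x == y
        if isinstance(x, float) and isinstance(y, float):
            return abs(x - y) <= tol
        if x is None or y is None:
            return x is y
        return x == y

    return eq(da, db)
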