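import numpy as np
import pytest

from startlekit import CohortConfig, default_group_params, generate_cohort, generate_session


@pytest.fixture(scope="session")
def group_params():
    return default_group_params()


@pytest.fixture(scope="session")
def one_session(group_params):
    """A single autism session at 60 Hz (fixed seed)."""
    return generate_session("autism", group_params["autism"], 123, frame_rate_hz=60.0)


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects/group at 30 Hz: fast shared cohort for pipeline tests."""
    cfg = CohortConfig(n_per_group=6, seed=7, frame_rate_hz=30.0)
    sessions, manifest = generate_cohort(cfg)
    return sessions, manifest


def flat_trial(nec=0.1, n=120, fps=60.0, kind="pulse_only", detected=True):
    """Hand-built Test I trial with a constant NEC trace."""
    from startlekit.io import Frames, StimulusSpec, Trial, default_layout

    t = np.arange(n) / fps * 1000.0
    stim = StimulusSpec(kind=kind, onsets_ms=[1000.0] if kind == "pulse_only" else [1000.0, 1120.0])
    det = np.full(n, bool(detected))
    fill = nec if detected else np.nan
    frames = Frames(
        t_ms=t,
        nec=np.full(n, fill),
        pupil_x=np.full(n, 0.0 if detected else np.nan),
        head_yaw_deg=np.full(n, 0.0 if detected else np.nan),
        bbox=np.full(n, 30.0 if detected else np.nan),
        mouth_area=np.full(n, 1.0 if detected else np.nan),
        face_detected=det,
        vocalizing=np.zeros(n, dtype=bool),
        headphone_touch=np.zeros(n, dtype=bool),
    )
    return Trial(1, "I", stim, default_layout("I", stim), frames)
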