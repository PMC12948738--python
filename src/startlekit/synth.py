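"""Synthetic cohort generator.

Emulates the study conditions of a smartphone startle/PPI case-control
cohort: two diagnostic groups whose group-level outcome distributions match
configured means/SDs for every neurometric and behavioral endpoint, with
per-subject random intercepts, trial-level noise, long-term habituation of
the pulse-only startle, sensitization in the random Test II train, and
overdispersed (beta-binomial) binary behavior events.

Design notes
------------
* Eyelid traces are ``rest + baseline wiggle + stimulus-locked transient``;
  the transient is a gamma-density-shaped kernel (shape 3, scale 40 ms,
  peak latency 80 ms) scaled by a per-trial amplitude.
* Non-negative latent quantities (startle amplitudes, behavior levels) are
  drawn from a *moment-matched censored normal*: the latent Gaussian
  parameters are solved so that ``max(0, N(mu, sigma))`` has exactly the
  configured mean and SD.  This keeps configured targets recoverable
  despite the physical floor at zero.
* Subject-level latents are drawn by stratified (quantile-balanced)
  sampling and binary event counts use balanced remainders, so cohort
  means concentrate tightly on the configured targets at realistic cohort
  sizes.  :func:`generate_null_cohort` instead pools one parameter set and
  randomly assigns diagnosis labels, which preserves the calibration of
  downstream significance tests (randomization validity).
* Within-subject correlation between different biomarkers is not modelled:
  metrics are independent given the group, which real data will not be.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import fsolve
from scipy.stats import norm

from .io import (
    Frames,
    Session,
    StimulusSpec,
    Trial,
    WindowLayout,
    default_layout,
)

EVENT_KINDS = ("screen_avoidance", "headphone_touch", "vocalization", "head_rotation")


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class GroupParams:
    """Generator targets for one diagnostic group.

    Continuous targets are (mean, SD) pairs of the *observed* outcome the
    extraction modules compute; binary behaviors are (per-trial event
    probability, across-subject SD of the per-subject event fraction).
    """

    # Test I startle amplitudes (baseline-corrected window-max NEC)
    asr_mean: float = 0.33
    asr_sd: float = 0.34
    prepulse_means: dict = field(
        default_factory=lambda: {
            "pp5": (0.33, 0.34),
            "pp10": (0.32, 0.35),
            "pp25": (0.30, 0.34),
        }
    )
    #: long-term habituation: change in mean pulse-only amplitude per trial pair
    longterm_slope_per_pair: float = -0.03
    #: fraction of amplitude variance carried by the subject intercept
    intercept_share: float = 0.5
    #: Test II per-pulse mean-amplitude multipliers (sensitization profile)
    sens_multipliers: dict = field(
        default_factory=lambda: {
            "rhythmic": (1.0,) * 6,
            "random": (1.0, 1.05, 1.15, 1.05, 1.05, 1.05),
        }
    )
    # anticipatory eyeblink amplitude in the observation windows
    aeb_mean: float = 0.05
    aeb_sd: float = 0.10
    # baseline eyelid variability (x100 NEC units): subject level L_i and
    # trial-to-trial residual scale R_i
    baseline_level_mean: float = 8.31
    baseline_level_sd: float = 5.55
    baseline_resid_mean: float = 5.23
    baseline_resid_sd: float = 2.60
    # binary behaviors: (per-trial probability, subject SD of fraction)
    screen_avoidance: tuple = (0.0994, 0.1156)
    headphone_touch: tuple = (0.1131, 0.1674)
    vocalization: tuple = (0.1116, 0.1521)
    head_rotation: tuple = (0.4022, 0.2562)
    # continuous behaviors
    postural_sd: tuple = (4.24, 2.82)        # SD of face bounding-box size
    mouth_area: tuple = (9.55, 6.95)         # mean mouth surface area
    pupil_range: tuple = (14.33, 4.04)       # % of inter-ocular distance
    side_eye: tuple = (0.13, 0.08)
    #: amplitude of the stimulus-locked mouth-opening transient
    mouth_bump: float = 2.0
    # demographics (age-band shares for 3-5 / 6-8 / 9-12 y, P(boy))
    age_band_probs: tuple = (0.1709, 0.4836, 0.3455)
    boy_prob: float = 0.7127
    co_occurring_probs: dict = field(
        default_factory=lambda: {"none": 0.50, "adhd": 0.15, "id": 0.20, "adhd_id": 0.07, "unknown": 0.08}
    )
    # trace nuisance parameters
    rest_nec: float = 0.05
    post_noise_sd: float = 0.005
    yaw_noise_deg: float = 1.0
    rotation_yaw_deg: float = 25.0
    rotation_episode_ms: float = 300.0
    vocal_episode_ms: float = 500.0
    headphone_episode_ms: float = 500.0
    avoid_frac: float = 0.6
    bbox_center: float = 30.0

    def event_params(self, kind: str) -> tuple:
        return getattr(self, kind)

    def validate(self) -> None:
        for name in ("asr_sd", "aeb_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for kind in EVENT_KINDS:
            p, sd = self.event_params(kind)
            if not 0 <= p <= 1:
                raise ValueError(f"{kind} probability out of [0,1]")
            if sd < 0:
                raise ValueError(f"{kind} subject SD must be >= 0")
        for kind, (m, s) in self.prepulse_means.items():
            if s < 0:
                raise ValueError(f"{kind} SD must be >= 0")
            if not 0 < m / max(self.asr_mean, 1e-9) <= 1.5:
                raise ValueError(f"{kind} implies a PPI multiplier outside (0, 1.5]")


def default_group_params() -> dict[str, GroupParams]:
    """Default generator targets for the two diagnostic groups.

    The autism defaults are the :class:`GroupParams` defaults; the
    neurotypical group overrides every endpoint with its own group values.
    """
    autism = GroupParams()
    nt = GroupParams(
        asr_mean=0.29,
        asr_sd=0.31,
        prepulse_means={
            "pp5": (0.27, 0.30),
            "pp10": (0.25, 0.30),
            "pp25": (0.22, 0.28),
        },
        longterm_slope_per_pair=-0.01,
        sens_multipliers={"rhythmic": (1.0,) * 6, "random": (1.0,) * 6},
        baseline_level_mean=4.77,
        baseline_level_sd=3.51,
        baseline_resid_mean=3.27,
        baseline_resid_sd=1.85,
        screen_avoidance=(0.0366, 0.0776),
        headphone_touch=(0.0187, 0.0597),
        vocalization=(0.0043, 0.0240),
        head_rotation=(0.1662, 0.1676),
        postural_sd=(2.11, 1.77),
        mouth_area=(2.96, 3.02),
        pupil_range=(10.12, 3.48),
        side_eye=(0.09, 0.08),
        mouth_bump=0.0,
        age_band_probs=(0.3846, 0.4359, 0.1795),
        boy_prob=0.5577,
        co_occurring_probs={"none": 1.0},
    )
    return {"autism": autism, "neurotypical": nt}


@dataclass
class CohortConfig:
    n_per_group: int = 150
    seed: int = 0
    frame_rate_hz: float = 60.0
    group_params: dict | None = None
    rejection_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.group_params is None:
            self.group_params = default_group_params()
        for gp in self.group_params.values():
            gp.validate()


def params_hash(group_params: dict[str, GroupParams]) -> str:
    doc = {g: asdict(p) for g, p in sorted(group_params.items())}
    return hashlib.sha1(json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# censored-normal moment matching
# ---------------------------------------------------------------------------

def _censored_moments(mu: float, sig: float) -> tuple[float, float]:
    a = mu / sig
    m = mu * norm.cdf(a) + sig * norm.pdf(a)
    m2 = (mu**2 + sig**2) * norm.cdf(a) + mu * sig * norm.pdf(a)
    return m, float(np.sqrt(max(m2 - m**2, 1e-12)))


@lru_cache(maxsize=4096)
def censored_normal_params(mean: float, sd: float) -> tuple[float, float]:
    """Latent ``(mu, sigma)`` so ``max(0, N(mu, sigma))`` has the given moments."""
    if sd <= 1e-9:
        return float(mean), 1e-9

    def f(x):
        m, s = _censored_moments(x[0], abs(x[1]))
        return [m - mean, s - sd]

    sol, info, ok, _ = fsolve(f, [mean, sd], full_output=True)
    if ok != 1 or max(abs(np.asarray(f(sol)))) > 1e-6:
        raise ValueError(f"cannot moment-match censored normal to mean={mean}, sd={sd}")
    return float(sol[0]), float(abs(sol[1]))


def _censored_from_std_normal(z: np.ndarray, mean: float, sd: float) -> np.ndarray:
    mu, sig = censored_normal_params(mean, sd)
    return np.maximum(0.0, mu + sig * np.asarray(z))


def _doubly_censored_moments(mu: float, sig: float, upper: float) -> tuple[float, float]:
    a, b = (0.0 - mu) / sig, (upper - mu) / sig
    pa, pb = norm.pdf(a), norm.pdf(b)
    Fa, Fb = norm.cdf(a), norm.cdf(b)
    m = mu * (Fb - Fa) + sig * (pa - pb) + upper * (1 - Fb)
    e2 = (
        (mu**2 + sig**2) * (Fb - Fa)
        + sig**2 * (a * pa - b * pb)
        + 2 * mu * sig * (pa - pb)
        + upper**2 * (1 - Fb)
    )
    return m, float(np.sqrt(max(e2 - m**2, 1e-12)))


@lru_cache(maxsize=4096)
def doubly_censored_params(mean: float, sd: float, upper: float) -> tuple[float, float]:
    """Latent ``(mu, sigma)`` so ``clip(N(mu, sigma), 0, upper)`` has the
    given moments.  Used for startle amplitudes, whose traces are bounded
    above by full eyelid closure (NEC = 1) minus the baseline level."""
    if sd <= 1e-9:
        return float(mean), 1e-9
    if not 0 < mean < upper:
        raise ValueError(f"mean {mean} outside (0, {upper})")
    if sd >= np.sqrt(mean * (upper - mean)):
        raise ValueError(f"sd {sd} infeasible for mean {mean} on [0, {upper}]")

    def f(x):
        m, s = _doubly_censored_moments(x[0], abs(x[1]), upper)
        return [m - mean, s - sd]

    sol, info, ok, _ = fsolve(f, [mean, sd], full_output=True)
    if ok != 1 or max(abs(np.asarray(f(sol)))) > 1e-6:
        raise ValueError(
            f"cannot moment-match doubly censored normal to mean={mean}, sd={sd}, upper={upper}"
        )
    return float(sol[0]), float(abs(sol[1]))


#: median/SD ratio of the folded smoothed baseline wiggle (numerically
#: characterized for the default smoothing); sets the expected baseline level
FOLDED_MEDIAN_SD_RATIO = 1.46


def amplitude_ceiling(params: GroupParams) -> float:
    """Expected upper bound of a scored amplitude: NEC ceiling minus the
    typical baseline median for this group."""
    return 1.0 - params.rest_nec - FOLDED_MEDIAN_SD_RATIO * params.baseline_level_mean / 100.0


_GH_X, _GH_W = np.polynomial.hermite.hermgauss(61)


@lru_cache(maxsize=1024)
def logit_normal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a logit-normal with the given mean and SD on [0, 1].

    Subject-level event probabilities are logit-normal so the overdispersed
    binary events are exactly the world a random-intercept logistic model
    assumes, while still reproducing the configured across-subject SDs.
    """
    from scipy.special import expit

    z = np.sqrt(2.0) * _GH_X
    w = _GH_W / np.sqrt(np.pi)

    def mom(x):
        p = expit(x[0] + abs(x[1]) * z)
        m = float((w * p).sum())
        s = float(np.sqrt(max((w * p * p).sum() - m * m, 1e-14)))
        return [m - mean, s - sd]

    sol, info, ok, _ = fsolve(mom, [np.log(mean / (1 - mean)), 1.0], full_output=True)
    if ok != 1 or max(abs(np.asarray(mom(sol)))) > 1e-6:
        raise ValueError(f"cannot moment-match logit-normal to mean={mean}, sd={sd}")
    return float(sol[0]), float(abs(sol[1]))


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialProto:
    test: str
    kind: str
    onsets: tuple
    omitted: tuple
    length_ms: float


_T1_LEN = 2000.0
_RHYTHMIC = TrialProto(
    "II", "rhythmic", tuple(1000.0 + 500.0 * k for k in range(6)), (4000.0, 4500.0), 5000.0
)
# irregular inter-onset intervals (600, 300, 1100, 400, 800 ms); one omitted
# onset inside the longest gap and one continuing the train after the last pulse
_RANDOM = TrialProto(
    "II", "random", (1000.0, 1600.0, 1900.0, 3000.0, 3400.0, 4200.0), (2450.0, 4700.0), 5200.0
)


def test1_protocol() -> list[TrialProto]:
    """Test I: 8 pulse-only + 8 per prepulse intensity, fixed pseudo-random order."""
    kinds = ["pulse_only"] * 8 + ["pp5"] * 8 + ["pp10"] * 8 + ["pp25"] * 8
    order = np.random.default_rng(1723).permutation(len(kinds))
    out = []
    for k in (kinds[i] for i in order):
        onsets = (1000.0,) if k == "pulse_only" else (1000.0, 1120.0)
        out.append(TrialProto("I", k, onsets, (), _T1_LEN))
    return out


def test2_protocol() -> list[TrialProto]:
    """Test II: ten rhythmic and ten random six-pulse trains, alternating."""
    out = []
    for _ in range(10):
        out.extend([_RHYTHMIC, _RANDOM])
    return out


def session_protocol() -> list[TrialProto]:
    return test1_protocol() + test2_protocol()


def _proto_stimulus(p: TrialProto) -> StimulusSpec:
    frac = {"pulse_only": 0.0, "pp5": 0.05, "pp10": 0.10, "pp25": 0.25}.get(p.kind, 0.0)
    return StimulusSpec(
        kind=p.kind, onsets_ms=list(p.onsets), omitted_onsets_ms=list(p.omitted),
        prepulse_fraction=frac,
    )


# ---------------------------------------------------------------------------
# subject latents
# ---------------------------------------------------------------------------

@dataclass
class SubjectLatents:
    u: float                       # startle intercept deviation
    event_p: dict                  # per-trial event probability per behavior
    event_rem_u: dict              # uniforms deciding the count remainder
    postural_sigma: float
    mouth_level: float
    pupil_range: float             # fraction of inter-ocular distance
    side_eye: float
    baseline_level: float          # x100 NEC units
    baseline_resid: float
    aeb_z: float = 0.0
    #: cohort-level largest-remainder extras (one 0/1 per behavior), set when
    #: latents are drawn for a whole cohort
    event_extra: dict | None = None


def _grid(n: int, rng: np.random.Generator, stratified: bool) -> np.ndarray:
    if stratified:
        return (rng.permutation(n) + rng.random(n)) / n
    return rng.random(n)


def sigma_components(params: GroupParams) -> tuple[float, float]:
    """(sigma_u, sigma_total) of the latent pulse-only amplitude."""
    _, sig = doubly_censored_params(params.asr_mean, params.asr_sd, amplitude_ceiling(params))
    sig_u = np.sqrt(params.intercept_share) * sig
    return float(sig_u), float(sig)


def draw_latents(
    params: GroupParams, n: int, rng: np.random.Generator, stratified: bool = True
) -> list[SubjectLatents]:
    sig_u, _ = sigma_components(params)
    u = sig_u * norm.ppf(_grid(n, rng, stratified))
    event_p = {}
    event_rem = {}
    from scipy.special import expit

    for kind in EVENT_KINDS:
        p, sd = params.event_params(kind)
        if p <= 0.0:
            event_p[kind] = np.zeros(n)
        elif p >= 1.0:
            event_p[kind] = np.ones(n)
        elif sd <= 1e-9:
            event_p[kind] = np.full(n, p)
        else:
            mu_l, sig_l = logit_normal_params(p, min(sd, 0.95 * np.sqrt(p * (1 - p))))
            draws = expit(mu_l + sig_l * norm.ppf(_grid(n, rng, stratified)))
            if stratified and n >= 10 and draws.mean() > 0:
                # condition the cohort on its exact target mean (the heavy
                # logit-normal tail otherwise dominates the sample mean)
                draws = np.clip(draws * (p / draws.mean()), 0.0, 0.999)
            event_p[kind] = draws
        event_rem[kind] = _grid(n, rng, stratified)

    # cohort-level largest-remainder apportionment of the event counts: the
    # total number of event trials per behavior matches sum(n_trials * p_i)
    # to within one, with extras going to the largest fractional remainders
    event_extra: dict[str, np.ndarray] | None = None
    if stratified and n >= 10:
        n_trials = len(session_protocol())
        event_extra = {}
        for kind in EVENT_KINDS:
            c = n_trials * event_p[kind]
            rem = c - np.floor(c)
            r_total = int(round(rem.sum()))
            extra = np.zeros(n, dtype=int)
            if r_total > 0:
                extra[np.argsort(-rem, kind="stable")[:r_total]] = 1
            event_extra[kind] = extra
    post = _censored_from_std_normal(norm.ppf(_grid(n, rng, stratified)), *params.postural_sd)
    mouth = _censored_from_std_normal(norm.ppf(_grid(n, rng, stratified)), *params.mouth_area)
    # pupil range and side-eye are both horizontal-pupil magnitudes; drawing
    # them comonotone (one quantile grid) keeps every subject's side-eye
    # excursions representable within their own pupil range
    zp = norm.ppf(_grid(n, rng, stratified))
    pupil = _censored_from_std_normal(zp, params.pupil_range[0] / 100, params.pupil_range[1] / 100)
    side = _censored_from_std_normal(zp, *params.side_eye)
    # baseline level and residual scale are comonotone (one quantile grid):
    # subjects with quiet baselines also have stable ones, which keeps the
    # per-subject trial distribution from becoming degenerate
    zb = norm.ppf(_grid(n, rng, stratified))
    blevel = _censored_from_std_normal(zb, params.baseline_level_mean, params.baseline_level_sd)
    bresid = _censored_from_std_normal(zb, params.baseline_resid_mean, params.baseline_resid_sd)
    return [
        SubjectLatents(
            u=float(u[i]),
            event_p={k: float(event_p[k][i]) for k in EVENT_KINDS},
            event_rem_u={k: float(event_rem[k][i]) for k in EVENT_KINDS},
            event_extra=(
                {k: int(event_extra[k][i]) for k in EVENT_KINDS}
                if event_extra is not None else None
            ),
            postural_sigma=max(float(post[i]), 0.05),
            mouth_level=float(mouth[i]),
            pupil_range=max(float(pupil[i]), 0.005),
            side_eye=float(side[i]),
            baseline_level=float(blevel[i]),
            baseline_resid=float(bresid[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# trace synthesis
# ---------------------------------------------------------------------------

def startle_kernel(tau_ms: np.ndarray, peak_ms: float = 80.0, shape: float = 3.0) -> np.ndarray:
    """Gamma-density-shaped eyelid transient, normalized to unit peak."""
    theta = peak_ms / (shape - 1.0)
    tau = np.maximum(np.asarray(tau_ms, dtype=float), 0.0)
    return (tau / peak_ms) ** (shape - 1.0) * np.exp(-(tau - peak_ms) / theta)


def _smooth_noise(rng, shape: tuple, fps: float, corr_ms: float) -> np.ndarray:
    w = rng.standard_normal(shape)
    sig = max(corr_ms / 1000.0 * fps, 0.5)
    return gaussian_filter1d(w, sigma=sig, axis=-1, mode="reflect")


def _rescale_rows(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Rescale each row to zero mean / unit sample SD over ``mask`` columns."""
    out = np.zeros_like(x)
    for i in range(x.shape[0]):
        m = mask[i] if mask.ndim == 2 else mask
        v = x[i, m]
        if v.size < 2:
            continue
        sd = v.std(ddof=1)
        if sd < 1e-12:
            continue
        out[i] = (x[i] - v.mean()) / sd
    return out


def _amp_targets(params: GroupParams, proto: TrialProto, pulse_idx: int | None):
    """(mean, sd) target of the amplitude for one Test I trial / Test II pulse."""
    if proto.test == "I":
        if proto.kind == "pulse_only":
            pair = pulse_idx // 2 + 1  # pulse_idx is the 0-based pulse-only occurrence
            m = params.asr_mean + params.longterm_slope_per_pair * (pair - 2.5)
            return max(m, 0.01), params.asr_sd
        return params.prepulse_means[proto.kind]
    mult = params.sens_multipliers[proto.kind][pulse_idx]
    return params.asr_mean * mult, params.asr_sd


def generate_session(
    group: str,
    params: GroupParams,
    subject_seed: int,
    *,
    subject_id: str | None = None,
    latents: SubjectLatents | None = None,
    frame_rate_hz: float = 60.0,
    age_years: float | None = None,
    sex: str | None = None,
    co_occurring: str | None = None,
) -> Session:
    """Generate a full Test I + Test II session for one subject.

    With a fixed ``subject_seed`` the output is bit-reproducible.  When
    ``latents`` is omitted the subject-level quantities are drawn iid from
    the group distributions.
    """
    rng = np.random.default_rng(subject_seed)
    if latents is None:
        latents = draw_latents(params, 1, rng, stratified=False)[0]
    fps = float(frame_rate_hz)
    protos = session_protocol()
    n_trials = len(protos)
    sig_u, sig_tot = sigma_components(params)

    if age_years is None:
        band = rng.choice(3, p=np.asarray(params.age_band_probs) / np.sum(params.age_band_probs))
        age_years = float(rng.integers(*[(3, 6), (6, 9), (9, 13)][band]))
    if sex is None:
        sex = "boy" if rng.random() < params.boy_prob else "girl"
    if co_occurring is None:
        keys = list(params.co_occurring_probs)
        pr = np.asarray([params.co_occurring_probs[k] for k in keys], dtype=float)
        co_occurring = str(rng.choice(keys, p=pr / pr.sum()))

    # --- assign behavior events to trials (balanced remainders) ------------
    event_trials: dict[str, set] = {}
    for kind in EVENT_KINDS:
        c = n_trials * latents.event_p[kind]
        if latents.event_extra is not None:
            k = int(np.floor(c)) + int(latents.event_extra[kind])
        else:
            k = int(np.floor(c)) + int(latents.event_rem_u[kind] < (c - np.floor(c)))
        k = min(k, n_trials)
        event_trials[kind] = set(rng.choice(n_trials, size=k, replace=False).tolist())
    k_rot = len(event_trials["head_rotation"])

    # brief sub-threshold head "glances" (too small/short to count as head
    # rotations) during which the pupil counter-rotates: these make the
    # side-eye trait observable even for subjects without rotation events
    non_rot = [j for j in range(n_trials) if j not in event_trials["head_rotation"]]
    glance_trials = set(
        rng.choice(non_rot, size=min(4, len(non_rot)), replace=False).tolist()
    ) if non_rot else set()

    # side-eye / pupil-range reconciliation: solve the curve half-range h so
    # the expected per-trial horizontal excursion equals the subject target
    R, s = latents.pupil_range, latents.side_eye
    k_eye = k_rot + len(glance_trials)
    if R / 2 >= s or k_eye == 0:
        half_range = R / 2
    else:
        half_range = max((n_trials * R - k_eye * s) / (2 * n_trials - k_eye), 0.004)

    # per-trial baseline variability (x100 NEC): draws from a per-subject
    # moment-matched censored normal so the fitted level and residual SD
    # recover the subject's latent (L_i, R_i)
    L_i = max(latents.baseline_level, 0.5)
    R_i = max(latents.baseline_resid, 0.3)
    try:
        bmu, bsig = censored_normal_params(L_i, R_i)
        v_t = np.maximum(bmu + bsig * rng.standard_normal(n_trials), 0.0) / 100.0
    except ValueError:
        v_t = np.maximum(L_i + R_i * rng.standard_normal(n_trials), 0.0) / 100.0
    v_t = np.minimum(v_t, 0.30)  # keep the shifted baseline inside [0, 1]

    kernel_len = int(round(0.400 * fps)) + 1

    trials_t1: list[Trial] = []
    trials_t2: list[Trial] = []
    pulse_only_seen = 0
    mouth_rows = []          # for the session-level mouth mean shift
    assembled = []

    # group trials into blocks of identical length for vectorized synthesis
    blocks: dict[float, list[int]] = {}
    for j, p in enumerate(protos):
        blocks.setdefault(p.length_ms, []).append(j)

    ceil_g = amplitude_ceiling(params)
    per_trial_pulse_amps = {}
    # antithetic trial noise within (condition, occurrence-pair): the paired
    # +z/-z draws cancel most of the trial-noise contribution to cohort means
    # without changing the marginal amplitude distribution
    pending_z: dict[tuple, float] = {}
    occ_count: dict[str, int] = {}
    for j, p in enumerate(protos):
        if p.test == "I":
            if p.kind == "pulse_only":
                mt, st = _amp_targets(params, p, pulse_only_seen)
                pulse_only_seen += 1
            else:
                mt, st = _amp_targets(params, p, None)
            mu_j, sg_j = doubly_censored_params(mt, st, ceil_g)
            mus = [mu_j]
            sds = [np.sqrt(max(sg_j**2 - sig_u**2, 1e-8))]
            occ = occ_count.get(p.kind, 0)
            occ_count[p.kind] = occ + 1
            if p.kind == "pulse_only":
                # the habituation slope and Pearson r are computed from this
                # sequence, so its trial noise must stay iid
                z1 = rng.standard_normal(1)
            else:
                key = (p.kind, occ // 2)
                if key in pending_z:
                    z1 = np.array([-pending_z.pop(key)])
                else:
                    z1 = rng.standard_normal(1)
                    pending_z[key] = float(z1[0])
            u_j = max(1.0 - params.rest_nec - FOLDED_MEDIAN_SD_RATIO * v_t[j] - 0.02, 0.05)
            per_trial_pulse_amps[j] = np.clip(
                np.asarray(mus) + latents.u + np.asarray(sds) * z1, 0.0, u_j
            )
            continue
        mus, sds = [], []
        for k in range(len(p.onsets)):
            mt, st = _amp_targets(params, p, k)
            mu_k, sg_k = doubly_censored_params(mt, st, ceil_g)
            mus.append(mu_k)
            sds.append(np.sqrt(max(sg_k**2 - sig_u**2, 1e-8)))
        # clip at the trial's own ceiling (full closure minus the expected
        # baseline level) so the trace itself almost never saturates and the
        # scored amplitude equals the injected one
        u_j = max(1.0 - params.rest_nec - FOLDED_MEDIAN_SD_RATIO * v_t[j] - 0.02, 0.05)
        amps = np.clip(
            np.asarray(mus) + latents.u + np.asarray(sds) * rng.standard_normal(len(mus)),
            0.0, u_j,
        )
        per_trial_pulse_amps[j] = amps

    aeb_mu, aeb_sig = censored_normal_params(params.aeb_mean, params.aeb_sd)

    for length_ms, idxs in blocks.items():
        F = int(round(length_ms / 1000.0 * fps))
        nb = len(idxs)
        t = np.arange(F) / fps * 1000.0
        base_cols = t < 1000.0

        detected = np.ones((nb, F), dtype=bool)
        for r, j in enumerate(idxs):
            if j in event_trials["screen_avoidance"]:
                # anchored at trial start or end: the child leaves before the
                # trial ends or returns after it starts, so scoring windows
                # are either fully covered or fully missing
                dur = int(round(params.avoid_frac * F))
                start = 0 if rng.random() < 0.5 else F - dur
                detected[r, start : start + dur] = False

        # --- eyelid -------------------------------------------------------
        # baseline segment: rest level + one-sided ("folded") wiggle — brief
        # partial closures from an open resting lid — rescaled so its sample
        # SD over detected baseline frames equals v_t exactly.  The
        # post-stimulus segment sits at the realized baseline median, which
        # makes window-max-minus-baseline-median amplitudes unbiased
        # estimates of the injected transient peaks.
        base_mask = detected & base_cols[None, :]
        wig = np.abs(_smooth_noise(rng, (nb, F), fps, 100.0))
        wig[:, ~base_cols] = 0.0
        nec = np.empty((nb, F))
        base_med = np.full(nb, params.rest_nec)
        v_row = v_t[np.asarray(idxs)]
        for r in range(nb):
            bm = base_mask[r]
            if bm.sum() >= 2 and wig[r, bm].std(ddof=1) > 1e-9:
                scale = v_row[r] / wig[r, bm].std(ddof=1)
                nec[r, base_cols] = params.rest_nec + scale * wig[r, base_cols]
                base_med[r] = params.rest_nec + scale * float(np.median(wig[r, bm]))
            else:
                nec[r, base_cols] = params.rest_nec
            nec[r, ~base_cols] = base_med[r]
        post = _rescale_rows(_smooth_noise(rng, (nb, F), fps, 100.0), ~base_cols)
        post[:, base_cols] = 0.0
        nec += params.post_noise_sd * post
        for r, j in enumerate(idxs):
            p = protos[j]
            onsets = p.onsets if p.test == "II" else (p.onsets[-1],)
            for k, o in enumerate(onsets):
                i0 = int(np.searchsorted(t, o))
                sl = slice(i0, min(i0 + kernel_len, F))
                nec[r, sl] += per_trial_pulse_amps[j][k] * startle_kernel(t[sl] - o)
            for o in p.omitted:
                a_ow = max(0.0, aeb_mu + aeb_sig * rng.standard_normal())
                i0 = int(np.searchsorted(t, o))
                sl = slice(i0, min(i0 + kernel_len, F))
                nec[r, sl] += a_ow * startle_kernel(t[sl] - o)
        nec = np.clip(nec, 0.0, 1.0)

        # --- bbox (postural) ----------------------------------------------
        bbox = params.bbox_center + latents.postural_sigma * _rescale_rows(
            _smooth_noise(rng, (nb, F), fps, 150.0), detected
        )

        # --- yaw + rotation events, pupil + side-eye -----------------------
        yaw = params.yaw_noise_deg * _smooth_noise(rng, (nb, F), fps, 120.0)
        ev_mask = np.zeros((nb, F), dtype=bool)
        ev_sign = np.zeros(nb)

        def longest_detected_run(det):
            best_start, best_len, cur_start, cur_len = 0, 0, 0, 0
            for i in range(F):
                if det[i]:
                    if cur_len == 0:
                        cur_start = i
                    cur_len += 1
                    if cur_len > best_len:
                        best_len, best_start = cur_len, cur_start
                else:
                    cur_len = 0
            return best_start, best_len

        for r, j in enumerate(idxs):
            if j in event_trials["head_rotation"]:
                ep_ms, mag = params.rotation_episode_ms, params.rotation_yaw_deg
            elif j in glance_trials:
                ep_ms, mag = 150.0, 10.0
            else:
                continue
            # place the excursion inside the longest detected run
            best_start, best_len = longest_detected_run(detected[r])
            run_len = min(int(round(ep_ms / 1000.0 * fps)), max(best_len, 1))
            off = int(rng.integers(0, max(best_len - run_len, 0) + 1))
            sl = slice(best_start + off, best_start + off + run_len)
            sgn = 1.0 if rng.random() < 0.5 else -1.0
            yaw[r, sl] = sgn * mag
            ev_mask[r, sl] = True
            ev_sign[r] = sgn

        pupil = _rescale_rows(_smooth_noise(rng, (nb, F), fps, 250.0), detected & ~ev_mask)
        # map each row affinely onto [-h, +h] over its usable frames
        for r in range(nb):
            m = detected[r] & ~ev_mask[r]
            if m.sum() >= 2:
                lo, hi = pupil[r, m].min(), pupil[r, m].max()
                if hi > lo:
                    pupil[r] = (pupil[r] - lo) / (hi - lo) * 2 * half_range - half_range
            if ev_sign[r] != 0.0:
                pupil[r, ev_mask[r]] = -ev_sign[r] * s + 0.001 * rng.standard_normal(
                    int(ev_mask[r].sum())
                )

        # --- mouth ----------------------------------------------------------
        mouth = (0.25 * latents.mouth_level + 0.1) * _rescale_rows(
            _smooth_noise(rng, (nb, F), fps, 200.0), detected
        )
        if params.mouth_bump > 0:
            bump_len = int(round(0.8 * fps)) + 1
            for r, j in enumerate(idxs):
                p = protos[j]
                onsets = p.onsets if p.test == "II" else (p.onsets[-1],)
                for o in onsets:
                    i0 = int(np.searchsorted(t, o + 150.0))
                    sl = slice(i0, min(i0 + bump_len, F))
                    mouth[r, sl] += params.mouth_bump * startle_kernel(
                        t[sl] - o - 150.0, peak_ms=160.0
                    )

        # --- flags -----------------------------------------------------------
        vocal = np.zeros((nb, F), dtype=bool)
        touch = np.zeros((nb, F), dtype=bool)
        for flags, kind, ep_ms in (
            (vocal, "vocalization", params.vocal_episode_ms),
            (touch, "headphone_touch", params.headphone_episode_ms),
        ):
            run = max(int(round(ep_ms / 1000.0 * fps)), 1)
            for r, j in enumerate(idxs):
                if j in event_trials[kind]:
                    start = int(rng.integers(0, F - run + 1))
                    flags[r, start : start + run] = True

        mouth_rows.append((np.asarray(idxs), mouth, detected))
        assembled.append((idxs, t, nec, pupil, yaw, bbox, mouth, detected, vocal, touch))

    # session-level additive shift so the mean mouth area over detected frames
    # equals the subject's target level
    tot = sum(m[d].sum() for _, m, d in mouth_rows)
    cnt = sum(int(d.sum()) for _, _, d in mouth_rows)
    shift = latents.mouth_level - tot / max(cnt, 1)

    for idxs, t, nec, pupil, yaw, bbox, mouth, detected, vocal, touch in assembled:
        mouth = np.maximum(mouth + shift, 0.0)
        for r, j in enumerate(idxs):
            p = protos[j]
            det = detected[r]
            def masked(x):
                y = x.astype(float).copy()
                y[~det] = np.nan
                return y

            frames = Frames(
                t_ms=t.copy(),
                nec=masked(nec[r]),
                pupil_x=masked(pupil[r]),
                head_yaw_deg=masked(yaw[r]),
                bbox=masked(bbox[r]),
                mouth_area=masked(mouth[r]),
                face_detected=det.copy(),
                vocalizing=vocal[r].copy(),
                headphone_touch=touch[r].copy(),
            )
            stim = _proto_stimulus(p)
            trial = Trial(
                index=j + 1 if p.test == "I" else j + 1 - 32,
                test=p.test,
                stimulus=stim,
                windows=default_layout(p.test, stim),
                frames=frames,
            )
            (trials_t1 if p.test == "I" else trials_t2).append(trial)

    trials_t1.sort(key=lambda tr: tr.index)
    trials_t2.sort(key=lambda tr: tr.index)
    return Session(
        subject_id=subject_id or f"S{subject_seed}",
        group=group,
        age_years=float(age_years),
        sex=sex,
        co_occurring=co_occurring,
        trials_test1=trials_t1,
        trials_test2=trials_t2,
        frame_rate_hz=fps,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

_REJECTION_REASONS = ("volume", "headphone_refusal", "premature_termination")


def _cohort_rows(
    sessions: list[Session], seeds: list[int], success: np.ndarray, reasons: list
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in sessions],
            "group": [s.group for s in sessions],
            "age_years": [s.age_years for s in sessions],
            "sex": [s.sex for s in sessions],
            "co_occurring": [s.co_occurring for s in sessions],
            "subject_seed": seeds,
            "success": success,
            "rejection_reason": reasons,
        }
    )


def generate_cohort(config: CohortConfig) -> tuple[list[Session], pd.DataFrame]:
    """Generate ``n_per_group`` sessions per diagnostic group plus a manifest.

    Subject-level latents are stratified within each group so the cohort
    means track the configured group targets; each subject's traces are then
    produced from an independent per-subject seed.
    """
    ss = np.random.SeedSequence(config.seed)
    groups = sorted(config.group_params)
    sessions, seeds, reasons = [], [], []
    rng_master = np.random.default_rng(ss.spawn(1)[0])
    for g in groups:
        params = config.group_params[g]
        n = config.n_per_group
        gkey = int.from_bytes(hashlib.sha1(g.encode()).digest()[:4], "little")
        lat_rng = np.random.default_rng(np.random.SeedSequence((config.seed, gkey)))
        lats = draw_latents(params, n, lat_rng, stratified=True)
        child = ss.spawn(n)
        for i in range(n):
            seed_i = int(child[i].generate_state(1)[0] & 0x7FFFFFFF)
            sess = generate_session(
                g,
                params,
                seed_i,
                subject_id=f"{g[:2]}{i:04d}",
                latents=lats[i],
                frame_rate_hz=config.frame_rate_hz,
            )
            sessions.append(sess)
            seeds.append(seed_i)
    success = rng_master.random(len(sessions)) >= config.rejection_prob
    for ok in success:
        reasons.append("" if ok else str(rng_master.choice(_REJECTION_REASONS)))
    manifest = _cohort_rows(sessions, seeds, success, reasons)
    manifest.attrs["seed"] = config.seed
    manifest.attrs["params_hash"] = params_hash(config.group_params)
    return sessions, manifest


def generate_null_cohort(
    params: GroupParams,
    n_per_group: int,
    seed: int,
    frame_rate_hz: float = 60.0,
) -> tuple[list[Session], pd.DataFrame]:
    """Cohort with *identical* groups: 2n subjects from one parameter set,
    diagnosis labels assigned at random (label-randomization null)."""
    ss = np.random.SeedSequence(seed)
    n = 2 * n_per_group
    lat_rng = np.random.default_rng(ss.spawn(1)[0])
    lats = draw_latents(params, n, lat_rng, stratified=True)
    labels = np.array(["autism"] * n_per_group + ["neurotypical"] * n_per_group)
    lat_rng.shuffle(labels)
    sessions, seeds = [], []
    child = ss.spawn(n)
    for i in range(n):
        seed_i = int(child[i].generate_state(1)[0] & 0x7FFFFFFF)
        sessions.append(
            generate_session(
                str(labels[i]),
                params,
                seed_i,
                subject_id=f"N{i:04d}",
                latents=lats[i],
                frame_rate_hz=frame_rate_hz,
            )
        )
        seeds.append(seed_i)
    manifest = _cohort_rows(sessions, seeds, np.ones(n, dtype=bool), [""] * n)
    manifest.attrs["seed"] = seed
    manifest.attrs["params_hash"] = params_hash({"null": params})
    return sessions, manifest


def generator_targets(params: GroupParams) -> dict[str, float]:
    """The configured outcome targets the extraction stages should recover."""
    out = {
        "asr_mean": params.asr_mean,
        "pp5_mean": params.prepulse_means["pp5"][0],
        "pp10_mean": params.prepulse_means["pp10"][0],
        "pp25_mean": params.prepulse_means["pp25"][0],
        "screen_avoidance_pct": params.screen_avoidance[0] * 100,
        "headphone_touch_pct": params.headphone_touch[0] * 100,
        "vocalization_pct": params.vocalization[0] * 100,
        "head_rotation_pct": params.head_rotation[0] * 100,
        "postural_sd": params.postural_sd[0],
        "mouth_area_mean": params.mouth_area[0],
        "pupil_range": params.pupil_range[0],
        "side_eye": params.side_eye[0],
        "baseline_intercept": params.baseline_level_mean,
        "baseline_sd": params.baseline_resid_mean,
    }
    return out
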