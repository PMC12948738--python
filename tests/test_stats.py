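"""Statistics layer: Holm, contingency, rank-sum, LMM, GH logistic, OLS."""

import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from startlekit import (
    EffectEstimate,
    RandomInterceptLogit,
    TrialMixedLM,
    anova_lmm,
    chi_square_2x2,
    fit_event_logistic,
    fit_group_lmm,
    fit_subject_ols,
    holm_adjust,
    rank_sum,
)


# ---------------------------------------------------------------------------
# Holm adjustment
# ---------------------------------------------------------------------------

def test_holm_single_p_unchanged():
    assert holm_adjust([0.03]) == pytest.approx([0.03])


def test_holm_hand_computed_example():
    assert holm_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.04, 0.04])


def test_holm_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(3)
    for _ in range(20):
        p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 12))
        ours = holm_adjust(p)
        theirs = multipletests(p, method="holm")[1]
        assert np.allclose(ours, theirs, atol=1e-12)


def test_holm_rejects_bad_p():
    with pytest.raises(ValueError):
        holm_adjust([0.5, 0.0])
    with pytest.raises(ValueError):
        holm_adjust([1.5])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=15))
def test_holm_properties(p):
    adj = holm_adjust(p)
    p = np.asarray(p)
    assert np.all(adj >= p - 1e-15)
    assert np.all(adj <= 1.0)
    # monotone in the raw ordering
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)
    # equals Bonferroni when all p equal
    same = holm_adjust([p[0]] * 4)
    assert same == pytest.approx(min(1.0, 4 * p[0]))


# ---------------------------------------------------------------------------
# contingency + rank-sum
# ---------------------------------------------------------------------------

def test_chi2_identical_proportions_zero():
    res = chi_square_2x2([[40, 60], [20, 30]])
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)


def test_chi2_matches_brute_force():
    rng = np.random.default_rng(4)
    for _ in range(30):
        t = rng.integers(1, 80, size=(2, 2)).astype(float)
        res = chi_square_2x2(t)
        exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
        assert res.chi2 == pytest.approx(np.sum((t - exp) ** 2 / exp), rel=1e-12)


def test_chi2_zero_margin_error():
    with pytest.raises(ValueError):
        chi_square_2x2([[0, 0], [5, 3]])


def test_rank_sum_matches_enumeration():
    a, b = [1.2, 3.4, 5.6], [2.1, 0.7, 4.4]
    res = rank_sum(a, b)
    # exhaustive rank computation: U = # pairs where a_i > b_j
    u_brute = sum(x > y for x in a for y in b)
    assert res.W == pytest.approx(u_brute)


def test_rank_sum_identical_samples():
    res = rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
    assert res.r_effect == pytest.approx(0.0, abs=1e-12)


def test_rank_sum_separation_maximizes_r():
    """Fully separated samples have the largest |r| over all label permutations."""
    vals = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
    r_sep = abs(rank_sum(vals[3:], vals[:3]).r_effect)
    for comb in itertools.combinations(range(6), 3):
        a = [vals[i] for i in comb]
        b = [vals[i] for i in range(6) if i not in comb]
        assert abs(rank_sum(a, b).r_effect) <= r_sep + 1e-12


def test_rank_sum_empty_group():
    with pytest.raises(ValueError):
        rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------

def _trial_table(rng, n_per_group, n_trials, shift=0.0, subj_sd=0.15, noise_sd=0.25):
    rows = []
    for g, grp in enumerate(("neurotypical", "autism")):
        for i in range(n_per_group):
            u = rng.normal(0, subj_sd)
            for t in range(n_trials):
                y = max(0.0, 0.3 + shift * g + u + rng.normal(0, noise_sd))
                rows.append((f"{grp[:2]}{i}", grp, 7.0 + rng.integers(-3, 4), "boy", y))
    return pd.DataFrame(rows, columns=["subject_id", "group", "age_years", "sex", "amplitude"])


def test_lmm_reduces_to_ols_without_subject_variance():
    rng = np.random.default_rng(0)
    df = _trial_table(rng, 40, 8, shift=0.05, subj_sd=0.0)
    import statsmodels.api as sm

    eff = fit_group_lmm(df, "amplitude")
    x = (df["group"] == "autism").astype(float)
    ols = sm.OLS(df["amplitude"], sm.add_constant(x)).fit()
    assert eff.b == pytest.approx(ols.params.iloc[1], abs=1e-3)


def test_lmm_null_calibration_table_level():
    rng = np.random.default_rng(1)
    ps = []
    for _ in range(60):
        df = _trial_table(rng, 25, 8, shift=0.0)
        ps.append(fit_group_lmm(df, "amplitude").p_raw)
    ps = np.asarray(ps)
    assert 0.2 < ps.mean() < 0.8
    assert (ps < 0.05).mean() <= 0.15


def test_lmm_power_for_pp25_sized_shift():
    """A 0.04 amplitude shift at n=150/group, 8 trials each (subject SD 0.05,
    trial SD 0.25) is detected — CI excludes 0 — in at least 80% of runs."""
    hits = 0
    runs = 100
    for k in range(runs):
        rng = np.random.default_rng(100 + k)
        df = _trial_table(rng, 150, 8, shift=0.04, subj_sd=0.05, noise_sd=0.25)
        eff = fit_group_lmm(df, "amplitude")
        hits += eff.ci_low > 0
    assert hits / runs >= 0.8


def test_lmm_covariate_does_not_flip_sign():
    rng = np.random.default_rng(2)
    df = _trial_table(rng, 80, 8, shift=0.05)
    b0 = fit_group_lmm(df, "amplitude").b
    b1 = fit_group_lmm(df, "amplitude", covariates=("sex",)).b
    assert np.sign(b0) == np.sign(b1)


def test_anova_lmm_stimulus_term():
    rng = np.random.default_rng(5)
    rows = []
    for i in range(100):
        u = rng.normal(0, 0.1)
        for cond, mult in (("pulse_only", 1.0), ("pp10", 0.85), ("pp25", 0.75)):
            for t in range(6):
                rows.append((f"s{i}", "neurotypical", cond,
                             max(0.0, 0.3 * mult + u + rng.normal(0, 0.2))))
    df = pd.DataFrame(rows, columns=["subject_id", "group", "condition", "amplitude"])
    fit = TrialMixedLM(df, "amplitude", terms=["condition"]).fit()
    res = anova_lmm(fit, "condition")
    assert res["p"] < 0.01 and res["df1"] == 2
    with pytest.raises(ValueError, match="absent"):
        anova_lmm(fit, "trial_number")


# ---------------------------------------------------------------------------
# random-intercept logistic (Gauss-Hermite)
# ---------------------------------------------------------------------------

def _event_table(rng, n_per_group, n_trials, p_nt, p_aut, od=6.0):
    rows = []
    for grp, p in (("neurotypical", p_nt), ("autism", p_aut)):
        a, b = p * od, (1 - p) * od
        for i in range(n_per_group):
            pi = rng.beta(a, b)
            y = rng.random(n_trials) < pi
            for t in range(n_trials):
                rows.append((f"{grp[:2]}{i}", grp, int(y[t])))
    return pd.DataFrame(rows, columns=["subject_id", "group", "event"])


def test_logistic_null_or_near_one():
    rng = np.random.default_rng(0)
    ors = []
    for _ in range(25):
        df = _event_table(rng, 40, 30, 0.08, 0.08)
        ors.append(fit_event_logistic(df, "event").odds_ratio)
    assert np.median(ors) == pytest.approx(1.0, abs=0.35)


def test_logistic_detects_screen_avoidance_sized_effect():
    rng = np.random.default_rng(1)
    df = _event_table(rng, 150, 52, 0.0366, 0.0994)
    eff = fit_event_logistic(df, "event")
    assert eff.odds_ratio > 1.0
    assert np.exp(eff.ci_low) > 1.0
    assert eff.model == "logistic_ml" and eff.beta_std is None


def test_logistic_degenerate_outcome():
    df = pd.DataFrame(
        {"subject_id": ["a"] * 5 + ["b"] * 5, "group": ["autism"] * 5 + ["neurotypical"] * 5,
         "event": [0] * 10}
    )
    with pytest.raises(ValueError, match="degenerate"):
        fit_event_logistic(df, "event")


def test_logistic_separation_penalized_and_flagged():
    rng = np.random.default_rng(2)
    df = _event_table(rng, 25, 20, 0.05, 0.3)
    df.loc[df.group == "neurotypical", "event"] = 0
    eff = fit_event_logistic(df, "event")
    assert "penalized" in eff.flag
    assert np.isfinite(eff.b)


def test_gh_logistic_matches_lme4_glmer(tmp_path):
    """Independent oracle: lme4::glmer (adaptive quadrature) on a small fixture."""
    rng = np.random.default_rng(5)
    n, nt = 60, 30
    u = rng.normal(0, 1.0, n)
    grp = np.repeat([1, 0], n // 2)
    eta = -2.0 + 1.2 * grp + u
    rows = []
    for i in range(n):
        y = rng.random(nt) < 1 / (1 + np.exp(-eta[i]))
        for t in range(nt):
            rows.append((f"s{i}", "autism" if grp[i] else "neurotypical", int(grp[i]), int(y[t])))
    df = pd.DataFrame(rows, columns=["subject_id", "group", "aut", "y"])
    fit = RandomInterceptLogit(df, "y", terms=("group",)).fit()
    csv = tmp_path / "fix.csv"
    df.to_csv(csv, index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv('{csv}')
        m <- glmer(y ~ aut + (1|subject_id), data=d, family=binomial, nAGQ=10)
        cat(fixef(m)[2], sqrt(unlist(VarCorr(m))), sep='\\n')
    """)
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    beta_r, sigma_r = (float(x) for x in out.stdout.strip().split())
    i = fit.model.term_cols["group"][0]
    assert fit.params[i] == pytest.approx(beta_r, abs=0.05)
    assert fit.sigma_u == pytest.approx(sigma_r, abs=0.08)


# ---------------------------------------------------------------------------
# subject-level OLS
# ---------------------------------------------------------------------------

def test_ols_null_beta_near_zero():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(400)],
        "group": ["autism"] * 200 + ["neurotypical"] * 200,
        "y": rng.normal(1.0, 0.5, 400),
    })
    eff = fit_subject_ols(df, "y")
    assert abs(eff.beta_std) < 0.12


def test_ols_one_sd_shift_standardized_beta():
    # closed form: equal groups shifted by 1 SD -> beta_std = 0.5/sqrt(1.25)
    rng = np.random.default_rng(1)
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(4000)],
        "group": ["autism"] * 2000 + ["neurotypical"] * 2000,
        "y": np.concatenate([rng.normal(1.0, 1.0, 2000), rng.normal(0.0, 1.0, 2000)]),
    })
    eff = fit_subject_ols(df, "y")
    assert eff.beta_std == pytest.approx(0.5 / np.sqrt(1.25), abs=0.03)


def test_ols_constant_outcome_errors():
    df = pd.DataFrame({
        "subject_id": ["a", "b", "c", "d"],
        "group": ["autism", "autism", "neurotypical", "neurotypical"],
        "y": [1.0, 1.0, 1.0, 1.0],
    })
    with pytest.raises(ValueError, match="zero variance"):
        fit_subject_ols(df, "y")


def test_effect_estimate_invariants():
    with pytest.raises(ValueError, match="exactly one"):
        EffectEstimate("x", "ols", 0.1, 0.0, 0.2, 0.5, beta_std=0.1, odds_ratio=1.2)
    with pytest.raises(ValueError, match="CI"):
        EffectEstimate("x", "ols", 0.5, 0.0, 0.2, 0.5, beta_std=0.1)
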