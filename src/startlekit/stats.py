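"""Group-comparison statistics.

Three statsmodels-style model families, each a Model class whose ``fit()``
returns a Results object:

* :class:`TrialMixedLM` — trial-level linear mixed model with a per-subject
  random intercept (REML, Wald inference, residual-approximation df);
* :class:`RandomInterceptLogit` — trial-level binomial logistic regression
  with a per-subject random intercept, fitted by maximum likelihood with
  Gauss-Hermite quadrature; reports odds ratios;
* :class:`SubjectOLS` — ordinary least squares on one-value-per-subject
  outcomes.

Group contrasts are summarized as :class:`EffectEstimate` rows carrying the
raw coefficient ``b``, its Wald 95% CI, p value, and either a standardized
beta (outcome and predictor z-scored; linear families) or an odds ratio
(logistic family).  Multiplicity is controlled with the Bonferroni-Holm
step-down adjustment.  Cohort-description tests (chi-square without
continuity correction + Fisher exact; Wilcoxon rank-sum with continuity
correction and effect size r = Z/sqrt(N)) are also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import log_expit, logsumexp
from statsmodels.tools.numdiff import approx_hess1


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

@dataclass
class EffectEstimate:
    """One fitted group contrast."""

    outcome_name: str
    model: str                   # "lmm" | "logistic_ml" | "ols"
    b: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adjusted: float | None = None
    beta_std: float | None = None
    odds_ratio: float | None = None
    se: float = np.nan
    df: float = np.nan
    covariates_included: list = field(default_factory=list)
    flag: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.b) and not (self.ci_low - 1e-9 <= self.b <= self.ci_high + 1e-9):
            raise ValueError(f"{self.outcome_name}: CI does not bracket b")
        if np.isfinite(self.p_raw) and not 0 < self.p_raw <= 1:
            raise ValueError(f"{self.outcome_name}: p out of (0,1]")
        if (self.beta_std is None) == (self.odds_ratio is None):
            raise ValueError("exactly one of beta_std/odds_ratio must be set")


@dataclass
class ContingencyResult:
    chi2: float
    df: int
    p: float
    fisher_p: float | None = None
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if self.chi2 < 0 or self.df < 1:
            raise ValueError("invalid contingency result")


@dataclass
class RankSumResult:
    W: float
    p: float
    r_effect: float

    def __post_init__(self) -> None:
        if np.isfinite(self.r_effect) and abs(self.r_effect) > 1 + 1e-12:
            raise ValueError("|r_effect| must be <= 1")


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def _diagnosis_indicator(df: pd.DataFrame) -> np.ndarray:
    return (df["group"].astype(str) == "autism").astype(float).to_numpy()


def _design(df: pd.DataFrame, terms) -> tuple[np.ndarray, list[str], dict]:
    """Design matrix with intercept; categorical terms are dummy-coded."""
    cols, names = [np.ones(len(df))], ["const"]
    term_cols: dict[str, list[int]] = {}
    for term in terms:
        if term == "group":
            x = _diagnosis_indicator(df)
            cols.append(x)
            names.append("diagnosis[autism]")
            term_cols[term] = [len(names) - 1]
        elif term == "sex":
            cols.append((df["sex"].astype(str) == "boy").astype(float).to_numpy())
            names.append("sex[boy]")
            term_cols[term] = [len(names) - 1]
        elif df[term].dtype == object or isinstance(df[term].dtype, pd.CategoricalDtype):
            levels = sorted(df[term].astype(str).unique())
            idx = []
            for lv in levels[1:]:
                cols.append((df[term].astype(str) == lv).astype(float).to_numpy())
                names.append(f"{term}[{lv}]")
                idx.append(len(names) - 1)
            term_cols[term] = idx
        else:
            cols.append(df[term].astype(float).to_numpy())
            names.append(term)
            term_cols[term] = [len(names) - 1]
    return np.column_stack(cols), names, term_cols


def _wald(b: float, se: float, df: float) -> tuple[float, float, float]:
    tcrit = sps.t.ppf(0.975, df) if np.isfinite(df) and df > 0 else 1.96
    tval = b / se if se > 0 else np.nan
    p = 2 * sps.t.sf(abs(tval), df) if np.isfinite(tval) else np.nan
    p = float(np.clip(p, np.nextafter(0, 1), 1.0))
    return b - tcrit * se, b + tcrit * se, p


# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------

class TrialMixedLM:
    """Trial-level LMM ``outcome ~ terms`` with a subject random intercept."""

    def __init__(self, data: pd.DataFrame, outcome: str, terms=("group",),
                 groups: str = "subject_id"):
        d = data.dropna(subset=[outcome]).reset_index(drop=True)
        if d.empty:
            raise ValueError("no usable rows")
        self.data = d
        self.outcome = outcome
        self.terms = list(terms)
        self.groups = groups
        self.X, self.names, self.term_cols = _design(d, self.terms)
        self.y = d[outcome].astype(float).to_numpy()

    def fit(self, reml: bool = True) -> "MixedLMFit":
        flag = ""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                md = sm.MixedLM(self.y, self.X, groups=self.data[self.groups])
                res = md.fit(reml=reml)
                if not np.all(np.isfinite(res.bse_fe)) or float(np.asarray(res.cov_re)[0, 0]) < 1e-10:
                    raise ValueError("singular random-effects fit")
                params = np.asarray(res.fe_params)
                bse = np.asarray(res.bse_fe)
                cov = np.asarray(res.cov_params())[: len(params), : len(params)]
            except Exception:
                # singular fit: refit without the random intercept, flagged
                res = sm.OLS(self.y, self.X).fit()
                params = np.asarray(res.params)
                bse = np.asarray(res.bse)
                cov = np.asarray(res.cov_params())
                flag = "singular_refit_ols"
        n_subj = self.data[self.groups].nunique()
        df = max(n_subj - len(params), 1)
        return MixedLMFit(self, res, params, bse, cov, float(df), flag)


class MixedLMFit:
    def __init__(self, model, res, params, bse, cov, df, flag):
        self.model = model
        self.sm_result = res
        self.params = params
        self.bse = bse
        self.cov = cov
        self.df_inference = df
        self.flag = flag

    def effect(self, outcome_name: str, term: str = "group") -> EffectEstimate:
        i = self.model.term_cols[term][0]
        b, se = float(self.params[i]), float(self.bse[i])
        lo, hi, p = _wald(b, se, self.df_inference)
        x = self.model.X[:, i]
        sy = self.model.y.std(ddof=1)
        beta_std = b * x.std(ddof=1) / sy if sy > 0 else np.nan
        return EffectEstimate(
            outcome_name=outcome_name, model="lmm", b=b, ci_low=lo, ci_high=hi,
            p_raw=p, beta_std=float(beta_std), se=se, df=self.df_inference,
            covariates_included=[t for t in self.model.terms if t != term],
            flag=self.flag,
        )

    def wald_f(self, term: str) -> tuple[float, int, float, float]:
        """Type-III Wald F test of one term: (F, df1, df2, p)."""
        if term not in self.model.term_cols:
            raise ValueError(f"term {term!r} absent from the model")
        idx = self.model.term_cols[term]
        if not idx:
            raise ValueError(f"term {term!r} has no estimable contrast")
        b = self.params[idx]
        V = self.cov[np.ix_(idx, idx)]
        q = len(idx)
        stat = float(b @ np.linalg.solve(V, b))
        df2 = max(len(self.model.y) - len(self.params), 1)
        F = stat / q
        return F, q, df2, float(sps.f.sf(F, q, df2))


def fit_group_lmm(data: pd.DataFrame, outcome: str, covariates=(),
                  outcome_name: str | None = None) -> EffectEstimate:
    """Diagnosis contrast from a trial-level mixed model."""
    fit = TrialMixedLM(data, outcome, terms=["group", *covariates]).fit()
    return fit.effect(outcome_name or outcome)


def anova_lmm(fit: MixedLMFit, term: str) -> dict:
    F, df1, df2, p = fit.wald_f(term)
    return {"F": F, "df1": df1, "df2": df2, "p": p}


# ---------------------------------------------------------------------------
# random-intercept logistic regression (Gauss-Hermite maximum likelihood)
# ---------------------------------------------------------------------------

class RandomInterceptLogit:
    """Multilevel binomial logistic regression, subject random intercept.

    Covariates must be constant within subject (diagnosis, age, sex), so
    the trial-level table is aggregated to per-subject (events, trials)
    and the marginal likelihood is integrated with Gauss-Hermite quadrature.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, terms=("group",),
                 groups: str = "subject_id", n_nodes: int = 25):
        d = data.dropna(subset=[outcome])
        keep = [c for c in dict.fromkeys(list(terms) + ["group", "age_years", "sex"])
                if c in d.columns]
        agg = d.groupby(groups).agg(
            y=(outcome, "sum"), n=(outcome, "count"),
            **{c: (c, "first") for c in keep},
        ).reset_index()
        self.data = agg
        self.terms = list(terms)
        self.X, self.names, self.term_cols = _design(agg, self.terms)
        self.y = agg["y"].astype(float).to_numpy()
        self.n = agg["n"].astype(float).to_numpy()
        if self.y.sum() == 0 or (self.n - self.y).sum() == 0:
            raise ValueError("degenerate outcome: no events or no non-events")
        gx, gw = np.polynomial.hermite.hermgauss(n_nodes)
        self.nodes = np.sqrt(2.0) * gx
        self.logw = np.log(gw) - 0.5 * np.log(np.pi)

    def _ll_by_subject(self, theta: np.ndarray) -> np.ndarray:
        beta, logsig = theta[:-1], theta[-1]
        sig = np.exp(np.clip(logsig, -10, 4))
        eta = self.X @ beta
        lin = eta[:, None] + sig * self.nodes[None, :]
        ll = self.y[:, None] * log_expit(lin) + (self.n - self.y)[:, None] * log_expit(-lin)
        return logsumexp(ll + self.logw[None, :], axis=1)

    def _nll(self, theta: np.ndarray, ridge: float = 0.0) -> float:
        out = -float(self._ll_by_subject(theta).sum())
        if ridge > 0:
            out += 0.5 * ridge * float(np.sum(theta[:-1][1:] ** 2))
        return out

    def _score_by_subject(self, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
        """Per-subject score vectors (central differences), shape (S, k+1)."""
        k = len(theta)
        G = np.empty((len(self.y), k))
        for j in range(k):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += eps
            tm[j] -= eps
            G[:, j] = (self._ll_by_subject(tp) - self._ll_by_subject(tm)) / (2 * eps)
        return G

    def _separated(self) -> bool:
        for term, idx in self.term_cols.items():
            for i in idx:
                x = self.X[:, i]
                if set(np.unique(x)) <= {0.0, 1.0}:
                    for lv in (0.0, 1.0):
                        m = x == lv
                        if m.any() and (self.y[m].sum() == 0 or (self.n[m] - self.y[m]).sum() == 0):
                            return True
        return False

    def fit(self) -> "RandomInterceptLogitFit":
        from scipy.optimize import minimize

        ridge, flag = 0.0, ""
        if self._separated():
            ridge, flag = 1.0 / 25.0, "penalized_separation"
        rate = np.clip(self.y.sum() / self.n.sum(), 1e-4, 1 - 1e-4)
        x0 = np.zeros(self.X.shape[1] + 1)
        x0[0] = np.log(rate / (1 - rate))
        res = minimize(self._nll, x0, args=(ridge,), method="BFGS",
                       options={"maxiter": 500, "gtol": 1e-6})
        if not np.all(np.isfinite(res.x)):
            raise RuntimeError("logistic mixed model failed to converge")
        H = approx_hess1(res.x, self._nll, args=(ridge,))
        try:
            # cluster-robust (sandwich) covariance at the subject level:
            # model-based information understates the spread of the group
            # coefficient whenever the true random-effect distribution is
            # not exactly logit-normal (e.g., beta-binomial events)
            A_inv = np.linalg.inv(H)
            G = self._score_by_subject(res.x)
            B = G.T @ G
            cov = A_inv @ B @ A_inv
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.full((len(res.x),) * 2, np.nan)
            bse = np.full(len(res.x), np.nan)
            flag = (flag + "+singular_hessian").strip("+")
        df = max(len(self.y) - self.X.shape[1], 1)
        return RandomInterceptLogitFit(self, res.x, bse, cov, float(df), flag)


class RandomInterceptLogitFit:
    def __init__(self, model, params, bse, cov, df, flag):
        self.model = model
        self.params = params
        self.bse = bse
        self.cov = cov
        self.df_inference = df
        self.flag = flag

    @property
    def sigma_u(self) -> float:
        return float(np.exp(self.params[-1]))

    def _empirical_logit_p(self, i: int) -> float:
        """Small-sample-robust p for one coefficient: subject-level
        empirical-logit regression with HC3 covariance.

        Wald and likelihood-ratio tests in binomial mixed models are
        anti-conservative with tens of clusters (also in lme4), so the
        diagnosis-term p value is computed at the cluster level instead.
        """
        m = self.model
        lo = np.log((m.y + 0.5) / (m.n - m.y + 0.5))
        res = sm.OLS(lo, m.X).fit(cov_type="HC3")
        t = res.params[i] / res.bse[i]
        df = max(len(m.y) - m.X.shape[1], 1)
        return float(np.clip(2 * sps.t.sf(abs(t), df), np.nextafter(0, 1), 1.0))

    def effect(self, outcome_name: str, term: str = "group") -> EffectEstimate:
        i = self.model.term_cols[term][0]
        b, se = float(self.params[i]), float(self.bse[i])
        lo, hi, _ = _wald(b, se, self.df_inference)
        p = self._empirical_logit_p(i)
        return EffectEstimate(
            outcome_name=outcome_name, model="logistic_ml", b=b, ci_low=lo,
            ci_high=hi, p_raw=p, odds_ratio=float(np.exp(b)), se=se,
            df=self.df_inference,
            covariates_included=[t for t in self.model.terms if t != term],
            flag=self.flag,
        )


def fit_event_logistic(data: pd.DataFrame, outcome: str, covariates=(),
                       outcome_name: str | None = None) -> EffectEstimate:
    fit = RandomInterceptLogit(data, outcome, terms=["group", *covariates]).fit()
    return fit.effect(outcome_name or outcome)


# ---------------------------------------------------------------------------
# subject-level OLS
# ---------------------------------------------------------------------------

class SubjectOLS:
    """OLS of a one-value-per-subject scalar on diagnosis (+ covariates)."""

    def __init__(self, data: pd.DataFrame, outcome: str, terms=("group",)):
        d = data.dropna(subset=[outcome]).reset_index(drop=True)
        if d.empty:
            raise ValueError("no usable rows")
        y = d[outcome].astype(float)
        if y.std(ddof=1) < 1e-12:
            raise ValueError(f"outcome {outcome!r} has zero variance")
        self.data = d
        self.outcome = outcome
        self.terms = list(terms)
        self.X, self.names, self.term_cols = _design(d, self.terms)
        self.y = y.to_numpy()

    def fit(self) -> "SubjectOLSFit":
        res = sm.OLS(self.y, self.X).fit()
        return SubjectOLSFit(self, res)


class SubjectOLSFit:
    def __init__(self, model, res):
        self.model = model
        self.sm_result = res

    def effect(self, outcome_name: str, term: str = "group") -> EffectEstimate:
        i = self.model.term_cols[term][0]
        res = self.sm_result
        b, se = float(res.params[i]), float(res.bse[i])
        df = float(res.df_resid)
        lo, hi, p = _wald(b, se, df)
        x = self.model.X[:, i]
        beta_std = b * x.std(ddof=1) / self.model.y.std(ddof=1)
        return EffectEstimate(
            outcome_name=outcome_name, model="ols", b=b, ci_low=lo, ci_high=hi,
            p_raw=p, beta_std=float(beta_std), se=se, df=df,
            covariates_included=[t for t in self.model.terms if t != term],
        )


def fit_subject_ols(data: pd.DataFrame, outcome: str, covariates=(),
                    outcome_name: str | None = None) -> EffectEstimate:
    return SubjectOLS(data, outcome, terms=["group", *covariates]).fit().effect(
        outcome_name or outcome
    )


# ---------------------------------------------------------------------------
# multiplicity, contingency, rank-sum
# ---------------------------------------------------------------------------

def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[i]))
        adj[i] = running
    return adj


def chi_square_2x2(table) -> ContingencyResult:
    """Pearson chi-square (no continuity correction) + Fisher exact, df=1."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    _, fisher_p = sps.fisher_exact(t)
    return ContingencyResult(chi2=float(chi2), df=int(df), p=float(p),
                             fisher_p=float(fisher_p), continuity_corrected=False)


def rank_sum(values_a, values_b) -> RankSumResult:
    """Wilcoxon rank-sum with continuity correction; r = Z / sqrt(N).

    ``W`` is the Mann-Whitney U statistic of the first sample (the
    convention used by R's ``wilcox.test``).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    W = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2.0
    N = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * ((N + 1) - tie_term))
    if sigma == 0:
        return RankSumResult(W=W, p=1.0, r_effect=0.0)
    diff = W - mu
    z = (diff - 0.5 * np.sign(diff)) / sigma if diff != 0 else 0.0
    p = float(np.clip(2 * sps.norm.sf(abs(z)), np.nextafter(0, 1), 1.0))
    return RankSumResult(W=W, p=p, r_effect=float(z / np.sqrt(N)))
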