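"""High-level study interface: ``StartleStudy(sessions).fit() -> StudyResults``.

``StartleStudy`` is the model object a user builds from a list of sessions
(or a directory of session files); ``fit`` runs the full extraction +
group-comparison pipeline and returns a :class:`StudyResults` carrying the
trial- and subject-level tables, the fitted group contrasts with their
uncertainties and Holm-adjusted p values, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import startle as st
from . import stats as gs
from .io import Session, read_session

#: Holm families: adjustment is applied within each outcome category.
_BEHAVIOR_LOGIT = ("screen_avoidance", "headphone_touch", "vocalization")
_BEHAVIOR_OLS = (
    "postural_sd", "head_rotation_pct", "mouth_area_mean", "pupil_range",
    "side_eye", "baseline_intercept", "baseline_sd",
)


class StartleStudy:
    """A cohort of sessions plus the analysis configuration."""

    def __init__(self, sessions: list[Session], behavior_config: bhv.BehaviorConfig | None = None):
        if not sessions:
            raise ValueError("no sessions")
        self.sessions = sessions
        self.behavior_config = behavior_config or bhv.DEFAULT_CONFIG

    @classmethod
    def from_dir(cls, path: str | Path, **kw) -> "StartleStudy":
        files = sorted(Path(path).glob("*.json"))
        return cls([read_session(f) for f in files], **kw)

    def fit(self, adjusted: bool = True) -> "StudyResults":
        """Extract all outcomes and fit every group contrast.

        With ``adjusted=True`` each contrast is also fitted with age and sex
        as covariates; both versions are reported side by side.
        """
        amp = st.amplitude_table(self.sessions)
        cs = st.cumsum_table(self.sessions)
        nm = st.neurometrics_table(self.sessions)
        bt = bhv.behavior_table(self.sessions, self.behavior_config)
        ev = bhv.event_trial_table(self.sessions, self.behavior_config)

        effects: list[dict] = []
        skipped: list[tuple[str, str]] = []
        covsets = [((), False)]
        if adjusted:
            covsets.append((("age_years", "sex"), True))

        def add(category, name, fn, is_adj, covs):
            try:
                eff = fn()
            except (ValueError, RuntimeError) as e:
                skipped.append((name, str(e)))
                return
            row = {
                "category": category, "outcome": name, "model": eff.model,
                "adjusted": is_adj, "b": eff.b, "ci_low": eff.ci_low,
                "ci_high": eff.ci_high, "p_raw": eff.p_raw,
                "beta_std": eff.beta_std, "odds_ratio": eff.odds_ratio,
                "se": eff.se, "flag": eff.flag,
                "covariates": ",".join(covs),
            }
            effects.append(row)

        t1 = amp[(amp["test"] == "I") & (amp["window"] == "S1")]
        for covs, is_adj in covsets:
            add("asr", "amp_pulse_only",
                lambda c=covs: gs.fit_group_lmm(t1[t1["condition"] == "pulse_only"], "amplitude", c),
                is_adj, covs)
            for kind in ("pp5", "pp10", "pp25"):
                add("test1_amplitude", f"amp_{kind}",
                    lambda k=kind, c=covs: gs.fit_group_lmm(t1[t1["condition"] == k], "amplitude", c),
                    is_adj, covs)
            add("longterm", "longterm_r",
                lambda c=covs: gs.fit_subject_ols(nm, "longterm_r", c), is_adj, covs)
            for kind in ("pulse_only", "pp5", "pp10", "pp25"):
                add("variability", f"amp_{kind}_sd",
                    lambda k=kind, c=covs: gs.fit_subject_ols(nm, f"amp_{k}_sd", c),
                    is_adj, covs)
            for pat in ("rhythmic", "random"):
                add("cumsum", f"cumsum_{pat}",
                    lambda p=pat, c=covs: gs.fit_group_lmm(cs[cs["condition"] == p], "max_cumsum", c),
                    is_adj, covs)
                add("cumsum_variability", f"cumsum_{pat}_sd",
                    lambda p=pat, c=covs: gs.fit_subject_ols(nm, f"cumsum_{p}_sd", c),
                    is_adj, covs)
                for w in ("ow1", "ow2"):
                    sub = amp[(amp["condition"] == pat) & (amp["window"] == w.upper())]
                    add("aeb", f"aeb_{pat}_{w}",
                        lambda s=sub, c=covs: gs.fit_group_lmm(s, "amplitude", c),
                        is_adj, covs)
            for kind in _BEHAVIOR_LOGIT:
                add("behavior", kind,
                    lambda k=kind, c=covs: gs.fit_event_logistic(ev, k, c), is_adj, covs)
            for col in _BEHAVIOR_OLS:
                add("behavior", col,
                    lambda k=col, c=covs: gs.fit_subject_ols(bt, k, c), is_adj, covs)

        eff = pd.DataFrame(effects)
        if not eff.empty:
            eff["p_holm"] = np.nan
            for (_, _), idx in eff.groupby(["category", "adjusted"]).groups.items():
                eff.loc[idx, "p_holm"] = gs.holm_adjust(eff.loc[idx, "p_raw"].to_numpy())
        return StudyResults(
            study=self, amplitude=amp, cumsum=cs, neurometrics=nm,
            behavior=bt, events=ev, effects=eff, skipped=skipped,
        )


@dataclass
class StudyResults:
    study: StartleStudy
    amplitude: pd.DataFrame
    cumsum: pd.DataFrame
    neurometrics: pd.DataFrame
    behavior: pd.DataFrame
    events: pd.DataFrame
    effects: pd.DataFrame
    skipped: list = field(default_factory=list)

    def group_means(self) -> pd.DataFrame:
        """Per-group means of every subject-level outcome (neurometrics + behavior)."""
        num_nm = self.neurometrics.select_dtypes(include=[float, int]).columns
        nm = self.neurometrics.groupby("group")[list(num_nm)].mean(numeric_only=True)
        num_bt = [c for c in self.behavior.columns
                  if c not in ("subject_id", "group", "sex")]
        bt = self.behavior.groupby("group")[num_bt].mean(numeric_only=True)
        return pd.concat([nm, bt], axis=1)

    def summary(self, adjusted: bool = False) -> str:
        e = self.effects[self.effects["adjusted"] == adjusted].copy()
        e["effect"] = np.where(
            e["odds_ratio"].notna(), "OR=" + e["odds_ratio"].round(2).astype(str),
            "beta=" + e["beta_std"].round(2).astype(str),
        )
        cols = ["category", "outcome", "model", "b", "ci_low", "ci_high",
                "effect", "p_raw", "p_holm"]
        with pd.option_context("display.float_format", "{:0.4f}".format):
            body = e[cols].to_string(index=False)
        head = (
            f"StartleStudy results — {len(self.study.sessions)} subjects "
            f"({(self.neurometrics['group'] == 'autism').sum()} autism, "
            f"{(self.neurometrics['group'] == 'neurotypical').sum()} neurotypical); "
            f"{'age/sex-adjusted' if adjusted else 'unadjusted'} contrasts\n"
        )
        return head + body

    # ------------------------------------------------------------------
    # plots (qualitative; numeric acceptance lives in the tables)
    # ------------------------------------------------------------------

    def plot_mean_traces(self, test: str = "I", ax=None):
        """Group-averaged eyelid traces per condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for grp, color in (("autism", "tab:blue"), ("neurotypical", "tab:orange")):
            acc: dict[str, list] = {}
            t_axis = None
            for sess in self.study.sessions:
                if sess.group != grp:
                    continue
                trials = sess.trials_test1 if test == "I" else sess.trials_test2
                for tr in trials:
                    t_axis = tr.frames.t_ms
                    acc.setdefault(tr.condition, []).append(
                        np.where(tr.frames.face_detected, tr.frames.nec, np.nan)
                    )
            for cond, stack in sorted(acc.items()):
                arr = np.vstack([a for a in stack if a.size == stack[0].size])
                with np.errstate(invalid="ignore"):
                    ax.plot(t_axis, np.nanmean(arr, axis=0),
                            color=color, alpha=0.6, lw=1,
                            label=f"{grp} {cond}")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("NEC")
        ax.legend(fontsize=6)
        return ax

    def plot_ppi(self, ax=None):
        """Mean startle amplitude as a function of prepulse intensity."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        order = ["pulse_only", "pp5", "pp10", "pp25"]
        for grp in ("autism", "neurotypical"):
            sub = self.neurometrics[self.neurometrics["group"] == grp]
            means = [sub[f"amp_{c}_mean"].mean() for c in order]
            sems = [sub[f"amp_{c}_mean"].sem() for c in order]
            ax.errorbar(range(4), means, yerr=np.asarray(sems) * 1.96, label=grp, marker="o")
        ax.set_xticks(range(4), ["pulse", "pp5%", "pp10%", "pp25%"])
        ax.set_ylabel("mean startle amplitude (NEC)")
        ax.legend()
        return ax

    def plot_behavior(self, metric: str, ax=None):
        """Box + strip plot of one behavioral biomarker by group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        data = [self.behavior.loc[self.behavior["group"] == g, metric].dropna()
                for g in ("autism", "neurotypical")]
        ax.boxplot(data, tick_labels=["autism", "NT"])
        ax.set_ylabel(metric)
        return ax
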