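"""Pipeline orchestration, cohort-description tables, and reproducibility.

``run_pipeline`` chains simulate -> extract -> stats -> report, writing TSV
tables, qualitative figures and a manifest that suffices to re-run the
pipeline bit-identically.  ``table1_summary`` reproduces the demographic
arithmetic of a case-control enrolment table (success proportions, sex and
age composition, rejection breakdown) together with its tests: Fisher exact
on success x diagnosis, chi-square (no continuity correction) on
sex x diagnosis among successful participants, and a rank-sum test on age.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as gs
from .io import write_session
from .synth import CohortConfig, generate_cohort, params_hash
from .study import StartleStudy

#: Demographic composition of the enrolment cohort used for the worked
#: examples: 536 children aged 3-12, autism vs neurotypical, with per-cell
#: counts of sex, age band, documented severity level and rejection reason.
REFERENCE_DEMOGRAPHICS = {
    ("autism", True): {
        "n": 275, "girls": 79, "age_bands": (47, 133, 95),
        "severity": {"level1": 22, "level2": 34, "level3": 33},
        "rejection": {},
    },
    ("neurotypical", True): {
        "n": 156, "girls": 69, "age_bands": (60, 68, 28), "severity": {}, "rejection": {},
    },
    ("autism", False): {
        "n": 95, "girls": 35, "age_bands": (32, 37, 26), "severity": {},
        "rejection": {"volume": 15, "headphone_refusal": 35, "premature_termination": 45},
    },
    ("neurotypical", False): {
        "n": 10, "girls": 3, "age_bands": (5, 3, 2), "severity": {},
        "rejection": {"volume": 1, "headphone_refusal": 3, "premature_termination": 6},
    },
}

_BAND_MID = (4.0, 7.0, 10.5)


def reference_cohort() -> pd.DataFrame:
    """Expand the reference demographic counts into one row per subject.

    Sex, age band, severity label and rejection reason are assigned
    independently within each (group, success) cell, which preserves every
    margin the summary reports.
    """
    rows = []
    for (group, success), cell in REFERENCE_DEMOGRAPHICS.items():
        n = cell["n"]
        sexes = ["girl"] * cell["girls"] + ["boy"] * (n - cell["girls"])
        ages = [m for m, k in zip(_BAND_MID, cell["age_bands"]) for _ in range(k)]
        sev = [lv for lv, k in cell["severity"].items() for _ in range(k)]
        sev += [""] * (n - len(sev))
        rej = [r for r, k in cell["rejection"].items() for _ in range(k)]
        rej += [""] * (n - len(rej))
        for i in range(n):
            rows.append(
                dict(
                    subject_id=f"{group[:2]}{'s' if success else 'r'}{i:04d}",
                    group=group, success=success, sex=sexes[i],
                    age_years=ages[i], severity=sev[i], rejection_reason=rej[i],
                )
            )
    return pd.DataFrame(rows)


def table1_summary(subjects: pd.DataFrame) -> dict:
    """Demographic summary + cohort-description tests from per-subject rows.

    Expects columns group, sex, age_years, success; optional severity and
    rejection_reason.  Missing labels count as unknown (with a warning).
    """
    import warnings

    df = subjects.copy()
    for col, fallback in (("severity", ""), ("rejection_reason", "")):
        if col not in df.columns:
            df[col] = fallback
    if df[["group", "sex", "success"]].isna().any().any():
        warnings.warn("missing group/sex/success labels counted as unknown", stacklevel=2)

    n = len(df)
    succ = df[df["success"].astype(bool)]
    aut_s = succ[succ["group"] == "autism"]
    nt_s = succ[succ["group"] == "neurotypical"]
    aut_r = df[(df["group"] == "autism") & (~df["success"].astype(bool))]

    out = {
        "n_total": n,
        "n_successful": len(succ),
        "pct_success": 100.0 * len(succ) / n,
        "pct_autism_of_successful": 100.0 * len(aut_s) / len(succ) if len(succ) else np.nan,
        "pct_girls_overall": 100.0 * (df["sex"] == "girl").mean(),
        "pct_severity_documented": (
            100.0 * (aut_s["severity"] != "").mean() if len(aut_s) else np.nan
        ),
        "pct_premature_of_autism_rejections": (
            100.0 * (aut_r["rejection_reason"] == "premature_termination").mean()
            if len(aut_r) else np.nan
        ),
        "pct_rejected": 100.0 * (1 - len(succ) / n),
    }

    tests: dict = {}
    if df["group"].nunique() == 2 and 1 < len(succ) < n:
        ok = df["success"].astype(bool)
        aut = df["group"] == "autism"
        tbl = [
            [int((aut & ok).sum()), int((aut & ~ok).sum())],
            [int((~aut & ok).sum()), int((~aut & ~ok).sum())],
        ]
        tests["success_fisher_p"] = gs.chi_square_2x2(tbl).fisher_p
    if len(aut_s) and len(nt_s):
        sex_tbl = np.array(
            [
                [(aut_s["sex"] == "girl").sum(), (aut_s["sex"] == "boy").sum()],
                [(nt_s["sex"] == "girl").sum(), (nt_s["sex"] == "boy").sum()],
            ]
        )
        try:
            cr = gs.chi_square_2x2(sex_tbl.T)
            tests["sex_chi2"] = cr.chi2
            tests["sex_chi2_p"] = cr.p
        except ValueError:
            pass
        rs = gs.rank_sum(aut_s["age_years"], nt_s["age_years"])
        tests["age_ranksum_W"] = rs.W
        tests["age_ranksum_p"] = rs.p
        tests["age_ranksum_r"] = rs.r_effect
    else:
        import warnings as _w

        _w.warn("single-group cohort: tests skipped", stacklevel=2)
    out["tests"] = tests
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    out_dir: str = "startlekit_out"
    n_per_group: int = 20
    seed: int = 0
    frame_rate_hz: float = 60.0
    rejection_prob: float = 0.0
    write_sessions: bool = False
    make_plots: bool = True
    adjusted_models: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate -> extract -> compare; returns paths of everything written."""
    import sys

    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def log(msg):
        print(f"[startlekit +{time.time() - t0:6.1f}s] {msg}", file=sys.stderr)

    cohort_cfg = CohortConfig(
        n_per_group=config.n_per_group, seed=config.seed,
        frame_rate_hz=config.frame_rate_hz, rejection_prob=config.rejection_prob,
    )
    log(f"simulating cohort (n={config.n_per_group}/group, seed={config.seed})")
    sessions, manifest = generate_cohort(cohort_cfg)
    keep = [s for s, ok in zip(sessions, manifest["success"]) if ok]

    paths = {}
    if config.write_sessions:
        sdir = out / "sessions"
        for s in keep:
            write_session(s, sdir / f"{s.subject_id}.json")
        paths["sessions"] = str(sdir)

    log("extracting neurometrics and behavior")
    study = StartleStudy(keep)
    results = study.fit(adjusted=config.adjusted_models)

    log("fitting group contrasts")
    tables = {
        "trial_amplitudes.tsv": results.amplitude,
        "trial_cumsum.tsv": results.cumsum,
        "subject_neurometrics.tsv": results.neurometrics,
        "subject_behavior.tsv": results.behavior,
        "effects.tsv": results.effects,
        "manifest_subjects.tsv": manifest,
    }
    for name, df in tables.items():
        p = out / name
        df.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)

    run_manifest = {
        "seed": config.seed,
        "n_per_group": config.n_per_group,
        "frame_rate_hz": config.frame_rate_hz,
        "params_hash": params_hash(cohort_cfg.group_params),
        "config": asdict(config),
        "n_sessions": len(keep),
        "skipped_contrasts": results.skipped,
    }
    run_manifest["config_hash"] = hashlib.sha1(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:12]
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(run_manifest, fh, indent=1)
    paths["manifest.json"] = str(mpath)

    if config.make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        log("rendering figures")
        for name, fn in (
            ("traces_test1.png", lambda: results.plot_mean_traces("I")),
            ("ppi_curve.png", lambda: results.plot_ppi()),
            ("behavior_vocalization.png", lambda: results.plot_behavior("vocalization_pct")),
        ):
            ax = fn()
            ax.figure.savefig(out / name, dpi=100)
            plt.close(ax.figure)
            paths[name] = str(out / name)

    with open(out / "summary.txt", "w") as fh:
        fh.write(results.summary())
    paths["summary.txt"] = str(out / "summary.txt")
    log("done")
    return {"paths": paths, "results": results, "manifest": run_manifest}
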