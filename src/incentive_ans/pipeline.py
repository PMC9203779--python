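"""End-to-end orchestration: simulate -> EZ fit -> pupillometry -> stats.

The stage functions work on in-memory objects so tests and scripts can
drive them directly; :mod:`incentive_ans.cli` wraps them with file I/O.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from incentive_ans import cohort as co
from incentive_ans import design, ez, pupil
from incentive_ans import stats as st
from incentive_ans.io import RunConfig

__all__ = [
    "simulate_cohort",
    "ez_table",
    "pupil_table",
    "analysis_tables",
    "run_stats",
    "format_report",
]

#: Behavioural and model DVs analysed by default (pupil peaks are added
#: per phase as peak_pd_cue / peak_pd_stimulus / peak_pd_feedback).
BEHAVIOURAL_DVS = ("rt_ms", "accuracy", "v", "a", "t_ER")


def simulate_cohort(
    config: RunConfig,
    with_pupil: bool = True,
) -> list[dict]:
    """Simulate the full synthetic cohort described by ``config``.

    Returns one record per subject: profile, session, trial results and
    (optionally) the raw pupil stream.  Child seeds are spawned
    deterministically from ``config.seed``.
    """
    profiles = co.default_cohort(
        config.seed,
        n_children=config.n_children,
        n_adolescents=config.n_adolescents,
        effect_scale=config.effect_scale,
    )
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(len(profiles))
    records = []
    for profile, seq in zip(profiles, subject_seeds):
        session_seed, sim_seed, pupil_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(3)
        )
        idx = len(records)
        session = design.generate_session(
            seed=session_seed,
            n_blocks=config.n_blocks,
            trials_per_block=config.trials_per_block,
            ratios=config.ratio_fractions(),
            dot_range=tuple(config.dot_range),
            cue_color_reward="pink" if idx % 2 == 0 else "blue",
        )
        results = co.simulate_subject(profile, session, seed=sim_seed)
        rec = {"profile": profile, "session": session, "results": results}
        if with_pupil:
            rec["stream"] = co.synthesize_pupil(
                profile,
                results,
                sampling_rate_hz=config.sampling_rate_hz,
                seed=pupil_seed,
            )
        records.append(rec)
    return records


def ez_table(records: Sequence[dict], rt_window_ms=(250.0, 1500.0)) -> pd.DataFrame:
    """Per subject x condition behavioural summaries + EZ parameters."""
    rows = []
    for rec in records:
        profile = rec["profile"]
        kept, report = ez.filter_rts(rec["results"], *rt_window_ms)
        for cond in ("reward", "control"):
            summ = ez.summarize_condition([t for t in kept if t.incentive == cond])
            row = {
                "subject_id": profile.subject_id,
                "age_group": profile.age_group,
                "incentive": cond,
                "Pc": summ.Pc,
                "MRT_s": summ.MRT,
                "VRT_s2": summ.VRT,
                "n_total": summ.n_total,
                "n_correct": summ.n_correct,
                "n_excluded": sum(
                    v
                    for k, v in report.get(cond, {}).items()
                    if k != "kept"
                ),
                "valid": summ.valid,
            }
            if summ.valid:
                params = ez.ez_fit(summ)
                row.update(v=params.v, a=params.a, t_ER=params.t_ER)
            else:
                row.update(v=np.nan, a=np.nan, t_ER=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def pupil_table(records: Sequence[dict], config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Per subject x condition x phase peak PDs; incomplete subjects dropped.

    Mirrors the exclusion of participants whose cleaned data leave fewer
    than the minimum trials in any condition x phase cell.
    """
    rows = []
    curves: dict = {}
    for rec in records:
        profile = rec["profile"]
        out = pupil.process_subject(
            profile.subject_id,
            rec["stream"],
            min_trials=config.min_trials,
            max_blink_ms=config.max_blink_ms,
            max_missing_frac=config.max_missing_frac,
            guard_ms=config.guard_ms,
        )
        if not out["complete"]:
            continue
        curves[profile.subject_id] = out["curves"]
        for pk in out["peaks"]:
            rows.append(
                {
                    "subject_id": pk.subject,
                    "age_group": profile.age_group,
                    "incentive": pk.condition,
                    "phase": pk.phase,
                    "peak_pd_mm": pk.peak_pd_mm,
                    "n_trials": pk.n_trials_averaged,
                }
            )
    return pd.DataFrame(rows), curves


def analysis_tables(
    ez_df: pd.DataFrame, peaks_df: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Long AnalysisTables (subject, group, incentive, dv_value) per DV."""
    tables: dict[str, pd.DataFrame] = {}
    base = ez_df[ez_df["valid"]].copy()
    base["rt_ms"] = base["MRT_s"] * 1000.0
    base["accuracy"] = base["Pc"]
    # only subjects with both conditions valid stay balanced
    ok = base.groupby("subject_id")["incentive"].transform("nunique") == 2
    base = base[ok]
    for dv in BEHAVIOURAL_DVS:
        tables[dv] = base.rename(columns={dv: "dv_value"})[
            ["subject_id", "age_group", "incentive", "dv_value"]
        ].copy()
    if peaks_df is not None and len(peaks_df):
        for phase in ("cue", "stimulus", "feedback"):
            sub = peaks_df[peaks_df["phase"] == phase].rename(
                columns={"peak_pd_mm": "dv_value"}
            )[["subject_id", "age_group", "incentive", "dv_value"]]
            tables[f"peak_pd_{phase}"] = sub.copy()
    return tables


def run_stats(
    tables: dict[str, pd.DataFrame],
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit the Incentive x Age Group model per DV; permutation fallback
    whenever the residuals fail the Shapiro-Wilk check."""
    rows = []
    for dv, table in tables.items():
        results, model = st.fit_lmm(table)
        perm = st.residual_check_and_permute(
            model, table, n_perm=n_perm, seed=seed
        )
        for res in results:
            rows.append(
                {
                    "dv": dv,
                    "term": res.term,
                    "F": res.F,
                    "df_num": res.df_num,
                    "df_den": res.df_den,
                    "p": res.p,
                    "eta_p_sq": res.eta_p_sq,
                    "p_perm": perm["terms"][res.term]["p_perm"],
                    "residuals_normal": perm["normal"],
                    "significant": res.p <= alpha,
                }
            )
    return pd.DataFrame(rows)


def format_report(stats_df: pd.DataFrame) -> str:
    """Plain-text report mirroring a results-section layout."""
    lines = ["Incentive x Age Group mixed-effects results", "=" * 44]
    for dv, grp in stats_df.groupby("dv", sort=False):
        lines.append(f"\n{dv}:")
        for r in grp.itertuples():
            note = "" if r.residuals_normal else f" (perm p = {r.p_perm:.4f})"
            lines.append(
                f"  {r.term:<24s} F({r.df_num:g},{r.df_den:g}) = {r.F:6.2f}, "
                f"p = {r.p:.4f}, eta_p^2 = {r.eta_p_sq:.2f}{note}"
            )
    return "\n".join(lines) + "\n"
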