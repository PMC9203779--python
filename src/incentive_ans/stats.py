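"""Between-within mixed-effects inference.

The study design is one observation per subject x incentive condition
(reward vs control, within) with subjects nested in two age groups
(children vs adolescents, between).  Models are linear mixed-effects with
random subject intercepts, fitted by maximum likelihood; fixed-effect F
tests follow the classical between-within (split-plot) convention, which
for this balanced two-level design gives every term 1 numerator df and
``N_subjects - 2`` denominator dfs — 51 for the default 23 + 30 cohort.

For a balanced two-level within factor the split-plot F statistics have an
exact closed form in terms of per-subject condition means ``m_i`` and
differences ``d_i`` (effect-coded / unweighted-means, i.e. Type III):

    F(Incentive)       tests  (d_bar_1 + d_bar_2) / 2 = 0
    F(Incentive x Age) tests   d_bar_1 - d_bar_2      = 0
    F(Age Group)       tests   m_bar_1 - m_bar_2      = 0

each against the pooled within-group residual of the respective score.
Effect sizes are partial eta squared, eta_p^2 = F*df1 / (F*df1 + df2).
Posthoc pairwise t-tests (paired within, Welch between) are Holm-corrected.
When model residuals fail a Shapiro-Wilk normality check, seeded
permutation tests (within-subject condition swaps for within-factor terms,
subject-level group shuffles for between terms) provide fallback p-values.

A Greenhouse-Geisser-corrected mixed ANOVA with up to two within-subject
factors (:func:`mixed_anova_gg`) supports the gaze-parallax QC analysis
(Incentive x Phase x Age Group with epsilon-adjusted dfs for the
three-level Phase factor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FixedEffectResult",
    "fit_lmm",
    "partial_eta_squared",
    "holm_adjust",
    "holm_pairwise",
    "residual_check_and_permute",
    "mixed_anova_gg",
    "split_plot_f",
    "pivot_analysis_table",
]


@dataclass(frozen=True)
class FixedEffectResult:
    """One fixed-effect F test with its effect size."""

    term: str
    F: float
    df_num: float
    df_den: float
    p: float
    eta_p_sq: float


def partial_eta_squared(
    F: float, df_num: float, df_den: float, round_to: int | None = None
) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError("F must be non-negative")
    if df_num <= 0 or df_den <= 0:
        raise ValueError("degrees of freedom must be positive")
    eta = F * df_num / (F * df_num + df_den)
    return round(eta, round_to) if round_to is not None else eta


# ---------------------------------------------------------------------------
# split-plot F tests (2 within-levels x 2 groups)

def _two_group_f(z: np.ndarray, g1: np.ndarray, contrast: str) -> tuple[float, float]:
    """F test on scores ``z`` (subjects,) split by boolean group mask ``g1``.

    ``contrast="sum"`` tests the subject-weighted grand mean of ``z`` = 0
    (the sequential-ANOVA convention of nlme-style model comparisons, which
    the weighted grand mean reduces to for a two-level within factor);
    ``contrast="diff"`` tests z_bar1 - z_bar2 = 0.  Error is the pooled
    within-group residual with N - 2 dfs.  Returns (F, df_den).
    """
    n1, n2 = int(g1.sum()), int((~g1).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    zb1, zb2 = z[g1].mean(), z[~g1].mean()
    sse = ((z[g1] - zb1) ** 2).sum() + ((z[~g1] - zb2) ** 2).sum()
    df_den = n1 + n2 - 2
    mse = sse / df_den
    n = n1 + n2
    if contrast == "sum":
        est = z.mean()
        unit_var = 1.0 / n
    else:
        est = (zb1 - zb2) / 2.0
        unit_var = (1.0 / n1 + 1.0 / n2) / 4.0
    var = mse * unit_var
    if var == 0:
        return (math.inf if est != 0 else 0.0), df_den
    return float(est**2 / var), df_den


def split_plot_f(
    m: np.ndarray, d: np.ndarray, g1: np.ndarray
) -> dict[str, tuple[float, float]]:
    """Closed-form split-plot F tests from subject means/differences.

    ``m`` = per-subject mean over the two conditions, ``d`` = reward minus
    control difference, ``g1`` = boolean mask of the first age group.
    Returns {term: (F, df_den)} with df_num = 1 throughout.
    """
    return {
        "Incentive": _two_group_f(d, g1, "sum"),
        "Age Group": _two_group_f(m, g1, "diff"),
        "Incentive x Age Group": _two_group_f(d, g1, "diff"),
    }


def pivot_analysis_table(
    table: pd.DataFrame,
    dv: str = "dv_value",
    subject: str = "subject_id",
    within: str = "incentive",
    between: str = "age_group",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Long table -> (m, d, group-1 mask, subject order); validates balance."""
    wide = table.pivot_table(
        index=[subject, between], columns=within, values=dv, aggfunc="first"
    )
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"unbalanced within-subject cells for {missing}")
    levels = sorted(wide.columns)
    if len(levels) != 2:
        raise ValueError("fit_lmm expects exactly two within-factor levels")
    # reward - control orientation when those labels are present
    hi, lo = ("reward", "control") if set(levels) == {"reward", "control"} else (
        levels[1],
        levels[0],
    )
    m = wide.mean(axis=1).to_numpy()
    d = (wide[hi] - wide[lo]).to_numpy()
    groups = wide.index.get_level_values(between)
    g_levels = sorted(set(groups))
    if len(g_levels) != 2:
        raise ValueError("fit_lmm expects exactly two between-factor levels")
    g1 = np.asarray(groups == g_levels[0])
    return m, d, g1, list(wide.index.get_level_values(subject))


def fit_lmm(
    table: pd.DataFrame,
    dv: str = "dv_value",
    subject: str = "subject_id",
    within: str = "incentive",
    between: str = "age_group",
    fit_model: bool = True,
) -> tuple[list[FixedEffectResult], object | None]:
    """Fit the Incentive x Age Group model and test its fixed effects.

    Returns the F tests (Incentive, Age Group, Incentive x Age Group; each
    F(1, N-2)) and, when ``fit_model`` is true, a maximum-likelihood
    statsmodels ``MixedLM`` fit with random subject intercepts whose
    residuals feed the normality check.
    """
    m, d, g1, _ = pivot_analysis_table(table, dv, subject, within, between)
    results = []
    for term, (F, df_den) in split_plot_f(m, d, g1).items():
        p = float(sps.f.sf(F, 1, df_den))
        results.append(
            FixedEffectResult(
                term=term,
                F=F,
                df_num=1,
                df_den=df_den,
                p=p,
                eta_p_sq=partial_eta_squared(F, 1, df_den),
            )
        )
    handle = None
    if fit_model:
        import statsmodels.formula.api as smf

        df = table.rename(
            columns={dv: "y", subject: "subj", within: "w", between: "b"}
        )
        model = smf.mixedlm("y ~ C(w) * C(b)", df, groups=df["subj"])
        errors = []
        for method in ("lbfgs", "powell", "nm"):
            try:
                handle = model.fit(reml=False, method=method)
                break
            except Exception as err:
                errors.append(f"{method}: {err}")
        else:  # degenerate input: surface loudly, no silent fallback
            raise RuntimeError(
                "mixed model failed to converge: " + "; ".join(errors)
            )
    return results, handle


# ---------------------------------------------------------------------------
# Holm-corrected posthocs

def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment, preserving input order.

    Sort ascending, multiply p_(i) by (m - i), enforce monotonicity along
    the sorted sequence, cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass(frozen=True)
class Contrast:
    """One posthoc pairwise contrast.

    ``kind="paired"`` runs a paired t-test (within-subject comparison);
    ``kind="welch"`` a Welch two-sample t-test (between-group comparison,
    no equal-variance assumption, Welch-Satterthwaite dfs).
    """

    name: str
    kind: str
    x: np.ndarray
    y: np.ndarray


def holm_pairwise(contrasts: Sequence[Contrast], alpha: float = 0.05) -> pd.DataFrame:
    """Run the pairwise t-tests and Holm-correct across them."""
    if len(contrasts) == 0:
        raise ValueError("need at least one contrast")
    rows = []
    for c in contrasts:
        if c.kind == "paired":
            t, p = sps.ttest_rel(c.x, c.y)
            df = len(c.x) - 1
        elif c.kind == "welch":
            res = sps.ttest_ind(c.x, c.y, equal_var=False)
            t, p = res.statistic, res.pvalue
            df = res.df
        else:
            raise ValueError(f"unknown contrast kind {c.kind!r}")
        rows.append({"contrast": c.name, "t": float(t), "df": float(df), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    out["reject"] = out["p_holm"] <= alpha
    return out


# ---------------------------------------------------------------------------
# residual normality check + permutation fallback

def residual_check_and_permute(
    model,
    table: pd.DataFrame,
    dv: str = "dv_value",
    subject: str = "subject_id",
    within: str = "incentive",
    between: str = "age_group",
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Shapiro-Wilk on model residuals plus seeded permutation p-values.

    Permutation schemes respect the design's exchangeability: the within
    factor (and its interaction with group) permutes by swapping the two
    condition labels within subjects (a sign flip of the difference score);
    the between factor permutes by shuffling group membership across
    subjects.  Reports parametric and permutation p per term.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 is too unstable; refuse")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    resid = np.asarray(model.resid) if model is not None else None
    shapiro_w = shapiro_p = math.nan
    if resid is not None and resid.size >= 3:
        shapiro_w, shapiro_p = (float(v) for v in sps.shapiro(resid))

    m, d, g1, _ = pivot_analysis_table(table, dv, subject, within, between)
    n = m.size
    n1 = int(g1.sum())
    obs = split_plot_f(m, d, g1)

    # within-subject sign flips: Sum d_perm^2 is invariant, so the permuted
    # F has closed form from the permuted group means alone
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    d_perm = signs * d
    f_inc = _batch_f(d_perm, g1, "sum")
    # subject-level group shuffles for the between term and the interaction
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    f_age = _batch_f(np.take(m, perm_idx), _const_mask(n, n1), "diff")
    f_int = _batch_f(np.take(d, perm_idx), _const_mask(n, n1), "diff")

    def pval(null_f: np.ndarray, f_obs: float) -> float:
        return float((1 + np.sum(null_f >= f_obs)) / (n_perm + 1))

    report = {
        "shapiro_w": shapiro_w,
        "shapiro_p": shapiro_p,
        "normal": bool(shapiro_p > 0.05) if np.isfinite(shapiro_p) else None,
        "terms": {},
    }
    null_by_term = {
        "Incentive": f_inc,
        "Age Group": f_age,
        "Incentive x Age Group": f_int,
    }
    for term, (F, df_den) in obs.items():
        report["terms"][term] = {
            "F": F,
            "p_param": float(sps.f.sf(F, 1, df_den)),
            "p_perm": pval(null_by_term[term], F),
        }
    return report


def _const_mask(n: int, n1: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    mask[:n1] = True
    return mask


def _batch_f(z: np.ndarray, g1: np.ndarray, contrast: str) -> np.ndarray:
    """Vectorized :func:`_two_group_f` over rows of ``z`` (n_perm x n)."""
    n1, n2 = int(g1.sum()), int((~g1).sum())
    zb1 = z[:, g1].mean(axis=1)
    zb2 = z[:, ~g1].mean(axis=1)
    sse = ((z[:, g1] - zb1[:, None]) ** 2).sum(axis=1) + (
        (z[:, ~g1] - zb2[:, None]) ** 2
    ).sum(axis=1)
    mse = sse / (n1 + n2 - 2)
    if contrast == "sum":
        est = z.mean(axis=1)
        var = mse / (n1 + n2)
    else:
        est = (zb1 - zb2) / 2.0
        var = mse / 4.0 * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(var > 0, est**2 / var, np.where(est != 0, np.inf, 0.0))
    return f


def null_type1_rates(
    n_reps: int = 1000,
    n_per_group: tuple[int, int] = (10, 10),
    n_perm: int = 400,
    alpha: float = 0.05,
    seed: int = 0,
    subject_sd: float = 1.0,
    noise_sd: float = 0.7,
) -> dict[str, dict[str, float]]:
    """Type-I error calibration of the split-plot F tests and their
    permutation fallback under the model's null generative form.

    Each replicate draws a cohort with Gaussian random subject intercepts
    and condition noise but no fixed effects; under that null the subject
    condition-means ``m`` and differences ``d`` are independent normals.
    Returns per-term empirical rejection rates at ``alpha`` for the
    parametric F test and the permutation test.
    """
    rng = np.random.default_rng(seed)
    n1, n2 = n_per_group
    n = n1 + n2
    g1 = _const_mask(n, n1)
    d_sd = math.sqrt(2.0) * noise_sd  # var(d) = 2 * noise variance
    m_sd = math.sqrt(subject_sd**2 + noise_sd**2 / 2.0)
    terms = ("Incentive", "Age Group", "Incentive x Age Group")
    rej = {t: {"param": 0, "perm": 0} for t in terms}
    for _ in range(n_reps):
        m = rng.normal(0.0, m_sd, n)
        d = rng.normal(0.0, d_sd, n)
        obs = split_plot_f(m, d, g1)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        null_f = {
            "Incentive": _batch_f(signs * d, g1, "sum"),
            "Age Group": _batch_f(np.take(m, perm_idx), g1, "diff"),
            "Incentive x Age Group": _batch_f(np.take(d, perm_idx), g1, "diff"),
        }
        for t in terms:
            F, df_den = obs[t]
            if sps.f.sf(F, 1, df_den) <= alpha:
                rej[t]["param"] += 1
            p_perm = (1 + np.sum(null_f[t] >= F)) / (n_perm + 1)
            if p_perm <= alpha:
                rej[t]["perm"] += 1
    return {
        t: {k: v / n_reps for k, v in c.items()} for t, c in rej.items()
    }


# ---------------------------------------------------------------------------
# Greenhouse-Geisser mixed ANOVA (up to two within factors)

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal sum-to-zero contrast rows."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1)
    q, _ = np.linalg.qr(helmert.T)
    return q.T  # rows orthonormal, each orthogonal to the unit vector


def mixed_anova_gg(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: Sequence[str],
) -> pd.DataFrame:
    """Mixed ANOVA with Greenhouse-Geisser-corrected dfs for within terms.

    Supports one between-subject factor (two levels) and one or two fully
    crossed within-subject factors; each subject must contribute exactly
    one value per within-cell.  Within-factor terms with more than one
    numerator df get epsilon-adjusted degrees of freedom estimated from
    the pooled covariance of their orthonormal contrast scores; terms with
    a single df are unaffected (epsilon = 1).  Sums of squares follow the
    unweighted-means (Type III) convention, matching :func:`fit_lmm`.
    """
    within = list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("mixed_anova_gg supports one or two within factors")
    levels = [sorted(table[w].unique()) for w in within]
    if len(within) == 1:
        cells = pd.Index(levels[0], name=within[0])
        wide = table.pivot_table(
            index=[subject, between], columns=within[0], values=dv, aggfunc="first"
        ).reindex(columns=cells)
    else:
        cells = pd.MultiIndex.from_product(levels, names=within)
        wide = table.pivot_table(
            index=[subject, between], columns=within, values=dv, aggfunc="first"
        ).reindex(columns=cells)
    if wide.isna().any().any():
        raise ValueError("missing within-subject cells")
    Y = wide.to_numpy()
    groups = wide.index.get_level_values(between)
    g_levels = sorted(set(groups))
    if len(g_levels) != 2:
        raise ValueError("between factor must have two levels")
    g1 = np.asarray(groups == g_levels[0])
    n1, n2 = int(g1.sum()), int((~g1).sum())
    df_den_sub = n1 + n2 - 2

    k_levels = [len(lv) for lv in levels]
    bases = {w: _orthonormal_contrasts(k) for w, k in zip(within, k_levels)}
    ones = [np.ones((1, k)) / math.sqrt(k) for k in k_levels]

    def term_basis(involved: tuple[bool, ...]) -> np.ndarray:
        mats = [
            bases[w] if inv else ones[i]
            for i, (w, inv) in enumerate(zip(within, involved))
        ]
        out = mats[0]
        for mat in mats[1:]:
            out = np.kron(out, mat)
        return out

    terms: list[tuple[str, tuple[bool, ...]]] = []
    if len(within) == 1:
        terms = [(within[0], (True,))]
    else:
        terms = [
            (within[0], (True, False)),
            (within[1], (False, True)),
            (f"{within[0]} x {within[1]}", (True, True)),
        ]

    rows = []
    # between-subject main effect on the subject means
    z0 = Y.mean(axis=1)
    F_b, _ = _two_group_f(z0, g1, "diff")
    rows.append(_anova_row(between, F_b, 1.0, float(df_den_sub)))

    for name, involved in terms:
        C = term_basis(involved)
        k = C.shape[0]
        Z = Y @ C.T  # (N, k) contrast scores
        zb1 = Z[g1].mean(axis=0)
        zb2 = Z[~g1].mean(axis=0)
        R = np.vstack([Z[g1] - zb1, Z[~g1] - zb2])
        sse = float((R**2).sum())
        mse = sse / (k * df_den_sub)
        scale = 4.0 / (1.0 / n1 + 1.0 / n2)
        # within main effect: subject-weighted grand mean (matches fit_lmm)
        ss_within = float((n1 + n2) * (Z.mean(axis=0) ** 2).sum())
        ss_inter = float((((zb1 - zb2) / 2.0) ** 2).sum()) * scale
        if k > 1:
            S = (R.T @ R) / df_den_sub
            eps = float(np.trace(S) ** 2 / (k * np.trace(S @ S)))
            eps = min(max(eps, 1.0 / k), 1.0)
        else:
            eps = 1.0
        for label, ss in ((name, ss_within), (f"{name} x {between}", ss_inter)):
            F = (ss / k) / mse if mse > 0 else math.inf
            rows.append(_anova_row(label, F, k * eps, k * df_den_sub * eps, eps))
    return pd.DataFrame(rows)


def _anova_row(
    term: str, F: float, df1: float, df2: float, eps: float = 1.0
) -> dict:
    return {
        "term": term,
        "F": float(F),
        "df_num": round(df1, 2),
        "df_den": round(df2, 2),
        "eps": round(eps, 4),
        "p": float(sps.f.sf(F, df1, df2)),
        "eta_p_sq": partial_eta_squared(F, df1, df2),
    }
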