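"""EZ-diffusion decomposition of two-choice behaviour.

The EZ-diffusion model inverts three summary statistics of a condition —
proportion correct ``Pc``, and the mean ``MRT`` and variance ``VRT`` of
correct-response RTs (seconds) — into the three core parameters of the
drift-diffusion model:

- drift rate ``v``: speed/quality of evidence accumulation (here an index
  of approximate-number-system precision),
- boundary separation ``a``: response caution (evidence required to decide),
- non-decision time ``t_ER``: encoding + motor time outside the diffusion.

With logit ``L = ln(Pc / (1 - Pc))`` and diffusion scaling ``s`` (0.1 by
convention), the closed forms are::

    x    = L * (L*Pc**2 - L*Pc + Pc - 1/2) / VRT
    v    = sign(Pc - 1/2) * s * x**(1/4)
    a    = s**2 * L / v
    MDT  = (a / (2*v)) * (1 - exp(-v*a/s**2)) / (1 + exp(-v*a/s**2))
    t_ER = MRT - MDT

``ez_forward`` evaluates the exact inverse mapping (parameters ->
predicted summaries) for round-trip testing and simulation cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TrialResult",
    "ConditionSummary",
    "EZParams",
    "filter_rts",
    "summarize_condition",
    "ez_fit",
    "ez_forward",
    "check_suitability",
    "RT_WINDOW_MS",
]

#: Inclusive RT window (ms) retained for analysis.
RT_WINDOW_MS: tuple[float, float] = (250.0, 1500.0)


@dataclass(frozen=True)
class TrialResult:
    """One observed trial: RT in ms (None on omission), accuracy, points."""

    block_index: int
    trial_index: int
    incentive: str
    rt_ms: float | None
    correct: bool
    points_delta: int = 0


@dataclass(frozen=True)
class ConditionSummary:
    """Per subject x condition EZ input: (Pc, MRT, VRT) plus bookkeeping.

    ``MRT``/``VRT`` are over correct kept trials only, in seconds; ``VRT``
    uses the unbiased (n-1) estimator.  ``valid`` is False when the summary
    cannot support an EZ fit (fewer than 2 correct trials or zero variance).
    """

    Pc: float
    MRT: float
    VRT: float
    n_total: int
    n_correct: int
    n_filtered_out: int = 0
    valid: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.Pc <= 1.0):
            raise ValueError("Pc must lie in [0, 1]")
        if self.n_correct > self.n_total:
            raise ValueError("n_correct cannot exceed n_total")
        if self.valid and self.VRT < 0:
            raise ValueError("VRT must be non-negative")


@dataclass(frozen=True)
class EZParams:
    """Drift-diffusion parameters (evidence units/s, units, s)."""

    v: float
    a: float
    t_ER: float
    s: float = 0.1

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary separation a must be positive")
        if self.s <= 0:
            raise ValueError("diffusion scaling s must be positive")

    @property
    def t_ER_ms(self) -> float:
        return 1000.0 * self.t_ER


def filter_rts(
    trials: Sequence[TrialResult],
    lo_ms: float = RT_WINDOW_MS[0],
    hi_ms: float = RT_WINDOW_MS[1],
) -> tuple[list[TrialResult], dict]:
    """Keep trials with lo <= RT <= hi (closed interval); drop omissions.

    Returns the kept trials and an exclusion report with per-condition
    counts of trials removed as too fast, too slow, or missing an RT.
    """
    kept: list[TrialResult] = []
    report: dict[str, dict[str, int]] = {}
    for t in trials:
        rep = report.setdefault(
            t.incentive, {"too_fast": 0, "too_slow": 0, "omitted": 0, "kept": 0}
        )
        if t.rt_ms is None or not np.isfinite(t.rt_ms):
            rep["omitted"] += 1
        elif t.rt_ms < lo_ms:
            rep["too_fast"] += 1
        elif t.rt_ms > hi_ms:
            rep["too_slow"] += 1
        else:
            rep["kept"] += 1
            kept.append(t)
    return kept, report


def summarize_condition(trials: Sequence[TrialResult]) -> ConditionSummary:
    """Summarize RT-filtered trials of one condition into the EZ input.

    Pc is the proportion correct over all kept trials; MRT and VRT are the
    mean and unbiased variance of correct-trial RTs converted to seconds.
    With fewer than 2 correct trials (VRT undefined) or zero RT variance
    the summary is flagged invalid and ``ez_fit`` will refuse it.
    """
    n_total = len(trials)
    if n_total == 0:
        return ConditionSummary(0.0, math.nan, math.nan, 0, 0, valid=False)
    correct_rts = np.array(
        [t.rt_ms for t in trials if t.correct], dtype=float
    ) / 1000.0
    n_correct = correct_rts.size
    pc = n_correct / n_total
    if n_correct < 2:
        return ConditionSummary(pc, math.nan, math.nan, n_total, n_correct, valid=False)
    mrt = float(np.mean(correct_rts))
    # identical RTs must yield VRT exactly 0 (not float-rounding dust)
    vrt = 0.0 if np.ptp(correct_rts) == 0.0 else float(np.var(correct_rts, ddof=1))
    return ConditionSummary(
        pc, mrt, vrt, n_total, n_correct, valid=vrt > 0.0
    )


def _edge_correct(pc: float, n: int) -> float:
    """Standard EZ edge correction so the logit is finite and nonzero."""
    if pc not in (0.0, 0.5, 1.0):
        return pc
    if n <= 0:
        raise ValueError("edge correction requires n > 0 trials")
    if pc == 1.0:
        return 1.0 - 1.0 / (2 * n)
    if pc == 0.0:
        return 1.0 / (2 * n)
    if pc == 0.5:
        return 0.5 + 1.0 / (2 * n)
    return pc


def ez_fit(summary: ConditionSummary, s: float = 0.1) -> EZParams:
    """Invert a condition summary into EZ-diffusion parameters.

    Edge cases Pc in {0, 1/2, 1} are first nudged by the standard 1/(2n)
    correction.  Raises on invalid summaries (zero/undefined RT variance).
    """
    if not summary.valid or not np.isfinite(summary.VRT):
        raise ValueError("summary invalid for EZ fit (too few correct trials)")
    if summary.VRT <= 0:
        raise ValueError("zero RT variance")
    pc = _edge_correct(summary.Pc, summary.n_total)
    L = math.log(pc / (1.0 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / summary.VRT
    v = math.copysign(s * x**0.25, pc - 0.5)
    a = s**2 * L / v
    y = math.exp(-v * a / s**2)
    mdt = (a / (2.0 * v)) * (1.0 - y) / (1.0 + y)
    t_er = summary.MRT - mdt
    return EZParams(v=v, a=a, t_ER=t_er, s=s)


def ez_forward(params: EZParams) -> ConditionSummary:
    """Exact forward prediction (Pc, MRT, VRT) of an EZ parameter set.

    The returned summary carries ``n_total = n_correct = 0`` (it is a
    model prediction, not data).  ``ez_fit(ez_forward(p)) == p`` for all
    valid parameters with v != 0.
    """
    if params.v == 0:
        raise ValueError(
            "v = 0 has Pc = 1/2 exactly; the closed forms are singular there "
            "(take the symmetric limit separately)"
        )
    v, a, s = params.v, params.a, params.s
    L = a * v / s**2  # logit of Pc
    pc = 1.0 / (1.0 + math.exp(-L))
    y = math.exp(-L)
    mdt = (a / (2.0 * v)) * (1.0 - y) / (1.0 + y)
    mrt = mdt + params.t_ER
    vrt = s**4 * L * (L * pc**2 - L * pc + pc - 0.5) / v**4
    return ConditionSummary(
        Pc=pc, MRT=mrt, VRT=vrt, n_total=0, n_correct=0, valid=True
    )


def check_suitability(
    trials_by_condition: dict[str, Sequence[TrialResult]],
    pc_ceiling: float = 0.97,
    pc_floor: float = 0.55,
    min_n: int = 20,
) -> dict[str, dict]:
    """Diagnostics on whether filtered data can support an EZ fit.

    Per condition, reports proportion correct near ceiling/floor, the
    skewness of the correct-RT distribution (a diffusion process predicts
    right skew; skew <= 0 is suspicious), the post-filter trial count, and
    whether the fitted non-decision time comes out negative (MRT < MDT).
    Diagnostic only — never raises.
    """
    out: dict[str, dict] = {}
    for cond, trials in trials_by_condition.items():
        summ = summarize_condition(trials)
        rts = np.array([t.rt_ms for t in trials if t.correct], dtype=float)
        skew = float(sps.skew(rts, bias=False)) if rts.size >= 3 else math.nan
        flags: list[str] = []
        if summ.Pc >= pc_ceiling:
            flags.append("accuracy_near_ceiling")
        if summ.Pc <= pc_floor:
            flags.append("accuracy_near_chance")
        if np.isfinite(skew) and skew <= 0:
            flags.append("no_right_skew")
        if summ.n_total < min_n:
            flags.append("few_trials")
        t_er = math.nan
        if summ.valid and summ.Pc not in (0.0, 1.0):
            try:
                t_er = ez_fit(summ).t_ER
                if t_er < 0:
                    flags.append("negative_non_decision_time")
            except ValueError:
                flags.append("unfittable")
        else:
            flags.append("unfittable")
        out[cond] = {
            "Pc": summ.Pc,
            "n": summ.n_total,
            "rt_skewness": skew,
            "t_ER": t_er,
            "flags": flags,
        }
    return out


def fit_conditions(
    trials: Iterable[TrialResult], s: float = 0.1
) -> dict[str, tuple[ConditionSummary, EZParams | None]]:
    """Filter, summarize and EZ-fit each incentive condition of one subject."""
    kept, _ = filter_rts(list(trials))
    out: dict[str, tuple[ConditionSummary, EZParams | None]] = {}
    for cond in sorted({t.incentive for t in kept}):
        summ = summarize_condition([t for t in kept if t.incentive == cond])
        summ = replace(summ, n_filtered_out=sum(
            1 for t in trials if t.incentive == cond
        ) - summ.n_total)
        params = ez_fit(summ, s=s) if summ.valid else None
        out[cond] = (summ, params)
    return out
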