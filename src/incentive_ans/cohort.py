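"""Synthetic behavioural + pupillometric cohort generator.

Stands in for the study's non-public raw data: decisions are governed by a
drift-diffusion process with condition-specific parameters, and the eye
tracker record is a two-eye pupil stream of tonic diameter plus phase-locked
gamma-shaped phasic responses, with blinks, gaze samples and event labels.

The generator's defaults encode the study design and its qualitative
findings: 23 children and 30 adolescents; adolescents accumulate evidence
faster (higher drift ``v``) with shorter non-decision time ``t_ER``; reward
raises ``v`` and lengthens ``t_ER`` in both groups; children respond more
cautiously (wider boundary ``a``) in control trials but relax the boundary
under reward; cue-phase pupil dilation is larger under reward with a wider
reward-control gap in adolescents; children blink more (higher data loss).
Effect *magnitudes* are the package's own plausible choices — the source
data are not public — so only signs and orderings are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from incentive_ans.design import TrialSpec, TrialTiming, score_trial
from incentive_ans.ez import EZParams, TrialResult

__all__ = [
    "SubjectProfile",
    "PupilStream",
    "simulate_ddm_trial",
    "simulate_ddm_trials",
    "simulate_subject",
    "synthesize_pupil",
    "make_profile",
    "default_cohort",
    "pupil_kernel",
    "GROUP_DEFAULTS",
]

PHASES = ("cue", "stimulus", "feedback")
CONDITIONS = ("reward", "control")

#: Gamma impulse-response shape and peak latency of the phasic pupil kernel.
KERNEL_SHAPE = 10.0
KERNEL_PEAK_S = 0.9


@dataclass(frozen=True)
class SubjectProfile:
    """Generative ground truth for one synthetic participant."""

    subject_id: str
    age_group: str  # "children" | "adolescents"
    ez_params: dict  # condition -> EZParams
    tonic_pupil_mm: float
    phasic_amplitudes_mm: dict  # (phase, condition) -> amplitude >= 0
    blink_rate_hz: float
    gaze_dispersion_deg: float

    def __post_init__(self) -> None:
        if self.age_group not in ("children", "adolescents"):
            raise ValueError(f"unknown age group {self.age_group!r}")
        if any(a < 0 for a in self.phasic_amplitudes_mm.values()):
            raise ValueError("phasic amplitudes must be non-negative")


@dataclass
class PupilStream:
    """Synthetic eye-tracker record for one subject's session.

    ``samples`` columns: t_ms, left_mm, right_mm, gaze_x_deg, gaze_y_deg,
    event_label (fixation/saccade/blink/none); blink samples carry NaN
    diameters.  ``trial_events`` has one row per trial with the phase
    timestamps (ms); ``blink_schedule`` records the ground-truth blink
    intervals for oracle tests.
    """

    sampling_rate_hz: float
    samples: pd.DataFrame
    trial_events: pd.DataFrame
    blink_schedule: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# drift-diffusion simulation

def simulate_ddm_trials(
    params: EZParams,
    n: int,
    rng: np.random.Generator | int,
    dt: float = 0.001,
    max_time: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate ``n`` first-passage trials of the diffusion process.

    Euler–Maruyama walk from ``a/2`` with increments ``v*dt + s*sqrt(dt)*xi``;
    absorption at ``a`` is a correct response, at 0 an error; the reported RT
    adds the non-decision time ``t_ER``.  Walkers still unabsorbed at
    ``max_time`` are flagged as timeouts (RT = NaN).

    Returns ``(rt_s, correct, timeout)`` arrays.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_steps = int(math.ceil(max_time / dt))
    pos = np.full(n, params.a / 2.0)
    active = np.arange(n)
    rt = np.full(n, np.nan)
    correct = np.zeros(n, dtype=bool)
    drift = params.v * dt
    sd = params.s * math.sqrt(dt)
    for step in range(1, n_steps + 1):
        pos[active] += drift + sd * rng.standard_normal(active.size)
        hit_hi = pos[active] >= params.a
        hit_lo = pos[active] <= 0.0
        done = hit_hi | hit_lo
        if done.any():
            idx = active[done]
            rt[idx] = step * dt + params.t_ER
            correct[idx] = hit_hi[done]
            active = active[~done]
            if active.size == 0:
                break
    timeout = np.isnan(rt)
    return rt, correct, timeout


def simulate_ddm_trial(
    params: EZParams,
    dt: float = 0.001,
    max_time: float = 5.0,
    seed_state: np.random.Generator | int = 0,
) -> tuple[float, bool] | None:
    """Single-trial wrapper: returns (rt_s, correct) or None on timeout."""
    rt, correct, timeout = simulate_ddm_trials(params, 1, seed_state, dt, max_time)
    if timeout[0]:
        return None
    return float(rt[0]), bool(correct[0])


def simulate_subject(
    profile: SubjectProfile,
    session: Sequence[TrialSpec],
    seed: np.random.Generator | int,
    dt: float = 0.001,
    max_time: float = 5.0,
    timing: TrialTiming = TrialTiming(),
) -> list[TrialResult]:
    """Simulate a subject's responses to a planned session.

    Each trial runs under the profile's condition-specific EZ parameters;
    RTs are reported in ms.  No response by the deadline (or diffusion
    timeout) is an omission: RT missing, scored as an error.
    """
    if not session:
        raise ValueError("session must be non-empty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    results: list[TrialResult] = []
    # simulate per condition in batch (cheap), then map back in session order
    order = {c: [i for i, t in enumerate(session) if t.incentive == c]
             for c in CONDITIONS}
    rt_ms_all = np.full(len(session), np.nan)
    correct_all = np.zeros(len(session), dtype=bool)
    for cond in CONDITIONS:
        idx = order[cond]
        if not idx:
            continue
        rt, correct, timeout = simulate_ddm_trials(
            profile.ez_params[cond], len(idx), rng, dt, max_time
        )
        rt_ms = rt * 1000.0
        late = ~timeout & (rt_ms > timing.response_deadline)
        rt_ms[timeout | late] = np.nan
        correct[timeout | late] = False
        rt_ms_all[idx] = rt_ms
        correct_all[idx] = correct
    for i, spec in enumerate(session):
        omitted = not np.isfinite(rt_ms_all[i])
        acc = bool(correct_all[i])
        results.append(
            TrialResult(
                block_index=spec.block_index,
                trial_index=spec.trial_index,
                incentive=spec.incentive,
                rt_ms=None if omitted else float(rt_ms_all[i]),
                correct=acc,
                points_delta=score_trial(spec, acc),
            )
        )
    return results


# ---------------------------------------------------------------------------
# pupil stream synthesis

def pupil_kernel(
    t_s: np.ndarray,
    shape: float = KERNEL_SHAPE,
    peak_s: float = KERNEL_PEAK_S,
    support_s: float | None = None,
) -> np.ndarray:
    """Gamma-family pupillary impulse response, unit peak at ``peak_s``.

    ``h(t) = (t/tp)^k * exp(-k*(t/tp - 1))`` for t >= 0, so an event of
    amplitude A produces a maximum dilation of exactly A.  With
    ``support_s`` set, the kernel is hard-zeroed beyond that lag (useful
    for analytic end-to-end checks in a paradigm without inter-trial
    intervals, where tails otherwise bleed into the next trial).
    """
    t = np.asarray(t_s, dtype=float)
    u = np.clip(t / peak_s, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(t > 0, np.exp(shape * (np.log(np.where(u > 0, u, 1.0)) + 1.0 - u)), 0.0)
    if support_s is not None:
        h = np.where(t > support_s, 0.0, h)
    return h


def _trial_event_table(
    results: Sequence[TrialResult], timing: TrialTiming
) -> pd.DataFrame:
    """Contiguous trial timeline: cue 1500 ms, stimulus until response (or
    deadline on omission), feedback 1500 ms, no inter-trial interval."""
    rows = []
    t = 0.0
    for k, r in enumerate(results):
        cue_on = t
        stim_on = cue_on + timing.cue_duration
        resp = (
            stim_on + r.rt_ms
            if r.rt_ms is not None
            else stim_on + timing.response_deadline
        )
        fb_on = resp  # feedback follows the response immediately
        fb_off = fb_on + timing.feedback_duration
        rows.append(
            {
                "trial": k,
                "incentive": r.incentive,
                "correct": r.correct,
                "cue_onset_ms": cue_on,
                "stimulus_onset_ms": stim_on,
                "response_ms": np.nan if r.rt_ms is None else resp,
                "feedback_onset_ms": fb_on,
                "feedback_offset_ms": fb_off,
            }
        )
        t = fb_off
    return pd.DataFrame(rows)


def _poisson_intervals(
    rng: np.random.Generator,
    rate_hz: float,
    t_end_ms: float,
    dur_lo_ms: float,
    dur_hi_ms: float,
) -> list[tuple[float, float]]:
    out = []
    if rate_hz <= 0:
        return out
    t = rng.exponential(1000.0 / rate_hz)
    while t < t_end_ms:
        dur = rng.uniform(dur_lo_ms, dur_hi_ms)
        out.append((t, min(t + dur, t_end_ms)))
        t = t + dur + rng.exponential(1000.0 / rate_hz)
    return out


def _gaze_track(
    rng: np.random.Generator,
    t_ms: np.ndarray,
    dispersion_deg: float,
    excursion_prob: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixation/saccade gaze model: mostly central fixations with occasional
    eccentric excursions; brief saccade samples between fixations."""
    n = t_ms.size
    x = np.zeros(n)
    y = np.zeros(n)
    label = np.full(n, "fixation", dtype=object)
    dt_ms = float(t_ms[1] - t_ms[0]) if n > 1 else 16.7
    i = 0
    px, py = 0.0, 0.0
    while i < n:
        if rng.random() < excursion_prob:
            ecc = rng.uniform(5.5, 9.0)
            ang = rng.uniform(0, 2 * math.pi)
            fx, fy = ecc * math.cos(ang), ecc * math.sin(ang)
        else:
            fx, fy = rng.normal(0.0, dispersion_deg, size=2)
        dur = max(2, int(rng.gamma(4.0, 80.0) / dt_ms))  # ~320 ms fixations
        n_sacc = min(2, n - i)
        for j in range(n_sacc):  # transition samples
            w = (j + 1) / (n_sacc + 1)
            x[i + j] = px + w * (fx - px)
            y[i + j] = py + w * (fy - py)
            label[i + j] = "saccade"
        j_end = min(i + n_sacc + dur, n)
        x[i + n_sacc : j_end] = fx
        y[i + n_sacc : j_end] = fy
        px, py = fx, fy
        i = j_end
    return x, y, label


def synthesize_pupil(
    profile: SubjectProfile,
    results: Sequence[TrialResult],
    sampling_rate_hz: float = 60.0,
    seed: np.random.Generator | int = 0,
    noise_sd_mm: float = 0.02,
    eye_noise_sd_mm: float = 0.008,
    blink_duration_ms: tuple[float, float] = (80.0, 400.0),
    artifact_rate_hz: float = 0.03,
    kernel_support_s: float | None = None,
    timing: TrialTiming = TrialTiming(),
) -> PupilStream:
    """Synthesize the two-eye pupil/gaze stream for a simulated session.

    Diameter = tonic + sum of phase-locked gamma kernels (cue, stimulus and
    feedback onsets; amplitudes from the profile) + shared Gaussian noise;
    each eye adds small independent noise so the two channels are highly
    correlated.  Blinks are Poisson-onset missing segments; gaze is
    predominantly central with occasional excursions; a low rate of
    unlabelled ("none") artifacts mimics unclassifiable gaze samples.
    """
    if sampling_rate_hz < 50:
        raise ValueError("sampling_rate_hz must be >= 50")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    events = _trial_event_table(results, timing)
    t_end = float(events["feedback_offset_ms"].iloc[-1])
    dt_ms = 1000.0 / sampling_rate_hz
    t_ms = np.arange(0.0, t_end, dt_ms)

    signal = np.full(t_ms.size, profile.tonic_pupil_mm)
    # kernel tails are numerically zero past ~8 s; evaluate only there
    window_s = kernel_support_s if kernel_support_s is not None else 8.0
    win_n = int(window_s * sampling_rate_hz) + 1
    onset_cols = {
        "cue": "cue_onset_ms",
        "stimulus": "stimulus_onset_ms",
        "feedback": "feedback_onset_ms",
    }
    for _, ev in events.iterrows():
        for phase, col in onset_cols.items():
            amp = profile.phasic_amplitudes_mm[(phase, ev["incentive"])]
            if amp == 0.0:
                continue
            i0 = int(np.searchsorted(t_ms, ev[col]))
            i1 = min(i0 + win_n, t_ms.size)
            lag_s = (t_ms[i0:i1] - ev[col]) / 1000.0
            signal[i0:i1] += amp * pupil_kernel(lag_s, support_s=kernel_support_s)

    shared = signal + (noise_sd_mm * rng.standard_normal(t_ms.size)
                       if noise_sd_mm > 0 else 0.0)
    left = shared + (eye_noise_sd_mm * rng.standard_normal(t_ms.size)
                     if eye_noise_sd_mm > 0 else 0.0)
    right = shared + (eye_noise_sd_mm * rng.standard_normal(t_ms.size)
                      if eye_noise_sd_mm > 0 else 0.0)

    gaze_x, gaze_y, label = _gaze_track(rng, t_ms, profile.gaze_dispersion_deg)

    blink_schedule = _poisson_intervals(
        rng, profile.blink_rate_hz, t_end, *blink_duration_ms
    )
    for b0, b1 in blink_schedule:
        m = (t_ms >= b0) & (t_ms < b1)
        left[m] = np.nan
        right[m] = np.nan
        label[m] = "blink"
    for a0, a1 in _poisson_intervals(rng, artifact_rate_hz, t_end, 80.0, 250.0):
        m = (t_ms >= a0) & (t_ms < a1) & (label != "blink")
        label[m] = "none"

    samples = pd.DataFrame(
        {
            "t_ms": t_ms,
            "left_mm": left,
            "right_mm": right,
            "gaze_x_deg": gaze_x,
            "gaze_y_deg": gaze_y,
            "event_label": label,
        }
    )
    return PupilStream(
        sampling_rate_hz=sampling_rate_hz,
        samples=samples,
        trial_events=events,
        blink_schedule=blink_schedule,
    )


# ---------------------------------------------------------------------------
# cohort defaults

#: Group-level generative means. EZ tuples are (v, a, t_ER); pupil
#: amplitudes are mm at the kernel peak.  Orderings encode the study's
#: qualitative findings; magnitudes are package choices (see docs).
GROUP_DEFAULTS = {
    "children": {
        "ez": {"control": (0.12, 0.130, 0.38), "reward": (0.15, 0.115, 0.40)},
        "amp": {
            ("cue", "reward"): 0.14,
            ("cue", "control"): 0.10,
            ("stimulus", "reward"): 0.26,
            ("stimulus", "control"): 0.18,
            ("feedback", "reward"): 0.24,
            ("feedback", "control"): 0.16,
        },
        "tonic": 5.2,
        "blink_rate_hz": 0.30,
        "gaze_dispersion_deg": 1.2,
    },
    "adolescents": {
        "ez": {"control": (0.20, 0.105, 0.28), "reward": (0.23, 0.105, 0.30)},
        "amp": {
            ("cue", "reward"): 0.25,
            ("cue", "control"): 0.10,
            ("stimulus", "reward"): 0.30,
            ("stimulus", "control"): 0.22,
            ("feedback", "reward"): 0.28,
            ("feedback", "control"): 0.20,
        },
        "tonic": 4.7,
        "blink_rate_hz": 0.15,
        "gaze_dispersion_deg": 0.9,
    },
}

#: Between-subject SDs around the group means.
SUBJECT_SD = {"v": 0.03, "a": 0.012, "t_ER": 0.03, "amp": 0.04, "tonic": 0.35}


def make_profile(
    subject_id: str,
    age_group: str,
    rng: np.random.Generator | int,
    effect_scale: float = 1.0,
) -> SubjectProfile:
    """Draw one subject's generative parameters around the group means.

    ``effect_scale`` shrinks every condition contrast toward the
    group-average (0 gives a per-subject null with no reward effects),
    which calibration tests use to probe type-I error.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    g = GROUP_DEFAULTS[age_group]
    # subject-level deviations are shared across conditions (random intercepts)
    dv, da, dt = (
        rng.normal(0, SUBJECT_SD["v"]),
        rng.normal(0, SUBJECT_SD["a"]),
        rng.normal(0, SUBJECT_SD["t_ER"]),
    )
    mean_ez = {
        k: np.mean([g["ez"][c][i] for c in CONDITIONS])
        for i, k in enumerate(("v", "a", "t_ER"))
    }
    ez = {}
    for cond in CONDITIONS:
        v0, a0, t0 = g["ez"][cond]
        v = mean_ez["v"] + effect_scale * (v0 - mean_ez["v"]) + dv
        a = mean_ez["a"] + effect_scale * (a0 - mean_ez["a"]) + da
        t = mean_ez["t_ER"] + effect_scale * (t0 - mean_ez["t_ER"]) + dt
        ez[cond] = EZParams(v=max(v, 0.04), a=max(a, 0.06), t_ER=max(t, 0.15))
    damp = rng.normal(0, SUBJECT_SD["amp"])
    mean_amp = {
        ph: np.mean([g["amp"][(ph, c)] for c in CONDITIONS]) for ph in PHASES
    }
    amps = {
        (ph, c): max(
            0.0,
            mean_amp[ph] + effect_scale * (g["amp"][(ph, c)] - mean_amp[ph]) + damp,
        )
        for ph in PHASES
        for c in CONDITIONS
    }
    return SubjectProfile(
        subject_id=subject_id,
        age_group=age_group,
        ez_params=ez,
        tonic_pupil_mm=float(rng.normal(g["tonic"], SUBJECT_SD["tonic"])),
        phasic_amplitudes_mm=amps,
        blink_rate_hz=g["blink_rate_hz"],
        gaze_dispersion_deg=g["gaze_dispersion_deg"],
    )


def default_cohort(
    seed: int,
    n_children: int = 23,
    n_adolescents: int = 30,
    effect_scale: float = 1.0,
) -> list[SubjectProfile]:
    """The default synthetic cohort: 23 children + 30 adolescents."""
    rng = np.random.default_rng(seed)
    profiles = [
        make_profile(f"c{i:02d}", "children", rng, effect_scale)
        for i in range(1, n_children + 1)
    ]
    profiles += [
        make_profile(f"a{i:02d}", "adolescents", rng, effect_scale)
        for i in range(1, n_adolescents + 1)
    ]
    return profiles
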