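"""Phase-locked pupillometry preprocessing.

Transforms a raw two-eye pupil stream into per-subject, per-condition,
per-phase peak pupil dilation (PD) values:

1. average the left and right eye samplewise,
2. interpolate small blinks (cubic) and discard trials with excessive
   missing data,
3. smooth with an unweighted 5-point moving average,
4. epoch per trial phase — stimulus-locked 1500 ms windows for the cue and
   feedback phases, a response-locked 1500 ms window ending 200 ms after
   the button press for the stimulus phase,
5. subtract the mean of the 200 ms window preceding each phase onset,
6. average valid epochs per condition (at least 10 trials required),
7. extract the peak PD: for the cue phase the dilation relative to the
   trace minimum (max - min; the pupil is still recovering from the
   previous trial because there is no inter-trial interval), for the
   stimulus and feedback phases the maximum.

Gaze-based parallax QC quantifies the percent of fixation/saccade time
spent within a central area of 10 degrees visual angle in diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from incentive_ans.cohort import PupilStream

__all__ = [
    "CleanTrace",
    "PupilEpoch",
    "PhasePeak",
    "average_eyes",
    "deblink",
    "smooth",
    "epoch_phase",
    "baseline_correct",
    "condition_average",
    "peak_pd",
    "gaze_central_fraction",
    "process_subject",
    "EPOCH_MS",
    "BASELINE_MS",
    "POST_RESPONSE_MS",
]

#: Epoch length (ms) for every phase window.
EPOCH_MS = 1500.0
#: Baseline window (ms) immediately preceding the phase onset.
BASELINE_MS = 200.0
#: The stimulus-phase window ends this long (ms) after the button press.
POST_RESPONSE_MS = 200.0

PHASES = ("cue", "stimulus", "feedback")


@dataclass
class CleanTrace:
    """Eye-averaged pupil trace on the stream's native time grid."""

    t_ms: np.ndarray
    diameter_mm: np.ndarray  # NaN where invalid
    valid: np.ndarray  # bool; False where missing before interpolation
    sampling_rate_hz: float
    trial_validity: pd.DataFrame | None = None  # set by deblink


@dataclass
class PupilEpoch:
    """One phase-locked epoch of one trial."""

    phase: str
    locking: str  # "stimulus_locked" | "response_locked"
    trial: int
    incentive: str
    t_rel_ms: np.ndarray
    trace: np.ndarray
    baseline_mm: float = math.nan  # set by baseline_correct
    valid: bool = True


@dataclass(frozen=True)
class PhasePeak:
    """Peak pupil dilation of a subject x condition x phase cell."""

    subject: str
    condition: str
    phase: str
    peak_pd_mm: float
    n_trials_averaged: int


def average_eyes(stream: PupilStream) -> CleanTrace:
    """Samplewise mean of the two eyes; a single valid eye is used alone."""
    s = stream.samples
    left = s["left_mm"].to_numpy(dtype=float)
    right = s["right_mm"].to_numpy(dtype=float)
    both = np.isfinite(left) & np.isfinite(right)
    mean = np.where(
        both, (left + right) / 2.0, np.where(np.isfinite(left), left, right)
    )
    valid = np.isfinite(mean)
    return CleanTrace(
        t_ms=s["t_ms"].to_numpy(dtype=float),
        diameter_mm=mean,
        valid=valid,
        sampling_rate_hz=stream.sampling_rate_hz,
    )


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index runs of invalid samples."""
    runs = []
    n = valid.size
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def deblink(
    trace: CleanTrace,
    trial_events: pd.DataFrame,
    max_blink_ms: float = 500.0,
    max_missing_frac: float = 0.25,
    guard_ms: float = 40.0,
) -> CleanTrace:
    """Interpolate small blinks; flag trials with excessive missing data.

    Invalid runs are first widened by a guard margin (the samples flanking
    a blink are distorted by the closing/opening lid); runs no longer than
    ``max_blink_ms`` are then filled by cubic interpolation through the two
    nearest valid samples on each side.  Runs touching the trace boundary
    cannot be interpolated and stay missing.  A trial whose guarded missing
    fraction (cue onset to feedback offset) exceeds ``max_missing_frac`` is
    marked invalid and excluded downstream.
    """
    t = trace.t_ms
    dt_ms = 1000.0 / trace.sampling_rate_hz
    guard_n = int(round(guard_ms / dt_ms))
    valid = trace.valid.copy()
    for i0, i1 in _invalid_runs(trace.valid):
        valid[max(0, i0 - guard_n) : min(valid.size, i1 + guard_n)] = False

    diam = np.where(valid, trace.diameter_mm, np.nan)
    filled = diam.copy()
    for i0, i1 in _invalid_runs(valid):
        gap_ms = (i1 - i0) * dt_ms
        if gap_ms > max_blink_ms:
            continue
        left_idx = np.arange(max(0, i0 - 2), i0)
        right_idx = np.arange(i1, min(valid.size, i1 + 2))
        left_idx = left_idx[valid[left_idx]] if left_idx.size else left_idx
        right_idx = right_idx[valid[right_idx]] if right_idx.size else right_idx
        anchors = np.concatenate([left_idx, right_idx])
        if left_idx.size == 0 or right_idx.size == 0:
            continue  # boundary gap: cannot bridge
        deg = min(3, anchors.size - 1)
        coef = np.polyfit(t[anchors], diam[anchors], deg)
        filled[i0:i1] = np.polyval(coef, t[i0:i1])

    # per-trial missing fraction from the *guarded* mask, before filling
    rows = []
    for _, ev in trial_events.iterrows():
        m = (t >= ev["cue_onset_ms"]) & (t < ev["feedback_offset_ms"])
        frac = float(1.0 - valid[m].mean()) if m.any() else 1.0
        rows.append(
            {
                "trial": int(ev["trial"]),
                "incentive": ev["incentive"],
                "missing_frac": frac,
                "valid": frac <= max_missing_frac,
            }
        )
    return CleanTrace(
        t_ms=t,
        diameter_mm=filled,
        valid=np.isfinite(filled),
        sampling_rate_hz=trace.sampling_rate_hz,
        trial_validity=pd.DataFrame(rows),
    )


def smooth(trace: CleanTrace, window: int = 5) -> CleanTrace:
    """Centered unweighted moving average; edge windows shrink.

    Samples that are missing stay missing (the filter never invents data
    across unfilled gaps).
    """
    s = pd.Series(trace.diameter_mm)
    out = s.rolling(window, center=True, min_periods=1).mean().to_numpy()
    out[~trace.valid] = np.nan
    return replace(trace, diameter_mm=out)


def _extract(
    trace: CleanTrace, start_ms: float, n_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """First ``n_samples`` samples at or after ``start_ms``; empty when the
    requested window extends beyond either end of the trace."""
    i0 = int(np.searchsorted(trace.t_ms, start_ms - 1e-9))
    idx = np.arange(i0, i0 + n_samples)
    if idx[-1] >= trace.t_ms.size or i0 < 0:
        return np.array([]), np.array([])
    window_ms = n_samples * 1000.0 / trace.sampling_rate_hz
    if trace.t_ms[i0] >= start_ms + window_ms:  # window precedes the trace
        return np.array([]), np.array([])
    return trace.t_ms[idx], trace.diameter_mm[idx]


def epoch_phase(
    trace: CleanTrace, trial_events: pd.DataFrame, phase: str
) -> list[PupilEpoch]:
    """Extract fixed-length phase epochs for every trial.

    Cue and feedback epochs are stimulus-locked: [onset, onset + 1500 ms].
    The stimulus epoch is response-locked: 1500 ms ending 200 ms after the
    button press; trials without a response are skipped.  Trials flagged
    invalid by :func:`deblink`, and epochs containing unfilled samples,
    carry ``valid=False``.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    fs = trace.sampling_rate_hz
    n_ep = int(round(EPOCH_MS / 1000.0 * fs))
    validity = (
        trace.trial_validity.set_index("trial")["valid"]
        if trace.trial_validity is not None
        else None
    )
    epochs: list[PupilEpoch] = []
    for _, ev in trial_events.iterrows():
        if phase == "cue":
            start = ev["cue_onset_ms"]
            locking = "stimulus_locked"
        elif phase == "feedback":
            start = ev["feedback_onset_ms"]
            locking = "stimulus_locked"
        else:
            if not np.isfinite(ev["response_ms"]):
                continue  # omission: no response-locked window
            start = ev["response_ms"] + POST_RESPONSE_MS - EPOCH_MS
            locking = "response_locked"
        t_win, y = _extract(trace, start, n_ep)
        if t_win.size == 0:
            continue
        trial_ok = bool(validity.get(int(ev["trial"]), True)) if validity is not None else True
        epochs.append(
            PupilEpoch(
                phase=phase,
                locking=locking,
                trial=int(ev["trial"]),
                incentive=ev["incentive"],
                t_rel_ms=t_win - start,
                trace=y,
                valid=trial_ok and bool(np.isfinite(y).all()),
            )
        )
    return epochs


def baseline_correct(
    epoch: PupilEpoch, trace: CleanTrace, trial_events: pd.DataFrame
) -> PupilEpoch:
    """Subtract the mean of the 200 ms window preceding the phase onset.

    The epoch is dropped (``valid=False``) when the baseline window
    contains unfilled samples.
    """
    fs = trace.sampling_rate_hz
    n_bl = int(round(BASELINE_MS / 1000.0 * fs))
    ev = trial_events.loc[trial_events["trial"] == epoch.trial].iloc[0]
    if epoch.phase == "cue":
        onset = ev["cue_onset_ms"]
    elif epoch.phase == "feedback":
        onset = ev["feedback_onset_ms"]
    else:
        onset = ev["response_ms"] + POST_RESPONSE_MS - EPOCH_MS
    _, bl = _extract(trace, onset - BASELINE_MS, n_bl)
    if bl.size == 0 or not np.isfinite(bl).all():
        return replace(epoch, valid=False)
    baseline = float(np.mean(bl))
    return replace(epoch, trace=epoch.trace - baseline, baseline_mm=baseline)


def condition_average(
    epochs: Sequence[PupilEpoch], min_trials: int = 10
) -> tuple[np.ndarray, int] | None:
    """Pointwise mean over valid epochs; None when fewer than ``min_trials``.

    A rejected cell makes the subject unavailable for that analysis —
    mirroring the exclusion of participants with too few clean trials.
    """
    good = [e for e in epochs if e.valid]
    if len(good) < min_trials:
        return None
    return np.mean([e.trace for e in good], axis=0), len(good)


def peak_pd(mean_curve: np.ndarray, phase: str) -> float:
    """Peak PD of a condition-average curve, in mm.

    Cue phase: dilation relative to the curve minimum (max - min) — the
    baseline-corrected cue trace starts near its maximum while the pupil
    still recovers from the previous trial.  Stimulus/feedback: maximum.
    """
    if mean_curve.size == 0:
        raise ValueError("empty curve")
    if phase == "cue":
        return float(np.max(mean_curve) - np.min(mean_curve))
    return float(np.max(mean_curve))


def gaze_central_fraction(
    stream: PupilStream,
    area_diameter_deg: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent of gaze time within the central screen area, per trial x phase.

    Only samples labelled fixation or saccade enter the denominator (blinks
    and unclassifiable samples carry no usable gaze position); a sample is
    central when its radial eccentricity from screen centre is below half
    the area diameter.  Returns the per-trial table and the mean percent
    per condition x phase.  Trials with no fixation/saccade time in a phase
    are skipped in aggregation.
    """
    s = stream.samples
    t = s["t_ms"].to_numpy()
    ecc = np.hypot(s["gaze_x_deg"].to_numpy(), s["gaze_y_deg"].to_numpy())
    usable = s["event_label"].isin(["fixation", "saccade"]).to_numpy()
    central = ecc < (area_diameter_deg / 2.0)
    windows = {
        "cue": ("cue_onset_ms", "stimulus_onset_ms"),
        "stimulus": ("stimulus_onset_ms", "feedback_onset_ms"),
        "feedback": ("feedback_onset_ms", "feedback_offset_ms"),
    }
    rows = []
    for _, ev in stream.trial_events.iterrows():
        for phase, (c0, c1) in windows.items():
            m = (t >= ev[c0]) & (t < ev[c1]) & usable
            denom = int(m.sum())
            if denom == 0:
                continue
            rows.append(
                {
                    "trial": int(ev["trial"]),
                    "incentive": ev["incentive"],
                    "phase": phase,
                    "pct_central": 100.0 * central[m].sum() / denom,
                }
            )
    per_trial = pd.DataFrame(rows)
    if per_trial.empty:
        return per_trial, per_trial
    agg = (
        per_trial.groupby(["incentive", "phase"], as_index=False)["pct_central"]
        .mean()
    )
    return per_trial, agg


def process_subject(
    subject_id: str,
    stream: PupilStream,
    min_trials: int = 10,
    max_blink_ms: float = 500.0,
    max_missing_frac: float = 0.25,
    guard_ms: float = 40.0,
) -> dict:
    """Full per-subject pipeline: raw stream -> PhasePeak table + curves.

    Returns a dict with keys ``peaks`` (list of :class:`PhasePeak`),
    ``curves`` ({(condition, phase): mean curve}), ``complete`` (False when
    any condition x phase cell misses the trial minimum, in which case the
    subject should be excluded from pupil analyses), ``gaze`` (per
    condition x phase central-gaze percents) and ``trial_validity``.
    """
    trace = average_eyes(stream)
    trace = deblink(
        trace,
        stream.trial_events,
        max_blink_ms=max_blink_ms,
        max_missing_frac=max_missing_frac,
        guard_ms=guard_ms,
    )
    trace = smooth(trace)
    peaks: list[PhasePeak] = []
    curves: dict[tuple[str, str], np.ndarray] = {}
    complete = True
    for phase in PHASES:
        epochs = epoch_phase(trace, stream.trial_events, phase)
        corrected = [
            baseline_correct(e, trace, stream.trial_events) for e in epochs
        ]
        for cond in ("reward", "control"):
            cell = [e for e in corrected if e.incentive == cond]
            avg = condition_average(cell, min_trials=min_trials)
            if avg is None:
                complete = False
                continue
            curve, n = avg
            curves[(cond, phase)] = curve
            peaks.append(
                PhasePeak(
                    subject=subject_id,
                    condition=cond,
                    phase=phase,
                    peak_pd_mm=peak_pd(curve, phase),
                    n_trials_averaged=n,
                )
            )
    _, gaze_agg = gaze_central_fraction(stream)
    return {
        "peaks": peaks,
        "curves": curves,
        "complete": complete,
        "gaze": gaze_agg,
        "trial_validity": trace.trial_validity,
    }
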