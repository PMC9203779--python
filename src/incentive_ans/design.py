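"""Incentivized dot-comparison task structure and reward scheme.

The task is a two-alternative numerosity discrimination: on every trial two
dot clouds appear left and right of fixation and the participant reports
which contains more dots.  A coloured fixation cross (the incentive cue)
announces whether the trial is *rewarded* (correct: +3 points, error: -3)
or a *control* trial (0 points either way).  Difficulty is set by the
larger:smaller dot-count ratio (4:3, 5:4, 8:7 or 10:9 — lower ratio, harder
discrimination), with 12-32 dots per cloud.

A session is 32 blocks of 24 trials; reward and control trials are
randomized within block in equal numbers.  Accumulated points map onto 15
bonus levels spanning five win options whose thresholds are percentile
ranks of a reference score distribution, so that the scheme is comparably
hard for cohorts of different ability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "RATIOS",
    "DOT_RANGE",
    "TrialSpec",
    "TrialTiming",
    "BonusScheme",
    "admissible_dot_pairs",
    "generate_session",
    "build_bonus_scheme",
    "score_trial",
    "session_points",
]

#: Larger:smaller numerosity ratios used in the task, hardest last.
RATIOS: tuple[Fraction, ...] = (
    Fraction(4, 3),
    Fraction(5, 4),
    Fraction(8, 7),
    Fraction(10, 9),
)

#: Inclusive bounds on the number of dots in either cloud.
DOT_RANGE: tuple[int, int] = (12, 32)

#: Default percentile ranks of the five win options (pen ... 25 EUR voucher).
WIN_PERCENTILES: tuple[float, ...] = (0.05, 35.0, 85.0, 95.0, 99.9)

WIN_LABELS: tuple[str, ...] = (
    "pen",
    "10 EUR voucher",
    "15 EUR voucher",
    "20 EUR voucher",
    "25 EUR voucher",
)

#: Points gained (lost) for a correct (error) response in a reward trial.
POINTS_PER_OUTCOME: int = 3

#: Number of bonus levels shown to participants.
N_LEVELS: int = 15


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial of the dot-comparison task."""

    block_index: int
    trial_index: int
    incentive: str  # "reward" | "control"
    ratio: Fraction
    larger_side: str  # "left" | "right"
    n_dots_left: int
    n_dots_right: int
    cue_color: str = "pink"  # counterbalanced across participants

    def __post_init__(self) -> None:
        if self.incentive not in ("reward", "control"):
            raise ValueError(f"unknown incentive {self.incentive!r}")
        if self.larger_side not in ("left", "right"):
            raise ValueError(f"unknown side {self.larger_side!r}")
        big, small = max(self.n_dots_left, self.n_dots_right), min(
            self.n_dots_left, self.n_dots_right
        )
        if Fraction(big, small) != self.ratio:
            raise ValueError(
                f"dot counts {self.n_dots_left}:{self.n_dots_right} do not "
                f"realise ratio {self.ratio}"
            )

    @property
    def correct_side(self) -> str:
        return self.larger_side


@dataclass(frozen=True)
class TrialTiming:
    """Phase durations of a trial, in milliseconds.

    The cue is shown for 1500 ms; the stimulus disappears at response or
    after 1200 ms at the latest, with responses accepted until 3000 ms after
    stimulus onset; feedback is shown for 1500 ms.  There is no inter-trial
    interval, so the feedback of one trial abuts the cue of the next.
    """

    cue_duration: int = 1500
    stimulus_max_display: int = 1200
    response_deadline: int = 3000
    feedback_duration: int = 1500
    inter_trial_interval: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cue_duration",
            "stimulus_max_display",
            "response_deadline",
            "feedback_duration",
            "inter_trial_interval",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class BonusScheme:
    """Percentile-rank based mapping from point totals to win options.

    ``level_points[k]`` is the minimum point total for bonus level ``k+1``;
    the 15 levels split evenly over the five win options (three levels per
    option), with the top level of option *i* pinned at that option's
    percentile rank of the reference distribution.
    """

    percentile_thresholds: tuple[float, ...]
    win_labels: tuple[str, ...]
    level_points: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.win_labels) != len(self.percentile_thresholds):
            raise ValueError("one label per win option required")
        if any(
            a > b
            for a, b in zip(self.percentile_thresholds, self.percentile_thresholds[1:])
        ):
            raise ValueError("percentile thresholds must be non-decreasing")
        if any(a > b for a, b in zip(self.level_points, self.level_points[1:])):
            raise ValueError("level thresholds must be non-decreasing")

    def level_for(self, points: float) -> int:
        """Bonus level (0..15) reached with ``points``; negatives floor at 0."""
        pts = max(0.0, float(points))
        return int(np.sum(np.asarray(self.level_points) <= pts))

    def win_for(self, points: float) -> str | None:
        """Win option earned with ``points`` (highest level group reached)."""
        level = self.level_for(points)
        if level == 0:
            return None
        per_option = len(self.level_points) // len(self.win_labels)
        return self.win_labels[min((level - 1) // per_option, len(self.win_labels) - 1)]


def admissible_dot_pairs(
    ratio: Fraction, dot_range: tuple[int, int] = DOT_RANGE
) -> list[tuple[int, int]]:
    """All (n_large, n_small) integer pairs realising ``ratio`` within range.

    A pair is admissible when n_large/n_small equals the ratio exactly and
    both counts lie within the inclusive ``dot_range``.
    """
    lo, hi = dot_range
    ratio = Fraction(ratio)
    p, q = ratio.numerator, ratio.denominator
    pairs = [
        (k * p, k * q)
        for k in range(1, hi // p + 1)
        if k * q >= lo and k * p <= hi
    ]
    if not pairs:
        raise ValueError(
            f"ratio {p}:{q} admits no integer dot pair within {lo}-{hi}"
        )
    return pairs


def _block_cells(trials_per_block: int, ratios: Sequence[Fraction]) -> list[tuple[str, Fraction]]:
    """Equal reward/control split per block, ratios cycled for balance."""
    half = trials_per_block // 2
    cells = []
    for incentive in ("reward", "control"):
        for i in range(half):
            cells.append((incentive, ratios[i % len(ratios)]))
    return cells


def generate_session(
    seed: int,
    n_blocks: int = 32,
    trials_per_block: int = 24,
    ratios: Sequence[Fraction] = RATIOS,
    dot_range: tuple[int, int] = DOT_RANGE,
    cue_color_reward: str = "pink",
) -> list[TrialSpec]:
    """Generate a full session of trial specifications.

    Reward and control trials occur in equal numbers within every block with
    randomized order; ratio and larger-side assignments are balanced across
    the session to the extent divisibility allows.  Deterministic given
    ``seed``.

    Parameters
    ----------
    seed
        Seed for the session-order randomization.
    cue_color_reward
        Colour of the reward cue for this participant ("pink" or "blue");
        the control cue takes the other colour.  Counterbalance by subject
        index parity across a cohort.
    """
    if trials_per_block % 2 != 0:
        raise ValueError("trials_per_block must be even (reward/control split)")
    ratios = tuple(Fraction(r) for r in ratios)
    pair_table = {r: admissible_dot_pairs(r, dot_range) for r in ratios}
    other = {"pink": "blue", "blue": "pink"}[cue_color_reward]

    rng = np.random.default_rng(seed)
    session: list[TrialSpec] = []
    # global per-(incentive, ratio) side counters keep sides balanced session-wide
    side_counter: dict[tuple[str, Fraction], int] = {}
    for block in range(1, n_blocks + 1):
        cells = _block_cells(trials_per_block, ratios)
        order = rng.permutation(len(cells))
        for trial_idx, cell_idx in enumerate(order, start=1):
            incentive, ratio = cells[cell_idx]
            count = side_counter.get((incentive, ratio), 0)
            side_counter[(incentive, ratio)] = count + 1
            larger_side = "left" if count % 2 == 0 else "right"
            n_large, n_small = pair_table[ratio][
                rng.integers(len(pair_table[ratio]))
            ]
            left, right = (
                (n_large, n_small) if larger_side == "left" else (n_small, n_large)
            )
            session.append(
                TrialSpec(
                    block_index=block,
                    trial_index=trial_idx,
                    incentive=incentive,
                    ratio=ratio,
                    larger_side=larger_side,
                    n_dots_left=left,
                    n_dots_right=right,
                    cue_color=cue_color_reward if incentive == "reward" else other,
                )
            )
    return session


def _percentile_lookup(sorted_scores: np.ndarray, pr: float) -> float:
    """Score at percentile rank ``pr`` by sorted-index lookup.

    Index = ceil(pr/100 * n) - 1, clipped to the valid range; ties in the
    reference distribution therefore tie thresholds.
    """
    n = len(sorted_scores)
    idx = int(np.ceil(pr / 100.0 * n)) - 1
    return float(sorted_scores[min(max(idx, 0), n - 1)])


def build_bonus_scheme(
    reference_scores: Sequence[float],
    percentiles: Sequence[float] = WIN_PERCENTILES,
    wins: Sequence[str] = WIN_LABELS,
    n_levels: int = N_LEVELS,
) -> BonusScheme:
    """Derive the 15-level bonus scheme from a reference score distribution.

    The five win options sit at the given percentile ranks of
    ``reference_scores`` (e.g. a pilot cohort of the same age group).  Each
    option owns ``n_levels / len(wins)`` consecutive levels whose thresholds
    interpolate linearly in percentile-rank space between the previous
    option's rank (0 before the first) and this option's rank, so the top
    level of option *i* lands exactly on its printed rank.
    """
    scores = np.asarray(reference_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("reference_scores must be non-empty")
    percentiles = tuple(float(p) for p in percentiles)
    if any(not (0.0 < p < 100.0) for p in percentiles):
        raise ValueError("percentiles must lie in (0, 100)")
    if n_levels % len(wins) != 0:
        raise ValueError("n_levels must be a multiple of the number of win options")
    if len(np.unique(scores)) < n_levels:
        warnings.warn(
            "fewer distinct reference scores than bonus levels; levels will tie",
            stacklevel=2,
        )
    per_option = n_levels // len(wins)
    srt = np.sort(scores)
    level_ranks: list[float] = []
    prev = 0.0
    for pr in percentiles:
        for j in range(1, per_option + 1):
            level_ranks.append(prev + j / per_option * (pr - prev))
        prev = pr
    level_points = tuple(_percentile_lookup(srt, r) for r in level_ranks)
    return BonusScheme(
        percentile_thresholds=percentiles,
        win_labels=tuple(wins),
        level_points=level_points,
    )


def score_trial(spec: TrialSpec, result_accuracy: bool) -> int:
    """Points delta for one trial: reward +/-3 by accuracy, control 0."""
    if spec.incentive != "reward":
        return 0
    return POINTS_PER_OUTCOME if result_accuracy else -POINTS_PER_OUTCOME


def session_points(specs: Sequence[TrialSpec], accuracies: Sequence[bool]) -> int:
    """Total points over a session (omissions count as errors)."""
    return sum(score_trial(s, a) for s, a in zip(specs, accuracies, strict=True))
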