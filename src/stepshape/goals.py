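"""Adaptive daily step goals via rank-order percentile shaping.

The shaping rule is borrowed from operant conditioning: each morning the
participant's most recent daily step counts (a 9-day moving window) are
ranked from lowest to highest and the goal is placed inside a percentile
range just above the median of that personal distribution (nearest-rank
P50–P70 by default). A uniform random draw inside the range sets the exact
goal, so difficulty varies from day to day while tracking the participant's
own recent performance: as behavior improves the criterion rises with it,
and after a setback it relaxes.

Early-history compensation: with fewer than ``min_history_days`` measured
days the goal falls back to a fixed floor; with a partial window the
available days are ranked as-is. Days with zero recorded steps are treated
as non-wear artifacts and never enter the window.

Reproducibility contract: the goal for a given (policy seed, participant,
date) is a pure function of the measured history before that date — no
look-ahead, and no dependence on how many goals were computed before.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import DailyRecord, ProtocolError


@dataclass(frozen=True)
class GoalPolicy:
    """Parameters of the percentile-shaping goal rule.

    window_days: length of the moving window of measured days (9).
    percentile_low/high: nearest-rank percentile range bracketing the goal
        (50–70 by default: "slightly above the median").
    rounding_step: goals are rounded to this granularity in steps (10).
    floor_goal: minimum goal ever assigned, also the early-history fallback.
    min_history_days: measured days required before the window rule engages.
    seed: base seed for the per-day random goal selection.
    """

    window_days: int = 9
    percentile_low: float = 50.0
    percentile_high: float = 70.0
    rounding_step: int = 10
    floor_goal: int = 2000
    min_history_days: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.percentile_low < self.percentile_high < 100):
            raise ValueError("need 0 < percentile_low < percentile_high < 100")
        if self.rounding_step <= 0:
            raise ValueError("rounding_step must be positive")
        if self.floor_goal < self.rounding_step:
            raise ValueError("floor_goal must be >= rounding_step")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.min_history_days < 0:
            raise ValueError("min_history_days must be >= 0")


@dataclass(frozen=True)
class GoalDecision:
    """One day's computed goal with its provenance.

    window_values holds the ranked measurements the goal was computed from
    (empty when the fallback fired); random_offset is goal minus the window
    median, i.e. the day's random adjustment relative to recent typical
    performance; compensated flags any day decided on less than a full
    window of history.
    """

    date: dt.date | None
    window_values: tuple[int, ...]
    bound_low: int | None
    bound_high: int | None
    goal: int
    random_offset: float
    compensated: bool


def ranked_window(history: Sequence[int], policy: GoalPolicy) -> list[int]:
    """The most recent ``window_days`` measurements, sorted ascending.

    ``history`` is date-ordered (oldest first); shorter histories are ranked
    in full. An empty history yields an empty list (the caller falls through
    to the compensation rule).
    """
    return sorted(history[-policy.window_days:])


def nearest_rank(ranked: Sequence[int], percentile: float) -> int:
    """Nearest-rank percentile: 1-based order statistic ceil(p/100 * n)."""
    n = len(ranked)
    if n == 0:
        raise ValueError("nearest_rank needs a non-empty sequence")
    k = math.ceil(percentile / 100.0 * n)
    k = min(max(k, 1), n)
    return ranked[k - 1]


def percentile_bounds(
    ranked: Sequence[int], policy: GoalPolicy
) -> tuple[int, int]:
    """The (low, high) nearest-rank percentile range of the ranked window."""
    return (
        nearest_rank(ranked, policy.percentile_low),
        nearest_rank(ranked, policy.percentile_high),
    )


def _round_to_step(x: float, step: int) -> int:
    # round half away from zero, so 5 -> 10 at step 10
    return int(math.floor(x / step + 0.5)) * step


def _select_goal(draw: float, low: int, high: int, policy: GoalPolicy) -> int:
    """Round a draw from [low, high] to the policy granularity.

    Preferentially stays inside the percentile range: the rounded value is
    clamped onto the multiples of rounding_step inside [low, high] when any
    exist; a range narrower than one step falls back to the nearest multiple.
    """
    step = policy.rounding_step
    lo_mult = math.ceil(low / step) * step
    hi_mult = math.floor(high / step) * step
    g = _round_to_step(draw, step)
    if lo_mult <= hi_mult:
        g = min(max(g, lo_mult), hi_mult)
    return max(g, policy.floor_goal)


def daily_goal(
    history: Sequence[int],
    policy: GoalPolicy,
    rng: np.random.Generator,
    date: dt.date | None = None,
) -> GoalDecision:
    """Compute one day's goal from the measured history before that day.

    With at least ``min_history_days`` measured days the goal is a uniform
    draw on the nearest-rank percentile range of the ranked window, rounded
    and clamped to ``floor_goal``; otherwise the fixed floor is assigned.
    """
    ranked = ranked_window(list(history), policy)
    if len(ranked) < policy.min_history_days or not ranked:
        return GoalDecision(
            date=date,
            window_values=tuple(ranked),
            bound_low=None,
            bound_high=None,
            goal=policy.floor_goal,
            random_offset=(
                policy.floor_goal - nearest_rank(ranked, 50.0) if ranked else 0.0
            ),
            compensated=True,
        )
    low, high = percentile_bounds(ranked, policy)
    draw = rng.uniform(low, high) if high > low else float(low)
    goal = _select_goal(draw, low, high, policy)
    return GoalDecision(
        date=date,
        window_values=tuple(ranked),
        bound_low=low,
        bound_high=high,
        goal=goal,
        random_offset=goal - nearest_rank(ranked, 50.0),
        compensated=len(ranked) < policy.window_days,
    )


def _participant_key(participant_id: str) -> int:
    digest = hashlib.blake2s(participant_id.encode("utf-8"), digest_size=4)
    return int.from_bytes(digest.digest(), "big")


def goal_rng(
    seed: int, participant_id: str, date: dt.date
) -> np.random.Generator:
    """Independent random stream for one (seed, participant, date) goal."""
    ss = np.random.SeedSequence(
        [int(seed), _participant_key(participant_id), date.toordinal()]
    )
    return np.random.default_rng(ss)


def goal_series(
    records: Iterable[DailyRecord],
    policy: GoalPolicy,
    treatment_dates: Sequence[dt.date] | None = None,
) -> list[GoalDecision]:
    """One GoalDecision per treatment day, with no look-ahead.

    Only treatment-phase measured days feed the window (run-in data are
    excluded to mirror live operation, where no pre-enrollment history
    exists); zero-step days are dropped as non-wear artifacts. The goal for
    day *d* uses only records dated strictly before *d*, so truncating the
    records after any day never changes earlier decisions.
    """
    treatment = sorted(
        (r for r in records if r.phase == "treatment"), key=lambda r: r.date
    )
    dates_seen = [r.date for r in treatment]
    if len(set(dates_seen)) != len(dates_seen):
        raise ProtocolError("duplicate treatment dates in goal_series input")
    if treatment_dates is None:
        treatment_dates = dates_seen
    if not treatment:
        if not treatment_dates:
            return []
        pid = ""
    else:
        pid = treatment[0].participant_id

    decisions = []
    for d in treatment_dates:
        history = [r.steps for r in treatment if r.date < d and r.steps > 0]
        decisions.append(
            daily_goal(history, policy, goal_rng(policy.seed, pid, d), date=d)
        )
    return decisions
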