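"""Trial outcome statistics.

Primary outcome: between-arm difference in the change in mean steps/day
from baseline (run-in) to follow-up, tested with a two-tailed independent-
samples t test (Welch by default, pooled-variance optional). Secondary
outcome: the proportion of participants per arm gaining at least 1000
steps/day, compared by an uncorrected Pearson chi-square on the 2x2 table.
Also provided: per-stratum comparisons (excluding the small active
stratum), a sensitivity analysis that drops the follow-up window
requirement, and treatment-phase engagement metrics.

The repeated-measures mixed-effects robustness model is deliberately not
reimplemented here; ``change_scores`` exposes the per-participant long-form
data so standard tooling (e.g. statsmodels MixedLM) can fit it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import trial as trialmod
from .trial import TrialDataset


@dataclass(frozen=True)
class ArmComparison:
    """Two-arm summary with a two-tailed t test (intervention - control)."""

    n_control: int
    n_intervention: int
    mean_control: float
    mean_intervention: float
    sd_control: float
    sd_intervention: float
    difference: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    method: str = "welch"


@dataclass(frozen=True)
class ResponderResult:
    """2x2 responder contrast: change >= threshold, by arm."""

    threshold: float
    n_control: int
    n_intervention: int
    responders_control: int
    responders_intervention: int
    proportion_control: float
    proportion_intervention: float
    chi_square: float
    p_value: float


def t_test_two_sample(
    values_a: Sequence[float] | None = None,
    values_b: Sequence[float] | None = None,
    *,
    summary_a: tuple[int, float, float] | None = None,
    summary_b: tuple[int, float, float] | None = None,
    method: str = "welch",
) -> ArmComparison:
    """Two-tailed independent-samples t test, arm b minus arm a.

    Accepts raw samples or per-arm (n, mean, sd) summary triplets; both
    entry points agree when the summaries match the data. Degenerate input
    (zero variance in both arms with equal means) yields t=0, p=1.
    """
    if summary_a is None:
        a = np.asarray(values_a, dtype=float)
        if len(a) < 2:
            raise ValueError("each arm needs at least 2 observations")
        summary_a = (len(a), float(a.mean()), float(a.std(ddof=1)))
    if summary_b is None:
        b = np.asarray(values_b, dtype=float)
        if len(b) < 2:
            raise ValueError("each arm needs at least 2 observations")
        summary_b = (len(b), float(b.mean()), float(b.std(ddof=1)))
    n1, m1, s1 = summary_a
    n2, m2, s2 = summary_b
    if n1 < 2 or n2 < 2:
        raise ValueError("each arm needs at least 2 observations")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")

    diff = m2 - m1
    if method == "welch":
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = math.sqrt(v1 + v2)
        if se == 0.0:
            t_stat, df, p = 0.0, float(n1 + n2 - 2), 1.0
        else:
            t_stat = diff / se
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
            p = 2.0 * stats.t.sf(abs(t_stat), df)
    elif method == "pooled":
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        if se == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = diff / se
            p = 2.0 * stats.t.sf(abs(t_stat), df)
    else:
        raise ValueError("method must be 'welch' or 'pooled'")
    return ArmComparison(
        n_control=n1,
        n_intervention=n2,
        mean_control=m1,
        mean_intervention=m2,
        sd_control=s1,
        sd_intervention=s2,
        difference=diff,
        t_statistic=t_stat,
        degrees_of_freedom=df,
        p_value=min(max(p, np.nextafter(0, 1)), 1.0),
        method=method,
    )


def responder_analysis(
    changes_control: Sequence[float],
    changes_intervention: Sequence[float],
    threshold: float = 1000.0,
) -> ResponderResult:
    """Pearson chi-square (no continuity correction) on responders by arm.

    A responder gained at least ``threshold`` steps/day (inclusive).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not len(changes_control) or not len(changes_intervention):
        raise ValueError("both arms must be non-empty")
    rc = int(sum(c >= threshold for c in changes_control))
    ri = int(sum(c >= threshold for c in changes_intervention))
    nc, ni = len(changes_control), len(changes_intervention)
    chi2, p = pearson_chi_square_2x2(rc, nc - rc, ri, ni - ri)
    return ResponderResult(
        threshold=threshold,
        n_control=nc,
        n_intervention=ni,
        responders_control=rc,
        responders_intervention=ri,
        proportion_control=rc / nc,
        proportion_intervention=ri / ni,
        chi_square=chi2,
        p_value=p,
    )


def pearson_chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Uncorrected Pearson chi-square for the table [[a, b], [c, d]].

    Returns (0, 1) when a margin is empty (no information in the table).
    """
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Dataset-level analyses


def change_scores(dataset: TrialDataset) -> pd.DataFrame:
    """Per-participant baseline mean, follow-up mean, and change score.

    One row per randomized participant; ``included`` marks the primary
    analysis set (baseline and a valid follow-up assessment both present).
    """
    rows = []
    for p in dataset.participants:
        if not p.eligible or p.arm is None:
            continue
        included = p.completed_followup and p.baseline_mean_steps is not None
        change = (
            p.followup_mean_steps - p.baseline_mean_steps if included else None
        )
        rows.append(
            {
                "participant_id": p.participant_id,
                "arm": p.arm,
                "stratum": p.stratum,
                "baseline_mean": p.baseline_mean_steps,
                "followup_mean": p.followup_mean_steps,
                "change": change,
                "included": included,
            }
        )
    return pd.DataFrame(rows)


def _arm_changes(scores: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    inc = scores[scores["included"]]
    return (
        inc.loc[inc["arm"] == "control", "change"].to_numpy(dtype=float),
        inc.loc[inc["arm"] == "intervention", "change"].to_numpy(dtype=float),
    )


def primary_analysis(dataset: TrialDataset, method: str = "welch") -> ArmComparison:
    """Between-arm t test on change scores over the primary analysis set."""
    ctrl, interv = _arm_changes(change_scores(dataset))
    return t_test_two_sample(ctrl, interv, method=method)


def stratified_analysis(
    dataset: TrialDataset, method: str = "welch"
) -> dict[str, ArmComparison | None]:
    """Per-stratum comparisons; the small active stratum is excluded.

    A stratum with fewer than 2 participants per arm is reported as None
    (not computable).
    """
    scores = change_scores(dataset)
    out: dict[str, ArmComparison | None] = {}
    for stratum in ("sedentary", "low_to_somewhat"):
        sub = scores[scores["stratum"] == stratum]
        ctrl, interv = _arm_changes(sub)
        if len(ctrl) < 2 or len(interv) < 2:
            out[stratum] = None
        else:
            out[stratum] = t_test_two_sample(ctrl, interv, method=method)
    return out


def sensitivity_all_available(
    dataset: TrialDataset, method: str = "welch"
) -> ArmComparison:
    """Primary contrast with the follow-up window requirement dropped.

    Follow-up means are recomputed over all valid days across both
    assessment windows (days still need the wear threshold); participants
    with any valid follow-up day enter, enlarging the sample.
    """
    ctrl, interv = [], []
    for p in dataset.participants:
        if not p.eligible or p.arm is None or p.baseline_mean_steps is None:
            continue
        fu = trialmod.all_available_follow_up_mean(dataset, p.participant_id)
        if fu is None:
            continue
        (ctrl if p.arm == "control" else interv).append(
            fu - p.baseline_mean_steps
        )
    return t_test_two_sample(ctrl, interv, method=method)


def engagement_summary(
    dataset: TrialDataset,
    worn_threshold: int = 100,
    event_log: Mapping[str, Sequence] | None = None,
) -> pd.DataFrame:
    """Treatment-phase engagement, intervention arm only.

    A day counts as worn when more than ``worn_threshold`` steps were
    recorded; a goal counts as completed when steps reached the day's goal
    (inclusive). ``active_final_week`` is true with any worn day in the
    last 7 treatment days, or any logged email-open / site-visit event
    there (``event_log`` maps participant_id to event dates).
    """
    proto = dataset.protocol
    treatment_dates = proto.phase_dates("treatment")
    final_week = set(treatment_dates[-7:])
    rows = []
    for p in dataset.participants:
        if p.arm != "intervention":
            continue
        recs = dataset.records_for(p.participant_id, phase="treatment")
        goals = {g.date: g.goal for g in dataset.goals.get(p.participant_id, [])}
        worn = [r for r in recs if r.steps > worn_threshold]
        completed = sum(
            1 for r in recs if r.date in goals and r.steps >= goals[r.date]
        )
        active = any(r.date in final_week for r in worn)
        if event_log and not active:
            active = any(
                d in final_week for d in event_log.get(p.participant_id, [])
            )
        rows.append(
            {
                "participant_id": p.participant_id,
                "days_worn": len(worn),
                "goals_completed": completed,
                "active_final_week": active,
            }
        )
    return pd.DataFrame(rows)
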