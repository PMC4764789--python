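"""Trial protocol execution: run-in eligibility, stratified randomization,
follow-up completion, and the trial dataset container.

The protocol clock is shared by all participants: a 7-day run-in
(baseline), 42 days of treatment, a 7-day follow-up assessment window, and
a second 7-day retry window granted to participants whose first window
misses the wear criterion. Baseline activity strata follow the standard
steps/day cutpoints: sedentary (<5000), low-to-somewhat active (5000–9999),
active-to-highly-active (>=10,000).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import records as rec
from .goals import GoalDecision
from .records import AssessmentRule, DailyRecord, NoValidDaysError

STRATA = ("sedentary", "low_to_somewhat", "active")
ARMS = ("control", "intervention")


def classify_stratum(mean_steps: float) -> str:
    """Baseline activity stratum from mean steps/day.

    <5000 sedentary; 5000–9999 low_to_somewhat; >=10000 active.
    """
    if mean_steps < 0:
        raise ValueError(f"mean steps must be non-negative, got {mean_steps}")
    if mean_steps < 5000:
        return "sedentary"
    if mean_steps < 10000:
        return "low_to_somewhat"
    return "active"


@dataclass(frozen=True)
class Protocol:
    """Phase lengths (days) and the wear criterion shared by all assessments."""

    run_in_days: int = 7
    treatment_days: int = 42
    follow_up_days: int = 7
    retry_days: int = 7
    start_date: dt.date = dt.date(2014, 9, 8)
    rule: AssessmentRule = field(default_factory=AssessmentRule)

    def __post_init__(self) -> None:
        if min(self.run_in_days, self.treatment_days, self.follow_up_days) <= 0:
            raise ValueError("phase lengths must be positive")

    @property
    def total_days(self) -> int:
        return (
            self.run_in_days
            + self.treatment_days
            + self.follow_up_days
            + self.retry_days
        )

    def phase_of(self, study_day: int) -> str:
        if study_day < self.run_in_days:
            return "run_in"
        if study_day < self.run_in_days + self.treatment_days:
            return "treatment"
        if study_day < self.run_in_days + self.treatment_days + self.follow_up_days:
            return "follow_up"
        if study_day < self.total_days:
            return "follow_up_retry"
        raise ValueError(f"study day {study_day} outside protocol")

    def date_of(self, study_day: int) -> dt.date:
        return self.start_date + dt.timedelta(days=study_day)

    def phase_dates(self, phase: str) -> list[dt.date]:
        return [
            self.date_of(d)
            for d in range(self.total_days)
            if self.phase_of(d) == phase
        ]


@dataclass
class Participant:
    participant_id: str
    baseline_mean_steps: float | None = None
    stratum: str | None = None
    arm: str | None = None
    eligible: bool = False
    completed_followup: bool = False
    followup_mean_steps: float | None = None

    def __post_init__(self) -> None:
        if self.stratum is not None and self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.arm is not None and self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")


@dataclass
class TrialDataset:
    """All participants and phase-labelled daily records for one trial."""

    participants: list[Participant]
    records: list[DailyRecord]
    protocol: Protocol = field(default_factory=Protocol)
    goals: dict[str, list[GoalDecision]] = field(default_factory=dict)
    epoch_days: list = field(default_factory=list)

    def by_id(self) -> dict[str, Participant]:
        return {p.participant_id: p for p in self.participants}

    def records_for(
        self, participant_id: str, phase: str | None = None
    ) -> list[DailyRecord]:
        out = [
            r
            for r in self.records
            if r.participant_id == participant_id
            and (phase is None or r.phase == phase)
        ]
        return sorted(out, key=lambda r: r.date)

    # -- persistence (plain-text dataset directory) -------------------------

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rec.write_daily_csv(self.records, path / "daily.csv")
        pd.DataFrame(
            {
                "participant_id": [p.participant_id for p in self.participants],
                "baseline_mean_steps": [
                    "" if p.baseline_mean_steps is None
                    else round(p.baseline_mean_steps, 4)
                    for p in self.participants
                ],
                "stratum": [p.stratum or "" for p in self.participants],
                "arm": [p.arm or "" for p in self.participants],
                "eligible": [int(p.eligible) for p in self.participants],
                "completed_followup": [
                    int(p.completed_followup) for p in self.participants
                ],
                "followup_mean_steps": [
                    "" if p.followup_mean_steps is None
                    else round(p.followup_mean_steps, 4)
                    for p in self.participants
                ],
            }
        ).to_csv(path / "participants.csv", index=False)
        if self.goals:
            rows = []
            for pid, decs in sorted(self.goals.items()):
                for g in decs:
                    rows.append(
                        {
                            "participant_id": pid,
                            "date": g.date.isoformat() if g.date else "",
                            "goal": g.goal,
                            "bound_low": "" if g.bound_low is None else g.bound_low,
                            "bound_high": "" if g.bound_high is None else g.bound_high,
                            "compensated": int(g.compensated),
                        }
                    )
            pd.DataFrame(rows).to_csv(path / "goals.csv", index=False)
        if self.epoch_days:
            rec.write_epoch_csv(self.epoch_days, path / "epoch.csv")
        proto = asdict(self.protocol)
        proto["start_date"] = self.protocol.start_date.isoformat()
        (path / "protocol.json").write_text(
            json.dumps(proto, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_dir(cls, path) -> "TrialDataset":
        path = Path(path)
        daily = rec.read_daily_csv(path / "daily.csv")
        protocol = Protocol()
        pj = path / "protocol.json"
        if pj.exists():
            raw = json.loads(pj.read_text())
            rule = AssessmentRule(**raw.pop("rule"))
            raw["start_date"] = dt.date.fromisoformat(raw["start_date"])
            protocol = Protocol(rule=rule, **raw)
        participants: list[Participant] = []
        pcsv = path / "participants.csv"
        if pcsv.exists():
            df = pd.read_csv(pcsv, dtype=str, keep_default_na=False)
            for _, row in df.iterrows():
                participants.append(
                    Participant(
                        participant_id=row["participant_id"],
                        baseline_mean_steps=(
                            float(row["baseline_mean_steps"])
                            if row.get("baseline_mean_steps")
                            else None
                        ),
                        stratum=row.get("stratum") or None,
                        arm=row.get("arm") or None,
                        eligible=bool(int(row.get("eligible") or 0)),
                        completed_followup=bool(
                            int(row.get("completed_followup") or 0)
                        ),
                        followup_mean_steps=(
                            float(row["followup_mean_steps"])
                            if row.get("followup_mean_steps")
                            else None
                        ),
                    )
                )
        else:
            participants = [
                Participant(participant_id=pid)
                for pid in sorted({r.participant_id for r in daily})
            ]
        goals: dict[str, list[GoalDecision]] = {}
        gcsv = path / "goals.csv"
        if gcsv.exists():
            df = pd.read_csv(gcsv, dtype=str, keep_default_na=False)
            for _, row in df.iterrows():
                goals.setdefault(row["participant_id"], []).append(
                    GoalDecision(
                        date=dt.date.fromisoformat(row["date"]),
                        window_values=(),
                        bound_low=int(row["bound_low"]) if row["bound_low"] else None,
                        bound_high=(
                            int(row["bound_high"]) if row["bound_high"] else None
                        ),
                        goal=int(row["goal"]),
                        random_offset=float("nan"),
                        compensated=bool(int(row["compensated"])),
                    )
                )
        return cls(
            participants=participants, records=daily, protocol=protocol, goals=goals
        )


def participants_from_records(records: Sequence[DailyRecord]) -> list[Participant]:
    return [
        Participant(participant_id=pid)
        for pid in sorted({r.participant_id for r in records})
    ]


def apply_run_in(dataset: TrialDataset) -> TrialDataset:
    """Set eligibility, baseline mean, and stratum from the run-in week.

    A participant is eligible iff their run-in window meets the wear
    criterion; the baseline is the mean of run-in valid days. Re-running is
    idempotent (pure function of records and rule).
    """
    rule = dataset.protocol.rule
    for p in dataset.participants:
        run_in = dataset.records_for(p.participant_id, phase="run_in")
        p.eligible = rec.assessment_is_valid(run_in, rule)
        if p.eligible:
            p.baseline_mean_steps = rec.mean_steps_per_day(run_in, rule)
            p.stratum = classify_stratum(p.baseline_mean_steps)
        else:
            p.baseline_mean_steps = None
            p.stratum = None
            p.arm = None
    return dataset


def stratified_randomize(
    participants: Iterable[Participant], rng: np.random.Generator
) -> dict[str, str]:
    """1:1 blocked randomization within baseline stratum.

    Within each stratum, arm counts differ by at most one for every seed;
    which arm receives the odd participant is seed-determined. Returns and
    also sets the assignment map (participant_id -> arm).
    """
    eligible = [p for p in participants if p.eligible]
    if any(p.stratum is None for p in eligible):
        raise ValueError("all eligible participants need a stratum before randomization")
    assignment: dict[str, str] = {}
    for stratum in STRATA:
        members = [p for p in eligible if p.stratum == stratum]
        if not members:
            continue
        order = list(rng.permutation(len(members)))
        first = rng.integers(0, 2)  # which arm leads the alternation
        for slot, idx in enumerate(order):
            arm = ARMS[(slot + first) % 2]
            members[idx].arm = arm
            assignment[members[idx].participant_id] = arm
    return assignment


def follow_up_summary(
    dataset: TrialDataset, participant_id: str
) -> tuple[bool, float | None]:
    """(completed, follow-up mean) using the first valid assessment window.

    The first 7-day window is used when it meets the wear criterion even if
    the retry window is also valid; otherwise the retry window is tried.
    """
    rule = dataset.protocol.rule
    for phase in ("follow_up", "follow_up_retry"):
        window = dataset.records_for(participant_id, phase=phase)
        if window and rec.assessment_is_valid(window, rule):
            return True, rec.mean_steps_per_day(window, rule)
    return False, None


def apply_follow_up(dataset: TrialDataset) -> TrialDataset:
    """Set completion flags and follow-up means from the assessment windows."""
    for p in dataset.participants:
        if not p.eligible:
            p.completed_followup = False
            p.followup_mean_steps = None
            continue
        completed, mean = follow_up_summary(dataset, p.participant_id)
        p.completed_followup = completed
        p.followup_mean_steps = mean
    return dataset


def all_available_follow_up_mean(
    dataset: TrialDataset, participant_id: str
) -> float | None:
    """Mean over all valid follow-up days across both windows (sensitivity).

    Drops the 4-day/weekend window requirement; days still need >=10 h wear.
    None when the participant has no valid follow-up day at all.
    """
    rule = dataset.protocol.rule
    days = [
        r
        for phase in ("follow_up", "follow_up_retry")
        for r in dataset.records_for(participant_id, phase=phase)
    ]
    try:
        return rec.mean_steps_per_day(days, rule)
    except NoValidDaysError:
        return None
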