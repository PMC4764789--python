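"""Daily and epoch-level step records, wear-time estimation, and assessment rules.

A consumer-grade hip/shoe accelerometer reports step counts in 20-minute
epochs (72 bins per day). Wear time is estimated as the clock span from the
earliest to the latest activity of the day. A *valid day* has at least 10
hours of estimated wear; a 7-day assessment window is *valid* when it holds
at least 4 valid days including one weekend day. Mean steps/day for an
assessment is the total steps on valid days divided by the number of valid
days — invalid days contribute nothing.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

N_BINS = 72
BIN_MINUTES = 20

PHASES = ("run_in", "treatment", "follow_up", "follow_up_retry")


class RecordError(ValueError):
    """A record violates a structural invariant."""


class ProtocolError(ValueError):
    """Records do not fit the study protocol (window span, duplicates...)."""


class NoValidDaysError(RecordError):
    """An assessment summary was requested over zero valid days."""


@dataclass(frozen=True)
class EpochDay:
    """One participant-day of 72 twenty-minute step bins.

    Bin ``k`` covers clock minutes ``[20k, 20(k+1))`` from midnight.
    """

    participant_id: str
    date: dt.date
    bins: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bins) != N_BINS:
            raise RecordError(
                f"epoch day needs exactly {N_BINS} bins, got {len(self.bins)}"
            )
        if any(b < 0 for b in self.bins):
            raise RecordError("epoch bins must be non-negative")
        object.__setattr__(self, "bins", tuple(int(b) for b in self.bins))

    @property
    def steps(self) -> int:
        return sum(self.bins)


@dataclass(frozen=True)
class DailyRecord:
    """One participant-day: total steps, estimated wear hours, study phase."""

    participant_id: str
    date: dt.date
    steps: int
    wear_hours: float
    phase: str | None = None

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise RecordError(f"steps must be non-negative, got {self.steps}")
        if not 0.0 <= self.wear_hours <= 24.0:
            raise RecordError(
                f"wear_hours must lie in [0, 24], got {self.wear_hours}"
            )
        if self.phase is not None and self.phase not in PHASES:
            raise RecordError(
                f"unknown phase {self.phase!r}; expected one of {PHASES}"
            )


@dataclass(frozen=True)
class AssessmentRule:
    """Valid-day and assessment-window criteria.

    Defaults encode the trial rule: at least ``min_wear_hours`` (10 h) of wear
    makes a day valid; an assessment over a ``window_days`` (7) calendar window
    is valid with at least ``min_valid_days`` (4) valid days including one
    weekend day.
    """

    min_wear_hours: float = 10.0
    min_valid_days: int = 4
    require_weekend_day: bool = True
    window_days: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.min_wear_hours <= 24:
            raise ValueError("min_wear_hours must lie in (0, 24]")
        if not 1 <= self.min_valid_days <= self.window_days:
            raise ValueError("need 1 <= min_valid_days <= window_days")


def wear_time(epoch_day: EpochDay) -> float:
    """Estimated wear in hours: span from first to last activity of the day.

    The span runs from the start of the earliest non-zero bin to the end of
    the latest non-zero bin; interior zero bins count as wear. Returns 0 for
    an all-zero day; a single active bin yields 20 minutes (1/3 h).
    """
    first = last = None
    for i, b in enumerate(epoch_day.bins):
        if b > 0:
            if first is None:
                first = i
            last = i
    if first is None:
        return 0.0
    return (last + 1 - first) * BIN_MINUTES / 60.0


def daily_from_epoch(epoch_day: EpochDay, phase: str | None = None) -> DailyRecord:
    """Collapse an epoch day to a daily record (bin-sum steps, span wear)."""
    return DailyRecord(
        participant_id=epoch_day.participant_id,
        date=epoch_day.date,
        steps=epoch_day.steps,
        wear_hours=wear_time(epoch_day),
        phase=phase,
    )


def is_valid_day(record: DailyRecord, rule: AssessmentRule) -> bool:
    """True iff the day meets the wear threshold (inclusive: 'at least')."""
    return record.wear_hours >= rule.min_wear_hours


def valid_days(
    records: Iterable[DailyRecord], rule: AssessmentRule
) -> list[DailyRecord]:
    return [r for r in records if is_valid_day(r, rule)]


def assessment_is_valid(
    records: Sequence[DailyRecord], rule: AssessmentRule
) -> bool:
    """Whether one contiguous assessment window meets the wear criterion.

    Requires >= ``rule.min_valid_days`` valid days and, if
    ``rule.require_weekend_day``, at least one valid Saturday or Sunday.
    Missing calendar days simply count as invalid (zero-wear) days.
    """
    if records:
        span = (max(r.date for r in records) - min(r.date for r in records)).days + 1
        if span > rule.window_days:
            raise ProtocolError(
                f"records span {span} calendar days, window is {rule.window_days}"
            )
    good = valid_days(records, rule)
    if len(good) < rule.min_valid_days:
        return False
    if rule.require_weekend_day and not any(r.date.weekday() >= 5 for r in good):
        return False
    return True


def mean_steps_per_day(
    records: Sequence[DailyRecord], rule: AssessmentRule
) -> float:
    """Total steps on valid days divided by the number of valid days."""
    good = valid_days(records, rule)
    if not good:
        raise NoValidDaysError("no valid days in assessment window")
    return sum(r.steps for r in good) / len(good)


# ---------------------------------------------------------------------------
# CSV I/O (daily: participant_id,date,steps,wear_hours[,phase];
#          epoch: participant_id,date,bin_00..bin_71)

_DAILY_REQUIRED = ("participant_id", "date", "steps", "wear_hours")
_BIN_COLS = tuple(f"bin_{i:02d}" for i in range(N_BINS))


def _parse_date(value: str, row: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise RecordError(f"row {row}: unparsable ISO date {value!r}") from exc


def read_daily_csv(path) -> list[DailyRecord]:
    """Read daily records from CSV; header row required, dates ISO-8601.

    Validation failures name the offending row (header = row 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _DAILY_REQUIRED if c not in df.columns]
    if missing:
        raise RecordError(f"daily CSV missing required columns: {missing}")
    has_phase = "phase" in df.columns
    out: list[DailyRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            steps = int(d["steps"])
            wear = float(d["wear_hours"])
        except ValueError as exc:
            raise RecordError(f"row {i}: non-numeric steps/wear_hours") from exc
        phase = d.get("phase") or None if has_phase else None
        try:
            out.append(
                DailyRecord(
                    participant_id=str(d["participant_id"]),
                    date=_parse_date(d["date"], i),
                    steps=steps,
                    wear_hours=wear,
                    phase=phase,
                )
            )
        except RecordError as exc:
            raise RecordError(f"row {i}: {exc}") from exc
    return out


def write_daily_csv(records: Iterable[DailyRecord], path) -> None:
    _daily_frame(list(records)).to_csv(path, index=False)


def _daily_frame(records: list[DailyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "date": [r.date.isoformat() for r in records],
            "steps": [r.steps for r in records],
            "wear_hours": [round(r.wear_hours, 4) for r in records],
            "phase": [r.phase or "" for r in records],
        }
    )


def read_epoch_csv(path) -> list[EpochDay]:
    """Read epoch days (72 twenty-minute bins per row) from CSV."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("participant_id", "date", *_BIN_COLS) if c not in df.columns]
    if missing:
        raise RecordError(f"epoch CSV missing required columns: {missing[:5]}...")
    out: list[EpochDay] = []
    for i, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            bins = tuple(int(row[c]) for c in _BIN_COLS)
        except ValueError as exc:
            raise RecordError(f"row {i}: non-integer bin value") from exc
        try:
            out.append(
                EpochDay(
                    participant_id=str(row["participant_id"]),
                    date=_parse_date(row["date"], i),
                    bins=bins,
                )
            )
        except RecordError as exc:
            raise RecordError(f"row {i}: {exc}") from exc
    return out


def write_epoch_csv(epoch_days: Iterable[EpochDay], path) -> None:
    rows = []
    for e in epoch_days:
        row = {"participant_id": e.participant_id, "date": e.date.isoformat()}
        row.update({c: b for c, b in zip(_BIN_COLS, e.bins)})
        rows.append(row)
    pd.DataFrame(rows, columns=["participant_id", "date", *_BIN_COLS]).to_csv(
        path, index=False
    )


def merge_epoch_daily(
    epoch_days: Sequence[EpochDay], daily: Sequence[DailyRecord]
) -> list[DailyRecord]:
    """Combine epoch and daily sources; epoch-derived values win on conflict.

    Epoch data is the raw source, so when both are supplied for the same
    (participant, date) the epoch-derived steps/wear replace the daily row
    (a warning is logged); the daily row's phase label is kept.
    """
    by_key = {(r.participant_id, r.date): r for r in daily}
    for e in epoch_days:
        key = (e.participant_id, e.date)
        derived = daily_from_epoch(e)
        if key in by_key:
            existing = by_key[key]
            if (existing.steps, existing.wear_hours) != (
                derived.steps,
                derived.wear_hours,
            ):
                logger.warning(
                    "epoch data overrides daily row for %s on %s", *key
                )
            by_key[key] = replace(derived, phase=existing.phase)
        else:
            by_key[key] = derived
    return sorted(by_key.values(), key=lambda r: (r.participant_id, r.date))
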