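import datetime as dt

import pytest

from stepshape.records import AssessmentRule, DailyRecord, EpochDay, N_BINS
from stepshape.trial import Participant, Protocol, TrialDataset

START = dt.date(2014, 9, 8)  # a Monday, so every 7-day window holds a weekend


def make_bins(active: dict[int, int]) -> tuple[int, ...]:
    """72 epoch bins with steps only at the given bin indices."""
    bins = [0] * N_BINS
    for idx, steps in active.items():
        bins[idx] = steps
    return tuple(bins)


def make_week(
    pid: str,
    phase: str,
    start: dt.date,
    steps: list[int],
    wear: float | list[float] = 14.0,
) -> list[DailyRecord]:
    wears = wear if isinstance(wear, list) else [wear] * len(steps)
    return [
        DailyRecord(pid, start + dt.timedelta(days=i), s, w, phase)
        for i, (s, w) in enumerate(zip(steps, wears))
    ]


@pytest.fixture
def rule() -> AssessmentRule:
    return AssessmentRule()


@pytest.fixture
def protocol() -> Protocol:
    return Protocol(start_date=START)


def build_dataset(per_participant: dict[str, dict[str, list[DailyRecord]]],
                  protocol: Protocol | None = None) -> TrialDataset:
    """Assemble a TrialDataset from {pid: {phase: records}} blocks."""
    protocol = protocol or Protocol(start_date=START)
    records = [
        r
        for blocks in per_participant.values()
        for recs in blocks.values()
        for r in recs
    ]
    return TrialDataset(
        participants=[Participant(participant_id=pid) for pid in per_participant],
        records=records,
        protocol=protocol,
    )


@pytest.fixture
def two_arm_dataset(protocol) -> TrialDataset:
    """Four eligible participants, two per arm, with clean week data.

    Baselines / follow-ups chosen so change scores are simple round numbers:
      C1: 5000 -> 4600 (change -400)   C2: 6000 -> 5600 (change -400)
      I1: 5000 -> 6000 (change +1000)  I2: 4000 -> 4500 (change +500)
    """
    fu_start = protocol.date_of(protocol.run_in_days + protocol.treatment_days)
    arm_setup = {
        "C1": (5000, 4600, "control"),
        "C2": (6000, 5600, "control"),
        "I1": (5000, 6000, "intervention"),
        "I2": (4000, 4500, "intervention"),
    }
    blocks = {}
    for pid, (base, fu, _) in arm_setup.items():
        blocks[pid] = {
            "run_in": make_week(pid, "run_in", START, [base] * 7),
            "follow_up": make_week(pid, "follow_up", fu_start, [fu] * 7),
        }
    ds = build_dataset(blocks, protocol)
    from stepshape.trial import apply_follow_up, apply_run_in

    apply_run_in(ds)
    for p in ds.participants:
        p.arm = arm_setup[p.participant_id][2]
    apply_follow_up(ds)
    return ds
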