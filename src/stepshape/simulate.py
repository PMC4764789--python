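"""Synthetic cohort generator for the walking trial.

Generates per-participant daily step series with the structure the trial
design assumes: participant-level baseline means drawn within activity
strata, day-of-week modulation, within-person noise, measurement reactivity
that decays over the study, a secular (seasonal) linear decline, slow
person-level drift between baseline and follow-up, realistic wear-time and
non-wear patterns, follow-up attrition, and an intervention response.
Treatment-arm days are generated interactively against the goal engine, so
adaptive goals can causally gate behavior with no look-ahead.

The daily expectation for participant *i* on study day *d* is

    mu(i, d) = baseline_i * dow(weekday) + A_i * 2^(-d / halflife)
               + slope * d + drift_i * 1[d >= run-in]
               + response_i * 1[arm = intervention, d >= treatment start]
               + boost * 1[pursuing and mu < goal]

with realized steps drawn Normal(mu, within_sd) clipped at zero. Control
participants generate no treatment-phase data (they are instructed not to
wear the tracker between baseline and follow-up).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import goals as goalmod
from . import trial as trialmod
from .goals import GoalPolicy
from .records import DailyRecord, EpochDay, N_BINS, wear_time
from .trial import Participant, Protocol, TrialDataset

_DOW_DEFAULT = (0.98, 1.00, 1.00, 1.00, 1.04, 1.08, 0.90)  # Mon..Sun, mean 1


@dataclass(frozen=True)
class BehaviorProfile:
    """Latent behavioral parameters of one simulated participant."""

    baseline_mean: float
    dow_multipliers: tuple[float, ...] = _DOW_DEFAULT
    within_sd: float = 1800.0
    reactivity_amplitude: float = 800.0
    reactivity_halflife: float = 5.0
    secular_slope: float = -2.32
    level_drift: float = 0.0           # persistent post-baseline shift
    response: float = 0.0              # additive program response (steps/day)
    goal_pursuit_prob: float = 0.0
    pursuit_boost: float = 0.0
    wear_mean_hours: float = 14.4
    wear_sd_hours: float = 1.2
    nonwear_prob: float = 0.08

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if len(self.dow_multipliers) != 7 or min(self.dow_multipliers) <= 0:
            raise ValueError("need 7 positive day-of-week multipliers")
        if abs(sum(self.dow_multipliers) / 7 - 1.0) > 0.02:
            raise ValueError("day-of-week multipliers must average to ~1")
        for p in (self.goal_pursuit_prob, self.nonwear_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class StratumBaseline:
    """Distribution of baseline means within one activity stratum."""

    mean: float
    sd: float
    lo: float
    hi: float


DEFAULT_STRATUM_BASELINES: Mapping[str, StratumBaseline] = {
    "sedentary": StratumBaseline(3800.0, 950.0, 1500.0, 4999.0),
    "low_to_somewhat": StratumBaseline(6800.0, 1250.0, 5000.0, 9999.0),
    "active": StratumBaseline(11000.0, 900.0, 10000.0, 14000.0),
}


@dataclass(frozen=True)
class EffectProfile:
    """Treatment-arm modifications applied after randomization.

    response_mean/response_sd: per-participant additive program response
    (steps/day, active on treatment and follow-up days). goal_pursuit_prob /
    pursuit_boost: an optional goal-coupled mechanism — on pursued days the
    boost is added only when the day's expectation sits below the goal.
    """

    response_mean: float = 970.0
    response_sd: float = 800.0
    goal_pursuit_prob: float = 0.7
    pursuit_boost: float = 0.0


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated trial."""

    n_participants: int = 265
    stratum_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "sedentary": 0.536,
            "low_to_somewhat": 0.449,
            "active": 0.015,
        }
    )
    stratum_baselines: Mapping[str, StratumBaseline] = field(
        default_factory=lambda: dict(DEFAULT_STRATUM_BASELINES)
    )
    effect: EffectProfile | None = field(default_factory=EffectProfile)
    protocol: Protocol = field(default_factory=Protocol)
    dow_multipliers: tuple[float, ...] = _DOW_DEFAULT
    within_sd: float = 1800.0
    reactivity_mean: float = 800.0
    reactivity_sd: float = 500.0
    reactivity_halflife: float = 5.0
    secular_slope: float = -2.32
    drift_sd: float = 1350.0
    wear_mean_hours: float = 14.4
    wear_sd_hours: float = 1.2
    nonwear_prob: float = 0.08
    dropout_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if abs(sum(self.stratum_mix.values()) - 1.0) > 1e-6:
            raise ValueError("stratum_mix must sum to 1")


def stratum_counts(config: CohortConfig) -> dict[str, int]:
    """Deterministic largest-remainder allocation of participants to strata."""
    n = config.n_participants
    raw = {s: config.stratum_mix.get(s, 0.0) * n for s in trialmod.STRATA}
    counts = {s: int(math.floor(v)) for s, v in raw.items()}
    short = n - sum(counts.values())
    for s in sorted(raw, key=lambda s: raw[s] - counts[s], reverse=True)[:short]:
        counts[s] += 1
    return counts


def sample_profile(
    stratum: str, config: CohortConfig, rng: np.random.Generator
) -> BehaviorProfile:
    """Draw one participant's latent behavior profile for a stratum."""
    if stratum not in config.stratum_baselines:
        raise ValueError(f"unknown stratum {stratum!r}")
    sb = config.stratum_baselines[stratum]
    baseline = float(np.clip(rng.normal(sb.mean, sb.sd), sb.lo, sb.hi))
    reactivity = max(0.0, rng.normal(config.reactivity_mean, config.reactivity_sd))
    drift = rng.normal(0.0, config.drift_sd)
    return BehaviorProfile(
        baseline_mean=baseline,
        dow_multipliers=config.dow_multipliers,
        within_sd=config.within_sd,
        reactivity_amplitude=reactivity,
        reactivity_halflife=config.reactivity_halflife,
        secular_slope=config.secular_slope,
        level_drift=drift,
        wear_mean_hours=config.wear_mean_hours,
        wear_sd_hours=config.wear_sd_hours,
        nonwear_prob=config.nonwear_prob,
    )


def expected_steps(
    profile: BehaviorProfile,
    date: dt.date,
    study_day: int,
    phase: str = "treatment",
) -> float:
    """Closed-form expected steps before goal pursuit and noise."""
    mu = profile.baseline_mean * profile.dow_multipliers[date.weekday()]
    mu += profile.reactivity_amplitude * 2.0 ** (
        -study_day / profile.reactivity_halflife
    )
    mu += profile.secular_slope * study_day
    if phase != "run_in":
        mu += profile.level_drift
        mu += profile.response
    return mu


def simulate_day(
    profile: BehaviorProfile,
    date: dt.date,
    study_day: int,
    goal: int | None,
    rng: np.random.Generator,
    phase: str = "treatment",
    participant_id: str = "P0000",
    worn: bool = True,
    make_epoch: bool = False,
) -> tuple[DailyRecord, EpochDay | None]:
    """Realize one participant-day (steps + wear; optional epoch breakdown)."""
    if study_day < 0:
        raise ValueError("study_day must be >= 0")
    if not worn:
        record = DailyRecord(participant_id, date, 0, 0.0, phase)
        epoch = (
            EpochDay(participant_id, date, (0,) * N_BINS) if make_epoch else None
        )
        return record, epoch

    mu = expected_steps(profile, date, study_day, phase)
    if (
        goal is not None
        and profile.pursuit_boost > 0
        and mu < goal
        and rng.random() < profile.goal_pursuit_prob
    ):
        mu += profile.pursuit_boost

    nonwear = rng.random() < profile.nonwear_prob
    noise = rng.normal(0.0, profile.within_sd) if profile.within_sd > 0 else 0.0
    base_steps = max(0.0, mu + noise)
    if nonwear:
        wear = rng.uniform(0.0, 2.0)
        steps = int(round(base_steps * wear / profile.wear_mean_hours))
    else:
        wear = float(
            np.clip(rng.normal(profile.wear_mean_hours, profile.wear_sd_hours),
                    0.5, 24.0)
        )
        steps = int(round(base_steps))

    if not make_epoch:
        return DailyRecord(participant_id, date, steps, wear, phase), None

    epoch = _make_epoch(participant_id, date, steps, wear, rng)
    record = DailyRecord(participant_id, date, epoch.steps, wear_time(epoch), phase)
    return record, epoch


def _make_epoch(
    participant_id: str,
    date: dt.date,
    steps: int,
    wear_hours: float,
    rng: np.random.Generator,
) -> EpochDay:
    """Spread a day's steps over 20-minute bins spanning the wear window."""
    bins = np.zeros(N_BINS, dtype=int)
    if steps > 0 and wear_hours > 0:
        span = int(np.clip(round(wear_hours * 3), 1, N_BINS))
        # waking start: around 06:00-08:00 when the span allows it
        lo = min(18, N_BINS - span)
        hi = min(24, N_BINS - span)
        start = int(rng.integers(lo, hi + 1))
        probs = np.full(span, 1.0 / span)
        alloc = rng.multinomial(steps, probs)
        if span >= 2 and steps >= 2:
            # wear span is defined by first/last activity: pin the endpoints
            if alloc[0] == 0:
                alloc[int(np.argmax(alloc))] -= 1
                alloc[0] += 1
            if alloc[-1] == 0:
                alloc[int(np.argmax(alloc))] -= 1
                alloc[-1] += 1
        bins[start : start + span] = alloc
    return EpochDay(participant_id, date, tuple(int(b) for b in bins))


def simulate_cohort(
    config: CohortConfig,
    policy: GoalPolicy | None = None,
    compute_goals: bool = True,
    make_epochs: bool = False,
) -> TrialDataset:
    """Run the whole randomized trial in silico.

    Samples profiles per stratum (largest-remainder allocation over the
    configured mix), simulates the run-in week, applies the eligibility
    rule, block-randomizes eligible participants 1:1 within stratum, then
    generates treatment and follow-up (+retry) days — intervention-arm
    goals are produced day by day by the goal engine from data strictly
    before each day. Fully reproducible from ``config.seed``.
    """
    protocol = config.protocol
    policy = policy or GoalPolicy(seed=config.seed)
    n = config.n_participants
    streams = np.random.SeedSequence(config.seed).spawn(n + 2)
    rand_rng = np.random.default_rng(streams[n])
    effect_rng = np.random.default_rng(streams[n + 1])

    counts = stratum_counts(config)
    strata_seq = [s for s in trialmod.STRATA for _ in range(counts[s])]

    pids = [f"P{i:04d}" for i in range(n)]
    rngs = {pid: np.random.default_rng(streams[i]) for i, pid in enumerate(pids)}
    profiles: dict[str, BehaviorProfile] = {}
    dropout: dict[str, bool] = {}
    records: list[DailyRecord] = []
    epochs: list[EpochDay] = []

    run_in_days = [d for d in range(protocol.total_days)
                   if protocol.phase_of(d) == "run_in"]
    for pid, stratum in zip(pids, strata_seq):
        rng = rngs[pid]
        profiles[pid] = sample_profile(stratum, config, rng)
        dropout[pid] = bool(rng.random() < config.dropout_prob)
        for d in run_in_days:
            record, epoch = simulate_day(
                profiles[pid], protocol.date_of(d), d, None, rng,
                phase="run_in", participant_id=pid, make_epoch=make_epochs,
            )
            records.append(record)
            if epoch is not None:
                epochs.append(epoch)

    dataset = TrialDataset(
        participants=[Participant(participant_id=pid) for pid in pids],
        records=records,
        protocol=protocol,
    )
    trialmod.apply_run_in(dataset)
    trialmod.stratified_randomize(dataset.participants, rand_rng)

    # arm-specific behavior: draw intervention responses in participant order
    for p in dataset.participants:
        if p.arm == "intervention" and config.effect is not None:
            eff = config.effect
            profiles[p.participant_id] = dataclasses.replace(
                profiles[p.participant_id],
                response=effect_rng.normal(eff.response_mean, eff.response_sd),
                goal_pursuit_prob=eff.goal_pursuit_prob,
                pursuit_boost=eff.pursuit_boost,
            )

    later_days = [d for d in range(protocol.total_days)
                  if protocol.phase_of(d) != "run_in"]
    for p in dataset.participants:
        pid = p.participant_id
        rng = rngs[pid]
        profile = profiles[pid]
        history: list[int] = []  # measured treatment-phase steps, in date order
        decisions = []
        for d in later_days:
            phase = protocol.phase_of(d)
            date = protocol.date_of(d)
            goal = None
            worn = True
            if not p.eligible:
                worn = False  # excluded at run-in: no further data collected
            elif phase == "treatment":
                if p.arm == "control":
                    worn = False  # control asked not to wear until follow-up
                elif compute_goals:
                    decision = goalmod.daily_goal(
                        history, policy,
                        goalmod.goal_rng(policy.seed, pid, date), date=date,
                    )
                    decisions.append(decision)
                    goal = decision.goal
            else:  # follow-up windows
                if dropout[pid]:
                    worn = False
            record, epoch = simulate_day(
                profile, date, d, goal, rng, phase=phase,
                participant_id=pid, worn=worn, make_epoch=make_epochs,
            )
            if phase == "treatment" and p.arm == "intervention" and record.steps > 0:
                history.append(record.steps)
            records.append(record)
            if epoch is not None:
                epochs.append(epoch)
        if decisions:
            dataset.goals[pid] = decisions

    dataset.records.sort(key=lambda r: (r.participant_id, r.date))
    trialmod.apply_follow_up(dataset)
    dataset.epoch_days = sorted(epochs, key=lambda e: (e.participant_id, e.date))
    return dataset


def null_config(config: CohortConfig | None = None, **overrides) -> CohortConfig:
    """A copy of the study conditions with no treatment effect (both arms
    behaviorally identical) — used for type-I-error calibration."""
    base = config or CohortConfig()
    return dataclasses.replace(base, effect=None, **overrides)
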