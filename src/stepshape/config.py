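"""YAML run configuration: one file (and one seed) reproduces a whole run."""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .goals import GoalPolicy
from .records import AssessmentRule
from .simulate import CohortConfig, EffectProfile, StratumBaseline
from .trial import Protocol


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs besides the input data."""

    seed: int = 0
    policy: GoalPolicy = field(default_factory=GoalPolicy)
    rule: AssessmentRule = field(default_factory=AssessmentRule)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    responder_threshold: float = 1000.0
    t_test: str = "welch"


def _protocol_from(raw: dict, rule: AssessmentRule) -> Protocol:
    raw = dict(raw)
    if "start_date" in raw:
        raw["start_date"] = dt.date.fromisoformat(str(raw["start_date"]))
    return Protocol(rule=rule, **raw)


def _cohort_from(raw: dict, rule: AssessmentRule, seed: int) -> CohortConfig:
    raw = dict(raw)
    if "effect" in raw:
        raw["effect"] = EffectProfile(**raw["effect"]) if raw["effect"] else None
    if "stratum_baselines" in raw:
        raw["stratum_baselines"] = {
            k: StratumBaseline(**v) for k, v in raw["stratum_baselines"].items()
        }
    if "dow_multipliers" in raw:
        raw["dow_multipliers"] = tuple(raw["dow_multipliers"])
    proto = raw.pop("protocol", {})
    return CohortConfig(
        protocol=_protocol_from(proto, rule), seed=seed, **raw
    )


def load_run_config(path=None, seed: int | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file; CLI --seed overrides the file's."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if seed is None:
        seed = int(raw.get("seed", 0))
    rule = AssessmentRule(**raw.get("assessment_rule", {}))
    policy_raw = dict(raw.get("goal_policy", {}))
    policy_raw.setdefault("seed", seed)
    return RunConfig(
        seed=seed,
        policy=GoalPolicy(**policy_raw),
        rule=rule,
        cohort=_cohort_from(raw.get("cohort", {}), rule, seed),
        responder_threshold=float(raw.get("responder_threshold", 1000.0)),
        t_test=str(raw.get("t_test", "welch")),
    )


def config_digest(config: RunConfig) -> str:
    """Stable hash of a run configuration, for the run manifest."""

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, dt.date):
            return o.isoformat()
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
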