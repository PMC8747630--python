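"""Single-subject execution of an activity with caregiver-help escalation.

One simulated subject walks through the activity's steps in stage order.
Retrieval steps query declarative memory; on a failure (omission or
commission) the caregiver intervenes by *boosting* the target chunk and the
request is retried.  The amount of help is read off the escalation ladder:
success without boosts is independent, success after one boost required a
verbal cue, after two boosts physical assistance, and a step that still
fails after the allowed attempts is scored "not capable" (the caregiver is
assumed to complete it; later stages proceed).  Behaviour steps resolve a
{succeed, fail} production pair; on failure the verbal-help production runs
with an extra utility bonus, then the physical-help production with a larger
bonus, and if that also fails the subject is incapable of the step.

The full event log, one record per attempt, forms the
:class:`SubjectTrace`, together with the three memory-problem counters a
single-subject report prints: times the subject forgot something, times a
similar item was confused, and times some other item was confused.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

from .activities import Activity, ActivityStep
from .memory import RetrievalStatus, boost, retrieve
from .production import Production, resolve_conflict

if TYPE_CHECKING:  # pragma: no cover
    from .profiles import ADProfile

__all__ = [
    "HELP_LEVELS",
    "INDEPENDENT",
    "VERBAL",
    "PHYSICAL",
    "INCAPABLE",
    "EventRecord",
    "SubjectTrace",
    "simulate_subject",
]

#: Help levels, indexed by the numeric level used throughout (and by KTA).
HELP_LEVELS = ("independent", "verbal", "physical", "incapable")
INDEPENDENT, VERBAL, PHYSICAL, INCAPABLE = range(4)

_OUTCOMES = ("success", "omission", "commission", "behaviour_failure")


@dataclass(frozen=True)
class EventRecord:
    """One attempt at one step.

    ``help_level`` is the assistance level in force for this attempt: for a
    success, the number of boosts / help productions that were needed first;
    for a failure, the escalation level the failure triggers (3 = incapable
    when the ladder is exhausted).
    """

    step_id: str
    outcome: str
    help_level: int
    boosts_used: int = 0
    confused_with: Optional[str] = None
    attempt: int = 1

    def __post_init__(self):
        if self.outcome not in _OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if not (0 <= self.help_level <= 3):
            raise ValueError("help_level must be in 0..3")
        if self.outcome == "success" and self.attempt == 1 and self.help_level != INDEPENDENT:
            raise ValueError("first-attempt success must be independent")
        if self.confused_with is not None and self.outcome != "commission":
            raise ValueError("confused_with is only set for commission outcomes")


@dataclass
class SubjectTrace:
    """Ordered event log of one simulated execution, plus problem counters."""

    activity: str
    level: str
    events: list = field(default_factory=list)
    forgot_count: int = 0
    similar_confusion_count: int = 0
    other_confusion_count: int = 0

    def step_help_levels(self) -> dict[str, int]:
        """Final help level per step (maximum over the step's events)."""
        out: dict[str, int] = {}
        for ev in self.events:
            out[ev.step_id] = max(out.get(ev.step_id, 0), ev.help_level)
        return out

    def check_consistency(self) -> None:
        """Verify the help ladder is reproducible from the event log alone."""
        by_step: dict[str, list] = {}
        for ev in self.events:
            by_step.setdefault(ev.step_id, []).append(ev)
        for step_id, evs in by_step.items():
            successes = [e for e in evs if e.outcome == "success"]
            failures = [e for e in evs if e.outcome != "success"]
            if len(successes) > 1:
                raise ValueError(f"step {step_id!r}: more than one success event")
            if successes:
                if successes[0].help_level != min(len(failures), INCAPABLE):
                    raise ValueError(
                        f"step {step_id!r}: success help level inconsistent with failures"
                    )
            elif failures and max(e.help_level for e in failures) != INCAPABLE:
                raise ValueError(f"step {step_id!r}: exhausted ladder must end incapable")
        omissions = sum(1 for e in self.events if e.outcome == "omission")
        commissions = sum(1 for e in self.events if e.outcome == "commission")
        if self.forgot_count != omissions:
            raise ValueError("forgot_count does not match omission events")
        if self.similar_confusion_count + self.other_confusion_count != commissions:
            raise ValueError("confusion counters do not match commission events")

    def to_jsonl(self) -> str:
        """Line-delimited structured log, one JSON record per event."""
        lines = []
        for ev in self.events:
            lines.append(
                json.dumps(
                    {
                        "step": ev.step_id,
                        "attempt": ev.attempt,
                        "outcome": ev.outcome,
                        "help_level": ev.help_level,
                        "help": HELP_LEVELS[ev.help_level],
                        "boosts_used": ev.boosts_used,
                        "confused_with": ev.confused_with,
                    },
                    sort_keys=True,
                )
            )
        return "\n".join(lines)


def _failure_help_level(attempt: int, max_attempts: int) -> int:
    """Escalation triggered by a failure at the given attempt.

    With the default three-attempt ladder: first failure summons verbal help
    (one boost), second physical (two boosts), third exhausts the ladder.
    """
    if attempt >= max_attempts:
        return INCAPABLE
    return min(attempt, PHYSICAL)


def _run_retrieval_step(step, memory, params, boost_increment, rng, trace, similar_partner):
    memory.reset_episode()
    for attempt in range(1, params.max_attempts + 1):
        out = retrieve(step.target_item, list(step.context), memory, params, rng, attempt)
        chunk = memory.chunk(step.target_item)
        if out.status is RetrievalStatus.SUCCESS:
            trace.events.append(
                EventRecord(
                    step_id=step.id,
                    outcome="success",
                    help_level=min(chunk.boost_count, INCAPABLE),
                    boosts_used=chunk.boost_count,
                    attempt=attempt,
                )
            )
            return
        if out.status is RetrievalStatus.OMISSION:
            trace.forgot_count += 1
            outcome, confused = "omission", None
        else:
            outcome, confused = "commission", out.winner
            if out.winner == similar_partner:
                trace.similar_confusion_count += 1
            else:
                trace.other_confusion_count += 1
        trace.events.append(
            EventRecord(
                step_id=step.id,
                outcome=outcome,
                help_level=_failure_help_level(attempt, params.max_attempts),
                boosts_used=chunk.boost_count,
                confused_with=confused,
                attempt=attempt,
            )
        )
        if attempt < params.max_attempts:
            boost(step.target_item, memory, boost_increment)
    # ladder exhausted: the step is skipped; the caregiver completes it


def _run_behaviour_step(step: ActivityStep, profile: "ADProfile", rng, trace) -> None:
    gap = profile.gap_for(step.category)
    g, c = (gap, 0.0) if gap >= 0 else (0.0, -gap)
    extras = (0.0, profile.help_extra_verbal, profile.help_extra_physical)
    for rung, extra in enumerate(extras):
        succeed = Production(
            id=f"{step.id}::succeed",
            P_success=1.0,
            G=g,
            C=c,
            noise_scale_util=profile.noise_scale_util,
            extra_utility=extra,
            noise_dist=profile.noise_dist,
        )
        fail = Production(
            id=f"{step.id}::fail",
            P_success=1.0,
            noise_scale_util=profile.noise_scale_util,
            noise_dist=profile.noise_dist,
        )
        chosen, fired = resolve_conflict([succeed, fail], rng)
        if chosen == succeed.id and fired:
            trace.events.append(
                EventRecord(
                    step_id=step.id,
                    outcome="success",
                    help_level=rung,
                    attempt=rung + 1,
                )
            )
            return
        trace.events.append(
            EventRecord(
                step_id=step.id,
                outcome="behaviour_failure",
                help_level=min(rung + 1, INCAPABLE),
                attempt=rung + 1,
            )
        )
    # physical help failed: incapable of performing; the caregiver takes over


def simulate_subject(
    activity: Activity, profile: "ADProfile", rng: np.random.Generator
) -> SubjectTrace:
    """Execute one subject through the activity and return the full trace.

    Steps run in stage order.  The simulation always terminates: both
    escalation ladders are bounded, and skipped (incapable) steps do not
    block later stages.
    """
    params = profile.memory_params()
    memory = activity.build_memory(profile.similarity_scale)
    trace = SubjectTrace(activity=activity.name, level=profile.level)
    for step in activity.ordered_steps():
        if step.kind == "retrieval":
            partner = activity.similarities.most_similar_partner(step.target_item)
            _run_retrieval_step(
                step, memory, params, profile.boost_increment, rng, trace, partner
            )
        else:
            _run_behaviour_step(step, profile, rng, trace)
    trace.check_consistency()
    return trace
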