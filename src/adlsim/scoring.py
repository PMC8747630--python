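"""KTA functional-test scoring of a simulated execution trace.

The Kitchen Task Assessment scores six cognitive components — initiation,
organization, performs all steps, sequencing, judgment & safety, completion —
each 0 (independent), 1 (required verbal clues), 2 (required physical
assistance) or 3 (not capable), for a total of 0-18.  A component's score is
the worst (maximum) help level observed on any step tagged with that
category, matching the test's semantics of scoring by the amount of help
needed; scoring is a pure function of the trace.
"""

from __future__ import annotations

from dataclasses import dataclass

from .activities import CATEGORIES, Activity
from .subject import SubjectTrace

__all__ = ["KTAScore", "score_trace", "MAX_TOTAL"]

#: Maximum attainable total: six components at "not capable" (3) each.
MAX_TOTAL = 3 * len(CATEGORIES)


@dataclass(frozen=True)
class KTAScore:
    """Six component scores (each 0-3) and their 0-18 total."""

    components: dict
    total: int

    def __post_init__(self):
        if set(self.components) != set(CATEGORIES):
            raise ValueError("components must cover exactly the six categories")
        for cat, v in self.components.items():
            if v not in (0, 1, 2, 3):
                raise ValueError(f"component {cat!r} score {v} outside 0-3")
        if self.total != sum(self.components.values()):
            raise ValueError("total does not equal the component sum")


def score_trace(trace: SubjectTrace, activity: Activity) -> KTAScore:
    """Score one subject's trace against the activity's category tags.

    Component score for category c = maximum help level over all events on
    steps tagged c (0 when no help was needed).
    """
    step_cat = {s.id: s.category for s in activity.steps}
    components = {cat: 0 for cat in CATEGORIES}
    for ev in trace.events:
        try:
            cat = step_cat[ev.step_id]
        except KeyError:
            raise ValueError(
                f"trace references step {ev.step_id!r} absent from activity {activity.name!r}"
            ) from None
        if ev.help_level > components[cat]:
            components[cat] = ev.help_level
    return KTAScore(components=components, total=sum(components.values()))
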