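"""Declarative definitions of the three daily activities.

An :class:`Activity` is an ordered list of typed steps grouped into stages,
plus the item vocabulary (chunks), the similarity table that drives
commission errors, and the goal-to-item association links that drive
spreading activation.  Steps are either *retrieval* steps (fetch an item
from declarative memory — e.g. "find the teabag") or *behaviour* steps
(execute an action — e.g. "let the tea rest for 3-4 min"), and each step is
tagged with exactly one of the six functional-test categories: initiation,
organization, performs-all-steps, sequencing, judgment & safety, completion.

The shipped definitions (tea preparation, washing hands, dressing) live in
YAML files under ``adlsim/data/activities`` so they can be edited without
code changes; :func:`build_activity` loads them and
:func:`validate_activity` checks the structural invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from .memory import Chunk, DeclarativeMemory, SimilarityTable

__all__ = [
    "CATEGORIES",
    "ACTIVITY_NAMES",
    "ActivityStep",
    "Activity",
    "build_activity",
    "validate_activity",
    "activity_from_dict",
    "activity_to_dict",
]

#: The six functional-test (KTA) score components, in reporting order.
CATEGORIES = (
    "initiation",
    "organization",
    "performs_all_steps",
    "sequencing",
    "judgment_safety",
    "completion",
)

ACTIVITY_NAMES = ("tea", "handwash", "dressing")

STEP_KINDS = ("retrieval", "behaviour")


@dataclass(frozen=True)
class ActivityStep:
    """One goal step of an activity.

    Retrieval steps name a ``target_item`` and the context sources that
    spread activation to it; behaviour steps do not.  ``conflict_group``
    lists step ids this step can be confused or reordered with;
    ``safety_critical`` marks steps whose failure endangers the subject
    (e.g. not turning off the kettle or the tap).
    """

    id: str
    kind: str
    category: str
    stage: int
    target_item: Optional[str] = None
    context: tuple[str, ...] = ()
    conflict_group: frozenset = frozenset()
    safety_critical: bool = False


@dataclass
class Activity:
    name: str
    steps: list[ActivityStep] = field(default_factory=list)
    items: list[str] = field(default_factory=list)
    similarities: SimilarityTable = field(default_factory=SimilarityTable)
    associations: list[tuple[str, str]] = field(default_factory=list)

    def build_memory(self, similarity_scale: float = 1.0) -> DeclarativeMemory:
        """A fresh declarative-memory store for one simulated subject.

        ``similarity_scale`` multiplies every similarity magnitude (more
        severe impairment profiles confuse items more readily).
        """
        chunks = [Chunk(id=i) for i in self.items]
        sims = self.similarities.scaled(similarity_scale)
        return DeclarativeMemory(chunks, sims, self.associations)

    def step_map(self) -> dict[str, ActivityStep]:
        return {s.id: s for s in self.steps}

    @property
    def retrieval_steps(self) -> list[ActivityStep]:
        return [s for s in self.steps if s.kind == "retrieval"]

    def ordered_steps(self) -> list[ActivityStep]:
        """Steps in execution order: by stage, then definition order."""
        return sorted(self.steps, key=lambda s: s.stage)


def _load_activity_text(name: str) -> str:
    ref = resources.files("adlsim").joinpath(f"data/activities/{name}.yaml")
    return ref.read_text(encoding="utf-8")


def build_activity(name: str) -> Activity:
    """Load one of the canonical shipped activity definitions."""
    if name not in ACTIVITY_NAMES:
        raise ValueError(
            f"unknown activity {name!r}; supported activities: {', '.join(ACTIVITY_NAMES)}"
        )
    activity = activity_from_dict(yaml.safe_load(_load_activity_text(name)))
    diagnostics = validate_activity(activity)
    if diagnostics:  # pragma: no cover - shipped data is validated by tests
        raise ValueError(f"shipped activity {name!r} is invalid: {diagnostics}")
    return activity


def activity_from_dict(d: dict) -> Activity:
    steps = []
    for s in d.get("steps", []):
        steps.append(
            ActivityStep(
                id=s["id"],
                kind=s["kind"],
                category=s["category"],
                stage=int(s["stage"]),
                target_item=s.get("target"),
                context=tuple(s.get("context", ())),
                conflict_group=frozenset(s.get("conflict_group", ())),
                safety_critical=bool(s.get("safety_critical", False)),
            )
        )
    sims = SimilarityTable((a, b, float(m)) for a, b, m in d.get("similarities", []))
    return Activity(
        name=d["name"],
        steps=steps,
        items=list(d.get("items", [])),
        similarities=sims,
        associations=[tuple(p) for p in d.get("associations", [])],
    )


def activity_to_dict(a: Activity) -> dict:
    """Pure-data form of an activity; round-trips bit-exactly through YAML."""
    steps = []
    for s in a.ordered_steps():
        row: dict = {"id": s.id, "kind": s.kind, "category": s.category, "stage": s.stage}
        if s.target_item is not None:
            row["target"] = s.target_item
        if s.context:
            row["context"] = list(s.context)
        if s.conflict_group:
            row["conflict_group"] = sorted(s.conflict_group)
        if s.safety_critical:
            row["safety_critical"] = True
        steps.append(row)
    return {
        "name": a.name,
        "items": list(a.items),
        "associations": [list(p) for p in a.associations],
        "similarities": [[x, y, m] for x, y, m in a.similarities.entries()],
        "steps": steps,
    }


def validate_activity(a: Activity) -> list[str]:
    """Human-readable structural diagnostics; empty iff the activity is valid."""
    diags: list[str] = []
    items = set(a.items)
    step_ids = [s.id for s in a.steps]
    if len(step_ids) != len(set(step_ids)):
        diags.append("duplicate step ids")
    if len(a.items) != len(items):
        diags.append("duplicate item ids")

    stages = sorted({s.stage for s in a.steps})
    if stages and stages != list(range(stages[-1] + 1)):
        diags.append(f"stages are not contiguous from 0: {stages}")

    present = {s.category for s in a.steps}
    for cat in CATEGORIES:
        if cat not in present:
            diags.append(f"no step tagged with category {cat!r}")

    for s in a.steps:
        if s.kind not in STEP_KINDS:
            diags.append(f"step {s.id!r}: unknown kind {s.kind!r}")
        if s.category not in CATEGORIES:
            diags.append(f"step {s.id!r}: unknown category {s.category!r}")
        if s.kind == "retrieval":
            if s.target_item is None:
                diags.append(f"retrieval step {s.id!r} has no target item")
            elif s.target_item not in items:
                diags.append(f"retrieval step {s.id!r} targets undeclared item {s.target_item!r}")
            for src in s.context:
                if src not in items:
                    diags.append(f"step {s.id!r}: undeclared context source {src!r}")
        elif s.target_item is not None:
            diags.append(f"behaviour step {s.id!r} must not have a target item")
        for other in s.conflict_group:
            if other not in step_ids:
                diags.append(f"step {s.id!r}: conflict-group member {other!r} not in activity")

    for x, y, _ in a.similarities.entries():
        for cid in (x, y):
            if cid not in items:
                diags.append(f"similarity entry ({x}, {y}) references undeclared item {cid!r}")
    for src, dst in a.associations:
        for cid in (src, dst):
            if cid not in items:
                diags.append(f"association ({src}, {dst}) references undeclared item {cid!r}")
    return diags
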