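"""Production system with noisy PG-C utilities and conflict resolution.

Each condition-action rule (*production*) carries a utility

    U_i = P_i * G - C_i + extra + eps

where ``P_i`` is the expected probability of a successful firing, ``G`` the
value of the goal (in time units), ``C_i`` the cost in time, ``extra`` an
additive bonus used by caregiver-help productions, and ``eps`` transitory
zero-mean noise.  When several productions are eligible at once the one with
the highest noisy utility fires; its firing then succeeds with probability
``P_i``.  Misbehaviour (sequencing slips, perseveration, failure to start or
finish) is modelled as the "fail" member of a {succeed, fail} production pair
winning this competition.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isfinite
from typing import Sequence

import numpy as np

from .memory import draw_noise

__all__ = ["Production", "utility", "resolve_conflict"]


@dataclass(frozen=True)
class Production:
    """One production rule with PG-C utility parameters."""

    id: str
    P_success: float = 1.0
    G: float = 0.0
    C: float = 0.0
    noise_scale_util: float = 0.0
    extra_utility: float = 0.0
    noise_dist: str = "logistic"

    def __post_init__(self):
        if not (0.0 <= self.P_success <= 1.0):
            raise ValueError("P_success must be in [0, 1]")
        for name in ("G", "C"):
            v = getattr(self, name)
            if not isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.noise_scale_util < 0 or self.extra_utility < 0:
            raise ValueError("noise_scale_util and extra_utility must be >= 0")

    @property
    def base_utility(self) -> float:
        """Noise-free utility P*G - C + extra."""
        return self.P_success * self.G - self.C + self.extra_utility


def utility(prod: Production, rng: np.random.Generator) -> float:
    """One noisy utility draw for a production (deterministic at scale 0)."""
    return prod.base_utility + draw_noise(rng, prod.noise_scale_util, prod.noise_dist)


def resolve_conflict(
    eligible: Sequence[Production], rng: np.random.Generator
) -> tuple[str, bool]:
    """Pick the firing production among simultaneously eligible ones.

    Draws a noisy utility for each production; the argmax fires (ties go to
    the first in list order).  The firing then succeeds with the chosen
    production's ``P_success`` (an independent draw).  Returns
    ``(chosen_id, succeeded)``.
    """
    if not eligible:
        raise ValueError("resolve_conflict requires at least one eligible production")
    utilities = [utility(p, rng) for p in eligible]
    best = 0
    for i in range(1, len(utilities)):
        if utilities[i] > utilities[best]:
            best = i
    chosen = eligible[best]
    succeeded = bool(rng.random() < chosen.P_success)
    return chosen.id, succeeded
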