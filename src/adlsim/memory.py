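"""ACT-R-style declarative memory: chunks, activation, and threshold retrieval.

Working memory is modelled as a store of *chunks* — the smallest retrievable
units of knowledge (items such as ``teabag`` or ``kettle``).  Whether a chunk
can be recalled is governed by its total activation

    A_i = B_i + sum_j (W/n) * S_ji + sum_k P * M_ki + eps

where ``B_i`` is the chunk's base-level activation, the second term is
spreading activation from the ``n`` context sources currently in focus
(attentional weight ``W/n``, associative strength ``S`` for sources linked to
the chunk), the third term is the partial-matching penalty ``P * M`` applied
to chunks that merely resemble the retrieval cue (similarity ``M`` in
``[-1, 0]``), and ``eps`` is transient zero-mean noise.

A retrieval request succeeds when the cued chunk both wins the activation
competition against similar chunks and clears the retrieval threshold.
Losing to a similar chunk is a *commission* error (e.g. fetching the water
instead of the teabag); nothing clearing the threshold is an *omission*
error (forgetting).  Caregiver help is modelled by :func:`boost`, which
re-strengthens a chunk's base level so a failed retrieval can be retried.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from math import isfinite
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Chunk",
    "SimilarityTable",
    "MemoryParams",
    "DeclarativeMemory",
    "RetrievalStatus",
    "RetrievalOutcome",
    "UnknownChunkError",
    "activation",
    "retrieve",
    "boost",
    "draw_noise",
]


class UnknownChunkError(KeyError):
    """Raised when an operation references a chunk id absent from the store."""


def draw_noise(rng: np.random.Generator, scale: float, dist: str = "logistic") -> float:
    """One fresh draw of zero-mean symmetric noise with the given scale.

    ``dist`` is ``"logistic"`` (the conventional choice for activation and
    utility noise in this model family) or ``"gaussian"``.
    """
    if scale < 0:
        raise ValueError("noise scale must be >= 0")
    if scale == 0:
        return 0.0
    if dist == "logistic":
        return float(rng.logistic(0.0, scale))
    if dist == "gaussian":
        return float(rng.normal(0.0, scale))
    raise ValueError(f"unknown noise distribution {dist!r}")


@dataclass
class Chunk:
    """One declarative-memory element.

    ``base_level`` is the B term of the activation equation; ``boost_count``
    tracks how many help interventions were applied in the current retrieval
    episode (reset at episode start).
    """

    id: str
    attributes: dict = field(default_factory=dict)
    base_level: float = 0.0
    boost_count: int = 0


class SimilarityTable:
    """Symmetric chunk-pair similarities M in [-1, 0].

    0 means identical; more negative means less similar.  Self-similarity is
    always 0.  Pairs without an entry have no defined similarity (they do not
    compete during retrieval).
    """

    def __init__(self, entries: Iterable[tuple[str, str, float]] = ()):
        self._entries: dict[frozenset, float] = {}
        for a, b, m in entries:
            self.set(a, b, m)

    def set(self, a: str, b: str, m: float) -> None:
        if a == b:
            if m != 0.0:
                raise ValueError("self-similarity must be 0")
            return
        if not (-1.0 <= m <= 0.0):
            raise ValueError(f"similarity must be in [-1, 0], got {m}")
        self._entries[frozenset((a, b))] = float(m)

    def get(self, a: str, b: str, default=None):
        if a == b:
            return 0.0
        return self._entries.get(frozenset((a, b)), default)

    def partners(self, chunk_id: str) -> list[str]:
        """Chunk ids with an explicit similarity entry to ``chunk_id``, sorted."""
        out = set()
        for pair in self._entries:
            if chunk_id in pair:
                out.update(pair - {chunk_id})
        return sorted(out)

    def most_similar_partner(self, chunk_id: str) -> Optional[str]:
        """The designated similar item: entry with the largest (least negative) M."""
        best = None
        for p in self.partners(chunk_id):
            m = self.get(chunk_id, p)
            if best is None or m > self.get(chunk_id, best):
                best = p
        return best

    def scaled(self, factor: float) -> "SimilarityTable":
        """A copy with magnitudes multiplied by ``factor``, clipped to [-1, 0]."""
        t = SimilarityTable()
        for pair, m in self._entries.items():
            a, b = sorted(pair)
            t.set(a, b, max(-1.0, min(0.0, m * factor)))
        return t

    def entries(self) -> list[tuple[str, str, float]]:
        return sorted((min(p), max(p), m) for p, m in self._entries.items())

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, SimilarityTable) and self._entries == other._entries


@dataclass
class MemoryParams:
    """Parameters of the activation equation and of threshold retrieval.

    W_total
        Total attentional weight W, shared over the context sources (each
        source contributes W/n); conventionally 1 in healthy cognition.
    S
        Associative strength for an associated source; conventionally 2.
    P
        Partial-matching scale applied to similarity penalties.
    noise_scale_act
        Scale of the transient activation noise (0 disables noise).
    threshold
        Retrieval threshold tau: only activations >= tau can be retrieved.
    max_attempts
        Retrieval attempts allowed per step before the step is declared
        impossible (bounds the help-escalation ladder).
    noise_dist
        ``"logistic"`` or ``"gaussian"``.
    """

    W_total: float = 1.0
    S: float = 2.0
    P: float = 1.0
    noise_scale_act: float = 0.0
    threshold: float = 0.0
    max_attempts: int = 3
    noise_dist: str = "logistic"

    def __post_init__(self):
        for name in ("W_total", "S", "P", "noise_scale_act", "threshold"):
            v = getattr(self, name)
            if not isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.W_total <= 0:
            raise ValueError("W_total must be > 0")
        if self.P < 0 or self.noise_scale_act < 0:
            raise ValueError("P and noise_scale_act must be >= 0")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


class RetrievalStatus(str, Enum):
    SUCCESS = "success"
    OMISSION = "omission"
    COMMISSION = "commission"


@dataclass(frozen=True)
class RetrievalOutcome:
    """Result of one retrieval attempt.

    ``winner`` is the chunk that won the activation competition (None when
    nothing cleared the threshold); ``target`` is the cued chunk.
    """

    status: RetrievalStatus
    winner: Optional[str]
    target: str
    attempt_index: int = 1

    def __post_init__(self):
        if self.status is RetrievalStatus.COMMISSION:
            if self.winner is None or self.winner == self.target:
                raise ValueError("commission requires a non-target winner")
        if self.status is RetrievalStatus.OMISSION and self.winner is not None:
            raise ValueError("omission implies no winner")


class DeclarativeMemory:
    """A chunk store with a similarity table and source-association links.

    ``associations`` is a set of ``(source_id, chunk_id)`` pairs: a context
    source spreads activation ``(W/n) * S`` to every chunk it is associated
    with.  The store remembers each chunk's initial base level so a retrieval
    episode can be reset (base levels are stable in this model — there is no
    decay learning; caregiver boosts are the only within-episode modifier).
    """

    def __init__(
        self,
        chunks: Iterable[Chunk],
        similarities: Optional[SimilarityTable] = None,
        associations: Iterable[tuple[str, str]] = (),
    ):
        self._chunks: dict[str, Chunk] = {}
        for c in chunks:
            if c.id in self._chunks:
                raise ValueError(f"duplicate chunk id {c.id!r}")
            self._chunks[c.id] = c
        self.similarities = similarities if similarities is not None else SimilarityTable()
        self.associations = set(tuple(p) for p in associations)
        self._base0 = {cid: c.base_level for cid, c in self._chunks.items()}

    def chunk(self, chunk_id: str) -> Chunk:
        try:
            return self._chunks[chunk_id]
        except KeyError:
            raise UnknownChunkError(f"unknown chunk {chunk_id!r}") from None

    def __contains__(self, chunk_id: str) -> bool:
        return chunk_id in self._chunks

    def ids(self) -> list[str]:
        return sorted(self._chunks)

    def reset_episode(self) -> None:
        """Start a fresh retrieval episode: restore base levels, zero boosts."""
        for cid, c in self._chunks.items():
            c.base_level = self._base0[cid]
            c.boost_count = 0


def activation(
    chunk_id: str,
    context_sources: Sequence[str],
    memory: DeclarativeMemory,
    params: MemoryParams,
    rng: np.random.Generator,
    cue: Optional[str] = None,
) -> float:
    """Total activation of a chunk: base + spreading + partial match + noise.

    ``cue`` is the retrieval cue; a chunk that differs from the cue and has a
    similarity entry to it receives the penalty ``P * M(chunk, cue)``.  An
    empty context contributes no spreading activation (no division by n = 0).
    """
    chunk = memory.chunk(chunk_id)
    total = chunk.base_level
    n = len(context_sources)
    if n:
        w = params.W_total / n
        for src in context_sources:
            if (src, chunk_id) in memory.associations:
                total += w * params.S
    if cue is not None and cue != chunk_id:
        m = memory.similarities.get(chunk_id, cue)
        if m is not None:
            total += params.P * m
    return total + draw_noise(rng, params.noise_scale_act, params.noise_dist)


def retrieve(
    target_id: str,
    context_sources: Sequence[str],
    memory: DeclarativeMemory,
    params: MemoryParams,
    rng: np.random.Generator,
    attempt_index: int = 1,
) -> RetrievalOutcome:
    """Attempt to retrieve ``target_id`` against its similar competitors.

    Candidates are the target plus every chunk with an explicit similarity
    entry to it (similar chunks carry the partial-matching penalty against
    the cue).  The highest activation wins, with ties broken in favour of the
    target; a winner below the threshold yields an omission, a non-target
    winner a commission.
    """
    memory.chunk(target_id)  # raises UnknownChunkError early
    competitors = memory.similarities.partners(target_id)
    acts = {
        cid: activation(cid, context_sources, memory, params, rng, cue=target_id)
        for cid in (target_id, *competitors)
    }
    winner = target_id
    for cid in competitors:
        if acts[cid] > acts[winner]:
            winner = cid
    if acts[winner] < params.threshold:
        return RetrievalOutcome(RetrievalStatus.OMISSION, None, target_id, attempt_index)
    if winner == target_id:
        return RetrievalOutcome(RetrievalStatus.SUCCESS, target_id, target_id, attempt_index)
    return RetrievalOutcome(RetrievalStatus.COMMISSION, winner, target_id, attempt_index)


def boost(target_id: str, memory: DeclarativeMemory, increment: float = 1.0) -> Chunk:
    """Re-strengthen a chunk (the caregiver-help mechanism).

    Raises the chunk's base level by ``increment`` and counts the
    intervention; subsequent retrievals in the same episode see the raised
    base level.  Returns the updated chunk.
    """
    chunk = memory.chunk(target_id)
    chunk.base_level += increment
    chunk.boost_count += 1
    return chunk
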