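"""Shared fixtures: small memory stores, a one-step activity, zero-noise profiles."""

import numpy as np
import pytest

from adlsim import (
    Activity,
    ActivityStep,
    ADProfile,
    Chunk,
    DeclarativeMemory,
    MemoryParams,
    SimilarityTable,
    build_activity,
    load_default_profiles,
)


@pytest.fixture(scope="session")
def tea():
    return build_activity("tea")


@pytest.fixture(scope="session")
def shipped_profiles():
    return load_default_profiles()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pair_memory():
    """Target 't' (base 1.0) with one similar competitor 'c' (base 1.2, M=-0.5)."""
    chunks = [Chunk("t", base_level=1.0), Chunk("c", base_level=1.2)]
    sims = SimilarityTable([("t", "c", -0.5)])
    return DeclarativeMemory(chunks, sims)


def make_profile(level="cdr1", **kw):
    """A hand-built profile; defaults describe an unimpaired subject."""
    base = dict(
        level=level,
        W_total=1.0,
        noise_scale_act=0.0,
        threshold=0.0,
        boost_increment=1.0,
        utility_gap={"default": 10.0},
        noise_scale_util=0.0,
        help_extra_verbal=25.0,
        help_extra_physical=33.0,
    )
    base.update(kw)
    return ADProfile(**base)


@pytest.fixture
def zero_noise_profile():
    return make_profile()


def one_step_activity(target="cup", context=("goal",)):
    """A single-retrieval-step activity covering all six categories via tags.

    Only the retrieval step is simulated; the other five categories are
    carried by trivially easy behaviour steps so the activity validates.
    """
    steps = [
        ActivityStep(id="begin", kind="behaviour", category="initiation", stage=0),
        ActivityStep(
            id="fetch",
            kind="retrieval",
            category="organization",
            stage=1,
            target_item=target,
            context=tuple(context),
        ),
        ActivityStep(id="do", kind="behaviour", category="performs_all_steps", stage=2),
        ActivityStep(id="order", kind="behaviour", category="sequencing", stage=2),
        ActivityStep(id="safe", kind="behaviour", category="judgment_safety", stage=2),
        ActivityStep(id="finish", kind="behaviour", category="completion", stage=3),
    ]
    return Activity(
        name="tea",
        steps=steps,
        items=[target, *context],
        similarities=SimilarityTable(),
        associations=[(c, target) for c in context],
    )
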