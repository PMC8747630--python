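"""Per-CDR-level parameter presets and their calibration.

Disease severity is encoded on the Clinical Dementia Rating scale — CDR-0.5
(MCI / questionable AD), CDR-1 (mild), CDR-2 (moderate), CDR-3 (severe) — as
an :class:`ADProfile`: a bundle of memory-engine parameters (attentional
weight, activation noise, retrieval threshold, boost increment, matching
scale, similarity scaling), behaviour parameters (per-category utility gap
of the {succeed, fail} production pair, utility noise) and the caregiver
help bonuses.  Progression is structural: the attentional weight W is
reduced and the noise scales raised at each successive stage.

Because the underlying model family publishes no numeric parameter values,
the shipped presets are *calibration outputs*: :func:`calibrate` fits, per
level, the retrieval threshold (to a structural first-attempt success
anchor) and the behaviour utility gap (by coordinate grid search on the
simulated mean KTA total of a cohort) against the reference mean KTA scores
per CDR stage.  The presets checked into ``adlsim/data/profiles.yaml`` were
produced by exactly this procedure and can be regenerated with the
``adlsim calibrate`` command.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import yaml

from .activities import CATEGORIES, Activity, build_activity
from .memory import MemoryParams, RetrievalStatus, activation

__all__ = [
    "LEVELS",
    "LEVEL_LABELS",
    "ADProfile",
    "default_profile",
    "load_default_profiles",
    "apply_overrides",
    "check_profile_ordering",
    "SearchSpec",
    "default_search_spec",
    "CalibrationResult",
    "CalibrationError",
    "calibrate",
    "load_reference_means",
]

#: Canonical level keys, ordered by increasing severity.
LEVELS = ("cdr0.5", "cdr1", "cdr2", "cdr3")

LEVEL_LABELS = {
    "cdr0.5": "CDR-0.5 (MCI / questionable AD)",
    "cdr1": "CDR-1 (mild AD)",
    "cdr2": "CDR-2 (moderate AD)",
    "cdr3": "CDR-3 (severe AD)",
}

_ALIASES = {
    "cdr-0.5": "cdr0.5",
    "cdr-1": "cdr1",
    "cdr-2": "cdr2",
    "cdr-3": "cdr3",
    "mci": "cdr0.5",
    "mild": "cdr1",
    "moderate": "cdr2",
    "severe": "cdr3",
}


def normalize_level(level: str) -> str:
    key = level.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in LEVELS:
        raise ValueError(f"unknown AD level {level!r}; expected one of {LEVELS}")
    return key


@dataclass(kw_only=True)
class ADProfile:
    """The complete parameter bundle for one CDR level."""

    level: str
    # memory engine
    W_total: float
    noise_scale_act: float
    threshold: float
    boost_increment: float = 1.0
    P: float = 1.0
    similarity_scale: float = 1.0
    S: float = 2.0
    max_attempts: int = 3
    # behaviour / production engine
    utility_gap: dict = field(default_factory=dict)  # category -> gap
    noise_scale_util: float = 0.0
    help_extra_verbal: float = 25.0
    help_extra_physical: float = 33.0
    noise_dist: str = "logistic"

    def __post_init__(self):
        self.level = normalize_level(self.level)
        if not (20.0 <= self.help_extra_verbal <= 30.0):
            raise ValueError("help_extra_verbal must lie in [20, 30]")
        if self.help_extra_physical <= self.help_extra_verbal:
            raise ValueError("help_extra_physical must exceed help_extra_verbal")

    def memory_params(self) -> MemoryParams:
        return MemoryParams(
            W_total=self.W_total,
            S=self.S,
            P=self.P,
            noise_scale_act=self.noise_scale_act,
            threshold=self.threshold,
            max_attempts=self.max_attempts,
            noise_dist=self.noise_dist,
        )

    def gap_for(self, category: str) -> float:
        """Noise-free utility advantage of a step's succeed production."""
        if category in self.utility_gap:
            return float(self.utility_gap[category])
        return float(self.utility_gap.get("default", 0.0))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["utility_gap"] = {k: float(v) for k, v in self.utility_gap.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ADProfile":
        return cls(**d)


def _profiles_text() -> str:
    return resources.files("adlsim").joinpath("data/profiles.yaml").read_text("utf-8")


def load_default_profiles() -> dict[str, ADProfile]:
    """All four shipped calibrated presets, keyed by level."""
    raw = yaml.safe_load(_profiles_text())
    profiles = {lvl: ADProfile.from_dict(raw[lvl]) for lvl in LEVELS}
    problems = check_profile_ordering(profiles)
    if problems:  # pragma: no cover - shipped data is validated by tests
        raise ValueError(f"shipped presets violate ordering invariants: {problems}")
    return profiles


def default_profile(level: str) -> ADProfile:
    """The shipped calibrated preset for one CDR level."""
    return load_default_profiles()[normalize_level(level)]


def apply_overrides(profile: ADProfile, overrides: Optional[Mapping]) -> ADProfile:
    """A copy of ``profile`` with field overrides from a config mapping."""
    if not overrides:
        return profile
    unknown = set(overrides) - {f.name for f in dataclasses.fields(ADProfile)}
    if unknown:
        raise ValueError(f"unknown profile override(s): {sorted(unknown)}")
    return dataclasses.replace(profile, **dict(overrides))


def check_profile_ordering(profiles: Mapping[str, ADProfile]) -> list[str]:
    """Severity-ordering diagnostics: W nonincreasing, noise nondecreasing."""
    problems = []
    for a, b in zip(LEVELS, LEVELS[1:]):
        pa, pb = profiles[a], profiles[b]
        if pb.W_total > pa.W_total:
            problems.append(f"W_total increases from {a} to {b}")
        if pb.noise_scale_act < pa.noise_scale_act:
            problems.append(f"noise_scale_act decreases from {a} to {b}")
        if pb.noise_scale_util < pa.noise_scale_util:
            problems.append(f"noise_scale_util decreases from {a} to {b}")
    return problems


def load_reference_means() -> dict[str, float]:
    """Shipped reference mean KTA totals per CDR level (calibration targets).

    These are the published mean KTA totals for dementia cohorts that this
    model family is benchmarked against (see the package documentation).
    """
    text = resources.files("adlsim").joinpath("data/calibration_targets.yaml").read_text("utf-8")
    raw = yaml.safe_load(text)
    return {normalize_level(k): float(v) for k, v in raw.items()}


# --------------------------------------------------------------------------
# Calibration


class CalibrationError(RuntimeError):
    pass


@dataclass
class SearchSpec:
    """Bounds and structural (non-fitted) parameters for calibration.

    ``structural`` fixes, per level, every profile field that is part of the
    disease-progression structure rather than of the fit: the W ladder, the
    noise ladders, the boost increment, the help bonuses and the similarity
    scaling.  ``retrieval_success`` anchors, per level, the first-attempt
    retrieval success probability used to place the threshold; the threshold
    is then read off as a quantile of simulated winning target activations.
    The behaviour utility gap is the only parameter fitted against the mean
    KTA targets, by coordinate grid search within ``gap_bounds``.
    """

    structural: dict
    retrieval_success: dict
    threshold_bounds: tuple = (-6.0, 6.0)
    gap_bounds: tuple = (-80.0, 40.0)
    n_threshold_fit: int = 20000
    coarse_points: int = 25
    refine_rounds: int = 2
    refine_points: int = 11


def default_search_spec() -> SearchSpec:
    """The shipped calibration structure.

    The attentional weight W falls and both noise scales rise with severity;
    the verbal help bonus stays within the effective 20-30 utility band with
    the physical bonus a fixed 8 units above it.  The first-attempt
    retrieval-success ladder (0.95 / 0.6^(1/4) / 0.70 / 0.50) fixes how much
    of each level's impairment is mnemonic rather than behavioural; the
    CDR-1 anchor makes the probability that a four-retrieval organization
    component needs help equal 1 - (0.6^(1/4))^4 = 0.40, i.e. forty of a
    hundred mild-AD subjects need at least a verbal cue to gather their
    items.
    """
    structural = {
        "cdr0.5": dict(W_total=1.00, noise_scale_act=0.45, noise_scale_util=2.0,
                       boost_increment=1.0, help_extra_verbal=29.0,
                       help_extra_physical=37.0, P=8.0, similarity_scale=1.0),
        "cdr1": dict(W_total=0.85, noise_scale_act=0.55, noise_scale_util=3.0,
                     boost_increment=1.0, help_extra_verbal=27.0,
                     help_extra_physical=35.0, P=8.0, similarity_scale=1.0),
        "cdr2": dict(W_total=0.70, noise_scale_act=0.70, noise_scale_util=4.0,
                     boost_increment=1.0, help_extra_verbal=24.0,
                     help_extra_physical=32.0, P=8.0, similarity_scale=1.0),
        "cdr3": dict(W_total=0.55, noise_scale_act=0.85, noise_scale_util=5.0,
                     boost_increment=1.0, help_extra_verbal=21.0,
                     help_extra_physical=29.0, P=8.0, similarity_scale=1.0),
    }
    retrieval_success = {
        "cdr0.5": 0.95,
        "cdr1": 0.6 ** 0.25,
        "cdr2": 0.70,
        "cdr3": 0.50,
    }
    return SearchSpec(structural=structural, retrieval_success=retrieval_success)


@dataclass
class CalibrationResult:
    profiles: dict
    achieved_means: dict
    targets: dict


def _make_profile(level: str, spec: SearchSpec, threshold: float, gap: float) -> ADProfile:
    s = spec.structural[level]
    return ADProfile(
        level=level,
        threshold=threshold,
        utility_gap={"default": gap},
        **s,
    )


def _fit_threshold(
    level: str, spec: SearchSpec, activity: Activity, rng: np.random.Generator
) -> float:
    """Place the retrieval threshold as a quantile of winning activations.

    Simulates first attempts of every retrieval step of the activity (no
    threshold applied) and records, for episodes where the target wins the
    activation competition, the target's activation.  The threshold that
    yields first-attempt success probability p is the (1-p) upper quantile
    of that sample, because success = target wins AND clears the threshold.
    """
    p_target = spec.retrieval_success[level]
    profile = _make_profile(level, spec, 0.0, 0.0)
    params = profile.memory_params()
    memory = activity.build_memory(profile.similarity_scale)
    steps = activity.retrieval_steps
    if not steps:
        raise CalibrationError(f"activity {activity.name!r} has no retrieval steps")
    n = spec.n_threshold_fit
    winning_acts = []
    total = 0
    for i in range(n):
        step = steps[i % len(steps)]
        memory.reset_episode()
        competitors = memory.similarities.partners(step.target_item)
        acts = {
            cid: activation(cid, list(step.context), memory, params, rng, cue=step.target_item)
            for cid in (step.target_item, *competitors)
        }
        total += 1
        if acts[step.target_item] >= max(acts.values()):
            winning_acts.append(acts[step.target_item])
    win_rate = len(winning_acts) / total
    lo, hi = spec.threshold_bounds
    if lo >= hi:
        raise CalibrationError("infeasible threshold bounds")
    if win_rate <= p_target:
        # commissions alone already exceed the allowed failure budget; the
        # best achievable threshold is the lower bound
        return lo
    k = int(round(p_target * total))
    wins = np.sort(np.asarray(winning_acts))[::-1]
    tau = float(wins[k - 1]) if k >= 1 else float(wins[0]) + 1.0
    return float(np.clip(tau, lo, hi))


def _cohort_mean(
    activity: Activity, profile: ADProfile, n: int, seed_seq: np.random.SeedSequence
) -> float:
    from .scoring import score_trace
    from .subject import simulate_subject

    totals = np.empty(n)
    for i, child in enumerate(seed_seq.spawn(n)):
        rng = np.random.default_rng(child)
        trace = simulate_subject(activity, profile, rng)
        totals[i] = score_trace(trace, activity).total
    return float(totals.mean())


def _fit_gap(
    level: str,
    spec: SearchSpec,
    activity: Activity,
    threshold: float,
    target: float,
    n_per_eval: int,
    eval_entropy: int,
) -> float:
    """Coordinate grid search on the behaviour utility gap.

    Minimises |simulated mean KTA - target| over a coarse grid, then refines
    around the best point.  Every candidate is evaluated with the same
    evaluation seed (common random numbers), so the search is deterministic.
    """
    lo, hi = spec.gap_bounds
    if lo >= hi:
        raise CalibrationError("infeasible gap bounds")

    def objective(gap: float) -> float:
        profile = _make_profile(level, spec, threshold, gap)
        mean = _cohort_mean(
            activity, profile, n_per_eval, np.random.SeedSequence([eval_entropy, 1])
        )
        return abs(mean - target)

    grid = np.linspace(lo, hi, spec.coarse_points)
    best = min(grid, key=objective)
    span = (hi - lo) / (spec.coarse_points - 1)
    for _ in range(spec.refine_rounds):
        grid = np.linspace(max(lo, best - span), min(hi, best + span), spec.refine_points)
        best = min(grid, key=objective)
        span = 2 * span / (spec.refine_points - 1)
    return float(best)


def calibrate(
    targets: Mapping[str, float],
    activity: Activity | str = "tea",
    n_per_eval: int = 1000,
    search_spec: Optional[SearchSpec] = None,
    seed: int = 0,
) -> CalibrationResult:
    """Fit one preset per CDR level to the target mean KTA totals.

    ``targets`` must cover all four levels.  Per level the procedure fits
    the retrieval threshold to the search spec's first-attempt success
    anchor, then grid-searches the behaviour utility gap so that a simulated
    ``n_per_eval``-subject cohort's mean KTA total matches the target.
    Deterministic given ``seed``; fitted presets violating the
    severity-ordering invariants are rejected with a diagnostic.
    """
    targets = {normalize_level(k): float(v) for k, v in targets.items()}
    missing = set(LEVELS) - set(targets)
    if missing:
        raise ValueError(f"targets must cover all four levels; missing {sorted(missing)}")
    if isinstance(activity, str):
        activity = build_activity(activity)
    spec = search_spec if search_spec is not None else default_search_spec()

    profiles: dict[str, ADProfile] = {}
    achieved: dict[str, float] = {}
    for idx, level in enumerate(LEVELS):
        rng = np.random.default_rng(np.random.SeedSequence([seed, idx, 7]))
        tau = _fit_threshold(level, spec, activity, rng)
        gap = _fit_gap(
            level, spec, activity, tau, targets[level], n_per_eval,
            eval_entropy=seed * 4 + idx,
        )
        profile = _make_profile(level, spec, tau, gap)
        profiles[level] = profile
        achieved[level] = _cohort_mean(
            activity, profile, n_per_eval, np.random.SeedSequence([seed, idx, 11])
        )

    problems = check_profile_ordering(profiles)
    if problems:
        raise CalibrationError(f"fitted profiles violate ordering invariants: {problems}")
    return CalibrationResult(profiles=profiles, achieved_means=achieved, targets=targets)


def save_profiles(profiles: Mapping[str, ADProfile], path) -> None:
    """Write presets to a YAML file in the shipped config format."""
    data = {lvl: profiles[lvl].to_dict() for lvl in LEVELS if lvl in profiles}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
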