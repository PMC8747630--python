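"""Monte-Carlo cohort simulation, aggregation and reporting.

:func:`run_cohort` simulates ``n`` independent subjects (per-subject random
substreams derived deterministically from one seed), scores each trace, and
aggregates the mean and SD of the KTA totals, the per-category counts of
subjects at each help level (a subject's per-category level is their
component score), and the summed memory-problem tallies.  A one-subject run
is reported as text (:func:`report_single`); a cohort run is exported as a
category-by-help-level count table with a mean/SD annotation and an
error-bar flag that is set when the SD of the KTA total exceeds 2
(:func:`export_chart_data`), optionally rendered as a grouped bar chart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .activities import CATEGORIES, Activity, build_activity
from .profiles import LEVEL_LABELS, ADProfile, apply_overrides, default_profile, normalize_level
from .scoring import KTAScore, score_trace
from .subject import HELP_LEVELS, SubjectTrace, simulate_subject

__all__ = [
    "RunConfig",
    "CohortSummary",
    "ChartData",
    "run_cohort",
    "report_single",
    "export_chart_data",
    "render_chart",
    "write_outputs",
]

#: Error bars are displayed when the SD of the KTA total exceeds this value.
ERROR_BAR_SD = 2.0


@dataclass
class RunConfig:
    """Inputs of one cohort run: activity, AD level, cohort size, seed."""

    activity: str
    level: str
    n: int
    seed: int = 0
    overrides: Optional[dict] = None
    out_dir: Optional[str] = None
    plot: bool = False
    collapse_to_five: bool = False

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        self.level = normalize_level(self.level)


@dataclass
class CohortSummary:
    activity: str
    level: str
    n: int
    mean_total: float
    sd_total: float
    category_counts: dict  # category -> [independent, verbal, physical, incapable]
    error_tallies: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "activity": self.activity,
            "level": self.level,
            "level_label": LEVEL_LABELS[self.level],
            "n": self.n,
            "mean_total": self.mean_total,
            "sd_total": self.sd_total,
            "category_counts": {
                cat: dict(zip(HELP_LEVELS, counts))
                for cat, counts in self.category_counts.items()
            },
            "error_tallies": dict(self.error_tallies),
        }


def run_cohort(
    config: RunConfig,
    activity: Optional[Activity] = None,
    profile: Optional[ADProfile] = None,
) -> tuple[CohortSummary, list[tuple[SubjectTrace, KTAScore]]]:
    """Simulate a cohort and aggregate it; fully reproducible per seed.

    ``activity`` and ``profile`` default to the shipped definitions named in
    the config (the profile with config overrides applied).
    """
    if activity is None:
        activity = build_activity(config.activity)
    if profile is None:
        profile = apply_overrides(default_profile(config.level), config.overrides)

    results: list[tuple[SubjectTrace, KTAScore]] = []
    children = np.random.SeedSequence(config.seed).spawn(config.n)
    for child in children:
        rng = np.random.default_rng(child)
        trace = simulate_subject(activity, profile, rng)
        results.append((trace, score_trace(trace, activity)))

    totals = np.array([score.total for _, score in results], dtype=float)
    counts = {cat: [0, 0, 0, 0] for cat in CATEGORIES}
    for _, score in results:
        for cat in CATEGORIES:
            counts[cat][score.components[cat]] += 1
    tallies = {
        "forgot": sum(t.forgot_count for t, _ in results),
        "similar_confusions": sum(t.similar_confusion_count for t, _ in results),
        "other_confusions": sum(t.other_confusion_count for t, _ in results),
    }
    summary = CohortSummary(
        activity=activity.name,
        level=profile.level,
        n=config.n,
        mean_total=float(totals.mean()),
        sd_total=float(totals.std(ddof=1)) if config.n > 1 else 0.0,
        category_counts=counts,
        error_tallies=tallies,
    )
    if config.out_dir:
        write_outputs(config, summary, results)
    return summary, results


def report_single(trace: SubjectTrace, score: KTAScore) -> str:
    """Human-readable single-subject report: KTA scores + memory problems."""
    lines = [
        f"Subject report — activity: {trace.activity}, level: {LEVEL_LABELS[trace.level]}",
        "KTA component scores (0=independent, 1=verbal, 2=physical, 3=not capable):",
    ]
    for cat in CATEGORIES:
        v = score.components[cat]
        lines.append(f"  {cat.replace('_', ' ')}: {v} ({HELP_LEVELS[v]})")
    lines.append(f"Total KTA score: {score.total} / 18")
    lines.append("Memory problems encountered:")
    lines.append(f"  forgot something: {trace.forgot_count}")
    lines.append(f"  confused similar items: {trace.similar_confusion_count}")
    lines.append(f"  confused an item with a different one: {trace.other_confusion_count}")
    return "\n".join(lines)


@dataclass
class ChartData:
    """Grouped-bar table: per category, subject counts at each help level."""

    rows: list  # (category, [independent, verbal, physical, incapable])
    n: int
    mean_total: float
    sd_total: float
    error_bar: bool


def export_chart_data(summary: CohortSummary, collapse_to_five: bool = False) -> ChartData:
    """Chart table from a cohort summary (n > 1).

    ``collapse_to_five`` hides the performs-all-steps component so the chart
    shows the five reported problem categories; the component is hidden, not
    merged, and still contributes to the scores.
    """
    if summary.n <= 1:
        raise ValueError("chart export needs a cohort (n > 1); use report_single instead")
    cats = [c for c in CATEGORIES if not (collapse_to_five and c == "performs_all_steps")]
    rows = [(cat, list(summary.category_counts[cat])) for cat in cats]
    return ChartData(
        rows=rows,
        n=summary.n,
        mean_total=summary.mean_total,
        sd_total=summary.sd_total,
        error_bar=summary.sd_total > ERROR_BAR_SD,
    )


def render_chart(chart: ChartData, path, title: str = "") -> None:
    """Render the grouped bar chart (blue independent, orange verbal, green
    physical, red incapable) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = ["tab:blue", "tab:orange", "tab:green", "tab:red"]
    cats = [r[0].replace("_", "\n") for r in chart.rows]
    x = np.arange(len(cats))
    width = 0.2
    fig, ax = plt.subplots(figsize=(9, 4.5))
    for k, label in enumerate(HELP_LEVELS):
        vals = [r[1][k] for r in chart.rows]
        err = 2 if chart.error_bar else None
        ax.bar(x + (k - 1.5) * width, vals, width, label=label, color=colors[k],
               yerr=err, capsize=2 if err else 0)
    ax.set_xticks(x, cats)
    ax.set_ylabel(f"subjects (of {chart.n})")
    note = f"mean KTA = {chart.mean_total:.2f}, SD = {chart.sd_total:.2f}"
    ax.set_title(f"{title}\n{note}" if title else note)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def subjects_frame(results) -> pd.DataFrame:
    """Per-subject table: component scores, total, memory-problem counters."""
    rows = []
    for i, (trace, score) in enumerate(results):
        row = {"subject": i}
        row.update({cat: score.components[cat] for cat in CATEGORIES})
        row["total"] = score.total
        row["forgot"] = trace.forgot_count
        row["similar_confusions"] = trace.similar_confusion_count
        row["other_confusions"] = trace.other_confusion_count
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(config: RunConfig, summary: CohortSummary, results) -> None:
    """Write subjects.csv, summary.json and (optionally) the chart image."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects_frame(results).to_csv(out / "subjects.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary.to_dict(), indent=2), "utf-8")
    if config.plot and summary.n > 1:
        chart = export_chart_data(summary, config.collapse_to_five)
        title = f"{summary.activity} — {LEVEL_LABELS[summary.level]}"
        render_chart(chart, out / "cohort.png", title=title)
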