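"""Cohort-level descriptive outputs.

Completion patterns, during-treatment outcome rates, follow-up score
summaries and paired effect sizes, trajectory category counts, and the
combined data-collection estimate.  Every percentage is carried as a
numerator/denominator pair plus a rounded value so downstream consumers never
re-round; the project-wide rounding rule is *nearest integer, half away from
zero*, applied to the exact rational value.

Inferential significance tests are deliberately absent: this module reports
descriptives and effect sizes only.  Cohen's d for the paired design is
``mean(diff) / SD(diff)`` with the sample (n−1) standard deviation; a zero SD
leaves d undefined rather than infinite.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np

from .episodes import ChangeClass
from .measures import MeasureRegistry, ThresholdPolicy
from .trajectories import (
    PatientSeries,
    RelapseStatus,
    TrajectoryFinding,
    analyze_cohort,
    treatment_outcome,
)

__all__ = [
    "round_half_away",
    "round_ratio_percent",
    "Rate",
    "rate",
    "PairedEffect",
    "CohortSummary",
    "completion_histogram",
    "outcome_rates",
    "followup_effect_sizes",
    "combined_collection_estimate",
    "build_cohort_summary",
]


def round_half_away(x: Union[float, Fraction]) -> int:
    """Round to the nearest integer, ties away from zero."""
    f = Fraction(x).limit_denominator(10**12) if isinstance(x, float) else Fraction(x)
    half = Fraction(1, 2)
    if f >= 0:
        return int((f + half).__floor__())
    return -int((-f + half).__floor__())


def round_ratio_percent(numerator: int, denominator: int) -> int:
    """Exact percentage of a count ratio, rounded half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    return round_half_away(Fraction(100 * numerator, denominator))


@dataclass(frozen=True)
class Rate:
    """A count ratio with its rounded percentage (None when undefined)."""

    numerator: int
    denominator: int
    percent: Optional[int]

    def as_dict(self) -> dict:
        return {"numerator": self.numerator, "denominator": self.denominator, "percent": self.percent}


def rate(numerator: int, denominator: int) -> Rate:
    pct = None if denominator == 0 else round_ratio_percent(numerator, denominator)
    return Rate(int(numerator), int(denominator), pct)


@dataclass(frozen=True)
class PairedEffect:
    """Paired mean difference and Cohen's d for one measure vs one anchor."""

    n: int
    mean_diff: Optional[float]
    sd_diff: Optional[float]
    cohen_d: Optional[float]

    def as_dict(self) -> dict:
        return {"n": self.n, "mean_diff": self.mean_diff, "sd_diff": self.sd_diff, "cohen_d": self.cohen_d}


def completion_histogram(cohort: Iterable[PatientSeries]) -> Dict[int, int]:
    """Count patients by number of follow-up months with any submitted data."""
    hist: Counter = Counter()
    for series in cohort:
        k = len(series.followup_months())
        if k:
            hist[k] += 1
    return dict(sorted(hist.items()))


def outcome_rates(
    cohort: Sequence[PatientSeries],
    registry: MeasureRegistry,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> Dict[str, Rate]:
    """During-treatment improvement, deterioration and recovery rates.

    Improvement/deterioration denominators are all classified patients; the
    recovery denominator is restricted to patients above caseness on either
    primary measure at pre-treatment.
    """
    n_classified = 0
    n_improved = n_deteriorated = 0
    n_above_pre = n_recovered = 0
    for series in cohort:
        outcome = treatment_outcome(series, registry, policy)
        n_classified += 1
        n_improved += outcome.change is ChangeClass.RELIABLE_IMPROVEMENT
        n_deteriorated += outcome.change is ChangeClass.RELIABLE_DETERIORATION
        if outcome.started_above_caseness_either:
            n_above_pre += 1
            n_recovered += outcome.recovery
    return {
        "reliable_improvement": rate(n_improved, n_classified),
        "reliable_deterioration": rate(n_deteriorated, n_classified),
        "reliable_recovery": rate(n_recovered, n_above_pre),
    }


def _paired_effect(diffs: List[float]) -> PairedEffect:
    n = len(diffs)
    if n == 0:
        return PairedEffect(0, None, None, None)
    arr = np.asarray(diffs, dtype=float)
    mean = float(arr.mean())
    if n < 2:
        return PairedEffect(n, mean, None, None)
    sd = float(arr.std(ddof=1))
    d = mean / sd if sd > 0 else None
    return PairedEffect(n, mean, sd, d)


def followup_effect_sizes(
    cohort: Sequence[PatientSeries],
    measures: Sequence[str] = ("PHQ-9", "GAD-7"),
    anchors: Sequence[str] = ("pre", "post"),
) -> Dict[str, Dict[str, PairedEffect]]:
    """Paired effects of each user's follow-up average against pre and post.

    Per user: the follow-up average is the mean of that user's available
    monthly totals on the measure; the paired difference is
    ``follow-up average − anchor score``.  Users lacking the anchor score or
    any follow-up score on the measure are excluded for that comparison.
    """
    out: Dict[str, Dict[str, PairedEffect]] = {}
    for measure in measures:
        per_anchor: Dict[str, PairedEffect] = {}
        for anchor in anchors:
            diffs: List[float] = []
            for series in cohort:
                anchor_score = series.score(anchor, measure)
                fu = [
                    series.score(m, measure)
                    for m in series.followup_months()
                    if series.score(m, measure) is not None
                ]
                if anchor_score is None or not fu:
                    continue
                diffs.append(float(np.mean(fu)) - anchor_score)
            per_anchor["vs_start" if anchor == "pre" else "vs_end"] = _paired_effect(diffs)
        out[measure] = per_anchor
    return out


def followup_score_means(
    cohort: Sequence[PatientSeries],
    measures: Sequence[str] = ("PHQ-9", "GAD-7"),
) -> Dict[str, dict]:
    """Mean and SD over users of each user's follow-up average score."""
    out: Dict[str, dict] = {}
    for measure in measures:
        averages = []
        for series in cohort:
            fu = [
                series.score(m, measure)
                for m in series.followup_months()
                if series.score(m, measure) is not None
            ]
            if fu:
                averages.append(float(np.mean(fu)))
        if averages:
            arr = np.asarray(averages)
            out[measure] = {
                "n": len(averages),
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if len(averages) > 1 else None,
            }
        else:
            out[measure] = {"n": 0, "mean": None, "sd": None}
    return out


def combined_collection_estimate(
    uptake_num: int, uptake_den: int, submit_num: int, submit_den: int
) -> int:
    """Overall data-collection percentage: uptake rate × submission rate.

    The product of the app-uptake proportion and the follow-up submission
    proportion, as a rounded percentage.
    """
    if uptake_den <= 0 or submit_den <= 0:
        raise ZeroDivisionError("denominators must be positive")
    product = Fraction(uptake_num, uptake_den) * Fraction(submit_num, submit_den) * 100
    return round_half_away(product)


@dataclass
class CohortSummary:
    """Everything the cohort report prints, with full provenance."""

    n_users: int
    n_submitting: int
    completion_histogram: Dict[int, int]
    treatment_rates: Dict[str, Rate]
    followup_means: Dict[str, dict]
    paired_effects: Dict[str, Dict[str, PairedEffect]]
    vs_start_counts: Dict[str, Dict[str, int]]
    vs_end_counts: Dict[str, int]
    relapse: Dict[str, Rate]
    followup_recovery: Rate
    policy: ThresholdPolicy
    thresholds: Dict[str, dict] = field(default_factory=dict)
    horizon: int = 6

    def to_dict(self) -> dict:
        return {
            "provenance": {
                "policy": self.policy.as_dict(),
                "thresholds": self.thresholds,
                "horizon": self.horizon,
            },
            "n_users": self.n_users,
            "n_submitting": self.n_submitting,
            "completion_histogram": {str(k): v for k, v in self.completion_histogram.items()},
            "treatment_rates": {k: v.as_dict() for k, v in self.treatment_rates.items()},
            "followup_means": self.followup_means,
            "paired_effects": {
                m: {a: e.as_dict() for a, e in per.items()} for m, per in self.paired_effects.items()
            },
            "vs_start_counts": self.vs_start_counts,
            "vs_end_counts": self.vs_end_counts,
            "relapse": {k: v.as_dict() for k, v in self.relapse.items()},
            "followup_recovery": self.followup_recovery.as_dict(),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        lines = [
            "Cohort outcome report",
            f"  policy: caseness_inclusive={self.policy.caseness_inclusive} "
            f"rci_inclusive={self.policy.rci_inclusive}  horizon={self.horizon}",
            f"  users: {self.n_users}  submitting follow-up data: {self.n_submitting}",
            "  completion (months -> users): "
            + ", ".join(f"{k}:{v}" for k, v in self.completion_histogram.items()),
            "  during-treatment rates:",
        ]
        for name, r in self.treatment_rates.items():
            pct = "undefined" if r.percent is None else f"{r.percent}%"
            lines.append(f"    {name}: {pct} ({r.numerator}/{r.denominator})")
        for measure, per in self.paired_effects.items():
            for anchor, e in per.items():
                if e.mean_diff is None:
                    continue
                d = "undefined" if e.cohen_d is None else f"{e.cohen_d:.2f}"
                lines.append(
                    f"  {measure} follow-up average {anchor}: mean diff "
                    f"{e.mean_diff:+.2f} (d={d}, n={e.n})"
                )
        lines.append("  vs-end categories: " + ", ".join(f"{k}:{v}" for k, v in self.vs_end_counts.items()))
        for name, r in self.relapse.items():
            pct = "undefined" if r.percent is None else f"{r.percent}%"
            lines.append(f"  {name}: {pct} ({r.numerator}/{r.denominator})")
        fr = self.followup_recovery
        pct = "undefined" if fr.percent is None else f"{fr.percent}%"
        lines.append(f"  follow-up recovery (improved-not-recovered): {pct} ({fr.numerator}/{fr.denominator})")
        return "\n".join(lines)


def build_cohort_summary(
    cohort: Sequence[PatientSeries],
    registry: MeasureRegistry,
    policy: ThresholdPolicy = ThresholdPolicy(),
    horizon: int = 6,
    findings: Optional[Sequence[TrajectoryFinding]] = None,
) -> CohortSummary:
    """Assemble the full descriptive report for a classified cohort."""
    cohort = list(cohort)
    if findings is None:
        findings = analyze_cohort(cohort, registry, policy)
    hist = completion_histogram(cohort)
    vs_start: Dict[str, Counter] = {}
    vs_end: Counter = Counter()
    n_recovered = n_any_relapse = n_not_sustained = 0
    n_improved_not_recovered = n_followup_recovered = 0
    for f in findings:
        vs_start.setdefault(f.vs_start_group, Counter())[f.vs_start_category.value] += 1
        vs_end[f.vs_end_category.value] += 1
        if f.treatment_recovery:
            n_recovered += 1
            if f.relapse_status in (RelapseStatus.RELAPSE_SUSTAINED, RelapseStatus.RELAPSE_NOT_SUSTAINED):
                n_any_relapse += 1
                n_not_sustained += f.relapse_status is RelapseStatus.RELAPSE_NOT_SUSTAINED
        if f.treatment_change is ChangeClass.RELIABLE_IMPROVEMENT and not f.treatment_recovery:
            n_improved_not_recovered += 1
            n_followup_recovered += f.followup_recovery_month is not None
    return CohortSummary(
        n_users=len(cohort),
        n_submitting=sum(v for v in hist.values()),
        completion_histogram=hist,
        treatment_rates=outcome_rates(cohort, registry, policy),
        followup_means=followup_score_means(cohort),
        paired_effects=followup_effect_sizes(cohort),
        vs_start_counts={g: dict(c) for g, c in sorted(vs_start.items())},
        vs_end_counts=dict(vs_end),
        relapse={
            "any_relapse_among_recovered": rate(n_any_relapse, n_recovered),
            "relapse_not_sustained": rate(n_not_sustained, max(n_any_relapse, 0)),
        },
        followup_recovery=rate(n_followup_recovered, n_improved_not_recovered),
        policy=policy,
        thresholds=registry.thresholds_table(),
        horizon=horizon,
    )
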