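"""Follow-up trajectory analysis over a patient's monthly post-discharge series.

Patients discharged from treatment are invited to resubmit their outcome
questionnaires monthly for a follow-up horizon of H months (default 6).  Each
available month is classified as an episode against one of two anchors:

* *vs start* — each month compared with the pre-treatment score, stratified by
  the patient's during-treatment outcome (reliably improved / not improved /
  reliably recovered), each stratum with its own category tree;
* *vs end* — each month compared with the end-of-treatment score, yielding a
  seven-way partition (always improved, improved-or-stable, always stable,
  stable-or-deteriorated, always deteriorated, fluctuating, insufficient
  data);

plus, for patients who reliably recovered during treatment, *reliable
relapse* detection against the end-of-treatment anchor and a sustainment
judgement, and, for patients who improved without recovering, detection of
first reliable recovery during follow-up.

A month is classified only when the primary measure pair is complete at both
the anchor and that month; incomplete months are omitted and logged.  The
ADSM-for-GAD-7 substitution is decided per comparison, so a patient may be
classified on (PHQ-9, ADSM) in one month and (PHQ-9, GAD-7) in another.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple, Union

import pandas as pd

from .episodes import ChangeClass, EpisodeOutcome, classify_episode
from .errors import ConfigError, StructuralError
from .measures import MeasureRegistry, ScorePair, ThresholdPolicy, select_primary_pair

logger = logging.getLogger(__name__)

__all__ = [
    "Timepoint",
    "PatientSeries",
    "VsStartCategory",
    "VsEndCategory",
    "RelapseStatus",
    "TrajectoryFinding",
    "treatment_outcome",
    "timepoint_outcomes",
    "classify_vs_start",
    "classify_vs_end",
    "detect_relapse",
    "detect_followup_recovery",
    "analyze_patient",
    "analyze_cohort",
    "findings_frame",
]

Timepoint = Union[str, int]  # "pre", "post", or follow-up month 1..H


@dataclass
class PatientSeries:
    """One patient's scores at pre-treatment, end-of-treatment and follow-up.

    ``scores`` maps a timepoint ("pre", "post", or an int month 1..horizon)
    to a ``{measure_name: total_score}`` mapping.  Measures beyond the
    primary pair (WSAS, the GAD-7 of an ADSM user) are carried but only the
    primary pair enters classification.
    """

    patient_id: str
    scores: Dict[Timepoint, Dict[str, int]] = field(default_factory=dict)
    adsm_name: Optional[str] = None
    horizon: int = 6

    def __post_init__(self) -> None:
        for t in self.scores:
            if isinstance(t, int):
                if not (1 <= t <= self.horizon):
                    raise ConfigError(
                        f"patient {self.patient_id}: follow-up month {t} outside 1..{self.horizon}"
                    )
            elif t not in ("pre", "post"):
                raise ConfigError(f"patient {self.patient_id}: unknown timepoint {t!r}")

    def score(self, timepoint: Timepoint, measure: str) -> Optional[int]:
        return self.scores.get(timepoint, {}).get(measure)

    def measures_present(self) -> frozenset:
        out = set()
        for row in self.scores.values():
            out.update(row)
        return frozenset(out)

    def followup_months(self) -> List[int]:
        return sorted(t for t in self.scores if isinstance(t, int))

    def pair_at(self, timepoint: Timepoint, dep: str, anx: str) -> Optional[ScorePair]:
        d = self.score(timepoint, dep)
        a = self.score(timepoint, anx)
        if d is None or a is None:
            return None
        return ScorePair(d, a, dep, anx)


class VsStartCategory(str, enum.Enum):
    # improved-during-treatment stratum
    STAYED_RELIABLY_IMPROVED = "stayed_reliably_improved"
    LOST_IMPROVEMENT_AT_LEAST_ONCE = "lost_improvement_at_least_once"
    DETERIORATED_AT_LEAST_ONCE = "deteriorated_at_least_once"
    # recovered-during-treatment stratum (refines the improved tree)
    REMAINED_RELIABLY_RECOVERED = "remained_reliably_recovered"
    REMAINED_RECOVERED_OR_IMPROVED = "remained_recovered_or_improved"
    # not-improved stratum
    SUSTAINED_GAIN = "sustained_gain"
    TRANSIENT_GAIN = "transient_gain"
    NO_RELIABLE_CHANGES = "no_reliable_changes"
    DETERIORATED_AT_ANY_POINT = "deteriorated_at_any_point"
    # either stratum
    INSUFFICIENT_DATA = "insufficient_data"


class VsEndCategory(str, enum.Enum):
    ALWAYS_IMPROVED = "always_improved"
    IMPROVED_OR_STABLE = "improved_or_stable"
    ALWAYS_STABLE = "always_stable"
    STABLE_OR_DETERIORATED = "stable_or_deteriorated"
    ALWAYS_DETERIORATED = "always_deteriorated"
    FLUCTUATING = "fluctuating"
    INSUFFICIENT_DATA = "insufficient_data"


class RelapseStatus(str, enum.Enum):
    NO_RELAPSE = "no_relapse"
    RELAPSE_SUSTAINED = "relapse_sustained"
    RELAPSE_NOT_SUSTAINED = "relapse_not_sustained"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class TrajectoryFinding:
    """All follow-up classifications for one patient."""

    patient_id: str
    treatment_change: ChangeClass
    treatment_recovery: bool
    vs_start_group: str  # "improved" | "not_improved" | "recovered"
    vs_start_category: VsStartCategory
    vs_end_category: VsEndCategory
    relapse_status: RelapseStatus
    relapse_months: Tuple[int, ...]
    followup_recovery_month: Optional[int]


def treatment_outcome(
    series: PatientSeries,
    registry: MeasureRegistry,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> EpisodeOutcome:
    """Classify the during-treatment (pre → post) episode."""
    dep, anx = select_primary_pair(series, registry, anchors=("pre", "post"))
    a = series.pair_at("pre", dep, anx)
    b = series.pair_at("post", dep, anx)
    if a is None or b is None:
        missing = "pre" if a is None else "post"
        raise StructuralError(
            f"patient {series.patient_id}: incomplete primary pair ({dep}, {anx}) at {missing}"
        )
    return classify_episode(a.validate(registry), b.validate(registry), registry, policy)


def timepoint_outcomes(
    series: PatientSeries,
    anchor: Timepoint,
    registry: MeasureRegistry,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> List[Tuple[int, EpisodeOutcome]]:
    """Classify anchor → month for every follow-up month with a complete pair.

    Months lacking either score of the per-comparison primary pair are
    omitted with a log message.  Returned in ascending month order.
    """
    if anchor not in ("pre", "post"):
        raise ConfigError(f"anchor must be 'pre' or 'post', got {anchor!r}")
    if anchor not in series.scores:
        raise StructuralError(f"patient {series.patient_id}: anchor {anchor!r} absent")
    out: List[Tuple[int, EpisodeOutcome]] = []
    for month in series.followup_months():
        dep, anx = select_primary_pair(series, registry, anchors=(anchor, month))
        a = series.pair_at(anchor, dep, anx)
        b = series.pair_at(month, dep, anx)
        if a is None or b is None:
            where = anchor if a is None else f"month {month}"
            logger.info(
                "patient %s: month %d omitted (incomplete pair (%s, %s) at %s)",
                series.patient_id, month, dep, anx, where,
            )
            continue
        out.append((month, classify_episode(a.validate(registry), b.validate(registry), registry, policy)))
    return out


def _vs_start_group(outcome: EpisodeOutcome) -> str:
    return "improved" if outcome.change is ChangeClass.RELIABLE_IMPROVEMENT else "not_improved"


def classify_vs_start(
    series: PatientSeries,
    treatment: EpisodeOutcome,
    registry: MeasureRegistry,
    policy: ThresholdPolicy = ThresholdPolicy(),
    group: Optional[str] = None,
) -> VsStartCategory:
    """Categorise the follow-up series against the pre-treatment anchor.

    The tree depends on the during-treatment stratum.  ``group`` defaults to
    "improved"/"not_improved" from the treatment outcome; pass "recovered"
    for the finer tree applied to reliably recovered patients.  Precedence in
    the improved/recovered trees: deterioration at any month beats losing
    improvement, which beats full maintenance.  The not-improved tree is
    evaluated in first-match order: sustained gain, transient gain, no
    reliable changes, deterioration at any point.
    """
    if group is None:
        group = _vs_start_group(treatment)
    if group == "recovered" and not treatment.recovery:
        raise StructuralError(
            f"patient {series.patient_id}: recovered tree requested but patient did not recover"
        )
    outcomes = timepoint_outcomes(series, "pre", registry, policy)
    if not outcomes:
        return VsStartCategory.INSUFFICIENT_DATA
    changes = [o.change for _, o in outcomes]
    if group in ("improved", "recovered"):
        if ChangeClass.RELIABLE_DETERIORATION in changes:
            return VsStartCategory.DETERIORATED_AT_LEAST_ONCE
        if any(c is not ChangeClass.RELIABLE_IMPROVEMENT for c in changes):
            return VsStartCategory.LOST_IMPROVEMENT_AT_LEAST_ONCE
        if group == "recovered":
            if all(o.recovery for _, o in outcomes):
                return VsStartCategory.REMAINED_RELIABLY_RECOVERED
            return VsStartCategory.REMAINED_RECOVERED_OR_IMPROVED
        return VsStartCategory.STAYED_RELIABLY_IMPROVED
    if group == "not_improved":
        gain_months = [
            i for i, c in enumerate(changes) if c is ChangeClass.RELIABLE_IMPROVEMENT
        ]
        if gain_months:
            sustained = all(
                c is ChangeClass.RELIABLE_IMPROVEMENT for c in changes[gain_months[0]:]
            )
            return VsStartCategory.SUSTAINED_GAIN if sustained else VsStartCategory.TRANSIENT_GAIN
        if all(c is ChangeClass.NO_RELIABLE_CHANGE for c in changes):
            return VsStartCategory.NO_RELIABLE_CHANGES
        return VsStartCategory.DETERIORATED_AT_ANY_POINT
    raise ConfigError(f"unknown vs-start group {group!r}")


_warned_mixed = False


def _stability_bucket(change: ChangeClass) -> str:
    """Map a change class onto the vs-end improvement/stable/deterioration axis.

    Mixed reliable change is folded into "stable" (the seven-way analysis
    defines stability as no reliable change and gives no rule for mixed
    states); the fold is logged once per process.
    """
    global _warned_mixed
    if change is ChangeClass.RELIABLE_IMPROVEMENT:
        return "improvement"
    if change is ChangeClass.RELIABLE_DETERIORATION:
        return "deterioration"
    if change is ChangeClass.MIXED_RELIABLE_CHANGE and not _warned_mixed:
        logger.warning("mixed reliable change folded into 'stable' for the vs-end tree")
        _warned_mixed = True
    return "stable"


def classify_vs_end(
    series: PatientSeries,
    registry: MeasureRegistry,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> VsEndCategory:
    """Seven-way categorisation of follow-up months against the end score."""
    outcomes = timepoint_outcomes(series, "post", registry, policy)
    if not outcomes:
        return VsEndCategory.INSUFFICIENT_DATA
    buckets = {_stability_bucket(o.change) for _, o in outcomes}
    has_imp = "improvement" in buckets
    has_det = "deterioration" in buckets
    has_stab = "stable" in buckets
    if has_imp and has_det:
        return VsEndCategory.FLUCTUATING
    if has_imp:
        return VsEndCategory.IMPROVED_OR_STABLE if has_stab else VsEndCategory.ALWAYS_IMPROVED
    if has_det:
        return VsEndCategory.STABLE_OR_DETERIORATED if has_stab else VsEndCategory.ALWAYS_DETERIORATED
    return VsEndCategory.ALWAYS_STABLE


def detect_relapse(
    series: PatientSeries,
    treatment: EpisodeOutcome,
    registry: MeasureRegistry,
    policy: ThresholdPolicy = ThresholdPolicy(),
    sustained_rule: str = "latest_after_first",
) -> Tuple[RelapseStatus, List[int]]:
    """Detect reliable relapse against the end-of-treatment anchor.

    Only defined for patients who reliably recovered during treatment; others
    get ``NOT_APPLICABLE``.  A relapse is *not sustained* when later data
    contradicts it: under the default rule the latest available month after
    the first relapse month is the arbiter; under ``sustained_rule="any_later"``
    any later non-relapse month suffices.
    """
    if not treatment.recovery:
        return RelapseStatus.NOT_APPLICABLE, []
    outcomes = timepoint_outcomes(series, "post", registry, policy)
    relapse_months = [m for m, o in outcomes if o.relapse]
    if not relapse_months:
        return RelapseStatus.NO_RELAPSE, []
    first = relapse_months[0]
    later = [(m, o) for m, o in outcomes if m > first]
    if not later:
        return RelapseStatus.RELAPSE_SUSTAINED, relapse_months
    if sustained_rule == "latest_after_first":
        last_month, last_outcome = later[-1]
        sustained = last_outcome.relapse
    elif sustained_rule == "any_later":
        sustained = all(o.relapse for _, o in later)
    else:
        raise ConfigError(f"unknown sustained_rule {sustained_rule!r}")
    status = RelapseStatus.RELAPSE_SUSTAINED if sustained else RelapseStatus.RELAPSE_NOT_SUSTAINED
    return status, relapse_months


def detect_followup_recovery(
    series: PatientSeries,
    treatment: EpisodeOutcome,
    registry: MeasureRegistry,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> Optional[int]:
    """First follow-up month showing reliable recovery from the pre anchor.

    Defined only for the improved-but-not-recovered stratum; calling it for
    any other patient is a precondition error.
    """
    if treatment.change is not ChangeClass.RELIABLE_IMPROVEMENT or treatment.recovery:
        raise StructuralError(
            f"patient {series.patient_id}: follow-up recovery is defined only for "
            "patients who reliably improved without recovering during treatment"
        )
    for month, outcome in timepoint_outcomes(series, "pre", registry, policy):
        if outcome.recovery:
            return month
    return None


def analyze_patient(
    series: PatientSeries,
    registry: MeasureRegistry,
    policy: ThresholdPolicy = ThresholdPolicy(),
    sustained_rule: str = "latest_after_first",
) -> TrajectoryFinding:
    """Run every follow-up analysis for one patient."""
    treatment = treatment_outcome(series, registry, policy)
    group = "recovered" if treatment.recovery else _vs_start_group(treatment)
    vs_start = classify_vs_start(series, treatment, registry, policy, group=group)
    vs_end = classify_vs_end(series, registry, policy)
    relapse_status, relapse_months = detect_relapse(
        series, treatment, registry, policy, sustained_rule=sustained_rule
    )
    followup_recovery = None
    if treatment.change is ChangeClass.RELIABLE_IMPROVEMENT and not treatment.recovery:
        followup_recovery = detect_followup_recovery(series, treatment, registry, policy)
    return TrajectoryFinding(
        patient_id=series.patient_id,
        treatment_change=treatment.change,
        treatment_recovery=treatment.recovery,
        vs_start_group=group,
        vs_start_category=vs_start,
        vs_end_category=vs_end,
        relapse_status=relapse_status,
        relapse_months=tuple(relapse_months),
        followup_recovery_month=followup_recovery,
    )


def analyze_cohort(
    cohort: Iterable[PatientSeries],
    registry: MeasureRegistry,
    policy: ThresholdPolicy = ThresholdPolicy(),
    sustained_rule: str = "latest_after_first",
) -> List[TrajectoryFinding]:
    return [analyze_patient(s, registry, policy, sustained_rule) for s in cohort]


def findings_frame(findings: Iterable[TrajectoryFinding]) -> pd.DataFrame:
    """Per-patient findings table (one row per patient)."""
    rows = [
        {
            "patient_id": f.patient_id,
            "treatment_change": f.treatment_change.value,
            "treatment_recovery": f.treatment_recovery,
            "vs_start_group": f.vs_start_group,
            "vs_start_category": f.vs_start_category.value,
            "vs_end_category": f.vs_end_category.value,
            "relapse_status": f.relapse_status.value,
            "relapse_months": ";".join(str(m) for m in f.relapse_months),
            "followup_recovery_month": (
                "" if f.followup_recovery_month is None else f.followup_recovery_month
            ),
        }
        for f in findings
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "treatment_change", "treatment_recovery", "vs_start_group",
            "vs_start_category", "vs_end_category", "relapse_status", "relapse_months",
            "followup_recovery_month",
        ],
    )
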