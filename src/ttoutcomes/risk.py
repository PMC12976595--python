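"""Risk-item monitoring over item-level PHQ-9 submissions.

The ninth PHQ-9 item asks about thoughts of self-harm or suicide.  The
monitoring procedure flags any submission scoring above zero on that item and
attaches a fixed battery of four follow-on probe questions (plans,
preparations, behavioural intent, protective factors) whose free-text
responses are stored verbatim for clinician review — they are never scored
and no contact decision is automated here.

A flagged submission is additionally marked when its risk score strictly
exceeds the patient's most recent prior submission with item data.  By
default the comparison is on the risk item itself; ``increase_on="total"``
switches it to the PHQ-9 total score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .errors import ConfigError
from .report import Rate, rate

__all__ = ["PROBE_BATTERY", "Phq9Submission", "RiskFlag", "TriageReport", "flag_risk", "build_triage_report"]

PROBE_BATTERY: Tuple[str, ...] = ("plans", "preparations", "behavioral_intent", "protective_factors")

RISK_ITEM_INDEX = 8  # item 9, zero-based


@dataclass(frozen=True)
class Phq9Submission:
    """One PHQ-9 submission, optionally with its nine item scores."""

    patient_id: str
    month: int
    total: int
    item_scores: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not (0 <= self.total <= 27):
            raise ConfigError(
                f"patient {self.patient_id} month {self.month}: PHQ-9 total {self.total} outside 0..27"
            )
        if self.item_scores is not None:
            items = tuple(int(v) for v in self.item_scores)
            object.__setattr__(self, "item_scores", items)
            if len(items) != 9:
                raise ConfigError(
                    f"patient {self.patient_id} month {self.month}: expected 9 item scores, got {len(items)}"
                )
            for i, v in enumerate(items, start=1):
                if not (0 <= v <= 3):
                    raise ConfigError(
                        f"patient {self.patient_id} month {self.month}: item {i} score {v} outside 0..3"
                    )
            if sum(items) != self.total:
                raise ConfigError(
                    f"patient {self.patient_id} month {self.month}: item scores sum to "
                    f"{sum(items)}, total is {self.total}"
                )

    @property
    def item9(self) -> Optional[int]:
        return None if self.item_scores is None else self.item_scores[RISK_ITEM_INDEX]


@dataclass(frozen=True)
class RiskFlag:
    patient_id: str
    month: int
    item9_score: int
    flagged: bool
    increased_vs_last: bool
    probe_battery: Tuple[str, ...] = ()
    probe_responses: Optional[Dict[str, str]] = None


def flag_risk(
    submission: Phq9Submission,
    history: Sequence[Phq9Submission] = (),
    increase_on: str = "item9",
    probe_responses: Optional[Dict[str, str]] = None,
) -> RiskFlag:
    """Flag one submission and compare it against the last prior datapoint.

    ``history`` is the patient's prior submissions in chronological order.
    ``increased_vs_last`` is a strict increase over the most recent prior
    submission carrying the compared quantity; it is false for a patient's
    first submission.
    """
    if submission.item_scores is None:
        raise ConfigError(
            f"patient {submission.patient_id} month {submission.month}: "
            "item-level scores required for risk flagging"
        )
    if increase_on not in ("item9", "total"):
        raise ConfigError(f"increase_on must be 'item9' or 'total', got {increase_on!r}")
    item9 = submission.item9
    flagged = item9 > 0
    current = item9 if increase_on == "item9" else submission.total
    previous = None
    for prior in reversed(history):
        if increase_on == "total":
            previous = prior.total
            break
        if prior.item_scores is not None:
            previous = prior.item9
            break
    increased = previous is not None and current > previous
    return RiskFlag(
        patient_id=submission.patient_id,
        month=submission.month,
        item9_score=item9,
        flagged=flagged,
        increased_vs_last=increased,
        probe_battery=PROBE_BATTERY if flagged else (),
        probe_responses=dict(probe_responses) if (flagged and probe_responses) else None,
    )


@dataclass
class TriageReport:
    total_submissions: int
    flagged: Rate
    increased: Rate
    queue: pd.DataFrame = field(repr=False)


def build_triage_report(
    submissions: Iterable[Phq9Submission],
    increase_on: str = "item9",
) -> TriageReport:
    """Cohort-level triage: counts, percentages, and a deterministic queue.

    The queue lists flagged submissions ordered by (patient_id, month).
    Submissions without item data count toward the total but cannot flag.
    """
    by_patient: Dict[str, List[Phq9Submission]] = {}
    ordered = sorted(submissions, key=lambda s: (s.patient_id, s.month))
    flags: List[RiskFlag] = []
    n_total = 0
    for sub in ordered:
        n_total += 1
        history = by_patient.setdefault(sub.patient_id, [])
        if sub.item_scores is not None:
            flags.append(flag_risk(sub, history, increase_on=increase_on))
        history.append(sub)
    n_flagged = sum(f.flagged for f in flags)
    n_increased = sum(f.increased_vs_last for f in flags)
    queue = pd.DataFrame(
        [
            {
                "patient_id": f.patient_id,
                "month": f.month,
                "item9_score": f.item9_score,
                "increased_vs_last": f.increased_vs_last,
                "probes": ";".join(f.probe_battery),
            }
            for f in flags
            if f.flagged
        ],
        columns=["patient_id", "month", "item9_score", "increased_vs_last", "probes"],
    )
    return TriageReport(
        total_submissions=n_total,
        flagged=rate(n_flagged, n_total),
        increased=rate(n_increased, n_total),
        queue=queue,
    )
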