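"""Outcome classification of the change between two timepoints.

An *episode* is a comparison of a patient's paired depression + anxiety
scores at an earlier and a later timepoint.  Four change classes are
possible:

* ``reliable_improvement`` — at least one measure shows a reliable decrease
  and neither shows a reliable increase;
* ``reliable_deterioration`` — the mirror image;
* ``mixed_reliable_change`` — one measure reliably decreases while the other
  reliably increases (a state the improvement/deterioration definitions
  jointly exclude; surfaced explicitly rather than folded into "no change");
* ``no_reliable_change`` — neither measure changes reliably.

On top of the change class sit two caseness-gated flags:

* *reliable recovery*: above caseness on either measure at the earlier
  timepoint, reliable improvement, and below caseness on both at the later
  timepoint;
* *reliable relapse*: the time-reversal dual — below caseness on both at the
  earlier timepoint, reliable deterioration, and above caseness on either at
  the later timepoint.  Requiring reliable deterioration prevents a small
  drift from just below to just above the cutoff being called a relapse.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Tuple

from .errors import PairMismatchError
from .measures import (
    ChangeDirection,
    MeasureRegistry,
    ScorePair,
    ThresholdPolicy,
    is_above_caseness,
    reliable_change,
)

__all__ = ["ChangeClass", "EpisodeOutcome", "classify_change", "classify_episode"]


class ChangeClass(str, enum.Enum):
    RELIABLE_IMPROVEMENT = "reliable_improvement"
    RELIABLE_DETERIORATION = "reliable_deterioration"
    MIXED_RELIABLE_CHANGE = "mixed_reliable_change"
    NO_RELIABLE_CHANGE = "no_reliable_change"


@dataclass(frozen=True)
class EpisodeOutcome:
    """Full classification of one two-timepoint comparison."""

    change: ChangeClass
    recovery: bool
    relapse: bool
    started_above_caseness_either: bool
    ended_below_caseness_both: bool
    pair_used: Tuple[str, str]


def _check_same_pair(a: ScorePair, b: ScorePair) -> None:
    if a.measures != b.measures:
        raise PairMismatchError(
            f"cannot compare pairs on different measures: {a.measures} vs {b.measures}"
        )


def classify_change(
    a: ScorePair,
    b: ScorePair,
    registry: MeasureRegistry,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> ChangeClass:
    """Change class of the episode from pair ``a`` (earlier) to ``b`` (later)."""
    _check_same_pair(a, b)
    dep = reliable_change(registry[a.depression_measure], a.depression_score, b.depression_score, policy)
    anx = reliable_change(registry[a.anxiety_measure], a.anxiety_score, b.anxiety_score, policy)
    directions = (dep, anx)
    any_dec = ChangeDirection.RELIABLE_DECREASE in directions
    any_inc = ChangeDirection.RELIABLE_INCREASE in directions
    if any_dec and any_inc:
        return ChangeClass.MIXED_RELIABLE_CHANGE
    if any_dec:
        return ChangeClass.RELIABLE_IMPROVEMENT
    if any_inc:
        return ChangeClass.RELIABLE_DETERIORATION
    return ChangeClass.NO_RELIABLE_CHANGE


def classify_episode(
    a: ScorePair,
    b: ScorePair,
    registry: MeasureRegistry,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> EpisodeOutcome:
    """Classify change plus the caseness-gated recovery and relapse flags.

    Caseness is always evaluated on the same measure pair used for reliable
    change (i.e. after any ADSM substitution), never on a mixture.
    """
    change = classify_change(a, b, registry, policy)
    dep_m = registry[a.depression_measure]
    anx_m = registry[a.anxiety_measure]
    above_a = (
        is_above_caseness(dep_m, a.depression_score, policy)
        or is_above_caseness(anx_m, a.anxiety_score, policy)
    )
    above_b = (
        is_above_caseness(dep_m, b.depression_score, policy)
        or is_above_caseness(anx_m, b.anxiety_score, policy)
    )
    recovery = above_a and change is ChangeClass.RELIABLE_IMPROVEMENT and not above_b
    relapse = (not above_a) and change is ChangeClass.RELIABLE_DETERIORATION and above_b
    return EpisodeOutcome(
        change=change,
        recovery=recovery,
        relapse=relapse,
        started_above_caseness_either=above_a,
        ended_below_caseness_both=not above_b,
        pair_used=a.measures,
    )
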