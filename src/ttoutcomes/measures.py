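"""Questionnaire measures, caseness thresholds and reliable-change comparisons.

The outcome conventions implemented here are those of the English NHS Talking
Therapies (NHS TT) programme: every questionnaire has a *clinical caseness
cutoff* (the lowest score indicating probable clinical-level symptoms) and a
*reliable change index* (RCI, the smallest change in score regarded as
exceeding measurement error).  Classification always operates on a pair of
measures — a depression score (PHQ-9) alongside a generic anxiety score
(GAD-7) or, where the treated problem warranted one, an anxiety-disorder
specific measure (ADSM) that substitutes for the GAD-7.

Numeric thresholds are registry *configuration*, not hard-coded science: the
shipped defaults follow the published NHS TT manual conventions, and an
alternative registry can be loaded from YAML/JSON.  Whether a score exactly at
the cutoff counts as a case, and whether a change exactly equal to the RCI
counts as reliable, are governed by a :class:`ThresholdPolicy` (both inclusive
by default) that is fixed for a whole analysis run and echoed in every report.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Protocol, Sequence, Tuple, Union

import yaml

from .errors import ConfigError, ScoreRangeError, StructuralError

__all__ = [
    "MeasureDefinition",
    "ThresholdPolicy",
    "ScorePair",
    "ChangeDirection",
    "MeasureRegistry",
    "default_registry",
    "load_registry",
    "is_above_caseness",
    "reliable_change",
    "select_primary_pair",
    "DEPRESSION_MEASURE",
    "GENERIC_ANXIETY_MEASURE",
]

DEPRESSION_MEASURE = "PHQ-9"
GENERIC_ANXIETY_MEASURE = "GAD-7"


@dataclass(frozen=True)
class MeasureDefinition:
    """Score range, caseness cutoff and reliable change index of one measure."""

    name: str
    min_score: int
    max_score: int
    caseness_cutoff: int
    rci: int
    higher_is_worse: bool = True

    def __post_init__(self) -> None:
        if not (self.min_score <= self.caseness_cutoff <= self.max_score):
            raise ConfigError(
                f"measure {self.name!r}: cutoff {self.caseness_cutoff} outside "
                f"range [{self.min_score}, {self.max_score}]"
            )
        if self.rci < 1:
            raise ConfigError(f"measure {self.name!r}: rci must be >= 1, got {self.rci}")

    def check_score(self, score: int) -> int:
        if not (self.min_score <= score <= self.max_score):
            raise ScoreRangeError(self.name, score, self.min_score, self.max_score)
        return int(score)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Comparator conventions at the caseness cutoff and the RCI boundary.

    ``caseness_inclusive``: a score equal to the cutoff counts as a case.
    ``rci_inclusive``: an absolute change equal to the RCI counts as reliable.
    Both default to the inclusive convention of the NHS TT manual.
    """

    caseness_inclusive: bool = True
    rci_inclusive: bool = True

    def as_dict(self) -> dict:
        return {
            "caseness_inclusive": self.caseness_inclusive,
            "rci_inclusive": self.rci_inclusive,
        }


class ChangeDirection(str, enum.Enum):
    RELIABLE_DECREASE = "reliable_decrease"
    RELIABLE_INCREASE = "reliable_increase"
    NONE = "none"


@dataclass(frozen=True)
class ScorePair:
    """A patient's depression + anxiety scores at one timepoint."""

    depression_score: int
    anxiety_score: int
    depression_measure: str = DEPRESSION_MEASURE
    anxiety_measure: str = GENERIC_ANXIETY_MEASURE

    def validate(self, registry: "MeasureRegistry") -> "ScorePair":
        registry[self.depression_measure].check_score(self.depression_score)
        registry[self.anxiety_measure].check_score(self.anxiety_score)
        return self

    @property
    def measures(self) -> Tuple[str, str]:
        return (self.depression_measure, self.anxiety_measure)


# NHS TT manual conventions; registry configuration, overridable from file.
_DEFAULT_MEASURES: Sequence[Tuple[str, int, int, int, int]] = (
    # name, min, max, caseness cutoff, rci
    ("PHQ-9", 0, 27, 10, 6),
    ("GAD-7", 0, 21, 8, 4),
    ("WSAS", 0, 40, 10, 8),
    ("HAI", 0, 54, 18, 4),        # Health Anxiety Inventory (short week)
    ("OCI", 0, 168, 40, 32),      # Obsessive Compulsive Inventory
    ("PCL-5", 0, 80, 32, 10),     # PTSD Checklist for DSM-5
    ("PDSS", 0, 28, 8, 5),        # Panic Disorder Severity Scale
    ("PHQ-15", 0, 30, 10, 6),     # somatic symptoms
    ("SPIN", 0, 68, 19, 10),      # Social Phobia Inventory
)

_DEFAULT_ADSMS = frozenset({"HAI", "OCI", "PCL-5", "PDSS", "PHQ-15", "SPIN"})


class MeasureRegistry(Mapping[str, MeasureDefinition]):
    """Named collection of measures plus the set designated as ADSMs."""

    def __init__(
        self,
        measures: Iterable[MeasureDefinition],
        adsm_names: Iterable[str] = (),
        depression_name: str = DEPRESSION_MEASURE,
        generic_anxiety_name: str = GENERIC_ANXIETY_MEASURE,
    ):
        self._measures: dict = {}
        for m in measures:
            if m.name in self._measures:
                raise ConfigError(f"duplicate measure name {m.name!r} in registry")
            self._measures[m.name] = m
        self.adsm_names = frozenset(adsm_names)
        unknown = self.adsm_names - self._measures.keys()
        if unknown:
            raise ConfigError(f"ADSM names not in registry: {sorted(unknown)}")
        self.depression_name = depression_name
        self.generic_anxiety_name = generic_anxiety_name
        for required in (depression_name, generic_anxiety_name):
            if required not in self._measures:
                raise ConfigError(f"registry must define measure {required!r}")

    def __getitem__(self, name: str) -> MeasureDefinition:
        try:
            return self._measures[name]
        except KeyError:
            raise ConfigError(f"unknown measure {name!r}") from None

    def __contains__(self, name: object) -> bool:
        return name in self._measures

    def get(self, name: str, default=None):
        return self._measures.get(name, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._measures)

    def __len__(self) -> int:
        return len(self._measures)

    def is_adsm(self, name: str) -> bool:
        return name in self.adsm_names

    def thresholds_table(self) -> dict:
        """Thresholds in force, for provenance headers of reports."""
        return {
            name: {
                "min": m.min_score,
                "max": m.max_score,
                "caseness_cutoff": m.caseness_cutoff,
                "rci": m.rci,
            }
            for name, m in self._measures.items()
        }


def default_registry() -> MeasureRegistry:
    """Registry with the shipped NHS TT manual threshold conventions."""
    return MeasureRegistry(
        (MeasureDefinition(n, lo, hi, cut, rci) for n, lo, hi, cut, rci in _DEFAULT_MEASURES),
        adsm_names=_DEFAULT_ADSMS,
    )


def load_registry(path: Union[str, Path]) -> Tuple[MeasureRegistry, ThresholdPolicy]:
    """Load a registry + policy from a YAML or JSON configuration file.

    Expected layout::

        measures:
          PHQ-9: {min: 0, max: 27, cutoff: 10, rci: 6}
          ...
        adsm: [HAI, SPIN, ...]
        policy: {caseness_inclusive: true, rci_inclusive: true}
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "measures" not in data:
        raise ConfigError(f"registry file {path} must contain a 'measures' mapping")
    measures = []
    for name, entry in data["measures"].items():
        try:
            measures.append(
                MeasureDefinition(
                    name=name,
                    min_score=int(entry["min"]),
                    max_score=int(entry["max"]),
                    caseness_cutoff=int(entry["cutoff"]),
                    rci=int(entry["rci"]),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"measure {name!r}: missing key {exc}") from None
    policy_block = data.get("policy", {})
    policy = ThresholdPolicy(
        caseness_inclusive=bool(policy_block.get("caseness_inclusive", True)),
        rci_inclusive=bool(policy_block.get("rci_inclusive", True)),
    )
    registry = MeasureRegistry(measures, adsm_names=data.get("adsm", ()))
    return registry, policy


def is_above_caseness(
    measure: MeasureDefinition, score: int, policy: ThresholdPolicy = ThresholdPolicy()
) -> bool:
    """True when ``score`` meets the measure's clinical caseness threshold."""
    measure.check_score(score)
    if policy.caseness_inclusive:
        return score >= measure.caseness_cutoff
    return score > measure.caseness_cutoff


def reliable_change(
    measure: MeasureDefinition,
    earlier: int,
    later: int,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> ChangeDirection:
    """Direction of reliable change between two scores on one measure.

    A decrease (improvement, since higher scores are worse) is reliable when
    ``earlier - later`` meets the RCI under the policy comparator; an increase
    symmetrically.  Exactly one direction is returned.
    """
    measure.check_score(earlier)
    measure.check_score(later)
    delta = earlier - later
    threshold_met = abs(delta) >= measure.rci if policy.rci_inclusive else abs(delta) > measure.rci
    if not threshold_met:
        return ChangeDirection.NONE
    return ChangeDirection.RELIABLE_DECREASE if delta > 0 else ChangeDirection.RELIABLE_INCREASE


class SeriesLike(Protocol):
    """Minimal view of a patient series used for pair selection."""

    adsm_name: Optional[str]

    def score(self, timepoint, measure: str) -> Optional[int]:
        ...

    def measures_present(self) -> frozenset:
        ...


def select_primary_pair(
    series: SeriesLike,
    registry: MeasureRegistry,
    anchors: Sequence = ("pre", "post"),
) -> Tuple[str, str]:
    """Choose the (depression, anxiety) measure pair for one comparison.

    The designated ADSM substitutes for the GAD-7 only when the patient has an
    ADSM score at *both* anchor timepoints of the specific comparison;
    otherwise the pair falls back to the GAD-7 for that comparison.
    """
    dep = registry.depression_name
    gad = registry.generic_anxiety_name
    adsm = series.adsm_name
    if adsm is not None and all(series.score(t, adsm) is not None for t in anchors):
        return dep, adsm
    present = series.measures_present()
    if gad not in present and (adsm is None or adsm not in present):
        raise StructuralError(
            f"series has no anxiety measure (neither {gad} nor a designated ADSM)"
        )
    return dep, gad
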