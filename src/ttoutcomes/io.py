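"""Reading and writing the long-format cohort CSV.

One tidy file carries the whole cohort: a row per (patient, phase, month,
measure) with the total score, plus optional item-level PHQ-9 columns
``phq9_i1..phq9_i9`` on follow-up PHQ-9 rows.  ``month`` is 0 for the pre-
and end-of-treatment rows and 1..H for follow-up rows.  Duplicate rows for
the same (patient, phase, month, measure) — e.g. a resubmission within a
month — are resolved to the last occurrence, with a logged warning.

Row-level validation problems (unknown measure, out-of-range score,
phase/month inconsistency) are collected and reported together with their
CSV line numbers rather than failing at the first bad row.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Tuple, Union

import pandas as pd

from .errors import CohortValidationError
from .measures import MeasureRegistry
from .risk import Phq9Submission
from .trajectories import PatientSeries

logger = logging.getLogger(__name__)

__all__ = ["Cohort", "read_cohort", "write_cohort", "REQUIRED_COLUMNS", "ITEM_COLUMNS"]

REQUIRED_COLUMNS = ["patient_id", "phase", "month", "measure", "score"]
ITEM_COLUMNS = [f"phq9_i{i}" for i in range(1, 10)]
PHASES = ("pre", "post", "fu")


class Cohort:
    """A parsed cohort: patient series plus item-level PHQ-9 submissions."""

    def __init__(self, series: List[PatientSeries], phq9_submissions: List[Phq9Submission]):
        self.series = series
        self.phq9_submissions = phq9_submissions

    def __iter__(self):
        return iter(self.series)

    def __len__(self) -> int:
        return len(self.series)

    def by_id(self) -> Dict[str, PatientSeries]:
        return {s.patient_id: s for s in self.series}


def _timepoint(phase: str, month: int):
    return phase if phase in ("pre", "post") else int(month)


def read_cohort(
    source: Union[str, Path, pd.DataFrame],
    registry: MeasureRegistry,
    horizon: int = 6,
) -> Cohort:
    """Parse and validate a cohort CSV (or an equivalent DataFrame)."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, dtype={"patient_id": str, "phase": str, "measure": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError([(1, f"missing required column(s): {', '.join(missing)}")])

    problems: List[Tuple[int, str]] = []
    df = df.reset_index(drop=True)

    # CSV line numbers: header is line 1, first data row line 2
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        if row.phase not in PHASES:
            problems.append((line, f"unknown phase {row.phase!r}"))
        try:
            month = int(row.month)
        except (TypeError, ValueError):
            problems.append((line, f"non-integer month {row.month!r}"))
            continue
        if row.phase in ("pre", "post") and month != 0:
            problems.append((line, f"phase {row.phase!r} requires month 0, got {month}"))
        if row.phase == "fu" and not (1 <= month <= horizon):
            problems.append((line, f"follow-up month {month} outside 1..{horizon}"))
        if row.measure not in registry:
            problems.append((line, f"unknown measure {row.measure!r}"))
        else:
            m = registry[row.measure]
            try:
                score = int(row.score)
            except (TypeError, ValueError):
                problems.append((line, f"non-integer score {row.score!r}"))
            else:
                if not (m.min_score <= score <= m.max_score):
                    problems.append(
                        (line, f"score {score} outside [{m.min_score}, {m.max_score}] for {row.measure}")
                    )
    if problems:
        raise CohortValidationError(problems)

    df["month"] = df["month"].astype(int)
    df["score"] = df["score"].astype(int)

    # within-month deduplication: last occurrence wins
    n_before = len(df)
    df = df.drop_duplicates(subset=["patient_id", "phase", "month", "measure"], keep="last")
    if len(df) < n_before:
        logger.warning("%d duplicate row(s) resolved to the last occurrence", n_before - len(df))

    series_map: Dict[str, PatientSeries] = {}
    submissions: List[Phq9Submission] = []
    have_items = all(c in df.columns for c in ITEM_COLUMNS)
    for row in df.itertuples(index=False):
        s = series_map.setdefault(
            row.patient_id, PatientSeries(patient_id=row.patient_id, horizon=horizon)
        )
        t = _timepoint(row.phase, row.month)
        s.scores.setdefault(t, {})[row.measure] = int(row.score)
        if registry.is_adsm(row.measure):
            s.adsm_name = row.measure
        if row.phase == "fu" and row.measure == registry.depression_name:
            items = None
            if have_items:
                raw = [getattr(row, c) for c in ITEM_COLUMNS]
                if all(pd.notna(v) for v in raw):
                    items = tuple(int(v) for v in raw)
            submissions.append(
                Phq9Submission(
                    patient_id=row.patient_id,
                    month=int(row.month),
                    total=int(row.score),
                    item_scores=items,
                )
            )
    series = [series_map[k] for k in sorted(series_map)]
    return Cohort(series, submissions)


def _phase_order(phase: str) -> int:
    return PHASES.index(phase)


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write a cohort back to canonical long-format CSV.

    Rows are emitted in canonical order (patient, phase pre<post<fu, month,
    measure), so reading a canonical file and writing it back is value-
    identical.
    """
    items_by_key = {
        (s.patient_id, s.month): s.item_scores
        for s in cohort.phq9_submissions
        if s.item_scores is not None
    }
    rows = []
    for series in cohort.series:
        for t in sorted(
            series.scores,
            key=lambda t: (0, 0) if t == "pre" else (1, 0) if t == "post" else (2, t),
        ):
            phase = t if t in ("pre", "post") else "fu"
            month = 0 if phase != "fu" else t
            for measure in sorted(series.scores[t]):
                row = {
                    "patient_id": series.patient_id,
                    "phase": phase,
                    "month": month,
                    "measure": measure,
                    "score": series.scores[t][measure],
                }
                if phase == "fu" and measure == "PHQ-9":
                    items = items_by_key.get((series.patient_id, month))
                    if items is not None:
                        row.update({c: v for c, v in zip(ITEM_COLUMNS, items)})
                rows.append(row)
    df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS + ITEM_COLUMNS)
    for c in ITEM_COLUMNS:
        df[c] = df[c].astype("Int64")
    if df[ITEM_COLUMNS].isna().all().all():
        df = df[REQUIRED_COLUMNS]
    df.to_csv(path, index=False)
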