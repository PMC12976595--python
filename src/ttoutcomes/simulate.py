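"""Seeded generator of synthetic longitudinal cohorts.

The study data this package analyses (routine talking-therapies outcomes
with post-discharge monthly follow-up) are not publicly deposited, so every
stage of the pipeline is exercised against synthetic cohorts with the same
statistical structure:

* pre- and end-of-treatment scores drawn from truncated normal models whose
  defaults match the published cohort means/SDs (PHQ-9 14.45/5.66 pre,
  7.24/5.18 post; GAD-7 12.47/4.97 pre, 6.21/4.57 post);
* a during-treatment *responder class* per patient (reliably recovered /
  improved without recovering / no reliable change / deteriorated), realised
  by rejection-sampling score pairs against the actual episode classifier so
  the assigned label is correct by construction under whatever threshold
  policy is active;
* a two-state (well / relapsed) monthly Markov chain over the follow-up
  horizon.  In the well state the latent score is the patient's own
  end-of-treatment score; in the relapsed state it is the pre-treatment
  score plus a configurable extra shift (default 0: relapse returns the
  patient to their baseline severity, which by the recovery↔relapse duality
  makes a noiseless relapsed observation classify as reliable relapse for
  every recovered patient).  Observations add rounded Gaussian noise clipped
  to the measure range;
* a monthly-submission missingness process, by default the empirical
  months-submitted distribution {1:.34, 2:.13, 3:.11, 4:.12, 5:.11, 6:.19};
* ADSM assignment for a configurable fraction of patients (default 17%),
  with the ADSM generated on its own range by rescaling the generic anxiety
  model, and the GAD-7 still emitted alongside;
* item-level PHQ-9 decompositions for submitted follow-up questionnaires,
  with the risk item positive with configurable probability (default 16%).

Everything is driven by a single ``numpy`` Generator seeded from the config
and consumed in a fixed per-patient order, so the same seed and config
produce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .episodes import ChangeClass, classify_episode
from .errors import ConfigError
from .measures import (
    MeasureDefinition,
    MeasureRegistry,
    ScorePair,
    ThresholdPolicy,
    default_registry,
)

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate_cohort", "apply_missingness"]

RESPONDER_CLASSES = ("recover", "improve_only", "no_change", "deteriorate")

# Empirical months-submitted profile of the study cohort (fractions of
# submitting users providing data in exactly k of the 6 months).
DEFAULT_MISSINGNESS = {1: 0.34, 2: 0.13, 3: 0.11, 4: 0.12, 5: 0.11, 6: 0.19}

DEFAULT_CLASS_PROBS = {
    # Study-cohort during-treatment outcome mix: 89/156 recovered, 29/156
    # improved without recovering, 7/156 deteriorated, remainder no change.
    "recover": 0.57,
    "improve_only": 0.19,
    "no_change": 0.20,
    "deteriorate": 0.04,
}


@dataclass
class SimulationConfig:
    """Generative parameters of one synthetic cohort."""

    n_patients: int = 156
    seed: int = 0
    horizon: int = 6
    pre_model: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"PHQ-9": (14.45, 5.66), "GAD-7": (12.47, 4.97)}
    )
    post_model: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"PHQ-9": (7.24, 5.18), "GAD-7": (6.21, 4.57)}
    )
    responder_class_probs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS)
    )
    relapse_hazard_per_month: float = 0.07
    remission_prob_per_month: float = 0.30
    relapsed_state_shift: float = 0.0  # extra elevation above the pre-treatment level
    observation_noise_sd: float = 2.0
    missingness_mode: str = "empirical"  # or "bernoulli"
    missingness_distribution: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    p_submit: float = 1.0  # used in bernoulli mode
    adsm_fraction: float = 0.17
    risk_item_prob: float = 0.16
    include_wsas: bool = True
    wsas_model: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"pre": (20.0, 8.0), "post": (10.0, 7.0)}
    )
    max_rejection_attempts: int = 10000

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if self.horizon < 1:
            raise ConfigError("horizon must be >= 1")
        for name, p in {
            "relapse_hazard_per_month": self.relapse_hazard_per_month,
            "remission_prob_per_month": self.remission_prob_per_month,
            "p_submit": self.p_submit,
            "adsm_fraction": self.adsm_fraction,
            "risk_item_prob": self.risk_item_prob,
        }.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if set(self.responder_class_probs) != set(RESPONDER_CLASSES):
            raise ConfigError(f"responder_class_probs must have keys {RESPONDER_CLASSES}")
        total = sum(self.responder_class_probs.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"responder class probabilities sum to {total}, expected 1")
        if any(p < 0 for p in self.responder_class_probs.values()):
            raise ConfigError("responder class probabilities must be nonnegative")
        if self.missingness_mode not in ("empirical", "bernoulli"):
            raise ConfigError(f"unknown missingness_mode {self.missingness_mode!r}")
        if self.missingness_mode == "empirical":
            bad = [k for k in self.missingness_distribution if not (1 <= k <= self.horizon)]
            if bad:
                raise ConfigError(
                    f"missingness distribution keys {bad} outside 1..{self.horizon}"
                )
            total = sum(self.missingness_distribution.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigError(f"missingness distribution sums to {total}, expected 1")
        if self.observation_noise_sd < 0:
            raise ConfigError("observation_noise_sd must be >= 0")


@dataclass
class SimulatedCohort:
    """Long-format observed cohort plus the latent ground truth."""

    cohort: pd.DataFrame
    truth: pd.DataFrame


def _trunc_norm_int(rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int) -> int:
    """Integer draw from a normal truncated to [lo, hi], then rounded.

    The mean is clamped into [lo, hi] first, so proposal shifts that push
    past a scale end stay sampleable (mass piles up at the boundary).
    """
    mean = min(max(mean, lo), hi)
    if sd == 0:
        return int(min(max(round(mean), lo), hi))
    for _ in range(10000):
        x = rng.normal(mean, sd)
        xi = int(round(x))
        if lo <= xi <= hi:
            return xi
    raise ConfigError(
        f"truncated normal (mean={mean}, sd={sd}) produced no draw in [{lo}, {hi}]"
    )


def _scaled_anxiety_model(
    base: Tuple[float, float], gad: MeasureDefinition, target: MeasureDefinition
) -> Tuple[float, float]:
    """Rescale a GAD-7 (mean, sd) model onto another anxiety measure's range."""
    scale = (target.max_score - target.min_score) / (gad.max_score - gad.min_score)
    mean, sd = base
    return target.min_score + mean * scale, sd * scale


def _noisy_score(
    rng: np.random.Generator, mean: float, sd: float, measure: MeasureDefinition
) -> int:
    x = mean if sd == 0 else rng.normal(mean, sd)
    return int(min(max(round(x), measure.min_score), measure.max_score))


def _matches_class(outcome, cls: str) -> bool:
    if cls == "recover":
        return outcome.recovery
    if cls == "improve_only":
        return outcome.change is ChangeClass.RELIABLE_IMPROVEMENT and not outcome.recovery
    if cls == "no_change":
        return outcome.change is ChangeClass.NO_RELIABLE_CHANGE
    if cls == "deteriorate":
        return outcome.change is ChangeClass.RELIABLE_DETERIORATION
    raise ConfigError(f"unknown responder class {cls!r}")


def _draw_pre_post(
    rng: np.random.Generator,
    cls: str,
    dep: MeasureDefinition,
    anx: MeasureDefinition,
    pre_models: Dict[str, Tuple[float, float]],
    post_models: Dict[str, Tuple[float, float]],
    registry: MeasureRegistry,
    policy: ThresholdPolicy,
    cap: int,
) -> Tuple[Dict[str, int], Dict[str, int]]:
    """Rejection-sample (pre, post) primary-pair scores matching a class.

    Class-specific proposals keep the acceptance rate high (the end-score
    model for improvers, pre plus small noise for no-change, pre plus a
    positive shift for deterioration), but acceptance is always decided by
    the actual classifier, so labels remain exact under any policy.
    """
    for _ in range(cap):
        pre = {
            m.name: _trunc_norm_int(rng, *pre_models[m.name], m.min_score, m.max_score)
            for m in (dep, anx)
        }
        post: Dict[str, int] = {}
        for m in (dep, anx):
            if cls in ("recover", "improve_only"):
                post[m.name] = _trunc_norm_int(rng, *post_models[m.name], m.min_score, m.max_score)
            elif cls == "no_change":
                post[m.name] = _trunc_norm_int(rng, pre[m.name], 1.5, m.min_score, m.max_score)
            else:  # deteriorate: propose an upward shift scaled to the range
                shift = 8.0 * (m.max_score - m.min_score) / 27.0
                post[m.name] = _trunc_norm_int(rng, pre[m.name] + shift, 3.0, m.min_score, m.max_score)
        a = ScorePair(pre[dep.name], pre[anx.name], dep.name, anx.name)
        b = ScorePair(post[dep.name], post[anx.name], dep.name, anx.name)
        if _matches_class(classify_episode(a, b, registry, policy), cls):
            return pre, post
    raise ConfigError(
        f"could not generate a (pre, post) pair matching responder class {cls!r} "
        f"within {cap} attempts; the class may be infeasible under the configured "
        "score models and thresholds"
    )


def _decompose_phq9(rng: np.random.Generator, total: int, want_flag: bool) -> Tuple[int, ...]:
    """Split a PHQ-9 total into 9 item scores (0..3 each).

    The risk item (item 9) is positive when requested and feasible; it is
    forced positive when the total exceeds what items 1-8 can hold (24).
    """
    floor9 = max(0, total - 24)
    if want_flag and total >= 1:
        item9 = max(floor9, int(rng.integers(1, min(3, total) + 1)))
    else:
        item9 = floor9
    remaining = total - item9
    items = [0] * 8
    open_slots = list(range(8))
    while remaining > 0:
        idx = open_slots[int(rng.integers(len(open_slots)))]
        items[idx] += 1
        if items[idx] == 3:
            open_slots.remove(idx)
        remaining -= 1
    return tuple(items) + (item9,)


def _draw_retained_months(rng: np.random.Generator, config: SimulationConfig) -> List[int]:
    H = config.horizon
    if config.missingness_mode == "bernoulli":
        return [m for m in range(1, H + 1) if rng.random() < config.p_submit]
    keys = sorted(config.missingness_distribution)
    probs = np.array([config.missingness_distribution[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    k = int(rng.choice(keys, p=probs))
    months = rng.choice(np.arange(1, H + 1), size=k, replace=False)
    return sorted(int(m) for m in months)


def apply_missingness(
    full_cohort: pd.DataFrame, config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Thin a fully observed cohort to the configured submission pattern.

    Per patient, the number of retained follow-up months is drawn from the
    configured distribution (or per-month Bernoulli), the months chosen
    uniformly without replacement.  Pre/post rows are never removed.  Returns
    the observed cohort plus a retention mask (patient_id, month, retained).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mask_rows: List[dict] = []
    observed_parts: List[pd.DataFrame] = []
    for patient_id, group in full_cohort.groupby("patient_id", sort=True):
        retained = set(_draw_retained_months(rng, config))
        fu = group["phase"] == "fu"
        keep = ~fu | group["month"].isin(retained)
        observed_parts.append(group[keep])
        for month in range(1, config.horizon + 1):
            mask_rows.append(
                {"patient_id": patient_id, "month": month, "retained": month in retained}
            )
    observed = (
        pd.concat(observed_parts, ignore_index=True)
        if observed_parts
        else full_cohort.iloc[0:0].copy()
    )
    return observed, pd.DataFrame(mask_rows, columns=["patient_id", "month", "retained"])


_ITEM_COLS = [f"phq9_i{i}" for i in range(1, 10)]
_COHORT_COLS = ["patient_id", "phase", "month", "measure", "score"] + _ITEM_COLS


def simulate_cohort(
    config: SimulationConfig,
    registry: Optional[MeasureRegistry] = None,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> SimulatedCohort:
    """Generate one synthetic cohort under the configured process.

    Returns the observed long-format cohort table (after missingness) and a
    latent-truth table recording each patient's responder class, ADSM, the
    well/relapsed state path, and the retained months.
    """
    if registry is None:
        registry = default_registry()
    rng = np.random.default_rng(config.seed)
    dep = registry[registry.depression_name]
    gad = registry[registry.generic_anxiety_name]
    adsm_pool = sorted(registry.adsm_names)
    class_names = list(RESPONDER_CLASSES)
    class_probs = np.array([config.responder_class_probs[c] for c in class_names], dtype=float)
    class_probs = class_probs / class_probs.sum()

    rows: List[dict] = []
    truth_rows: List[dict] = []
    width = max(4, len(str(max(config.n_patients, 1))))
    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        use_adsm = bool(adsm_pool) and rng.random() < config.adsm_fraction
        adsm_name = str(rng.choice(adsm_pool)) if use_adsm else None
        cls = class_names[int(rng.choice(len(class_names), p=class_probs))]

        anx = registry[adsm_name] if use_adsm else gad
        pre_models = dict(config.pre_model)
        post_models = dict(config.post_model)
        if use_adsm:
            pre_models[anx.name] = _scaled_anxiety_model(config.pre_model["GAD-7"], gad, anx)
            post_models[anx.name] = _scaled_anxiety_model(config.post_model["GAD-7"], gad, anx)
        pre, post = _draw_pre_post(
            rng, cls, dep, anx, pre_models, post_models, registry, policy,
            config.max_rejection_attempts,
        )
        # GAD-7 is still completed by ADSM users, outside the primary pair.
        if use_adsm:
            pre["GAD-7"] = _trunc_norm_int(rng, *config.pre_model["GAD-7"], gad.min_score, gad.max_score)
            post["GAD-7"] = _trunc_norm_int(rng, *config.post_model["GAD-7"], gad.min_score, gad.max_score)
        if config.include_wsas:
            w = registry["WSAS"]
            pre["WSAS"] = _trunc_norm_int(rng, *config.wsas_model["pre"], w.min_score, w.max_score)
            post["WSAS"] = _trunc_norm_int(rng, *config.wsas_model["post"], w.min_score, w.max_score)

        # two-state follow-up chain: well -> relapsed with the monthly hazard,
        # relapsed -> well with the remission probability
        states: List[str] = []
        state = "W"
        for _ in range(config.horizon):
            if state == "W":
                if rng.random() < config.relapse_hazard_per_month:
                    state = "R"
            else:
                if rng.random() < config.remission_prob_per_month:
                    state = "W"
            states.append(state)

        followup: Dict[int, Dict[str, int]] = {}
        for month, st in enumerate(states, start=1):
            obs: Dict[str, int] = {}
            for name in pre:
                m = registry[name]
                if st == "W":
                    mean = float(post[name])
                else:
                    extra = config.relapsed_state_shift * (m.max_score - m.min_score) / 27.0
                    mean = float(pre[name]) + extra
                obs[name] = _noisy_score(rng, mean, config.observation_noise_sd, m)
            followup[month] = obs

        retained = _draw_retained_months(rng, config)
        for phase, month, scores in (
            [("pre", 0, pre), ("post", 0, post)]
            + [("fu", m, followup[m]) for m in retained]
        ):
            for name in sorted(scores):
                row = {
                    "patient_id": pid, "phase": phase, "month": month,
                    "measure": name, "score": scores[name],
                }
                if phase == "fu" and name == dep.name:
                    want_flag = rng.random() < config.risk_item_prob
                    items = _decompose_phq9(rng, scores[name], want_flag)
                    row.update({c: v for c, v in zip(_ITEM_COLS, items)})
                rows.append(row)
        truth_rows.append(
            {
                "patient_id": pid,
                "responder_class": cls,
                "adsm_name": adsm_name or "",
                "state_path": "".join(states),
                "retained_months": ";".join(str(m) for m in retained),
                "n_retained": len(retained),
            }
        )

    cohort = pd.DataFrame(rows, columns=_COHORT_COLS)
    for c in _ITEM_COLS:
        cohort[c] = cohort[c].astype("Int64")
    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "responder_class", "adsm_name", "state_path", "retained_months", "n_retained"],
    )
    return SimulatedCohort(cohort=cohort, truth=truth)
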