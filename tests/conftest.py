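import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from ttoutcomes import (
    ChangeClass,
    PatientSeries,
    ScorePair,
    ThresholdPolicy,
    classify_episode,
    default_registry,
)

CHANGE_CODE = {
    ChangeClass.NO_RELIABLE_CHANGE: 0,
    ChangeClass.RELIABLE_IMPROVEMENT: 1,
    ChangeClass.RELIABLE_DETERIORATION: 2,
    ChangeClass.MIXED_RELIABLE_CHANGE: 3,
}


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def policy():
    return ThresholdPolicy()


@pytest.fixture(scope="session")
def exclusive_policy():
    return ThresholdPolicy(caseness_inclusive=False, rci_inclusive=False)


@pytest.fixture(scope="session")
def phq_gad_grid(registry):
    """classify_episode evaluated over the full PHQ-9 x GAD-7 score grid.

    For each policy: ``states`` enumerates all (phq, gad) score pairs and the
    (n_states, n_states) arrays give the change class code, recovery flag and
    relapse flag for every earlier/later state combination (~380k episodes).
    """
    states = [(p, g) for p in range(28) for g in range(22)]
    pairs = [ScorePair(p, g) for p, g in states]
    n = len(pairs)
    out = {}
    for name, pol in {
        "inclusive": ThresholdPolicy(True, True),
        "exclusive": ThresholdPolicy(False, False),
    }.items():
        change = np.empty((n, n), dtype=np.uint8)
        recovery = np.empty((n, n), dtype=bool)
        relapse = np.empty((n, n), dtype=bool)
        for i, a in enumerate(pairs):
            for j, b in enumerate(pairs):
                o = classify_episode(a, b, registry, pol)
                change[i, j] = CHANGE_CODE[o.change]
                recovery[i, j] = o.recovery
                relapse[i, j] = o.relapse
        out[name] = {"states": states, "change": change, "recovery": recovery, "relapse": relapse}
    return out


@pytest.fixture
def make_series():
    """Factory for PatientSeries with (PHQ-9, GAD-7) score tuples per timepoint."""

    def _make(
        patient_id="p1",
        pre=(16, 12),
        post=(6, 5),
        followup=None,
        adsm_name=None,
        horizon=6,
        measures=("PHQ-9", "GAD-7"),
    ):
        scores = {}
        if pre is not None:
            scores["pre"] = dict(zip(measures, pre))
        if post is not None:
            scores["post"] = dict(zip(measures, post))
        for month, vals in (followup or {}).items():
            scores[month] = dict(zip(measures, vals)) if isinstance(vals, tuple) else dict(vals)
        return PatientSeries(
            patient_id=patient_id, scores=scores, adsm_name=adsm_name, horizon=horizon
        )

    return _make
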