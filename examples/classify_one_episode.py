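"""Classify a single during-treatment episode.

A patient starts treatment scoring PHQ-9 16 / GAD-7 12 (both above the
clinical caseness cutoffs of 10 and 8) and ends at 6 / 5.  Both measures
drop by at least their reliable change index (6 and 4 points), so the
episode is a reliable improvement, and because the end scores are below
caseness on both measures it also counts as reliable recovery.  Reversing
the two timepoints demonstrates the dual concept, reliable relapse.
"""

from ttoutcomes import ScorePair, ThresholdPolicy, classify_episode, default_registry

registry = default_registry()
policy = ThresholdPolicy()  # inclusive caseness and RCI comparators

start = ScorePair(depression_score=16, anxiety_score=12)
end = ScorePair(depression_score=6, anxiety_score=5)

outcome = classify_episode(start, end, registry, policy)
print(f"start -> end: {outcome.change.value}, recovery={outcome.recovery}")

reverse = classify_episode(end, start, registry, policy)
print(f"end -> start: {reverse.change.value}, relapse={reverse.relapse}")

# A small drift across the cutoff is NOT a relapse: the deterioration must
# exceed measurement error (the RCI) as well as crossing the caseness line.
drift = classify_episode(ScorePair(9, 7), ScorePair(10, 7), registry, policy)
print(f"9/7 -> 10/7: {drift.change.value}, relapse={drift.relapse}")
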