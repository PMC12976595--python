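"""Build the PHQ-9 risk-item triage queue from a simulated cohort.

Follow-up PHQ-9 submissions carry item-level scores; any submission scoring
above zero on the self-harm/suicidality item (item 9) is flagged, gets the
four-probe follow-on battery attached, and is compared against the
patient's previous submission to mark strict increases.  The queue is what
a reviewing clinician would work through, ordered by patient and month.
"""

from ttoutcomes import build_triage_report, default_registry, read_cohort
from ttoutcomes.simulate import SimulationConfig, simulate_cohort

registry = default_registry()
sim = simulate_cohort(SimulationConfig(n_patients=80, seed=5))
cohort = read_cohort(sim.cohort, registry)

report = build_triage_report(cohort.phq9_submissions)
print(f"PHQ-9 submissions: {report.total_submissions}")
print(f"flagged (item 9 > 0): {report.flagged.numerator} ({report.flagged.percent}%)")
print(f"increase vs last datapoint: {report.increased.numerator} ({report.increased.percent}%)")
print()
print("first entries of the review queue:")
print(report.queue.head(5).to_string(index=False))
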