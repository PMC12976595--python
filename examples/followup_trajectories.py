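"""Trace one patient's monthly follow-up trajectory.

A patient who reliably recovered during treatment submits questionnaires in
months 1, 2 and 3 after discharge.  Month 2 shows a return of clinical-level
symptoms (a reliable deterioration from the end-of-treatment score ending
above caseness = a reliable relapse), but month 3 shows scores back near the
end-of-treatment level, so the relapse is classed as not sustained.
"""

from ttoutcomes import PatientSeries, ThresholdPolicy, analyze_patient, default_registry

registry = default_registry()
policy = ThresholdPolicy()

series = PatientSeries(
    patient_id="example",
    scores={
        "pre": {"PHQ-9": 16, "GAD-7": 12},
        "post": {"PHQ-9": 6, "GAD-7": 5},
        1: {"PHQ-9": 7, "GAD-7": 6},
        2: {"PHQ-9": 16, "GAD-7": 12},
        3: {"PHQ-9": 8, "GAD-7": 6},
    },
)

finding = analyze_patient(series, registry, policy)
print(f"treatment outcome:   {finding.treatment_change.value} (recovery={finding.treatment_recovery})")
print(f"vs-start category:   {finding.vs_start_category.value} ({finding.vs_start_group} tree)")
print(f"vs-end category:     {finding.vs_end_category.value}")
print(f"relapse:             {finding.relapse_status.value} in months {list(finding.relapse_months)}")
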