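# ttoutcomes

Reliable-change outcome classification for longitudinal patient-reported
outcome data from talking-therapies services — during-treatment outcomes,
post-discharge follow-up trajectories, **reliable relapse** detection, PHQ-9
risk-item triage, and a seeded synthetic cohort generator.

## Who this is for

Psychological-therapy services in England (NHS Talking Therapies, NHS TT)
routinely collect the PHQ-9 (depression, 0–27), GAD-7 (generalized anxiety,
0–21) and WSAS (functioning, 0–40) at every session, and increasingly invite
discharged patients to resubmit questionnaires monthly after treatment ends.
This package turns those long-format score tables into the standard NHS TT
outcome categories, and extends them to the follow-up period: who stayed
well, who relapsed, whether relapses were sustained, and who went on to
recover after discharge. Because routine clinical datasets cannot be
redistributed, a first-class simulation module generates cohorts with the
same statistical structure (score distributions, responder mix, relapse
dynamics, monthly-submission missingness) so every stage is testable
end-to-end.

## The classification model

Each measure *m* has a clinical **caseness cutoff** `c_m` (lowest score
counting as a clinical case) and a **reliable change index** `RCI_m` (the
smallest change exceeding measurement error). Classification always uses a
pair of measures: PHQ-9 plus GAD-7, or PHQ-9 plus an anxiety-disorder
specific measure (ADSM) which substitutes for the GAD-7 when present at both
timepoints of a comparison. For scores at an earlier timepoint *a* and a
later timepoint *b*:

- **reliable improvement** — `a_m − b_m ≥ RCI_m` on at least one measure and
  no measure shows a reliable increase;
- **reliable deterioration** — the mirror image;
- **reliable recovery** — above caseness on either measure at *a*, reliable
  improvement, and below caseness on **both** measures at *b*;
- **reliable relapse** — the exact time-reversal dual: below caseness on
  both at *a*, reliable deterioration, and above caseness on either at *b*.
  Requiring reliable deterioration means a 1-point drift across the cutoff
  is never called a relapse.

Whether equality counts at the cutoff and at the RCI boundary is a
configurable `ThresholdPolicy` (both inclusive by default, following the
NHS TT manual convention); every report echoes the thresholds and policy in
a provenance header. Over the follow-up horizon (default 6 months,
configurable to 12), each available month is classified against the
pre-treatment anchor (stratified category trees) and the end-of-treatment
anchor (a seven-way partition from "always improved" to "fluctuating"),
relapses are detected against the end-of-treatment anchor, and a relapse is
*not sustained* when the latest later month no longer classifies as relapse.

## Worked example

```bash
python examples/classify_one_episode.py
```

```
start -> end: reliable_improvement, recovery=True
end -> start: reliable_deterioration, relapse=True
9/7 -> 10/7: no_reliable_change, relapse=False
```

A patient moving from PHQ-9 16 / GAD-7 12 to 6 / 5 improves by more than
both RCIs (6 and 4) and ends below both cutoffs (10 and 8): reliable
recovery. The reversed episode is a reliable relapse — recovery and relapse
are exact duals. The last line shows the guard built into the relapse
definition: crossing the cutoff by one point is no relapse.

A full cohort run (`python examples/simulate_and_report.py`) simulates 156
patients under the default study-like conditions and prints:

```
Cohort outcome report
  policy: caseness_inclusive=True rci_inclusive=True  horizon=6
  users: 156  submitting follow-up data: 156
  completion (months -> users): 1:47, 2:25, 3:25, 4:21, 5:14, 6:24
  during-treatment rates:
    reliable_improvement: 76% (119/156)
    reliable_deterioration: 3% (5/156)
    reliable_recovery: 56% (87/154)
  PHQ-9 follow-up average vs_start: mean diff -5.45 (d=-0.83, n=156)
  PHQ-9 follow-up average vs_end: mean diff +0.78 (d=0.30, n=156)
  ...
  any_relapse_among_recovered: 26% (23/87)
  relapse_not_sustained: 52% (12/23)
```

Read: 76% of the cohort reliably improved during treatment; among patients
who reliably recovered, 26% showed a reliable relapse at some follow-up
month, and about half of those relapses were contradicted by later data.
Follow-up PHQ-9 averages sit 0.78 points above the end-of-treatment score
(a small paired effect, d ≈ 0.3) while remaining far below the
pre-treatment level.

Other examples: `examples/followup_trajectories.py` (one patient's monthly
trajectory and relapse sustainment), `examples/risk_triage_queue.py`
(item-level risk flagging and the clinician review queue).

A thin CLI wraps the same functions for shell pipelines:

```bash
ttoutcomes simulate --n 156 --seed 1 --out cohort.csv
ttoutcomes trajectories --in cohort.csv --out findings.csv
ttoutcomes report --in cohort.csv --out report.json --text
```

## Layout

- `src/ttoutcomes/` — `measures` (registry, caseness, RCI), `episodes`
  (change/recovery/relapse classification), `trajectories` (follow-up
  trees), `risk` (PHQ-9 item-9 triage), `report` (cohort descriptives),
  `simulate` (synthetic cohorts), `io` (cohort CSV), `cli`.
- `configs/` — default measure registry (YAML) and the report JSON schema.
- `docs/methods.md` — the model, generator and numerical conventions in
  detail.
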