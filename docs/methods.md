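# Methods

## Outcome model

Classification follows the NHS Talking Therapies (NHS TT) convention of
joint criteria over a *measure pair*: a depression score (PHQ-9) and an
anxiety score (GAD-7, or an anxiety-disorder specific measure, ADSM, where
one was administered). For one comparison between an earlier timepoint *a*
and a later timepoint *b*:

| quantity | rule |
|---|---|
| reliable decrease on *m* | `a_m − b_m ≥ RCI_m` (inclusive policy) |
| reliable improvement | ≥ 1 measure decreases reliably, none increases reliably |
| reliable deterioration | mirror image |
| mixed reliable change | one measure decreases reliably, the other increases reliably |
| reliable recovery | above caseness on either at *a* ∧ reliable improvement ∧ below caseness on both at *b* |
| reliable relapse | below caseness on both at *a* ∧ reliable deterioration ∧ above caseness on either at *b* |

Mixed reliable change is not part of the four-category convention (the
improvement and deterioration definitions jointly exclude it) but is
surfaced as its own value rather than silently folded into "no change", so
downstream logic can treat it explicitly; in the seven-way vs-end tree it is
folded into "stable" with a logged warning, since that tree defines
stability as "no reliable change" and provides no rule for mixed states.

Relapse is by construction the time-reversal dual of recovery:
`classify_episode(a, b).recovery == classify_episode(b, a).relapse` for
every score pair. The test suite verifies this exhaustively over the full
PHQ-9 × GAD-7 integer grid (~380k comparisons) for both comparator
policies, alongside an equivalence check against an independent literal
transcription of the prose rules.

### Threshold policy

Descriptions of reliable change sometimes read "greater than the RCI" while
the operational convention treats a change *equal* to the index as reliable.
Rather than hard-coding one reading, both comparators (caseness and RCI) are
a `ThresholdPolicy` with inclusive defaults matching the operational NHS TT
convention. The policy is fixed for a whole run and echoed in every report
header, so the choice is always visible and testable.

### Registry defaults

The numeric thresholds are registry configuration, not code:

| measure | range | caseness cutoff | RCI |
|---|---|---|---|
| PHQ-9 | 0–27 | 10 | 6 |
| GAD-7 | 0–21 | 8 | 4 |
| WSAS | 0–40 | 10 | 8 |
| HAI | 0–54 | 18 | 4 |
| OCI | 0–168 | 40 | 32 |
| PCL-5 | 0–80 | 32 | 10 |
| PDSS | 0–28 | 8 | 5 |
| PHQ-15 | 0–30 | 10 | 6 |
| SPIN | 0–68 | 19 | 10 |

These follow the published NHS TT manual conventions; the PHQ-15 reliable
change value is less standardised across sources and is shipped as an
editable default. WSAS is carried through I/O and summaries but never
enters outcome classification, which is defined on PHQ-9 + GAD-7/ADSM only.

### ADSM substitution

An ADSM substitutes for the GAD-7 only when the patient has ADSM scores at
*both* timepoints of the specific comparison; otherwise that comparison
falls back to the GAD-7. Partial availability is not defined by the
convention, and this per-comparison rule keeps every comparison on a
complete pair while using the disorder-specific measure whenever possible.
Caseness flags are always computed on the same pair used for reliable
change, never mixing an ADSM for change with the GAD-7 for caseness.

## Follow-up trajectory trees

Patients are invited to resubmit questionnaires monthly for H months after
discharge (H = 6 by default, configurable to 12). A month enters
classification only when the primary pair is complete at both the anchor
and that month; incomplete months are omitted and logged (a strict mode
erroring instead is deliberately not the default — missingness is the norm
in this setting). Where a patient submits more than once in a month, the
within-month deduplication keeps the last submission, matching the
one-intended-observation-per-month design.

**vs start** (anchor = pre-treatment), stratified by during-treatment
outcome:

- *improved* stratum: deterioration at any month ≻ lost improvement at
  least once ≻ stayed reliably improved (precedence: worst state wins);
- *recovered* stratum refines the improved tree: when every month is an
  improvement, "remained reliably recovered" (every month also a recovery)
  is distinguished from "remained recovered or improved";
- *not improved* stratum, first match in order: sustained gain (some month
  reliably improves and every month from the first such month onward stays
  improved), transient gain, no reliable changes at all, deterioration at
  any point. A patient with both a transient gain and a deterioration is
  placed by this listed order; the prose convention does not pin this case
  down and the order is a package choice.

**vs end** (anchor = end of treatment): each month maps to improvement /
stable / deterioration, then the series maps to one of seven mutually
exclusive categories: always improved, improved-or-stable, always stable,
stable-or-deteriorated, always deteriorated, fluctuating (both improvement
and deterioration occur), insufficient data. The seven categories partition
every cohort; the suite asserts this on a 2,000-patient simulation.

**Relapse detection** runs only for patients who reliably recovered during
treatment (the relapse definition anchors at a below-caseness state, which
recovery guarantees at the end-of-treatment anchor). Relapse months are the
follow-up months whose end-vs-month episode classifies as reliable relapse.
Sustainment uses the *latest available month after the first relapse month*
as arbiter: if it still classifies as relapse the relapse is sustained,
otherwise not sustained; no later data means sustained. An alternative rule
(`any_later`: any later non-relapse month contradicts) is available behind
a switch. The default is the closest deterministic reading of "subsequent
available data showed the relapse was not sustained".

**Follow-up recovery** is defined only for the improved-but-not-recovered
stratum: the first month whose pre-vs-month episode classifies as reliable
recovery. Calling it for any other patient is a precondition error rather
than a silent `None`.

## Risk-item triage

Any follow-up PHQ-9 scoring > 0 on item 9 (self-harm/suicidality) is
flagged; flagged submissions get the four-probe battery (plans,
preparations, behavioural intent, protective factors) attached, and probe
responses are stored verbatim — never scored, since the procedure being
modelled ends at clinician review. "Increase compared to the last available
datapoint" is read as the risk item's own score (the phrase sits in the
risk-item context); a configuration switch (`increase_on="total"`) applies
it to the PHQ-9 total instead. An increase is strict and is false for a
patient's first submission.

## Cohort report

Percentages are carried everywhere as numerator/denominator pairs plus a
value rounded *half away from zero* on the exact rational — this rule
reproduces every published percentage whose numerator and denominator are
printed, which the acceptance tests check as fixtures. Recovery rates use
the denominator of patients above caseness on either primary measure at
pre-treatment; improvement/deterioration use all classified patients. A
zero denominator reports an undefined rate, not an error.

Paired effect sizes follow the routine-outcome convention: per user, the
follow-up average is the mean of that user's available monthly totals; the
paired difference is follow-up average minus anchor score; Cohen's d =
mean(diff) / SD(diff) with the sample (n−1) SD, undefined when the SD is
zero. Inferential tests (paired t, chi-squared, Mann–Whitney) are
deliberately out of scope: they are routine and add nothing to the
classification logic this package exists for.

The combined data-collection estimate is the product of the app-uptake
proportion and the follow-up submission proportion, rounded by the project
rule — with the published service counts (111/168 and 156/321) it evaluates
to 32%.

## Synthetic cohort generator

The generator emulates the statistical structure of a routine-care
follow-up cohort; it fits no causal model of app engagement.

- **Scores**: integer draws from normals truncated to each measure's range.
  Defaults: PHQ-9 pre (14.45, 5.66), post (7.24, 5.18); GAD-7 pre (12.47,
  4.97), post (6.21, 4.57) — the published cohort moments. PHQ-9 and GAD-7
  are drawn independently (no joint distribution is published; a
  correlation parameter was considered and deferred — see limitations).
- **Responder classes**: each patient is assigned recover / improve-only /
  no-change / deteriorate with default probabilities 0.57 / 0.19 / 0.20 /
  0.04, the published during-treatment mix. The (pre, post) pair is
  rejection-sampled against the *actual* episode classifier until it
  matches the assigned class, so labels are exactly consistent with
  whatever threshold policy is active — class-specific proposal
  distributions (the post model for improvers, pre plus small noise for
  no-change, pre plus an upward shift for deterioration) only speed up
  acceptance. Proposal means are clamped to the score range. Exceeding the
  attempt cap raises a configuration error naming the infeasible class.
- **Follow-up dynamics**: a two-state (well / relapsed) monthly Markov
  chain, default hazard 0.07/month and remission 0.30/month. The well-state
  latent score is the patient's own end-of-treatment score; the
  relapsed-state latent score is the patient's own *pre-treatment* score
  plus an optional extra shift (default 0). Returning to baseline severity
  is both the clinically natural picture of relapse and, by the
  recovery↔relapse duality, guarantees that a noiseless relapsed
  observation classifies as reliable relapse for every recovered patient —
  which makes the closed-form check `P(any relapse) = 1 − (1 − hazard)^H`
  exact when remission and noise are zero. Observation noise (default SD 2
  points, below both RCIs) is added and rounded/clipped to the range; the
  extra shift is rescaled for wider-range measures in proportion to range.
- **Missingness**: per patient, the number of submitted months is drawn
  from the empirical months-submitted profile {1: .34, 2: .13, 3: .11,
  4: .12, 5: .11, 6: .19} (the published completion pattern), months chosen
  uniformly without replacement; a per-month Bernoulli mode is available.
  The retention mask is recorded.
- **ADSM and risk items**: 17% of patients (default) get a random ADSM,
  generated on its own range by linearly rescaling the GAD-7 model;
  classification for those patients runs on (PHQ-9, ADSM) while GAD-7 is
  still emitted. Submitted follow-up PHQ-9 totals are decomposed into nine
  item scores with the risk item positive with probability 0.16 (default);
  the decomposition forces item 9 positive when the total exceeds what
  items 1–8 can carry (24), so totals always reconcile.
- **Determinism**: one `numpy` Generator seeded from the config, consumed
  in a fixed per-patient order; the same seed and config reproduce the
  tables byte-for-byte.

### What the generator does and does not show

Passing tests on synthetic cohorts demonstrate that the classification,
trajectory, triage and reporting logic is correct under the stated
generative assumptions. They cannot demonstrate properties the generator
does not model: correlation between depression and anxiety scores,
informative missingness (patients who feel worse may submit less, or more),
ADSM-specific dynamics, within-month resubmission behaviour, or uptake
selection effects. Observed relapse rates under the defaults run a few
points below the latent `1 − 0.93⁶ ≈ 35%` because missingness hides relapse
months and remission shortens episodes — the same mechanism the real study
flags when noting that fluctuations can only be seen where a subsequent
timepoint exists.

## Numerical and degenerate-input conventions

- Rounding: half away from zero, computed on exact rationals
  (`fractions.Fraction`), never on floating intermediates.
- Zero-denominator rates and zero-SD effect sizes are reported as
  undefined (`null` in JSON), never as errors or infinities.
- A patient with no classifiable follow-up months lands in
  `insufficient_data` in both trees; deleting all follow-up rows never
  raises.
- Scores outside a measure's range raise a range error naming the measure
  and value; mismatched measure pairs raise a structural error.
- Month indices are validated against the horizon on construction and at
  file read, with CSV line numbers in the validation report.

## Problem sizes in the test suite

The exhaustive grid checks run all ~380k PHQ-9 × GAD-7 comparisons twice
(one per policy); partition and label-fidelity checks use 1,000–2,000
simulated patients; the missingness marginal check uses 5,000 draws with
simultaneous (Bonferroni/Goodman) 95% multinomial bounds; the hazard
closed-form check uses 2,000 recovered patients. The whole suite runs in
well under a minute on one CPU.

## Known limitations

- The generator's independence of PHQ-9 and GAD-7 inflates the rate of
  single-measure reliable changes relative to real cohorts, where the two
  are strongly correlated.
- Published Cohen's d values for this setting cannot be verified without
  the raw data; the package reports its own computed effect sizes.
- The not-improved vs-start tree's listed-order rule and the
  latest-month sustainment arbiter are deterministic choices among
  defensible readings; both alternatives are exposed as configuration
  where they differ.
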