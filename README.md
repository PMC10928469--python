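# cvevents

Claims-based identification of **first and recurrent acute myocardial
infarction (AMI) and stroke events** from health-insurance billing data,
with the validation statistics used to assess such algorithms against
medical-record review, and a synthetic claims simulator so the whole
pipeline is testable without access to real claims.

Single-payer claims databases (such as the Korean NHIS, which covers the
whole population) are attractive for national cardiovascular surveillance,
but they are billing systems, not registries: one disease event generates
several claims (long stays are billed in ~30-day cycles, complication
readmissions file new claims), and diagnosis codes are carried over to
later, unrelated visits. Naively counting coded claims therefore
over-counts events, and recurrent events are especially unreliable. This
package implements the episode-of-care construction and rule-based event
classification designed for that setting.

## Method

**Hospitalization episodes.** A patient's disease-coded claims (AMI:
ICD-10 I21–I23; stroke: I60, I61, I63, I64, matched by 3-character prefix
at any diagnosis position) are scanned in chronological order. A claim *B*
starts a new episode only when **both** hold against the episode under
construction ending with claim *A*:

1. start(B) − start(A) > 28 days, and
2. start(B) − max end date of the episode ≥ 3 days.

Consecutive 30-day billing fragments violate (2) and merge; early
readmissions violate (1) or (2) and merge; genuinely new events satisfy
both and split.

**Event classification.** Each episode is scored on four features: the
position of the disease code (primary = first-listed vs secondary or
lower, aggregated over member claims), procedure evidence (AMI: ECG,
cardiac enzymes, CAG, PCI, CABG; stroke: brain imaging, therapeutic
interventions), episode length (≥ 3 days), and in-episode death. First
events use permissive criteria (e.g. primary I21–I23 plus any supporting
evidence, or death alone — the "type 3 MI" arm); recurrent events demand
confirmatory interventions and a minimum stay, because carried-over codes
make later hospitalizations unreliable. The first episode meeting the
first-event algorithm is the patient's first event; every later episode is
tested with the recurrent-event algorithm only.

**Validation statistics.** For a chart-review sample,
`PPV = 100 × n_true / n_identified` per (disease, kind, hospital tier)
stratum, with Wald 95% intervals
`100 × (p̂ ± 1.96 √(p̂(1−p̂)/n))`, plus unweighted (summed-count) and
case-count-weighted pooled PPVs. Hospital tier is assigned by the first or
the highest-level hospital visited in the episode.

## Worked example

```bash
cat > demo.yaml <<EOF
simulation:
  n_patients: 300
chart_review:
  default_true_ppv: 0.9
EOF
cvevents all --config demo.yaml --out-dir demo_out --seed 7
```

prints

```
patients=300 truth_events=277 identified=277 adjudicated=277
patients=177 episodes=417 events=277 AMI_F1=83 AMI_F2=19 AMI_R=29 STROKE_F1=61 STROKE_F2=25 STROKE_F3=23 STROKE_R1=18 STROKE_R2=12 STROKE_R3=7
```

The simulator scheduled 277 true events among 300 patients (177 of whom
had any disease-coded claim); the pipeline grouped their 800+ claims into
417 episodes (event episodes plus non-qualifying rule-out and
carried-over-code visits) and identified exactly the 277 scheduled events,
broken down by which algorithm row fired. The simulated chart review
(true-case probability 0.9 in every stratum) then yields a stratified PPV
report, e.g.:

```
disease      kind   stratum  n_adjudicated_true  n_identified  ppv_percent ...
    AMI     FIRST  tertiary                  40            41         97.6
    AMI     FIRST secondary                  35            37         94.6
```

Library use mirrors the CLI: `generate_cohort` → `sequence_cohort` →
`simulate_chart_review` → `stratified_ppv_table`; see the module
docstrings and `docs/methods.md`.

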