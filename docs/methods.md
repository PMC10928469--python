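# Methods

## Problem setting

Administrative claims are billed per encounter, not per disease event. Two
fragmentation mechanisms dominate hospital claims: stays longer than the
billing cycle are submitted as consecutive ~30-day claims, and patients
discharged after an acute event are readmitted within days for
complications of the same event. Meanwhile diagnosis codes, once assigned,
are carried over to later visits regardless of purpose, which makes raw
code counts — and recurrent-event counts in particular — unreliable.
`cvevents` implements the standard remedy: consolidate claims into
hospitalization episodes, then classify each episode with position-,
evidence-, length- and death-aware rules, separately tuned for first and
recurrent events.

## Episode construction

Claims enter a disease stream when any diagnosis position carries a code
of the stream's group (AMI: I21–I23; stroke: I60, I61, I63, I64), matched
by 3-character prefix so subdivided codes (I21.0…I21.9, I63.x) are
included. Scanning one patient's stream in `(start_date, end_date,
claim_id)` order, claim *B* opens a new episode iff both

1. `start(B) − start(A) > gap_days` (default 28), where *A* is the claim
   most recently appended, and
2. `start(B) − max_end ≥ interval_days` (default 3), where `max_end` is
   the running maximum end date of the current episode.

Design choices here:

* **Strict vs inclusive operators.** "Gap exceeding 28 days" is read as
  strictly `> 28`; "spanned 3 days or longer" as `≥ 3`. Both thresholds
  and both comparisons live in `EpisodeConfig`.
* **Running maximum vs pairwise end.** With overlapping or nested claims
  the sorted predecessor's end date can lie inside the episode's span;
  comparing against the running maximum end is the conservative reading
  (fewer spurious splits). A `strict_pairwise` switch restores the literal
  pairwise comparison for sensitivity analyses.
* **Day conventions.** All arithmetic is in whole calendar days; episode
  length is inclusive (`end − start + 1`), so a same-day admission and
  discharge counts as 1 day and "length ≥ 3 days" means at least three
  distinct calendar days.
* **Death** is a patient-level date; `in_episode_death` is true iff it
  falls inside the episode's date span. A death after discharge does not
  count, which is deliberate: the rules use death as a stand-in for
  procedures that could not be performed *during* the event.
* **No washout.** No look-back window is imposed before calling an event
  "first"; the first qualifying episode in the data is the first event.

The episode builder is verified against a brute-force checker that
enumerates every consecutive partition of a claim sequence and keeps the
(provably unique) partition consistent with the pairwise rules.

## Event classification

Each algorithm is an ordered list of branches; a branch has a
code-placement precondition and a boolean criterion. The first branch
whose precondition holds is the only one applied, which realizes the
"code group absent at primary position" row preconditions by ordering.
Criteria per branch:

| branch | precondition | criterion |
|---|---|---|
| AMI_F1 | primary I21–I23 | ECG ∪ enzymes ∪ CAG ∪ PCI ∪ CABG, or death |
| AMI_F2 | secondary-only I21–I23 | CAG ∪ PCI ∪ CABG |
| AMI_R | any-position I21–I23 | (PCI ∪ CABG) ∧ (length ≥ 3 ∨ death) |
| STROKE_F1 | primary I63–I64 | (imaging ∧ (length ≥ 3 ∨ death)) ∨ intervention ∨ death |
| STROKE_F2 | any-position I60–I61 | same as STROKE_F1 |
| STROKE_F3 | secondary-only I63–I64 | intervention ∧ (length ≥ 3 ∨ death) |
| STROKE_R1 | primary I63–I64 | (imaging ∨ intervention) ∧ (length ≥ 3 ∨ death) |
| STROKE_R2 | primary I60–I61 | same as STROKE_R1 |
| STROKE_R3 | secondary-only stroke codes | intervention ∧ (length ≥ 3 ∨ death) |

Positions are aggregated at the episode level: a group counts as primary
if it occupies position 1 on *any* member claim, because split billing
fragments of one stay may code the admission differently
(`RuleConfig.first_claim_positions_only` restores the stricter
first-claim reading). The recurrent row for AMI is position-independent,
per its single "all positions" row. Brain imaging is one flag (CT, MRI
and angiography are not distinguished at rule level), and all
stroke-specific therapeutic interventions (thrombolysis, endovascular
treatment, coil embolization, …) collapse into one flag.

Two structural properties hold by construction and are enforced by
exhaustive enumeration over code placements × all 2⁷ evidence subsets ×
length {2, 3} × death {no, yes} against an independently written
truth-table oracle: at most one branch fires per episode, and every
recurrent-accepted episode is also first-accepted (the recurrent criteria
are strictly more stringent).

Sequencing is a single chronological scan per (patient, disease): before
a first event exists only the first-event algorithm is consulted; after
it, only the recurrent one. An episode that meets first-event criteria
after the first event emits nothing. AMI and stroke streams never
interact.

## Validation statistics

`ppv(n_true, n_identified)` is on the percent scale with a Wald interval
`100 (p̂ ± z √(p̂(1−p̂)/n))` truncated to [0, 100]. Wald is the default
because it reproduces the printed intervals of the chart-review
validation this package accompanies (all 11 defined stratum intervals,
checked to one decimal); Wilson is available via `CIMethod`. Display
rounding is half-up to one decimal on the percentage scale. "N/A" is
reported when no events were identified or when the proportion is
degenerate (0/1 or 1/1) at n = 1; degenerate proportions at larger n get
the collapsed Wald interval (e.g. 100.0–100.0), matching the
perfect-agreement convention.

The unweighted pool is the PPV of summed counts. The weighted pool is
`Σ w_t PPV_t / Σ w_t` over hospital tiers with case counts as weights;
since no pooled-interval formula accompanies the published tables, the
interval combines stratum binomial variances as
`Σ (w_t/Σw)² p̂_t(1−p̂_t)/n_t` (a documented choice, not verifiable
against the published pooled intervals because the national case-count
weights themselves are not published — the published pooled values are
checked only against the bound min ≤ pooled ≤ max over strata, which any
weighted mean must satisfy).

## Synthetic cohort

The generator emulates exactly the phenomena the pipeline must handle:
billing-cycle fragmentation (stays longer than `billing_split_period`
emit consecutive fragments whose next start is `period` days after the
previous start and < 3 days after its end), merge-window complication
readmissions, pre-event rule-out visits and post-event carried-over-code
visits (short, evidence-free, spaced to form their own episodes), fatal
events including "type 3 MI"-like deaths with no procedures, and
per-claim hospital-tier assignment so both stratum rules are exercised.
Each scheduled event targets one algorithm branch and emits that branch's
code placement and evidence pattern; branch-targeted emission (rather
than uniform random evidence) guarantees coverage of rare rows such as
secondary-position ischemic stroke.

Defaults: 500 patients, 35% per-patient probability of each disease, 30%
recurrence, 25% long stays, 30% readmission, 40% carryover noise, 20%
rule-out visits, 8% fatal events, hospital mix 35/40/25
tertiary/secondary/primary. Stay lengths and fragment counts are
plausible placeholders — real claims fragmentation statistics are not
published — so passing recovery tests demonstrates correctness of the
grouping and rule logic under the modeled phenomena, not calibration to
real Korean claims. The generator also does not model demographic
structure, costs, drug claims, coding-revision or pandemic-era effects.

With every `detect_probability` at its default of 1.0 (the canonical
setting), each scheduled event emits a fully qualifying pattern and the
generator's label log is an exact oracle: the pipeline must recover
sensitivity and PPV of 100% against it, with zero recurrent calls at
noise dates. Lowering a branch's probability suppresses the qualifying
pattern entirely (no evidence, short stay, no death), producing labeled
undetectable events; note that an undetectable first event followed by a
detectable recurrent pattern will legitimately be identified as a first
event by the engine, so exact-recovery assertions apply only to the
canonical setting.

`simulate_chart_review` adjudicates each identified event independently
with its stratum's configured true-PPV probability — a pure binomial
model, standing in for the human chart-review procedures (UDMI-based AMI
adjudication, AHA/ASA-based stroke adjudication), which are out of scope.

## Numerical and interface notes

* All randomness flows through `numpy.random.default_rng` seeded from the
  config or CLI `--seed`; identical inputs give byte-identical outputs.
* Claim ordering ties are broken by `(start_date, end_date, claim_id)`.
* The acceptance script scales its checks to run in seconds: 10,000
  random episode instances of ≤ 5 claims in a 120-day window, the full
  131,072-case rule grid, 500-patient cohorts, 200 chart-review
  replicates.

## Known limitations

* PPV is the only accuracy metric computable from a review of identified
  events; sensitivity/specificity against the population would require
  adjudicating non-identified hospitalizations.
* Cross-disease recurrence (a stroke after a first AMI) is out of scope;
  streams are independent.
* Episode grouping considers only disease-coded claims; an intervening
  claim without the disease code (e.g. rehabilitation) neither joins nor
  splits an episode.
* Real procedure (EDI) service codes are site-specific configuration, not
  code: map them to the evidence flags via the two-column service-map
  file.
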