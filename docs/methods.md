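# Methods

This note documents the models and procedures `ueclink` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Entity resolution model

The pipeline performs *union* entity resolution: records from four sources
(telephone-helpline calls, ambulance incidents, ED attendances, inpatient
episodes) are partitioned into entities (people) without a master source.
It proceeds in two phases.

### Deterministic phase

Seven strict, non-revisiting steps; a record assigned at step *k* is never
reconsidered. The working assumption is that a valid (NHS number, date of
birth) pair identifies a person with near certainty, so such pairs seed the
entities (S1) and everything else attaches to them by progressively weaker
keys (S2–S5), clusters among itself (S6), or stands alone (S7).

Choices where the design was open:

* **S2 tolerance.** The approximate birth year (activity year minus age at
  activity) must match an entity's birth year within ±1: age in completed
  years straddles a calendar-year boundary, so an exact-year rule would
  wrongly reject about half of true links.
* **Same NHS number, different valid dobs** seed *distinct* entities; the
  pair is the key. Misrecorded NHS numbers are the reason the pair, not the
  number alone, is trusted.
* **"Uniquely matching one entity"** (S3–S5) is evaluated against the
  entities existing when the step begins; assignments made inside a step do
  not grow the index mid-step. This makes each step order-independent
  within itself.
* **Pattern eligibility applies to both sides of a key.** Ambulance
  records are excluded from provider-ID matching (no provider patient ID
  exists) and from demographic matching (their postcode is the incident
  location, not a residence); helpline records are excluded from name
  matching (no names). These exclusions bar an ineligible record both from
  *being matched* and from *seeding the key index*.
* **Communal postcodes.** The top `ceil(f × #distinct postcodes)` postcodes
  by number of distinct patients (default f = 0.01) are barred from S4/S5
  keys — high-occupancy addresses (prisons, care homes) make
  (sex, dob, postcode) non-identifying. Ties at the cut rank are broken
  lexicographically so the set is reproducible.
* **S6** clusters the remaining records by connected components over the
  union of the three patterns (transitive closure); components of size one
  are reported as S7 ("no deterministic link possible"), not as
  single-record clusters.
* Entity IDs are opaque sequential integers issued in input order, making
  runs bit-reproducible.

### Probabilistic phase

Conveyed ambulance incidents are linked to ED/inpatient records via the
Fellegi–Sunter model.

**Candidate generation.** Blocking on the conveyance destination site;
windowing: ED arrival within [−1 h, +3 h] of the ambulance's arrival at
the destination (boundaries inclusive), inpatient admission episodes on
the same calendar day, extended to the previous day when the ambulance
arrived before 01:00 and to the next day when after 21:00 (episode times
are unreliable, dates are not). A pair must additionally satisfy at least
one of seven agreement patterns (postcode match; both initials; one
initial + age within 10 years; dob within 31 days; dob year match with
day/month transposed; dob month and day match). A missing field fails any
pattern that needs it. Candidate generation is verified in the tests
against an exhaustive all-pairs oracle applying the same predicates.

**Comparison.** Eight fields: year, month, day of birth; age at activity;
first name; last name; postcode; sex. Names are compared by Jaro–Winkler
similarity (prefix scale 0.1, prefix cap 4) and count as agreeing at
similarity ≥ `name_similarity_threshold` (default 0.8, configurable — the
cut-off between "similar" and "different" names is a convention). All
other fields compare exactly. Either side missing → status *missing*.

**EM estimation.** A two-class conditional-independence mixture over the
binary agreement indicators; one class is the set of true matches. Missing
indicators are simply omitted from a pair's likelihood (and from the
corresponding M-step sums), which avoids biasing m/u by missingness but
assumes missingness is uninformative about match status. Initial values
m₀ = 0.9, u₀ = 0.1, p₀ = 0.01; convergence when the log-likelihood changes
by < 1e−6, capped at 1000 iterations (the log-likelihood is checked to be
non-decreasing). A field with no observed variation is flagged
uninformative and given zero weights with a warning. Ambulance→ED and
ambulance→inpatient candidates are pooled into a single model: they are
one linkage exercise with the same field semantics.

**Scoring and threshold.** Total match weight = Σ w⁺ (agreements) + Σ w⁻
(disagreements), missing → 0; a name agreement at similarity *s*
contributes w⁻ + s·(w⁺ − w⁻), the full w⁺ only at s = 1. The threshold is
selected on the labelled subset (both NHS numbers present; agreement =
"real" match): thresholds sweep the midpoints of adjacent distinct
observed weights plus sentinels beyond both extremes — midpoints make the
choice independent of floating-point representation, and the upper
sentinel makes specificity 1 always reachable, so the specificity target
is attainable whenever both label classes exist. The chosen threshold is
the smallest one with specificity ≥ the target (default 0.999). PPV is
reported as 1 (flagged by construction) at thresholds with no predicted
positives; F is the harmonic mean of PPV and sensitivity.

**Adjudication.** Among links at or above the threshold, each ambulance
record keeps only its greatest-weighted link and only if that weight is at
least twice the runner-up's; the same rule is then applied per hospital
record (the rule is symmetric because a hospital record can also have
several ambulance suitors). Surviving links are applied in descending
weight order under union–find; a link whose two current clusters carry
valid NHS-number sets (or valid dob sets) that are both non-empty and
disjoint is a transitivity conflict and is discarded. Accepted links merge
the clusters (merged ID = smaller entity ID) and mark the two endpoint
records with provenance `P`.

### Assembly

Order fixed and documented: duplicates → date exclusions → admission-method
exclusions; each record is counted under the first reason that applies.
Duplicates are records of the same resolved patient, same source, same
start and end date-times and same clinical key (treating specialty +
primary diagnosis); the smallest record_id is kept — deterministic and
order-independent. Exclusions drop records whose governing date (call
start for helpline/ambulance, arrival for ED, episode start for inpatient)
is missing or outside the platform period, and inpatient episodes whose
admission method is not `emergency`. Unlinked records keep their own
entity ID: they are genuine care activity. The per-source identity
`total = duplicates + exclusions + final` is asserted in tests on every
run.

**Evaluation** against generator truth is pairwise: precision/recall/F over
same-entity record pairs, computed by cluster-size arithmetic (equal to
brute-force pair enumeration, which the tests verify on small fixtures),
plus the fraction of true persons recovered as exactly one cluster. With
no predicted pairs, precision is reported as 1 with an explicit flag.

### Pathways

Journeys attach, for each helpline call, the earliest same-person ED
arrival in the half-open window (call, call + 48 h] — strictly after the
call, boundary inclusive at 48 h — and for each attached attendance the
earliest same-person emergency episode starting on the arrival date or the
next calendar day ("up to one night"; no clock-time rule exists for
admissions, so the rule is calendar-based). Ties are broken by earliest
time then smallest record_id, making attachment a function. Compliance
analysis defaults to callers aged ≥ 16 (`min_age` parameter; the adult
cut-off is a convention, and calls with unknown age are retained).
Urgency classification of attendances is a pluggable callable because the
published classification algorithm is external; the shipped
`admission_based_urgency` (urgent iff admitted) is a deliberately crude
stand-in for interface testing, not a clinical rule. Attendance frequency
uses NHS reporting years (April–March); top-k persistence clamps k to the
attending population.

## Synthetic generator

The generator's defaults encode the study conditions the pipeline targets:

| parameter | default | basis |
|---|---|---|
| NHS-number presence | IP 0.997, ED 0.980, NHS111 0.963, AMB 0.144 | per-source completeness the method was designed around |
| conveyance probability | 0.601 | fraction of ambulance incidents conveying to hospital |
| non-emergency admissions | 0.54 | share of inpatient episodes that are not emergency admissions |
| ED arrival offset | uniform [−15, +90] min from ambulance arrival | inside the −60/+180 linkage window; a configurable out-of-window tail creates hard negatives |
| event rates/person (1 year) | 111: 0.5, AMB: 0.4, ED: 0.8, IP: 0.35 | ordering of the real per-capita volumes, scaled to desk size |
| twin fraction | 0.02 | enough twin pairs to exercise the (sex, dob, postcode) ambiguity rule |
| communal postcode fraction | 0.01 of persons | exercises the postcode-exclusion rule |
| typo / dob-transposition / leading-zero-loss rates | 0.05 / 0.02 / 0.10 | observed corruption modes, desk-scale magnitudes |
| boundary duplicate rate | 0.01 | duplicates cluster in the two weeks after April 1 |

Event counts are Poisson per person per source (the simplest count model
producing the per-person multiplicity linkage needs); event times are
uniform over the period; names come from built-in lists; postcodes are
synthetic strings from a finite pool (only equality and frequency matter
to the pipeline). A single master seed feeds per-stage substreams
(population / activity / degradation), so outputs are bit-identical for a
fixed seed and stages are independently reproducible.

What the generator deliberately does **not** emulate: realistic UK
geography or postcode structure; seasonality and case-mix; mortality;
coupling between a call's disposition and subsequent ED attendance (event
streams are independent, so synthetic compliance rates are small and
structural — they exercise the analysis code, not the real-world rates);
non-conveyed ambulance structure beyond identifier-poor records with no
hospital descendant ("hear and treat"); multiple NHS numbers per person.
Consequently, passing tests demonstrate the pipeline's correctness and its
operating characteristics under controlled corruption — not the rates any
real system would show.

## Problem sizes

The end-to-end checks run on 20,000 persons (≈52,000 records, ≈7,800
candidate pairs, ≈1,100 labelled pairs), chosen so a full run takes well
under a minute while leaving several hundred labelled nonmatches for the
specificity sweep; calibration checks use ≥50,000 generated records so
3-sigma binomial bands are tight; parameter-recovery simulations use
50,000 agreement vectors. Oracle-equivalence checks run at ≤500 records
(candidates) and ≤50 records (pairwise metrics) where exhaustive
enumeration is feasible.

## Known limitations

* Conditional independence of fields given match status is assumed by the
  EM model but mildly violated by construction (dob components, age and
  dob are dependent); the estimated weights are still well separated, and
  threshold selection is label-driven, which absorbs the misspecification.
* With ~500 true matches in a 50,000-vector simulation at match prior
  0.01, the m-probabilities are recoverable only to their binomial
  sampling floor (sd ≈ 0.01–0.02 per field); the EM estimate coincides
  with the complete-data MLE to <0.01, which is the meaningful guarantee.
* The greedy one-link-per-record rule with the 2× dominance requirement is
  not a global assignment optimisation; ambiguous multi-link records are
  deliberately left unlinked.
* Deduplication requires resolved entities, so it runs after linkage;
  duplicates of records that failed to link to each other are not
  collapsed.
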