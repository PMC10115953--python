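# Methods

This note documents the models and procedures implemented in `trajmine`, the
choices made where the underlying study design was open, and what the
synthetic-data tests do and do not establish.

## Cohort definition

**Index date.** The first antidepressant (AD) dispensing in the study year
(default 2015) with no AD dispensing in the preceding `washout_days`
(default 365). Antipsychotics (AP) are never index-eligible and do not count
as prior AD exposure. If several drugs are dispensed on that date the index
record stores the alphabetically first; multiplicity itself is handled by
the eligibility cascade.

**Eligibility cascade** (fixed order; the first failing rule is the recorded
exclusion reason, so attrition counts are order-dependent and reproducible):

1. `no_ad` — no qualifying index dispensing;
2. `comorbid_dx` — any F20.x, F30.x, F31.x, or F00.x–F09.x diagnosis in
   baseline (365 days before index) **or** follow-up (365 days after);
3. `ect_baseline` — electroconvulsive therapy in baseline. EHR exports
   rarely carry harmonized procedure codes, so ECT enters as an optional
   boolean column (`ect_baseline`) on the patients table, defaulting to
   false when absent;
4. `age` — age at index, in completed years, outside [18, 65];
5. `multi_ad_index` — ≥2 distinct AD drug codes dispensed on the index date
   (new users must start on monotherapy); an AD plus an AP is monotherapy;
6. `no_mdd_dx` — no F32.x/F33.x diagnosis in baseline (index day included).

**Episode end.** Treatment "activity" is (a) an AD supply in hand, i.e. any
day inside [dispense, dispense + days_supply), and (b) a depression
diagnosis day (F32.x/F33.x). AP supplies are *not* activity: the rule is
about AD treatment, and AP-only tails without depression-coded visits are
treated as ended. The episode ends at the first activity-chain endpoint
followed by ≥ `episode_gap_days` (default 120) with no activity; trailing
record silence counts as an unbounded gap. Follow-up is
`end_day = min(episode end, 365)`; a patient "discontinued" iff the episode
ended before day 365. The gap scan is idempotent under truncation at the
computed end and monotone in the gap parameter (both property-tested).

## Sequence construction

**Drug episodes.** Per drug, supply intervals are merged when overlapping,
abutting, or separated by ≤ `refill_gap` (default 30) days; the episode's
`total_supply` is the sum of constituent supplies even when a bridged gap
makes the covered span longer.

**Step events.** A new-drug episode starting at day t with total supply
≥ `min_supply` (30) is a *switch* when every previously active drug's
episode ends within [t − 30, t + 30] (the symmetric window covers both
stop-then-start and start-then-stop transitions), and an *add-on* when at
least one prior drug remains active more than 30 days past t. Same-day
starts form one event; each event increments the step counter. Two decisions
the study design leaves open:

* a *restart of the same drug* after a refill gap is not an initiation of a
  different AD and generates no event;
* a sub-30-day trial drug appears in the class and polypharmacy channels
  (it is real exposure) but generates no step event.

**Channels.** For each day before `end_day`: polypharmacy is MULTI iff ≥2
distinct drugs are in supply; the class channel shows the class of the most
recently initiated active drug, with same-day ties broken by the fixed
priority SSRI > SNRI > TCA > NaSSA > OtherAD > AP (a daily channel must be
single-valued; the latest initiation reflects the newest therapeutic
decision — this collapse rule is a documented package choice and is recorded
in the run manifest); the step channel follows the event counter (S1, S2,
S3plus). Days with no supply before `end_day` carry the previous day's state
forward (LOCF); LOCF never crosses `end_day`, after which all channels are
DISC. Day 0 must have an active drug (it is the index day). All three
channels are exactly 365 states with an identical DISC suffix.

## Dissimilarity and clustering

**LCS distance.** `d(x,y) = |x| + |y| − 2·L(x,y)`; a metric (property-tested
including triangle inequality). The accelerated kernel processes the
run-length encoding of one side: appending a run `c^l` to a prefix obeys

    LCS(x·c^l, y[:j]) = max_t { LCS(x, y[:t]) + min(l, #c in y[t:j]) },

which becomes a sliding-window maximum because the saturation boundary
(where the count reaches `l`) is monotone in `j`. Cost O(runs(x)·|y|) per
pair versus O(|x|·|y|) naive; exact equality with the naive DP is asserted
on >2,000 random pairs. Daily 365-day sequences typically have 2–6 runs, so
the pipeline-scale speedup is roughly 60×. The distance matrix additionally
deduplicates identical per-channel sequences before computing pairs.

**Multi-channel modes.** Default `sum`: per-channel LCS distances added —
decomposable, integer-valued, and testable channel by channel. Alternative
`composite`: optimal matching on composite states with substitution cost
2 per differing channel and indel 3, the LCS-equivalent cost set summed over
channels (verified against exhaustive alignment enumeration on toy
sequences). Which of the two an analyst should prefer is a genuine modelling
choice; the mode used is written to the run manifest.

**Ward clustering** is implemented in-package as the Lance–Williams
recurrence on squared dissimilarities with heights reported as square roots
(the Ward.D2 convention) and global-minimum merging with lowest-pair-index
tie-breaking, so runs are bit-reproducible. It is verified against both a
naive O(n³) reference implementation and scipy's Ward linkage. The
implementation scans the full matrix each merge (O(n³) worst case,
vectorized); fine for cohorts up to a few thousand patients, which is the
intended scale.

**Partition assessment.** Standard silhouette on the precomputed matrix,
`s(i) = (b − a)/max(a, b)`, singletons scored 0, ASW = unweighted mean;
`scan_partitions` reports ASW and cluster sizes for each k and flags
ASW ≥ 0.51. The final k is deliberately *not* chosen automatically: cluster
count selection balances homogeneity, sizes, and interpretability, and the
package only surfaces the numbers. Cut labels are ranked 1..k by decreasing
cluster size.

## Synthetic data generator

The generator emulates prescription-level EHR whose derived trajectories
follow four archetypes calibrated to a published single-center cluster
profile (`REFERENCE_PROFILE`): mixture weights 0.737/0.095/0.111/0.057,
truncated-normal durations on [1, 365] with means (sd) 35.0 (27.62), 180.8
(46.25), 333.0 (49.64), 357.3 (18.66), initial-class probabilities with the
profile's SSRI/SNRI/NaSSA shares (TCA/OtherAD split the untabulated
residual evenly), and step-event count distributions with means 0.1, 0.7,
0.2, 2.3 (cumulative steps 1.1, 1.7, 1.2, 3.3). Values the profile does not
pin down were chosen once as plausible for this setting and not revisited:
per-archetype add-on probabilities (0.35/0.50/0.30/0.55), add-on durations
(normal, means 30/85/120/150 days, floor 30), a switch-destination matrix
favoring SSRI/SNRI, antipsychotic-heavy add-ons in archetype 4 (weight 0.4),
a 0.7 per-dispensing probability of a coded depression visit, and inpatient
index shares 0.5/0.8/0.4/3.1%. Demographics follow the profile marginals
(age ≈ N(39.1, 13.11) clipped to [18, 64], 65.6% female).

Mechanics: ~30-day supplies tile each drawn duration; switches stop all
active drugs at the event day and start a fresh drug; add-ons overlap the
continuing regimen for their drawn duration; event times are spaced ≥30 days
and end ≥31 days before the episode end, so every event clears the 30-day
supply rule and is detectable under the ±30-day switch window (durations
under 65 days host no events — archetype-1 step counts are feasibility-
capped, an acknowledged bias). A depression diagnosis is always coded on the
index day, so every generated patient has a baseline MDD diagnosis. Each
patient's randomness comes from a dedicated `(seed, patient index)` stream:
cohorts are extensible without perturbing existing patients, and identical
seeds give byte-identical tables.

The attrition fixture appends to the eligible stream four engineered strata
— comorbid diagnosis during follow-up (312), baseline ECT flag (12), age
drawn outside 18–65 (1,785), a second AD on the index day (3,259) — each
passing all earlier rules, so the cascade replays the published counts
exactly (10,371 → 5,003).

**What a green test establishes.** The generator reproduces the *moments*
the archetypes are calibrated to and clean, detectable regimen changes. It
does not emulate real-data features such as irregular refill timing, dose
changes, cross-hospital attrition, partially-overlapping switch windows,
miscoded diagnoses, or within-archetype heterogeneity of class mixes over
time. Archetype recovery (ARI ≥ 0.8, ASW ≥ 0.51 at n = 400, k = 4) therefore
validates the pipeline's correctness, not its discriminative power on real
EHR; no attempt is made to reproduce the published ASW of 0.65 or exact
cluster proportions from simulation.

## Numerical conventions

* Day coordinates: day 0 = index date; all intervals half-open [start, end).
* Distances are exact integers in `sum` mode and stored in double precision.
* Ward heights are monotone (checked); tie-breaks are lowest-index first.
* Summary statistics use sample sd (ddof = 1); display rounding is 1 decimal
  for means/percentages with raw values retained in CSV outputs.
* Percent time in a state is computed as mean state-days / mean follow-up
  days, matching the arithmetic used for the derived-share worked examples.

## Known limitations

* Only the first treatment episode per patient is analyzed.
* No dose/titration modelling, no adherence (MPR/PDC) metrics, no
  alternative sequence distances (Hamming, OMspell), no medoid clustering,
  no bootstrap cluster-stability assessment.
* The episode-end scan caps follow-up at day 365 regardless of whether the
  120-day gap completes after day 365.
* The in-package Ward implementation targets cohort-scale n (≤ a few
  thousand); very large cohorts would need a nearest-neighbor-chain variant.
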