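# Methods

## Data model and preprocessing

The unit of analysis is a patient *timeline*: the date of the first
occurrence of each code the patient ever carries.  Raw event rows
(patient, code, domain, ISO date, optional abnormal flag) are reduced by
these rules, applied in order:

1. medication codes are optionally mapped to user-supplied therapeutic
   groups (unmapped codes pass through and are counted);
2. diagnosis codes are truncated to their 3-character ICD-10 category
   (dot suffix removed first, so `E11.9` → `E11`), **except** codes in the
   configurable dementia-outcome set, which keep full specificity — the
   outcome codes are exactly what the analysis must discriminate;
3. lab events are restricted to abnormal results (a normal result carries
   no signal under first-occurrence reduction, so normal-only labs drop
   out entirely);
4. events are clipped to the study window (default 2013-01-01 to
   2022-12-31);
5. per patient and post-truncation code, only the earliest event is kept;
   same-day collisions between two originals mapping to one category are
   resolved by the lexicographically smallest original code, an arbitrary
   but deterministic rule.

Patients missing sex, race or a resolvable age are excluded, then
patients younger than 18 years at the window start (precedence:
incomplete demographics first, so each patient is counted under exactly
one reason and totals balance).  Age is evaluated at the window start
because that is the one date defined for every patient in the
abstraction; matched-control strata instead evaluate age at the exposed
patient's index event, where matching actually matters.  Patients with
demographics but no in-window events remain in the cohort — they are
legitimate members of the matched-control pool.

## Pair screening

Every unordered pair of codes across all four domains is tested on the
patient-level 2×2 presence table with the two-sided Fisher exact test
(scipy), keeping pairs with p < `alpha_pair` (default 0.05), positive
association (ad > bc; mutual exclusivity must not seed trajectories) and
at least `min_pair_patients` (default 10) carriers of both — a floor that
prevents degenerate ordering trials.  No multiplicity correction is
applied at this step; the correction belongs to the relative-risk stage.

Orientation uses the exact two-sided binomial test at success probability
1/2 on the numbers of carriers with C1 first versus C2 first.  Same-day
ties carry no ordering information and are excluded from the trial.
Pairs with p ≥ `alpha_dir` (default 0.05) stay undirected and are
dropped; otherwise the majority direction is adopted.

## Matched relative risk

For an exposure (a single code, or an ordered code prefix traversed with
every consecutive gap ≤ `max_gap_days`, default 1,826 days ≈ 5 years),
each exposed patient is matched to up to `k_controls` (default 10,000)
patients drawn uniformly without replacement from the same (sex, race,
decade-of-life) stratum, the decade evaluated at the exposed patient's
index event (first exposure code).  Decade = floor(age/10), with a year
of 365.25 days, so age 70.0 falls in decade 7.  When a stratum holds
fewer than k candidates all of them are taken and the shortfall is
recorded; an empty stratum contributes no comparison and is flagged.

Per-patient samples are pooled into one comparison group (union,
multiplicity removed).  With strata smaller than k — the usual case at
synthetic scale — the union is effectively the whole stratum, i.e. a
population sample that can include other exposure carriers; this matches
matching on "other patients" rather than on never-exposed patients, and
biases RR toward 1.

Outcome definitions are deliberately asymmetric:

* **exposed**: first occurrence of the outcome strictly after the last
  exposure code and within `max_gap_days` of it;
* **controls**: outcome anywhere in the record (default).  This is simple
  and conservative.  An index-aligned variant
  (`control_outcome="after_matched_index"`, multiplicity-weighted across
  per-exposed samples) is available.

A consequence worth stating: under the default control definition the RR
of two *independent* codes does not converge to 1 but to the closed-form
value obtained by setting the planted hazard multiplier to 1 — the ratio
of a bounded post-exposure window to the whole record — which is below 1.
The null is therefore conservative for the RR > 1 selection rule, and the
test suite checks convergence to that value rather than to unity.

RR = (n_EO/n_E)/(n_CO/n_C) with the Katz log-interval CI and a two-sided
normal p-value on ln RR / SE.  If either outcome count is zero, 0.5 is
added to all four counts and the estimate is flagged.  Bonferroni control
uses the family of directed pairs actually tested at this stage (family
size recorded in the run report); trajectory and cluster estimates reuse
the machinery with their own family sizes.  Every estimate's RNG seed is
derived from the master seed and the estimate's code key by SHA-256, so
the whole stage is bit-reproducible and independent of evaluation order.

## Trajectory assembly

Significant directed pairs are edges of a directed graph.  The procedure
assumes a DAG; if the data produce a directed cycle, the in-cycle edge
with the largest RR-stage p-value is removed iteratively (ties: smallest
RR, then lexicographic), and every removal is logged.  The graph is
restricted to outcome codes and their ancestors — codes from which an
outcome is reachable — since trajectories must end in an outcome.

Trajectories are simple paths of length ≥ 3 (default cap `max_len` = 5,
the span of published trajectory tables) ending at an outcome node, with
outcome codes allowed only in terminal position (post-diagnosis sequences
are not of interest).  A path's *support* is the number of patients whose
first-occurrence dates of its codes are strictly increasing in order with
every gap ≤ `max_gap_days`; support is monotone non-increasing under path
extension, so the depth-first enumeration prunes any prefix below
`min_support` (default 500) without loss — verified against unpruned
brute-force enumeration in the tests.  Each emitted trajectory is scored
by the matched RR with its non-terminal prefix as the exposure.

## Embedding and clustering

Each code's English description (falling back to the code token) is
embedded as a unit vector of dimension `embedding_dim` (default 256).
The default provider hashes lowercased character trigrams into signed
buckets and L2-normalises — fully deterministic, offline, and shaped like
any external text-embedding service, which can be substituted through the
same one-argument callable interface (with optional PCA to the target
dimension if its native output is larger).  Tests never require a remote
provider.

Trajectory dissimilarity is classic dynamic time warping over the
embedding sequences (terminal outcome codes included), Euclidean local
cost, no window constraint — on unit vectors Euclidean cost is monotone
in cosine distance, so the choice is nearly equivalent.  Clustering is
average-linkage (UPGMA) agglomeration on the precomputed distances, cut
at `cluster_k` clusters or at a distance threshold.  The agglomeration is
implemented directly (O(n³), trivially fast at trajectory counts) with an
explicit tie-break — among equal-distance merges, the pair with the
lexicographically smallest member sets wins — making the partition
invariant to input order; it agrees with standard library linkage
whenever distances are distinct.  A cluster's RR pools members' prefixes
as the exposure (per patient, the earliest qualifying prefix completion
sets the index and last-exposure dates) and members' terminal codes as
the outcome set.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline is meant for:

* demographics: sex 60.8% F / 39.2% M; race 80.9% White, 9.7% Black,
  9.4% other; ethnicity 90.2% non-Hispanic; age at window start from a
  truncated normal (mean 39.0, sd 25.3, bounds 18–95) — the marginals of
  a large ED-based adult cohort;
* per code, a latent first-occurrence time drawn from a homogeneous
  exponential process at a configured rate (events per patient-year) over
  a 3,652-day window, kept if inside the window;
* planted effects: once a trigger (code, or ordered code chain) has
  occurred, the target's hazard is multiplied by a configured factor for
  `max_lag` days (default 1,826, matching the analysis gap).  Sampling
  inverts the piecewise-constant cumulative hazard, so the law is exact;
* emission at day resolution (ties possible on purpose), with a
  configurable fraction of later duplicate rows and, for labs, extra
  normal-result rows — material for the preprocessing rules to remove.

Because the model is exponential throughout, the relative risk the
analysis targets for a single-trigger planted pair has a closed form:
the exposure-conditional probability of the target inside the lag window
over the *marginal* target probability (the comparison group is a
population sample, so its rate includes boosted trigger-carriers).  Both
terms are exponential integrals, implemented analytically and verified
against numerical quadrature and Monte-Carlo simulation in the tests.
The expected sequential support of a planted 3-code chain (a pair effect
plus a chain effect) is computed by numerical integration of the same
waiting-time densities.  Day rounding can merge adjacent dates and lose a
strict ordering, so observed support sits slightly below the continuous
prediction; the tests allow a few percent for this.

The reference conditions (`default_config`): 20,000 patients, 30 codes
across all four domains with first-occurrence rates between 0.002 and
0.065 per patient-year, three standalone planted pairs whose closed-form
expected RR is 5.5–5.9 (multipliers 30–35 on rare targets — strong,
specific associations of the kind that top published risk tables), and
two disjoint planted chains whose predicted sequential support (≈ 580 and
≈ 680) clears the 500-patient floor at this cohort size, so the published
support threshold is usable unscaled.  Null cohorts use the same code
rates with no planted effects.

What the generator does **not** emulate: realistic ICD-10 marginal
frequencies or code counts (30 codes versus ~12,600), age- or
sex-dependent incidence, correlated comorbidity beyond the planted
effects, coding-practice artifacts, censoring by death, or visit-driven
observation patterns.  Passing recovery tests therefore demonstrates the
pipeline's correctness and calibration under its own assumptions, not
clinical validity on real records.

## Problem sizes and numerical choices

Recovery and calibration experiments run at 20,000 patients × 30 codes —
large enough that every planted effect is detected with wide margins and
binomial noise on recovery quantities is a few percent, while a full
pipeline pass takes seconds.  Fisher and binomial tests delegate to
scipy's exact implementations and are verified against exhaustive
hypergeometric enumeration (all tables with total ≤ 40) and exact tail
sums (all n ≤ 30); DTW is verified against explicit warping-path
enumeration for sequence lengths ≤ 4.  Zero-margin contingency tables get
p = 1 by convention; an RR with a zero outcome cell gets the 0.5
continuity correction and a flag; degenerate inputs (empty sequences,
self-pairs, `max_len` < 3, k exceeding the trajectory count) raise
immediately.

## Known limitations

* Matching controls only sex, race and age decade; no regression
  adjustment for anything else, by design fidelity to the procedure.
* Controls' time-at-risk is not aligned with the exposed window in the
  default definition (see the null-bias note above).
* The ancestor restriction and support thresholds make the output depend
  on the configured outcome set; an empty or unrepresented outcome set
  yields an empty (warned) result, not an error.
* The offline embedding provider captures lexical, not semantic,
  similarity between code descriptions; clusters on real descriptions
  will differ from those produced by a learned text-embedding model.
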