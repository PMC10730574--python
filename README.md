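# trajmine

Temporal code-pair and trajectory mining for dementia risk from
longitudinal coded health records.

Dementia is usually studied through individual risk factors measured at a
single time point.  `trajmine` implements a data-driven temporal
alternative for biostatisticians and clinical informaticians working with
coded EHR extracts: it finds *directed* pairs of healthcare codes
(diagnoses, procedures, medications, abnormal labs) where one reliably
precedes the other, quantifies each pair with a demographically matched
relative risk, chains pairs into multi-step *trajectories* that terminate
in a dementia-related code, and groups trajectories into clusters by
dynamic time warping over embeddings of the codes' English descriptions.
Because real EHR extracts of this kind are confidential, the package
ships a synthetic-cohort generator with planted, analytically tractable
effects, so every stage can be validated against known ground truth.

## Method

For codes C1, C2 over patient first-occurrence timelines:

1. **Co-occurrence screen.** Two-sided Fisher exact test on the patient-level
   2×2 table of C1/C2 presence over the study window (p < 0.05), plus a
   positive-association filter (odds ratio > 1).
2. **Temporal orientation.** Among patients carrying both codes, an exact
   two-sided binomial test of whether C1's first occurrence precedes C2's
   more often than chance (date ties excluded); pairs without significant
   asymmetry are dropped.
3. **Matched relative risk.** Each exposed patient (C1, or a code-sequence
   prefix traversed with every gap ≤ 5 years) is matched to up to
   k = 10,000 patients of the same sex, race, and decade of life at the
   index event.  Pooling the matched samples,

       RR = (n_EO / n_E) / (n_CO / n_C)

   with the Katz log-interval 95% CI,
   exp(ln RR ± 1.96·√(1/n_EO − 1/n_E + 1/n_CO − 1/n_C)), and a two-sided
   normal p-value on ln RR.  Pairs survive if RR > 1 and p < 0.05 with
   Bonferroni correction over the tested family.
4. **Trajectories.** Significant pairs form a DAG (cycles broken at the
   weakest edge); paths of ≥ 3 codes ending in an outcome code, traversed
   sequentially by ≥ 500 patients with every consecutive gap ≤ 5 years,
   are scored with the same matched RR (prefix as exposure).
5. **Clustering.** Code descriptions are embedded as unit 256-vectors
   (deterministic offline hashing provider by default; any text-embedding
   callable can be plugged in), trajectory dissimilarity is classic DTW
   over the embedding sequences, and average-linkage agglomeration cuts at
   k clusters, each scored by a pooled matched RR.

## Worked example

The numbered scripts under `analysis/` run the reference experiment: a
synthetic cohort of 20,000 adults (60.8% female; 80.9% White, 9.7% Black;
age ≈ truncated normal, mean 39, sd 25.3) with 30 codes, three planted
directed pairs and two planted three-code chains ending in dementia codes.

```
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_screen_pairs.py
python analysis/04_matched_risk.py
python analysis/05_assemble_trajectories.py
python analysis/06_cluster_trajectories.py
python analysis/07_null_calibration.py
```

`04_matched_risk.py` prints (abridged):

```
Bonferroni family size: 16
significant directed pairs: 7
      E11 -> N18     RR   6.18 (95% CI 5.31-7.19)  [planted, expected 5.79]
      I10 -> I63     RR   6.00 (95% CI 5.17-6.96)  [planted, expected 5.85]
      F32 -> G62     RR   5.47 (95% CI 4.70-6.38)  [planted, expected 5.50]
      ...
```

All three planted pairs are recovered in the correct direction, with
estimates within a few percent of the generator's closed-form expected RR.
`05_assemble_trajectories.py` then recovers both planted chains verbatim:

```
trajectories with support >= 500: 2
  F41 -> F05 -> F03.90  support 673  RR 3.98 (95% CI 3.67-4.31)
  I25 -> I50 -> F01.50  support 592  RR 3.96 (95% CI 3.60-4.35)
```

and `07_null_calibration.py` confirms error control on cohorts with no
planted effects (screen pass rate 0.023 against the nominal 0.05 bound;
zero Bonferroni-significant pairs in 10 runs).

The same pipeline is available as a CLI over user-supplied delimited-text
event and demographics files:

```
trajmine run-all --config my_run.yaml
trajmine simulate|preprocess|pairs|risk|trajectories|cluster --config my_run.yaml
```

## Layout

```
src/trajmine/          library: event model, pair screening, matched risk,
                       trajectory assembly, embedding + DTW clustering,
                       synthetic cohort generator, pipeline + CLI
analysis/              numbered narrative drivers for the reference run
tests/                 pytest suite with independent brute-force oracles
scripts/acceptance.py  from-scratch recomputation of headline quantities
docs/methods.md        model, assumptions, parameter choices, limitations
```
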