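"""Shared configuration for the numbered analysis scripts.

One reference run: a 20,000-patient synthetic cohort with three planted
directed pairs (closed-form expected RR between 5 and 6) and two planted
three-code chains terminating in dementia codes, analysed at the published
thresholds (alpha = 0.05 at each screening step, Bonferroni at the RR
stage, 10,000 matched controls, 500-patient trajectory support, 5-year
maximum gap).
"""

from trajmine.pipeline import RunConfig

OUTDIR = "results/analysis"
SEED = 42


def run_config() -> RunConfig:
    return RunConfig(
        outdir=OUTDIR,
        master_seed=SEED,
        sim_n_patients=20000,
        events_path=f"{OUTDIR}/input/events.csv",
        demographics_path=f"{OUTDIR}/input/demographics.csv",
        outcome_codes=["F01.50", "F03.90"],
        min_support=500,
        cluster_k=2,
    )
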