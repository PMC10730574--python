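from __future__ import annotations

import pandas as pd
import pytest

from trajmine.event_model import build_timelines
from trajmine.matched_risk import _StratumIndex, child_seed, relative_risk
from trajmine.pair_screening import orient_pairs, screen_pairs
from trajmine.synthetic_cohort import default_config, generate_cohort

WINDOW = ("2013-01-01", "2022-12-31")


def make_cohort(event_rows, demo_rows, window=WINDOW, min_age=18.0,
                outcome_codes=("F03.90",), **kwargs):
    """Hand-built cohort from (pid, code, domain, date[, abnormal]) tuples."""
    events = pd.DataFrame(
        [r + (True,) * (5 - len(r)) for r in event_rows],
        columns=["patient_id", "code", "domain", "date", "abnormal"])
    events["date"] = pd.to_datetime(events["date"])
    demo = pd.DataFrame(demo_rows,
                        columns=["patient_id", "sex", "race", "birth_date"])
    demo["birth_date"] = pd.to_datetime(demo["birth_date"])
    return build_timelines(events, demo, window, min_age=min_age,
                           outcome_codes=outcome_codes, **kwargs)


@pytest.fixture(scope="session")
def planted_cohort():
    """The reference recovery conditions: 20,000 patients, 30 codes,
    3 planted pairs (closed-form expected RR > 5) and 2 planted chains."""
    cfg = default_config(n_patients=20000, master_seed=42)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def planted_pair_stage(planted_cohort):
    """Directed-pair screening plus matched RR estimates on the planted
    cohort, shared across recovery tests."""
    _, cohort, _ = planted_cohort
    directed = orient_pairs(cohort, screen_pairs(cohort))
    sidx = _StratumIndex(cohort)
    estimates = []
    for row in directed.itertuples(index=False):
        est = relative_risk(cohort, [row.c1], row.c2, k=10000,
                            seed=child_seed(42, "pair", row.c1, row.c2),
                            stratum_index=sidx)
        estimates.append(((row.c1, row.c2), est))
    return directed, estimates
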