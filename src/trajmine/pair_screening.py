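"""Screening and temporal orientation of co-occurring code pairs.

Step one tests every pairwise combination of codes (across all domains)
for patient-level co-occurrence with a two-sided Fisher exact test plus a
positive-association filter (odds ratio > 1): mutually exclusive codes
must not seed trajectories.  Step two orients each surviving pair with an
exact two-sided binomial test on which code's first occurrence precedes
the other's among patients carrying both; date ties carry no ordering
information and are excluded from the trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .event_model import Cohort


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Patient-level 2x2 table: a=both, b=code1 only, c=code2 only, d=neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class OrderingCounts:
    n_forward: int   # code1 strictly before code2
    n_backward: int  # code2 strictly before code1
    n_tied: int      # same date


def cooccurrence_table(cohort: Cohort, code1: str, code2: str) -> ContingencyTable2x2:
    """Patient-presence 2x2 table for two codes over the whole study period."""
    if code1 == code2:
        raise ValueError("self-pairs are undefined")
    p1 = cohort.dates_of(code1).notna().to_numpy()
    p2 = cohort.dates_of(code2).notna().to_numpy()
    a = int(np.sum(p1 & p2))
    b = int(np.sum(p1 & ~p2))
    c = int(np.sum(~p1 & p2))
    return ContingencyTable2x2(a, b, c, cohort.n_patients - a - b - c)


def fisher_exact_p(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value; any zero margin gives p = 1 by convention."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def ordering_counts(cohort: Cohort, code1: str, code2: str) -> OrderingCounts:
    d1 = cohort.dates_of(code1)
    d2 = cohort.dates_of(code2)
    both = d1.notna() & d2.notna()
    t1 = d1[both]
    t2 = d2[both]
    return OrderingCounts(n_forward=int((t1 < t2).sum()),
                          n_backward=int((t2 < t1).sum()),
                          n_tied=int((t1 == t2).sum()))


def direction_test(ordering: OrderingCounts, alpha_dir: float = 0.05,
                   ) -> tuple[Optional[str], float]:
    """Exact two-sided binomial test of temporal asymmetry.

    Returns ("forward"|"backward", p) when one ordering dominates at
    ``alpha_dir``; (None, p) when the pair stays undirected.
    """
    n = ordering.n_forward + ordering.n_backward
    if n == 0:
        return None, 1.0
    p = float(stats.binomtest(ordering.n_forward, n, 0.5,
                              alternative="two-sided").pvalue)
    if p >= alpha_dir:
        return None, p
    return ("forward" if ordering.n_forward >= ordering.n_backward
            else "backward"), p


def screen_pairs(cohort: Cohort, alpha_pair: float = 0.05,
                 min_pair_patients: int = 10) -> pd.DataFrame:
    """Step-one screen over all unordered code pairs.

    Keeps pairs with two-sided Fisher p < ``alpha_pair``, positive
    association (ad > bc) and at least ``min_pair_patients`` patients
    carrying both codes.  Output rows are lexicographic in (code1, code2),
    independent of timeline order.
    """
    codes = cohort.codes
    present = cohort.date_matrix[codes].notna().to_numpy()
    n = present.shape[0]
    both = present.T.astype(np.int64) @ present.astype(np.int64)
    totals = present.sum(axis=0)

    rows = []
    for i, c1 in enumerate(codes):
        for j in range(i + 1, len(codes)):
            a = int(both[i, j])
            if a < min_pair_patients:
                continue
            b = int(totals[i] - a)
            c = int(totals[j] - a)
            d = int(n - a - b - c)
            if a * d <= b * c:  # positive association only
                continue
            tab = ContingencyTable2x2(a, b, c, d)
            p = fisher_exact_p(tab)
            if p < alpha_pair:
                rows.append((c1, codes[j], a, b, c, d, p))
    return pd.DataFrame(rows, columns=["code1", "code2", "a", "b", "c", "d",
                                       "fisher_p"])


def orient_pairs(cohort: Cohort, candidates: pd.DataFrame,
                 alpha_dir: float = 0.05) -> pd.DataFrame:
    """Step-two orientation of screened pairs.

    Emits one row per pair that shows significant temporal asymmetry, with
    c1 -> c2 in the majority direction; undirected pairs are dropped.
    Columns mirror the candidate table plus ordering counts and binom_p.
    """
    rows = []
    for cand in candidates.itertuples(index=False):
        ordering = ordering_counts(cohort, cand.code1, cand.code2)
        direction, binom_p = direction_test(ordering, alpha_dir=alpha_dir)
        if direction is None:
            continue
        if direction == "forward":
            c1, c2 = cand.code1, cand.code2
            nf, nb = ordering.n_forward, ordering.n_backward
            b_only, c_only = cand.b, cand.c
        else:
            c1, c2 = cand.code2, cand.code1
            nf, nb = ordering.n_backward, ordering.n_forward
            b_only, c_only = cand.c, cand.b
        rows.append((c1, c2, cand.a, b_only, c_only, cand.d, cand.fisher_p,
                     nf, nb, ordering.n_tied, binom_p))
    df = pd.DataFrame(rows, columns=["c1", "c2", "a", "b", "c", "d", "fisher_p",
                                     "n_forward", "n_backward", "n_tied",
                                     "binom_p"])
    return df.sort_values(["c1", "c2"], kind="mergesort").reset_index(drop=True)
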