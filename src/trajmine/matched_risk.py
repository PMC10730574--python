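"""Demographically matched relative-risk estimation.

For each exposed patient (one who carries the exposure codes sequentially),
up to k comparison patients are drawn without replacement from the same
(sex, race, age-decade) stratum, the decade evaluated at the exposed
patient's index event.  Per-patient samples are pooled (union, multiplicity
removed) into one comparison group and

    RR = (n_exposed_outcome / n_exposed) / (n_control_outcome / n_control)

with a Katz log-interval 95% CI and a two-sided normal p-value on ln RR.
Controls count as outcome-positive if the outcome appears anywhere in
their record (conservative: biases RR toward 1); an index-aligned variant
is available via ``control_outcome="after_matched_index"``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .event_model import Cohort

DAYS_PER_DECADE = 3652.5
FIVE_YEARS_DAYS = 1826  # ceil(5 * 365.25)


def child_seed(master_seed: int, *key) -> int:
    """Deterministic per-estimate seed below 2**31, stable across runs."""
    digest = hashlib.sha256(repr((int(master_seed),) + key).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass(frozen=True)
class MatchStratum:
    sex: str
    race: str
    age_decade: int


@dataclass
class RiskEstimate:
    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_exposed: int
    n_exposed_outcome: int
    n_control: int
    n_control_outcome: int
    seed: int
    flags: list[str] = field(default_factory=list)
    n_shortfall: int = 0  # exposed patients whose stratum held < k candidates

    @property
    def defined(self) -> bool:
        return np.isfinite(self.rr)

    def to_dict(self) -> dict:
        return {
            "rr": self.rr, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_value, "n_exposed": self.n_exposed,
            "n_exposed_outcome": self.n_exposed_outcome,
            "n_control": self.n_control,
            "n_control_outcome": self.n_control_outcome,
            "seed": self.seed, "flags": list(self.flags),
            "n_shortfall": self.n_shortfall,
        }


def _day_values(series: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Datetime series -> (int64 days since epoch, presence mask)."""
    present = series.notna().to_numpy()
    days = series.to_numpy(dtype="datetime64[D]").astype("int64")
    return days, present


def exposed_patients(cohort: Cohort, exposure_codes: Sequence[str],
                     max_gap_days: int = FIVE_YEARS_DAYS) -> pd.DataFrame:
    """Patients carrying the exposure codes in order with bounded gaps.

    Dates must be strictly increasing along the code list with every
    consecutive gap <= ``max_gap_days``.  Returns a frame indexed by
    patient_id with ``index_day`` (first exposure code) and ``last_day``
    (last exposure code) as int64 days since epoch.
    """
    if len(exposure_codes) == 0:
        raise ValueError("exposure definition must be non-empty")
    days = []
    ok = np.ones(cohort.n_patients, dtype=bool)
    for code in exposure_codes:
        d, present = _day_values(cohort.dates_of(code))
        ok &= present
        days.append(d)
    mat = np.stack(days, axis=1)
    for col in range(1, mat.shape[1]):
        gap = mat[:, col] - mat[:, col - 1]
        ok &= (gap > 0) & (gap <= max_gap_days)
    return pd.DataFrame({"index_day": mat[ok, 0], "last_day": mat[ok, -1]},
                        index=pd.Index(cohort.patient_ids[ok],
                                       name="patient_id"))


class _StratumIndex:
    """Per-(sex, race) birth-day indices for fast decade matching."""

    def __init__(self, cohort: Cohort):
        demo = cohort.demographics
        self.birth_days = demo["birth_date"].to_numpy(
            dtype="datetime64[D]").astype("int64")
        self.groups: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        keys = pd.Series(list(zip(demo["sex"], demo["race"])),
                         index=demo.index)
        for key, idx in keys.groupby(keys).groups.items():
            pos = demo.index.get_indexer(idx)
            order = np.argsort(self.birth_days[pos], kind="stable")
            pos = pos[order]
            self.groups[key] = (self.birth_days[pos], pos)

    def candidates(self, sex: str, race: str, index_day: int,
                   birth_day: int) -> np.ndarray:
        """Positions of pool patients in the exposed patient's stratum."""
        group = self.groups.get((sex, race))
        if group is None:
            return np.empty(0, dtype=np.int64)
        births, pos = group
        decade = int(np.floor((index_day - birth_day) / DAYS_PER_DECADE))
        # same decade <=> birth day in (index - (dec+1)*3652.5, index - dec*3652.5]
        lo = index_day - (decade + 1) * DAYS_PER_DECADE
        hi = index_day - decade * DAYS_PER_DECADE
        i0 = int(np.searchsorted(births, lo, side="right"))
        i1 = int(np.searchsorted(births, hi, side="right"))
        return pos[i0:i1]


def sample_matched_controls(cohort: Cohort, exposed_id: str, index_day: int,
                            k: int, rng: np.random.Generator,
                            stratum_index: _StratumIndex | None = None,
                            ) -> np.ndarray:
    """Positions of up to k controls matched to one exposed patient."""
    sidx = stratum_index or _StratumIndex(cohort)
    loc = cohort.demographics.index.get_loc(exposed_id)
    row = cohort.demographics.iloc[loc]
    cand = sidx.candidates(row["sex"], row["race"], index_day,
                           sidx.birth_days[loc])
    cand = cand[cand != loc]
    if len(cand) > k:
        cand = rng.choice(cand, size=k, replace=False)
    return np.sort(cand)


def _outcome_presence(cohort: Cohort, outcome: Iterable[str],
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(earliest outcome day per patient, presence mask) over an outcome set."""
    best = np.full(cohort.n_patients, np.iinfo(np.int64).max, dtype=np.int64)
    any_present = np.zeros(cohort.n_patients, dtype=bool)
    for code in outcome:
        d, present = _day_values(cohort.dates_of(code))
        better = present & (d < best)
        best[better] = d[better]
        any_present |= present
    return best, any_present


def relative_risk(cohort: Cohort, exposure_codes: Sequence[str],
                  outcome: str | Iterable[str], k: int = 10000,
                  max_gap_days: int = FIVE_YEARS_DAYS, seed: int = 0,
                  control_outcome: str = "anywhere",
                  stratum_index: _StratumIndex | None = None) -> RiskEstimate:
    """Matched-cohort relative risk of the outcome following the exposure."""
    exposed = exposed_patients(cohort, exposure_codes, max_gap_days)
    return relative_risk_from_exposed(
        cohort, exposed, outcome, k=k, max_gap_days=max_gap_days, seed=seed,
        control_outcome=control_outcome, stratum_index=stratum_index)


def relative_risk_from_exposed(cohort: Cohort, exposed: pd.DataFrame,
                               outcome: str | Iterable[str], k: int = 10000,
                               max_gap_days: int = FIVE_YEARS_DAYS,
                               seed: int = 0,
                               control_outcome: str = "anywhere",
                               stratum_index: _StratumIndex | None = None,
                               ) -> RiskEstimate:
    """As :func:`relative_risk` but with a precomputed exposed set.

    ``exposed`` must carry ``index_day``/``last_day`` columns (int64 days);
    used directly by trajectory and cluster scoring, where the exposure is
    a code-sequence prefix or a union of prefixes.
    """
    outcome_set = {outcome} if isinstance(outcome, str) else set(outcome)
    out_day, out_present = _outcome_presence(cohort, outcome_set)

    flags: list[str] = []
    n_exposed = len(exposed)
    if n_exposed == 0:
        return RiskEstimate(np.nan, np.nan, np.nan, np.nan, 0, 0, 0, 0,
                            seed, ["no_exposed_patients"], 0)

    sidx = stratum_index or _StratumIndex(cohort)
    rng = np.random.default_rng(seed)
    demo = cohort.demographics
    exposed = exposed.sort_index()
    locs = demo.index.get_indexer(exposed.index)
    index_days = exposed["index_day"].to_numpy()
    last_days = exposed["last_day"].to_numpy()
    sexes = demo["sex"].to_numpy()
    races = demo["race"].to_numpy()

    pool_mask = np.zeros(cohort.n_patients, dtype=bool)
    n_shortfall = 0
    n_empty = 0
    aligned_comparisons = 0
    aligned_positives = 0
    for loc, idx_day in zip(locs, index_days):
        cand = sidx.candidates(sexes[loc], races[loc], int(idx_day),
                               int(sidx.birth_days[loc]))
        cand = cand[cand != loc]
        if len(cand) == 0:
            n_empty += 1
            continue
        if len(cand) > k:
            cand = rng.choice(cand, size=k, replace=False)
        else:
            n_shortfall += 1
        if control_outcome == "after_matched_index":
            aligned_comparisons += len(cand)
            aligned_positives += int(np.sum(out_present[cand]
                                            & (out_day[cand] > idx_day)))
        else:
            pool_mask[cand] = True
    if n_empty:
        flags.append("empty_strata")

    exposed_has_outcome = np.zeros(n_exposed, dtype=bool)
    present = out_present[locs]
    gap = out_day[locs] - last_days
    exposed_has_outcome = present & (gap > 0) & (gap <= max_gap_days)
    n_exposed_outcome = int(exposed_has_outcome.sum())

    if control_outcome == "after_matched_index":
        n_control = int(aligned_comparisons)
        n_control_outcome = int(aligned_positives)
        flags.append("index_aligned_controls")
    else:
        n_control = int(pool_mask.sum())
        n_control_outcome = int(np.sum(out_present & pool_mask))

    if n_control == 0:
        return RiskEstimate(np.nan, np.nan, np.nan, np.nan, n_exposed,
                            n_exposed_outcome, 0, 0, seed,
                            flags + ["no_controls"], n_shortfall)

    a, n1 = float(n_exposed_outcome), float(n_exposed)
    b, n0 = float(n_control_outcome), float(n_control)
    if n_exposed_outcome == 0 or n_control_outcome == 0:
        a += 0.5; n1 += 0.5; b += 0.5; n0 += 0.5
        flags.append("continuity_corrected")
    rr = (a / n1) / (b / n0)
    se = np.sqrt(max(1.0 / a - 1.0 / n1 + 1.0 / b - 1.0 / n0, 0.0))
    log_rr = np.log(rr)
    ci_low = float(np.exp(log_rr - 1.96 * se))
    ci_high = float(np.exp(log_rr + 1.96 * se))
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(log_rr) / se))
    else:
        p = 1.0 if rr == 1.0 else 0.0
    return RiskEstimate(float(rr), ci_low, ci_high, p, n_exposed,
                        n_exposed_outcome, n_control, n_control_outcome,
                        seed, flags, n_shortfall)


def katz_ci(rr: float, n_exposed_outcome: float, n_exposed: float,
            n_control_outcome: float, n_control: float,
            z: float = 1.96) -> tuple[float, float]:
    """Katz log-interval for a relative risk (closed form)."""
    se = np.sqrt(1.0 / n_exposed_outcome - 1.0 / n_exposed
                 + 1.0 / n_control_outcome - 1.0 / n_control)
    return float(np.exp(np.log(rr) - z * se)), float(np.exp(np.log(rr) + z * se))


def bonferroni_filter(estimates: Sequence[tuple[object, RiskEstimate]],
                      alpha: float = 0.05, m: int | None = None,
                      ) -> tuple[list[tuple[object, RiskEstimate]], int]:
    """Keep estimates with RR > 1 and p below the Bonferroni threshold.

    ``m`` is the family size (defaults to the number of estimates supplied);
    it is returned alongside the surviving subset for reporting.
    """
    estimates = list(estimates)
    if not estimates:
        return [], m or 0
    m = m if m is not None else len(estimates)
    threshold = alpha / m
    kept = [(key, est) for key, est in estimates
            if est.defined and est.rr > 1.0 and est.p_value < threshold]
    return kept, m
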