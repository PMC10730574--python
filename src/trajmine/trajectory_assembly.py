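"""Assembly of multi-step trajectories from significant directed pairs.

Significant oriented pairs form a directed graph; any residual cycles are
broken by repeatedly dropping the weakest in-cycle edge (largest RR-stage
p-value).  The graph is restricted to codes from which an outcome
(dementia-related) code is reachable, and trajectories are enumerated as
paths of >= 3 codes ending at an outcome node, each supported by at least
``min_support`` patients traversing the full code sequence in order with
every consecutive gap within the maximum lag.  Support is monotone
non-increasing under path extension, which makes prefix pruning exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .event_model import Cohort
from .matched_risk import (FIVE_YEARS_DAYS, RiskEstimate, _day_values,
                           child_seed, relative_risk)


@dataclass
class Trajectory:
    codes: tuple[str, ...]
    support: int
    risk: Optional[RiskEstimate] = None

    @property
    def terminal(self) -> str:
        return self.codes[-1]

    @property
    def prefix(self) -> tuple[str, ...]:
        return self.codes[:-1]

    def to_dict(self, vocabulary=None) -> dict:
        d = {"codes": list(self.codes), "support": self.support}
        if vocabulary is not None:
            d["descriptions"] = [vocabulary.description(c) for c in self.codes]
        if self.risk is not None:
            d["risk"] = self.risk.to_dict()
        return d


def build_pair_graph(pairs: pd.DataFrame) -> tuple[nx.DiGraph, list[tuple]]:
    """Directed graph of significant pairs, forced acyclic.

    ``pairs`` needs columns c1, c2, rr, p_value.  While a directed cycle
    remains, the in-cycle edge with the largest p-value is removed (ties:
    smallest rr, then lexicographic).  Returns the graph and the list of
    removed edges.
    """
    graph = nx.DiGraph()
    for row in pairs.itertuples(index=False):
        graph.add_edge(row.c1, row.c2, rr=float(row.rr), p=float(row.p_value))
    removed: list[tuple] = []
    while True:
        try:
            cycle = nx.find_cycle(graph, orientation="original")
        except nx.NetworkXNoCycle:
            break
        worst = max(
            ((u, v) for u, v, _ in cycle),
            key=lambda e: (graph.edges[e]["p"], -graph.edges[e]["rr"],
                           e[0], e[1]),
        )
        removed.append((worst[0], worst[1], graph.edges[worst]["p"]))
        graph.remove_edge(*worst)
    return graph, removed


def restrict_to_outcome_ancestors(graph: nx.DiGraph,
                                  outcome_codes: Iterable[str]) -> nx.DiGraph:
    """Keep only nodes lying on some directed path into an outcome code.

    Reverse breadth-first traversal from every outcome node present in the
    graph; the induced subgraph on {outcomes + their ancestors} is returned.
    """
    outcomes = [c for c in outcome_codes if c in graph]
    keep: set[str] = set(outcomes)
    for node in outcomes:
        keep |= nx.ancestors(graph, node)
    return graph.subgraph(keep).copy()


def count_support(cohort: Cohort, codes: Sequence[str],
                  max_gap_days: int = FIVE_YEARS_DAYS) -> int:
    """Patients whose first-occurrence dates of ``codes`` are strictly
    increasing in order with every consecutive gap <= ``max_gap_days``."""
    if len(codes) < 2:
        raise ValueError("support is defined for code lists of length >= 2")
    ok = np.ones(cohort.n_patients, dtype=bool)
    prev = None
    for code in codes:
        d, present = _day_values(cohort.dates_of(code))
        ok &= present
        if prev is not None:
            gap = d - prev
            ok &= (gap > 0) & (gap <= max_gap_days)
        prev = d
    return int(ok.sum())


def enumerate_trajectories(graph: nx.DiGraph, cohort: Cohort,
                           outcome_codes: Iterable[str],
                           min_support: int = 500, max_len: int = 5,
                           max_gap_days: int = FIVE_YEARS_DAYS,
                           k_controls: int = 10000, master_seed: int = 0,
                           score: bool = True) -> list[Trajectory]:
    """Enumerate supported outcome-terminated paths of length >= 3.

    Depth-bounded search extending paths edge-by-edge; any prefix whose
    sequential support drops below ``min_support`` is pruned (support
    monotonicity makes this lossless).  Outcome codes may only appear in
    terminal position.  Each emitted trajectory is scored by
    :func:`trajmine.matched_risk.relative_risk` with the non-terminal
    prefix as exposure, unless ``score`` is false.
    Output is ordered lexicographically by code sequence.
    """
    if max_len < 3:
        raise ValueError("max_len must be at least 3")
    outcomes = set(outcome_codes)
    results: list[Trajectory] = []

    def extend(path: list[str], support: int) -> None:
        node = path[-1]
        if node in outcomes:
            if len(path) >= 3:
                results.append(Trajectory(tuple(path), support))
            return  # outcomes are terminal only
        if len(path) == max_len:
            return
        for nxt in sorted(graph.successors(node)):
            if nxt in path:
                continue
            sup = count_support(cohort, path + [nxt], max_gap_days)
            if sup >= min_support:
                extend(path + [nxt], sup)

    for start in sorted(graph.nodes):
        if start in outcomes:
            continue
        extend([start], cohort.n_patients)

    results.sort(key=lambda t: t.codes)
    if score:
        for traj in results:
            traj.risk = relative_risk(
                cohort, list(traj.prefix), traj.terminal, k=k_controls,
                max_gap_days=max_gap_days,
                seed=child_seed(master_seed, "trajectory", traj.codes))
    return results


def trajectories_to_frame(trajectories: Sequence[Trajectory],
                          vocabulary=None) -> pd.DataFrame:
    """Tabular view mirroring the published trajectory tables."""
    rows = []
    for t in trajectories:
        desc = (" -> ".join(vocabulary.description(c) for c in t.codes)
                if vocabulary is not None else " -> ".join(t.codes))
        r = t.risk
        rows.append({
            "codes": " -> ".join(t.codes),
            "description": desc,
            "relative_risk": r.rr if r else np.nan,
            "ci_low": r.ci_low if r else np.nan,
            "ci_high": r.ci_high if r else np.nan,
            "p_value": r.p_value if r else np.nan,
            "support": t.support,
            "n_exposed": r.n_exposed if r else 0,
            "n_exposed_outcome": r.n_exposed_outcome if r else 0,
        })
    return pd.DataFrame(rows)
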