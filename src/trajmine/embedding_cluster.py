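"""Code-description embeddings, DTW distances and trajectory clustering.

Each code's English description is embedded as a unit vector (default
provider: deterministic character n-gram hashing into d = 256 signed
buckets, requiring no network or model weights; any callable mapping text
to a fixed-dimension vector can be plugged in).  Trajectories become
sequences of embeddings; pairwise dissimilarity is classic dynamic time
warping with Euclidean local cost, and trajectories are grouped by
average-linkage agglomeration on the resulting distance matrix with an
explicit lexicographic tie-break so cluster membership is independent of
input order.  Each cluster is scored with the same matched-cohort relative
risk as individual trajectories, pooling its members' prefixes as the
exposure and its members' terminal codes as the outcome set.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .event_model import Cohort, CodeVocabulary
from .matched_risk import (FIVE_YEARS_DAYS, RiskEstimate, child_seed,
                           exposed_patients, relative_risk_from_exposed)
from .trajectory_assembly import Trajectory

EmbeddingProvider = Callable[[str], np.ndarray]


class HashingEmbedder:
    """Deterministic offline text embedder.

    Character n-grams (default n = 3, on the lowercased text padded with
    spaces) are hashed into ``dim`` signed buckets; the bucket vector is
    L2-normalised.  Similar descriptions share n-grams and land close in
    cosine/Euclidean terms — a stand-in with the same interface and
    determinism guarantees as any external embedding service.
    """

    def __init__(self, dim: int = 256, ngram: int = 3):
        if dim < 1:
            raise ValueError("embedding dimension must be positive")
        self.dim = dim
        self.ngram = ngram

    def __call__(self, text: str) -> np.ndarray:
        padded = " " + text.lower().strip() + " "
        if len(padded) < self.ngram:
            padded = padded.ljust(self.ngram)
        vec = np.zeros(self.dim)
        for i in range(len(padded) - self.ngram + 1):
            gram = padded[i:i + self.ngram]
            h = hashlib.blake2b(gram.encode(), digest_size=8).digest()
            value = int.from_bytes(h, "big")
            bucket = value % self.dim
            sign = 1.0 if (value >> 32) & 1 else -1.0
            vec[bucket] += sign
        norm = np.linalg.norm(vec)
        if norm == 0.0:  # pathological all-cancelling text
            vec[0] = 1.0
            norm = 1.0
        return vec / norm


def embed_codes(vocabulary: CodeVocabulary,
                provider: Optional[EmbeddingProvider] = None,
                dim: int = 256) -> dict[str, np.ndarray]:
    """Embed every vocabulary code's description as a unit d-vector."""
    provider = provider or HashingEmbedder(dim=dim)
    out: dict[str, np.ndarray] = {}
    failures: list[str] = []
    for code in sorted(vocabulary.entries):
        try:
            vec = np.asarray(provider(vocabulary.description(code)), dtype=float)
        except Exception:
            failures.append(code)
            continue
        if vec.ndim != 1 or vec.shape[0] != dim:
            failures.append(code)
            continue
        norm = np.linalg.norm(vec)
        out[code] = vec / norm if norm > 0 else vec
    if failures:
        raise RuntimeError(f"embedding provider failed for codes: {failures}")
    return out


def dtw_distance(seq1: np.ndarray, seq2: np.ndarray) -> float:
    """Classic dynamic time warping with Euclidean local cost.

    D(i,j) = cost(i,j) + min(D(i-1,j), D(i,j-1), D(i-1,j-1)), D(0,0) = 0,
    no window constraint; symmetric in its arguments.
    """
    seq1 = np.atleast_2d(np.asarray(seq1, dtype=float))
    seq2 = np.atleast_2d(np.asarray(seq2, dtype=float))
    if seq1.shape[0] == 0 or seq2.shape[0] == 0:
        raise ValueError("DTW is undefined for empty sequences")
    cost = cdist(seq1, seq2)
    m, n = cost.shape
    acc = np.full((m + 1, n + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            acc[i, j] = cost[i - 1, j - 1] + min(acc[i - 1, j], acc[i, j - 1],
                                                 acc[i - 1, j - 1])
    return float(acc[m, n])


def trajectory_distance_matrix(trajectories: Sequence[Trajectory],
                               embeddings: dict[str, np.ndarray]) -> np.ndarray:
    """All-pairs DTW distances between trajectories' embedding sequences.

    Terminal outcome codes are part of the embedded sequence.
    """
    seqs = [np.stack([embeddings[c] for c in t.codes]) for t in trajectories]
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = dtw_distance(seqs[i], seqs[j])
    return dist


def average_linkage_clusters(dist: np.ndarray, k: Optional[int] = None,
                             threshold: Optional[float] = None,
                             ) -> list[list[int]]:
    """UPGMA agglomeration on a precomputed distance matrix.

    Inter-cluster distance is the mean of the original pairwise distances.
    Equal-distance merges are broken by the lexicographically smallest
    (sorted-member-tuple) pair, so the partition is invariant to input
    permutation.  Cut at ``k`` clusters or where the next merge would
    exceed ``threshold``.
    """
    n = dist.shape[0]
    if dist.shape != (n, n) or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    if k is None and threshold is None:
        raise ValueError("provide k or a distance threshold")
    if k is not None and (k < 1 or k > n):
        raise ValueError(f"k={k} incompatible with {n} trajectories")
    clusters: list[tuple[int, ...]] = [(i,) for i in range(n)]
    while len(clusters) > 1:
        if k is not None and len(clusters) == k:
            break
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                ci, cj = clusters[i], clusters[j]
                d = float(dist[np.ix_(ci, cj)].mean())
                cand = (d, min(ci, cj), max(ci, cj))
                if best is None or cand < best:
                    best = cand
        if threshold is not None and best[0] > threshold:
            break
        a, b = best[1], best[2]
        clusters = [c for c in clusters if c not in (a, b)]
        clusters.append(tuple(sorted(a + b)))
        clusters.sort()
    return [list(c) for c in sorted(clusters)]


@dataclass
class TrajectoryCluster:
    member_indices: list[int]
    members: list[Trajectory]
    medoid: int  # index into ``members``
    risk: Optional[RiskEstimate] = None

    def to_dict(self, vocabulary=None) -> dict:
        return {
            "members": [t.to_dict(vocabulary) for t in self.members],
            "medoid": self.medoid,
            "medoid_codes": list(self.members[self.medoid].codes),
            "risk": self.risk.to_dict() if self.risk else None,
        }


def cluster_risk(cohort: Cohort, members: Sequence[Trajectory],
                 k_controls: int = 10000,
                 max_gap_days: int = FIVE_YEARS_DAYS,
                 seed: int = 0) -> RiskEstimate:
    """Pooled matched-cohort RR for a cluster.

    Exposed = patients traversing the non-terminal prefix of at least one
    member (index/last dates from the earliest qualifying prefix);
    outcome = any member's terminal code.
    """
    frames = []
    for t in members:
        frames.append(exposed_patients(cohort, list(t.prefix), max_gap_days))
    pooled = pd.concat(frames)
    pooled = (pooled.sort_values(["last_day", "index_day"])
              .groupby(level=0).first())
    outcome_set = {t.terminal for t in members}
    return relative_risk_from_exposed(cohort, pooled, outcome_set,
                                      k=k_controls, max_gap_days=max_gap_days,
                                      seed=seed)


def cluster_trajectories(cohort: Cohort, trajectories: Sequence[Trajectory],
                         embeddings: dict[str, np.ndarray],
                         k: Optional[int] = None,
                         threshold: Optional[float] = None,
                         k_controls: int = 10000,
                         max_gap_days: int = FIVE_YEARS_DAYS,
                         master_seed: int = 0,
                         score: bool = True,
                         ) -> tuple[list[TrajectoryCluster], np.ndarray]:
    """Full clustering stage: DTW distances, agglomeration, cluster RRs."""
    if len(trajectories) == 0:
        raise ValueError("no trajectories to cluster")
    dist = trajectory_distance_matrix(trajectories, embeddings)
    parts = average_linkage_clusters(dist, k=k, threshold=threshold)
    clusters = []
    for part in parts:
        members = [trajectories[i] for i in part]
        sums = dist[np.ix_(part, part)].sum(axis=1)
        medoid = int(np.argmin(sums))  # ties: smallest index
        risk = None
        if score:
            key = tuple(tuple(t.codes) for t in members)
            risk = cluster_risk(cohort, members, k_controls=k_controls,
                                max_gap_days=max_gap_days,
                                seed=child_seed(master_seed, "cluster", key))
        clusters.append(TrajectoryCluster(part, members, medoid, risk))
    return clusters, dist
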