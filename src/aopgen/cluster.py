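"""Levenshtein distances and Butina sphere-exclusion clustering.

Candidate peptides that survive the filter cascade are grouped by edit
distance and one representative — the cluster centroid, i.e. the sequence
with the most neighbours at formation time — is kept per cluster.

Two neighbour-predicate dialects exist in circulating sphere-exclusion
implementations (strict ``d < t`` and inclusive ``d <= t``); with integer
edit distances the choice matters, so both are supported and tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .seqdata import PeptideCorpus


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


@dataclass
class DistanceMatrix:
    """Condensed pairwise integer distances in scipy ``squareform`` order."""

    n: int
    condensed: np.ndarray  # length n*(n-1)/2
    items: list[str] = field(default_factory=list)

    def get(self, i: int, j: int) -> int:
        if i == j:
            return 0
        if i > j:
            i, j = j, i
        return int(self.condensed[self.n * i - i * (i + 1) // 2 + (j - i - 1)])

    def square(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.condensed)


def pairwise_distances(corpus: PeptideCorpus | list[str]) -> DistanceMatrix:
    seqs = corpus.sequences if isinstance(corpus, PeptideCorpus) else list(corpus)
    n = len(seqs)
    if n < 1:
        raise ValueError("need at least one sequence")
    cond = np.empty(n * (n - 1) // 2, dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            cond[k] = levenshtein(seqs[i], seqs[j])
            k += 1
    return DistanceMatrix(n=n, condensed=cond, items=seqs)


@dataclass
class Cluster:
    centroid: int
    members: list[int]  # includes the centroid


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold: float
    predicate: str
    recount: str

    @property
    def assignment(self) -> np.ndarray:
        n = sum(len(c.members) for c in self.clusters)
        out = np.full(n, -1, dtype=int)
        for cid, c in enumerate(self.clusters):
            out[c.members] = cid
        return out


def butina_cluster(
    dist: DistanceMatrix,
    threshold: float = 2.0,
    predicate: str = "strict",
    recount: str = "dynamic",
) -> ClusterResult:
    """Sphere-exclusion clustering over a precomputed distance matrix.

    Repeatedly promotes the unassigned item with the most (unassigned)
    neighbours to centroid and absorbs its unassigned neighbours; ties go to
    the lowest index; singletons end up their own centroids.

    predicate: "strict" uses d < threshold, "inclusive" d <= threshold.
    recount: "dynamic" recounts neighbours among unassigned items at every
    selection; "static" ranks by the original full-neighbourhood counts.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if predicate not in ("strict", "inclusive"):
        raise ValueError("predicate must be 'strict' or 'inclusive'")
    if recount not in ("dynamic", "static"):
        raise ValueError("recount must be 'dynamic' or 'static'")
    n = dist.n
    if len(dist.condensed) != n * (n - 1) // 2:
        raise ValueError("condensed distance matrix has wrong length")
    D = dist.square() if n > 1 else np.zeros((1, 1))
    neigh = (D < threshold) if predicate == "strict" else (D <= threshold)
    np.fill_diagonal(neigh, False)
    static_counts = neigh.sum(axis=1)
    unassigned = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while unassigned.any():
        if recount == "dynamic":
            counts = (neigh & unassigned[None, :]).sum(axis=1)
        else:
            counts = static_counts
        masked = np.where(unassigned, counts, -1)
        centroid = int(masked.argmax())  # argmax takes the lowest index on ties
        members = [centroid] + [
            int(j) for j in np.flatnonzero(neigh[centroid] & unassigned) if j != centroid
        ]
        unassigned[members] = False
        clusters.append(Cluster(centroid=centroid, members=sorted(members)))
    return ClusterResult(clusters=clusters, threshold=threshold,
                         predicate=predicate, recount=recount)


def select_centroids(result: ClusterResult, corpus: PeptideCorpus) -> PeptideCorpus:
    """One representative per cluster, in cluster-formation order."""
    n = sum(len(c.members) for c in result.clusters)
    if n != len(corpus):
        raise ValueError("cluster result does not match corpus size")
    return PeptideCorpus(
        [corpus[c.centroid] for c in result.clusters],
        name=corpus.name + "/centroids",
    )


def cluster_table(result: ClusterResult, corpus: PeptideCorpus) -> "pandas.DataFrame":
    import pandas as pd

    rows = []
    for cid, c in enumerate(result.clusters):
        for m in c.members:
            rows.append({"cluster_id": cid, "is_centroid": m == c.centroid,
                         "sequence": corpus[m].sequence})
    return pd.DataFrame(rows)
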