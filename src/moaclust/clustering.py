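"""Maximal-dissimilarity partitioning and cluster-count selection.

The clustering is seeded: the first representative is a chosen seed
compound, and each subsequent representative is the compound whose maximum
similarity to the representatives already picked is smallest (MaxMin
diverse selection).  Every compound is then assigned to its most similar
representative.  Because the greedy representatives are nested — the first
``n`` picks of a long run are exactly the picks of a shorter run — a single
selection pass supports the whole cluster-count grid.

The number of clusters ``n`` is chosen from the average self-similarity
curve avg-s(n) (mean over clusters of the mean pairwise within-cluster
similarity, singletons contributing 1): the selected ``n`` is where the
biggest decrease avg-s(n−1) − avg-s(n) occurs.  On curves with no decrease
the same argmax (i.e. the smallest increase) is returned with a warning.

Partitions are compared by the pair-based Tanimoto c/(a+b−c), where a and b
count co-clustered compound pairs in each partition and c the pairs
co-clustered in both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .descriptors import DescriptorSet, SimilarityMatrix


@dataclass
class ClusterSet:
    """One seeded partition of a training library."""

    set_id: DescriptorSet
    centers: tuple[str, ...]
    assignment: dict[str, int]
    seed_index: int = 0

    def __post_init__(self):
        self.centers = tuple(self.centers)
        n = self.n_clusters
        counts = [0] * n
        for cid, k in self.assignment.items():
            if not (0 <= k < n):
                raise ValueError(f"cluster index {k} out of range for {cid}")
            counts[k] += 1
        for i, c in enumerate(self.centers):
            if self.assignment.get(c) != i:
                raise ValueError(f"center {c!r} not assigned to its own cluster {i}")
        if any(c == 0 for c in counts):
            raise ValueError("empty cluster in partition")

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def members(self, cluster_index: int) -> list[str]:
        return [cid for cid, k in self.assignment.items() if k == cluster_index]

    def clusters(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_clusters)]
        for cid, k in self.assignment.items():
            out[k].append(cid)
        return out


@dataclass
class AvgSCurve:
    """avg-s(n) over the cluster-count grid, plus the chosen count."""

    n_values: tuple[int, ...]
    avg_s: tuple[float, ...]
    chosen_n: int
    warned_no_drop: bool = False

    def drops(self) -> dict[int, float]:
        """avg-s(n−1) − avg-s(n) for each n ≥ 2 of the grid."""
        return {
            n: self.avg_s[i - 1] - self.avg_s[i]
            for i, n in enumerate(self.n_values)
            if i > 0
        }


def select_centers(
    sim: SimilarityMatrix, n_max: int, seed_compound: str
) -> list[str]:
    """Greedy MaxMin selection of ``n_max`` cluster representatives.

    ``centers[0]`` is the seed compound; each next representative is the
    compound minimizing its maximum similarity to those already chosen
    (ties broken by input order).
    """
    n = sim.n
    if not 1 <= n_max <= n:
        raise ValueError(f"n_max must be in [1, {n}], got {n_max}")
    seed = sim.index(seed_compound)
    chosen = [seed]
    # max similarity of every compound to the chosen set
    max_sim = sim.values[:, seed].copy()
    max_sim[seed] = np.inf  # never re-pick
    for _ in range(1, n_max):
        nxt = int(np.argmin(max_sim))  # argmin takes the first = lowest index
        chosen.append(nxt)
        np.maximum(max_sim, sim.values[:, nxt], out=max_sim)
        max_sim[nxt] = np.inf
    return [sim.ids[i] for i in chosen]


def partition(
    sim: SimilarityMatrix, centers: Sequence[str], seed_index: int = 0
) -> ClusterSet:
    """Assign every compound to its most similar representative.

    Ties go to the earlier representative in selection order; the
    representatives themselves always belong to their own cluster.
    """
    if not centers:
        raise ValueError("centers must be non-empty")
    cidx = [sim.index(c) for c in centers]
    # argmax returns the first maximum -> earliest center wins ties
    assign = np.argmax(sim.values[:, cidx], axis=1)
    for k, ci in enumerate(cidx):
        assign[ci] = k
    return ClusterSet(
        set_id=sim.set_id,
        centers=tuple(centers),
        assignment={cid: int(k) for cid, k in zip(sim.ids, assign)},
        seed_index=seed_index,
    )


def _avg_s_from_assignment(values: np.ndarray, assign: np.ndarray, n_clusters: int) -> float:
    order = np.argsort(assign, kind="stable")
    sorted_assign = assign[order]
    boundaries = np.searchsorted(sorted_assign, np.arange(n_clusters + 1))
    means = np.empty(n_clusters)
    for k in range(n_clusters):
        idx = order[boundaries[k] : boundaries[k + 1]]
        m = len(idx)
        if m <= 1:
            means[k] = 1.0  # a lone molecule is perfectly self-similar
        else:
            sub = values[np.ix_(idx, idx)]
            means[k] = (sub.sum() - np.trace(sub)) / (m * (m - 1))
    return float(means.mean())


def avg_self_similarity(cs: ClusterSet, sim: SimilarityMatrix) -> float:
    """Mean over clusters of the mean pairwise within-cluster similarity."""
    assign = np.array([cs.assignment[cid] for cid in sim.ids])
    if len(assign) != len(cs.assignment):
        raise ValueError("cluster set does not cover the similarity matrix")
    return _avg_s_from_assignment(sim.values, assign, cs.n_clusters)


def pick_biggest_drop(avg_s: Sequence[float]) -> tuple[int, bool]:
    """The cluster count with the biggest decrease avg-s(n−1) − avg-s(n).

    ``avg_s[i]`` is the value for n = i+1.  Ties go to the smaller n.
    Returns ``(chosen_n, warned)``; ``warned`` is True when no decrease
    exists anywhere and the smallest increase was returned instead.
    """
    if len(avg_s) < 2:
        raise ValueError("need avg-s for at least n = 1 and n = 2")
    diffs = [avg_s[i - 1] - avg_s[i] for i in range(1, len(avg_s))]
    best = int(np.argmax(diffs))  # first maximum -> smallest n on ties
    return best + 2, diffs[best] <= 0


def choose_cluster_count(
    sim: SimilarityMatrix, n_max: int, seed_compound: str
) -> AvgSCurve:
    """Sweep n = 1..n_max using nested greedy representatives and select
    the count at the biggest avg-s drop."""
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    centers = select_centers(sim, n_max, seed_compound)
    cidx = [sim.index(c) for c in centers]
    n = sim.n
    values = sim.values
    assign = np.zeros(n, dtype=int)
    best = values[:, cidx[0]].copy()
    avg_s = []
    for k, ci in enumerate(cidx):
        if k > 0:
            better = values[:, ci] > best  # strict: earlier center keeps ties
            assign[better] = k
            best[better] = values[better, ci]
            assign[ci] = k
            best[ci] = 1.0
        avg_s.append(_avg_s_from_assignment(values, assign, k + 1))
    chosen_n, warned = pick_biggest_drop(avg_s)
    if warned:
        warnings.warn(
            "avg-s never decreases on the cluster-count grid; choosing the "
            f"smallest increase (n = {chosen_n})",
            stacklevel=2,
        )
    return AvgSCurve(
        n_values=tuple(range(1, n_max + 1)),
        avg_s=tuple(avg_s),
        chosen_n=chosen_n,
        warned_no_drop=warned,
    )


def cluster_centre(members: Sequence[str], sim: SimilarityMatrix) -> str:
    """Medoid: the member maximizing mean similarity to its co-members.

    Singletons are their own centre; ties go to the earliest member in
    input order.
    """
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return members[0]
    idx = [sim.index(m) for m in members]
    sub = sim.values[np.ix_(idx, idx)]
    mean_to_others = (sub.sum(axis=1) - np.diag(sub)) / (len(idx) - 1)
    return members[int(np.argmax(mean_to_others))]


def _co_clustered_pairs(assignment: Mapping[str, int]) -> set[tuple[str, str]]:
    by_cluster: dict[int, list[str]] = {}
    for cid, k in assignment.items():
        by_cluster.setdefault(k, []).append(cid)
    pairs: set[tuple[str, str]] = set()
    for members in by_cluster.values():
        for a, b in combinations(sorted(members), 2):
            pairs.add((a, b))
    return pairs


def cluster_set_similarity(p1: ClusterSet, p2: ClusterSet) -> float:
    """Pair-based Tanimoto c/(a+b−c) between two partitions.

    a, b = number of co-clustered compound pairs in each partition, c = in
    both.  Two all-singleton partitions (a = b = 0) count as identical.
    """
    if set(p1.assignment) != set(p2.assignment):
        raise ValueError("partitions cover different compound universes")
    pairs1 = _co_clustered_pairs(p1.assignment)
    pairs2 = _co_clustered_pairs(p2.assignment)
    a, b = len(pairs1), len(pairs2)
    if a == 0 and b == 0:
        return 1.0
    c = len(pairs1 & pairs2)
    return c / (a + b - c)


def restrict_to_common(cs: ClusterSet, compound_ids: set[str]) -> ClusterSet:
    """Project a partition onto a compound subset (for cross-split
    comparisons); empty clusters are dropped and centres re-derived as the
    first remaining member in centre order."""
    kept = {cid: k for cid, k in cs.assignment.items() if cid in compound_ids}
    old_clusters: dict[int, list[str]] = {}
    for cid, k in kept.items():
        old_clusters.setdefault(k, []).append(cid)
    centers: list[str] = []
    assignment: dict[str, int] = {}
    for old_k in sorted(old_clusters):
        members = old_clusters[old_k]
        centre = cs.centers[old_k] if cs.centers[old_k] in compound_ids else members[0]
        new_k = len(centers)
        centers.append(centre)
        for cid in members:
            assignment[cid] = new_k
    return ClusterSet(
        set_id=cs.set_id,
        centers=tuple(centers),
        assignment=assignment,
        seed_index=cs.seed_index,
    )


def export_partition_csv(cs: ClusterSet, path) -> None:
    """Serialize a partition as ``compound_id,cluster_index,is_center``."""
    from .chem_io import write_records_csv

    center_set = set(cs.centers)
    rows = [
        {
            "compound_id": cid,
            "cluster_index": k,
            "is_center": int(cid in center_set),
        }
        for cid, k in cs.assignment.items()
    ]
    write_records_csv(rows, path, columns=["compound_id", "cluster_index", "is_center"])


def export_avg_s_csv(curve: AvgSCurve, path) -> None:
    """Serialize an avg-s curve as ``n,avg_s,drop``."""
    from .chem_io import write_records_csv

    drops = curve.drops()
    rows = [
        {"n": n, "avg_s": s, "drop": drops.get(n, "")}
        for n, s in zip(curve.n_values, curve.avg_s)
    ]
    write_records_csv(rows, path, columns=["n", "avg_s", "drop"])
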