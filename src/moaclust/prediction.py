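"""Nearest-cluster interaction prediction and its random baseline.

A query compound is scored against every eligible cluster (those with at
least ``min_cluster_size`` members under the active unknown-handling mode)
using one of three search rules: the cluster holding the single most
similar compound, the cluster whose centre (medoid) is most similar, or
the cluster with the highest average member similarity.  The predominant
interaction of the winning cluster is transferred to the query; the
prediction abstains when no cluster is eligible, when the winning score is
below the similarity threshold, or when the winning cluster has no unique
predominant label at the chosen level.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotation import (
    PredominanceProfile,
    cluster_profiles,
    predominant_label,
    profile_size,
)
from .chem_io import CompoundRecord, InteractionLabel
from .clustering import ClusterSet, cluster_centre
from .descriptors import (
    ContinuousScaler,
    DescriptorVector,
    SimilarityMatrix,
    similarity,
)


class SearchMethod(enum.Enum):
    MOST_SIMILAR_COMPOUND = "MOST_SIMILAR_COMPOUND"
    CLUSTER_CENTRE = "CLUSTER_CENTRE"
    AVERAGE_SIMILARITY = "AVERAGE_SIMILARITY"


@dataclass(frozen=True)
class PredictionConfig:
    """How the nearest cluster is found and when a prediction is made.

    ``similarity_threshold=None`` disables similarity-based abstention.
    ``include_unknown`` controls whether unknown-interaction compounds
    count in cluster sizes and label denominators (they always remain in
    the clustering itself).
    """

    method: SearchMethod = SearchMethod.CLUSTER_CENTRE
    min_cluster_size: int = 1
    level: float = 2.0 / 3.0
    similarity_threshold: float | None = None
    include_unknown: bool = True

    def __post_init__(self):
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("level must be in [0, 1]")
        if self.similarity_threshold is not None and not (
            0.0 <= self.similarity_threshold <= 1.0
        ):
            raise ValueError("similarity_threshold must be in [0, 1]")


@dataclass
class PredictionResult:
    """Outcome for one query; ``predicted`` is None on abstention."""

    query_id: str
    cluster_index: int | None
    similarity: float
    predicted: InteractionLabel | None
    correct: bool | None = None

    @property
    def abstained(self) -> bool:
        return self.predicted is None


class ClusterScorer:
    """Precomputed per-cluster data for scoring many queries cheaply.

    Query similarity vectors must be aligned with ``train_sim.ids``.
    Scores use all cluster members regardless of mode; the mode affects
    only size eligibility and label profiles.
    """

    def __init__(
        self,
        cs: ClusterSet,
        train_sim: SimilarityMatrix,
        records: Mapping[str, CompoundRecord],
        include_unknown: bool = True,
    ):
        self.cs = cs
        self.train_sim = train_sim
        self.include_unknown = include_unknown
        clusters = cs.clusters()
        self.member_idx = [
            np.array([train_sim.index(cid) for cid in members])
            for members in clusters
        ]
        self.medoid_idx = np.array(
            [train_sim.index(cluster_centre(members, train_sim)) for members in clusters]
        )
        self.profiles: list[PredominanceProfile] = cluster_profiles(
            cs, records, include_unknown
        )
        self.sizes = np.array([profile_size(p) for p in self.profiles])

    @property
    def n_clusters(self) -> int:
        return self.cs.n_clusters

    def eligible(self, min_cluster_size: int) -> np.ndarray:
        return np.flatnonzero(self.sizes >= min_cluster_size)

    def scores(self, query_sims: np.ndarray, method: SearchMethod) -> np.ndarray:
        """Per-cluster score of one query under one search rule."""
        if method is SearchMethod.CLUSTER_CENTRE:
            return query_sims[self.medoid_idx]
        if method is SearchMethod.MOST_SIMILAR_COMPOUND:
            return np.array([query_sims[idx].max() for idx in self.member_idx])
        if method is SearchMethod.AVERAGE_SIMILARITY:
            return np.array([query_sims[idx].mean() for idx in self.member_idx])
        raise ValueError(f"unknown search method {method!r}")

    def predominant(self, cluster_index: int, level: float) -> InteractionLabel | None:
        return predominant_label(self.profiles[cluster_index], level)


def nearest_cluster_from_sims(
    query_sims: np.ndarray, scorer: ClusterScorer, cfg: PredictionConfig
) -> tuple[int, float] | None:
    """Argmax cluster and score among eligible clusters; ties go to the
    lower cluster index; None when no cluster passes the size filter."""
    eligible = scorer.eligible(cfg.min_cluster_size)
    if eligible.size == 0:
        return None
    scores = scorer.scores(query_sims, cfg.method)[eligible]
    best = int(np.argmax(scores))  # first maximum -> lowest cluster index
    return int(eligible[best]), float(scores[best])


def nearest_cluster(
    query: DescriptorVector,
    cs: ClusterSet,
    training: Mapping[str, DescriptorVector],
    cfg: PredictionConfig,
    train_sim: SimilarityMatrix,
    records: Mapping[str, CompoundRecord],
    scaler: ContinuousScaler | None = None,
) -> tuple[int, float] | None:
    """Convenience single-query wrapper around :class:`ClusterScorer`."""
    if query.set_id != cs.set_id:
        raise ValueError("query descriptor set does not match the cluster set")
    sims = np.array([similarity(query, training[cid], scaler) for cid in train_sim.ids])
    scorer = ClusterScorer(cs, train_sim, records, cfg.include_unknown)
    return nearest_cluster_from_sims(sims, scorer, cfg)


def predict_from_sims(
    query_id: str,
    query_sims: np.ndarray,
    scorer: ClusterScorer,
    cfg: PredictionConfig,
    query_labels: frozenset[InteractionLabel] | None = None,
) -> PredictionResult:
    """Predict one query from its similarity vector to the training set."""
    found = nearest_cluster_from_sims(query_sims, scorer, cfg)
    if found is None:
        return PredictionResult(query_id, None, float("nan"), None)
    k, score = found
    if cfg.similarity_threshold is not None and score < cfg.similarity_threshold:
        return PredictionResult(query_id, k, score, None)
    label = scorer.predominant(k, cfg.level)
    correct = None
    if label is not None and query_labels:
        correct = label in query_labels
    return PredictionResult(query_id, k, score, label, correct)


def predict(
    query: CompoundRecord,
    query_vector: DescriptorVector,
    cs: ClusterSet,
    training: Mapping[str, DescriptorVector],
    records: Mapping[str, CompoundRecord],
    cfg: PredictionConfig,
    train_sim: SimilarityMatrix,
    scaler: ContinuousScaler | None = None,
) -> PredictionResult:
    """Single-query end-to-end prediction (see :func:`predict_from_sims`)."""
    sims = np.array(
        [similarity(query_vector, training[cid], scaler) for cid in train_sim.ids]
    )
    scorer = ClusterScorer(cs, train_sim, records, cfg.include_unknown)
    return predict_from_sims(query.compound_id, sims, scorer, cfg, query.labels)


def evaluate(
    results: Sequence[PredictionResult],
    records: Mapping[str, CompoundRecord],
) -> dict[str, float]:
    """Accuracy metrics over a set of labelled queries.

    ``pct_correct_all`` counts abstentions as incorrect (the headline
    metric); ``pct_correct_predicted`` is over non-abstained queries only
    (NaN when everything abstained); ``n_predicted`` counts non-abstained
    queries.
    """
    if not results:
        raise ValueError("no prediction results to evaluate")
    n_correct = 0
    n_predicted = 0
    for res in results:
        rec = records[res.query_id]
        if not rec.labels:
            raise ValueError(f"query {res.query_id!r} has no known labels")
        if res.predicted is None:
            continue
        n_predicted += 1
        if res.predicted in rec.labels:
            n_correct += 1
    n = len(results)
    return {
        "pct_correct_all": 100.0 * n_correct / n,
        "pct_correct_predicted": (
            100.0 * n_correct / n_predicted if n_predicted else float("nan")
        ),
        "n_predicted": float(n_predicted),
        "n_queries": float(n),
    }


def random_baseline(
    cs: ClusterSet,
    records: Mapping[str, CompoundRecord],
    queries: Sequence[CompoundRecord],
    cfg: PredictionConfig,
    reps: int = 1000,
    rng: np.random.Generator | int | None = None,
    train_sim: SimilarityMatrix | None = None,
    scorer: ClusterScorer | None = None,
) -> dict[str, float]:
    """Expected accuracy when the "nearest" cluster is drawn at random.

    Each repetition draws, per query, a uniformly random size-eligible
    cluster and applies the same predominance rule.  Alongside the
    Monte-Carlo percentage the analytic expectation
    ``100 · Σ_labels f(label) · q(label)`` is returned, where ``f`` is the
    fraction of eligible clusters whose predominant label at the level is
    that label and ``q`` the fraction of queries carrying it.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if scorer is None:
        if train_sim is None:
            raise ValueError("need either a ClusterScorer or a train_sim")
        scorer = ClusterScorer(cs, train_sim, records, cfg.include_unknown)
    eligible = scorer.eligible(cfg.min_cluster_size)
    if eligible.size == 0 or not queries:
        return {
            "mc_pct_correct": 0.0,
            "analytic_pct_correct": 0.0,
            "reps": float(reps),
        }
    labels = [scorer.predominant(int(k), cfg.level) for k in eligible]

    f: dict[InteractionLabel, float] = {}
    for label in labels:
        if label is not None:
            f[label] = f.get(label, 0.0) + 1.0 / eligible.size
    q: dict[InteractionLabel, float] = {}
    for rec in queries:
        for label in rec.labels:
            q[label] = q.get(label, 0.0) + 1.0 / len(queries)
    analytic = 100.0 * sum(f[l] * q.get(l, 0.0) for l in f)

    rng = np.random.default_rng(rng)
    draws = rng.integers(0, eligible.size, size=(reps, len(queries)))
    hits = 0
    for r in range(reps):
        for j, rec in enumerate(queries):
            label = labels[draws[r, j]]
            if label is not None and label in rec.labels:
                hits += 1
    return {
        "mc_pct_correct": 100.0 * hits / (reps * len(queries)),
        "analytic_pct_correct": analytic,
        "reps": float(reps),
    }
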