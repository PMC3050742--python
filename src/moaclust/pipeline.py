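"""End-to-end protocol orchestration.

The protocol mirrors the validation design of the study: five random
training/test splits of the library (60 labelled test compounds each, at
least one per interaction class; unlabelled compounds always stay in
training), five clustering seed compounds per split (drawn once per split
and shared across descriptor sets), seeded maximal-dissimilarity
clustering with the cluster count chosen on a 1..min(200, |train|/2) grid
by the biggest avg-s drop, predominance annotation, nearest-cluster
prediction of every test query under a grid of configurations, and the
random-assignment baseline.  Results aggregate as means and standard
deviations over the 25 (split × clustering-seed) runs per descriptor set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation, clustering, descriptors, prediction
from .chem_io import CompoundRecord, InteractionLabel, parse_smiles, records_by_id
from .clustering import AvgSCurve, ClusterSet
from .descriptors import ContinuousScaler, DescriptorSet, DescriptorVector, SimilarityMatrix
from .prediction import PredictionConfig, PredictionResult, SearchMethod


@dataclass(frozen=True)
class DatasetSplit:
    """One training/test split; test compounds are always labelled."""

    split_index: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


@dataclass
class ProtocolConfig:
    """Grid of study conditions swept by :func:`run_protocol`."""

    descriptor_sets: tuple[DescriptorSet, ...] = tuple(DescriptorSet)
    n_splits: int = 5
    test_size: int = 60
    n_clustering_seeds: int = 5
    levels: tuple[float, ...] = annotation.DEFAULT_LEVELS
    min_sizes: tuple[int, ...] = annotation.DEFAULT_MIN_SIZES
    methods: tuple[SearchMethod, ...] = tuple(SearchMethod)
    thresholds: tuple[float | None, ...] = (None, 0.7)
    include_unknown_modes: tuple[bool, ...] = (True, False)
    n_grid_cap: int = 200
    baseline_reps: int = 25
    rng_seed: int = 0
    #: Negative control: permute the label sets among the labelled
    #: training compounds of each split before annotation/prediction
    #: (clustering itself is label-free).  Queries keep their true labels.
    shuffle_training_labels: bool = False

    def to_dict(self) -> dict:
        return {
            "descriptor_sets": [d.value for d in self.descriptor_sets],
            "n_splits": self.n_splits,
            "test_size": self.test_size,
            "n_clustering_seeds": self.n_clustering_seeds,
            "levels": list(self.levels),
            "min_sizes": list(self.min_sizes),
            "methods": [m.value for m in self.methods],
            "thresholds": [t for t in self.thresholds],
            "include_unknown_modes": list(self.include_unknown_modes),
            "n_grid_cap": self.n_grid_cap,
            "baseline_reps": self.baseline_reps,
            "rng_seed": self.rng_seed,
            "shuffle_training_labels": self.shuffle_training_labels,
        }


@dataclass
class ResultBundle:
    """Everything one protocol run produces, ready for CSV export."""

    metrics: pd.DataFrame
    predominance: pd.DataFrame
    avg_s_curves: pd.DataFrame
    predictions: pd.DataFrame
    partition_similarity: pd.DataFrame
    manifest: dict
    cluster_sets: dict[tuple[str, int, int], ClusterSet] = field(default_factory=dict)

    def metrics_summary(self) -> pd.DataFrame:
        """Mean ± std over the (split × seed) runs per descriptor/config."""
        keys = [
            "descriptor_set",
            "method",
            "min_size",
            "level",
            "threshold",
            "include_unknown",
        ]
        grouped = self.metrics.groupby(keys, dropna=False)
        out = grouped.agg(
            pct_correct_all_mean=("pct_correct_all", "mean"),
            pct_correct_all_std=("pct_correct_all", "std"),
            pct_correct_predicted_mean=("pct_correct_predicted", "mean"),
            n_predicted_mean=("n_predicted", "mean"),
            n_above_threshold_mean=("n_above_threshold", "mean"),
            baseline_analytic_pct_mean=("baseline_analytic_pct", "mean"),
            baseline_mc_pct_mean=("baseline_mc_pct", "mean"),
            n_runs=("pct_correct_all", "size"),
        )
        return out.reset_index()


def make_splits(
    records: Sequence[CompoundRecord],
    n_splits: int = 5,
    test_size: int = 60,
    rng: np.random.Generator | int | None = None,
    required_classes: Sequence[InteractionLabel] | None = None,
    max_attempts: int = 10_000,
) -> list[DatasetSplit]:
    """Randomly draw training/test splits with per-class test coverage.

    Each split is drawn independently: ``test_size`` labelled compounds go
    to the test set, rejection-resampling until every required class has
    at least one test compound; everything else (including all unlabelled
    compounds) forms the training set.
    """
    rng = np.random.default_rng(rng)
    labelled = [r for r in records if r.labels]
    if required_classes is None:
        required = {l for r in labelled for l in r.labels}
    else:
        required = set(required_classes)
        missing = sorted(
            l.value for l in required if not any(l in r.labels for r in labelled)
        )
        if missing:
            raise ValueError(
                "no labelled compounds for class(es): " + ", ".join(missing)
            )
    if len(labelled) < test_size:
        raise ValueError(
            f"need at least test_size={test_size} labelled compounds, "
            f"have {len(labelled)}"
        )
    all_ids = [r.compound_id for r in records]
    labelled_ids = [r.compound_id for r in labelled]
    labels_of = {r.compound_id: r.labels for r in labelled}
    splits = []
    for si in range(1, n_splits + 1):
        for _ in range(max_attempts):
            test = rng.choice(labelled_ids, size=test_size, replace=False)
            covered = {l for cid in test for l in labels_of[cid]}
            if required <= covered:
                break
        else:
            raise ValueError(
                "could not draw a test set covering every class within "
                f"{max_attempts} attempts"
            )
        test_set = set(test.tolist())
        train = tuple(cid for cid in all_ids if cid not in test_set)
        test_ordered = tuple(cid for cid in all_ids if cid in test_set)
        splits.append(DatasetSplit(si, train, test_ordered))
    return splits


def compute_library_vectors(
    records: Sequence[CompoundRecord],
    descriptor_sets: Sequence[DescriptorSet],
) -> dict[DescriptorSet, dict[str, DescriptorVector]]:
    """Parse every SMILES once and compute all requested descriptor sets."""
    mols = {r.compound_id: parse_smiles(r.smiles) for r in records}
    return {
        set_id: descriptors.compute_vectors(mols, set_id)
        for set_id in descriptor_sets
    }


def _query_similarities(
    test_ids: Sequence[str],
    vectors: Mapping[str, DescriptorVector],
    train_sim: SimilarityMatrix,
    scaler: ContinuousScaler | None,
) -> np.ndarray:
    rows = []
    for qid in test_ids:
        qv = vectors[qid]
        rows.append(
            np.array(
                [descriptors.similarity(qv, vectors[t], scaler) for t in train_sim.ids]
            )
        )
    return np.vstack(rows)


def _run_one_clustering(
    train_sim: SimilarityMatrix,
    seed_compound: str,
    n_grid_cap: int,
    seed_index: int,
) -> tuple[ClusterSet, AvgSCurve]:
    n_max = max(2, min(n_grid_cap, train_sim.n // 2))
    curve = clustering.choose_cluster_count(train_sim, n_max, seed_compound)
    centers = clustering.select_centers(train_sim, curve.chosen_n, seed_compound)
    cs = clustering.partition(train_sim, centers, seed_index=seed_index)
    return cs, curve


def run_protocol(
    records: Sequence[CompoundRecord],
    config: ProtocolConfig | None = None,
    vectors_by_set: Mapping[DescriptorSet, Mapping[str, DescriptorVector]] | None = None,
) -> ResultBundle:
    """Run the full protocol grid and aggregate every result table.

    ``vectors_by_set`` short-circuits descriptor computation (used for
    fingerprint-space synthetic libraries); otherwise descriptors are
    computed from the records' SMILES for every configured set.
    """
    config = config or ProtocolConfig()
    by_id = records_by_id(records)
    rng = np.random.default_rng(config.rng_seed)
    splits = make_splits(records, config.n_splits, config.test_size, rng)
    # clustering seed compounds: drawn once per split, shared across sets
    seed_compounds = {
        s.split_index: tuple(
            rng.choice(s.train_ids, size=config.n_clustering_seeds, replace=False)
        )
        for s in splits
    }
    baseline_seeds = {
        (s.split_index, k): int(rng.integers(2**31))
        for s in splits
        for k in range(config.n_clustering_seeds)
    }
    by_id_for_split: dict[int, Mapping[str, CompoundRecord]] = {}
    for s in splits:
        if config.shuffle_training_labels:
            by_id_for_split[s.split_index] = _shuffle_train_labels(by_id, s, rng)
        else:
            by_id_for_split[s.split_index] = by_id
    if vectors_by_set is None:
        vectors_by_set = compute_library_vectors(records, config.descriptor_sets)

    metric_rows: list[dict] = []
    predominance_rows: list[dict] = []
    curve_rows: list[dict] = []
    prediction_rows: list[dict] = []
    cluster_sets: dict[tuple[str, int, int], ClusterSet] = {}
    failures: list[dict] = []

    for set_id in config.descriptor_sets:
        vectors = dict(vectors_by_set[set_id])
        set_failed = 0
        for split in splits:
            train_vecs = {cid: vectors[cid] for cid in split.train_ids}
            has_blocks = bool(next(iter(train_vecs.values())).blocks)
            scaler = (
                ContinuousScaler().fit(train_vecs.values()) if has_blocks else None
            )
            train_sim = descriptors.similarity_matrix(train_vecs, scaler)
            query_sims = _query_similarities(
                split.test_ids, vectors, train_sim, scaler
            )
            run_by_id = by_id_for_split[split.split_index]
            queries = [run_by_id[qid] for qid in split.test_ids]
            for k, seed_cid in enumerate(seed_compounds[split.split_index]):
                run_key = (set_id.value, split.split_index, k)
                try:
                    cs, curve = _run_one_clustering(
                        train_sim, seed_cid, config.n_grid_cap, seed_index=k
                    )
                    cluster_sets[run_key] = cs
                    for n, s in zip(curve.n_values, curve.avg_s):
                        curve_rows.append(
                            {
                                "descriptor_set": set_id.value,
                                "split": split.split_index,
                                "clustering_seed": k,
                                "n": n,
                                "avg_s": s,
                                "chosen": int(n == curve.chosen_n),
                            }
                        )
                    _evaluate_run(
                        set_id,
                        split,
                        k,
                        cs,
                        curve,
                        train_sim,
                        query_sims,
                        queries,
                        run_by_id,
                        config,
                        baseline_seeds[(split.split_index, k)],
                        metric_rows,
                        predominance_rows,
                        prediction_rows,
                    )
                except Exception as exc:  # pragma: no cover - defensive
                    set_failed += 1
                    failures.append(
                        {
                            "descriptor_set": set_id.value,
                            "split": split.split_index,
                            "clustering_seed": k,
                            "error": repr(exc),
                        }
                    )
        n_runs = config.n_splits * config.n_clustering_seeds
        if set_failed == n_runs:
            raise RuntimeError(
                f"every run of descriptor set {set_id.value} failed: {failures}"
            )

    partition_sim = _partition_similarity_table(cluster_sets)
    manifest = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "n_compounds": len(records),
        "splits": {
            s.split_index: {
                "n_train": len(s.train_ids),
                "n_test": len(s.test_ids),
                "test_ids": list(s.test_ids),
            }
            for s in splits
        },
        "clustering_seed_compounds": {
            str(si): list(map(str, seeds)) for si, seeds in seed_compounds.items()
        },
        "chosen_n": {
            "|".join(map(str, key)): cs.n_clusters for key, cs in cluster_sets.items()
        },
        "failures": failures,
    }
    return ResultBundle(
        metrics=pd.DataFrame(metric_rows),
        predominance=pd.DataFrame(predominance_rows),
        avg_s_curves=pd.DataFrame(curve_rows),
        predictions=pd.DataFrame(prediction_rows),
        partition_similarity=partition_sim,
        manifest=manifest,
        cluster_sets=cluster_sets,
    )


def _shuffle_train_labels(
    by_id: Mapping[str, CompoundRecord],
    split: DatasetSplit,
    rng: np.random.Generator,
) -> dict[str, CompoundRecord]:
    """Permute label sets among the labelled training compounds."""
    out = dict(by_id)
    labelled = [cid for cid in split.train_ids if by_id[cid].labels]
    label_sets = [by_id[cid].labels for cid in labelled]
    perm = rng.permutation(len(labelled))
    for cid, pi in zip(labelled, perm):
        rec = by_id[cid]
        out[cid] = CompoundRecord(
            compound_id=rec.compound_id,
            smiles=rec.smiles,
            labels=label_sets[int(pi)],
            source_note=rec.source_note,
        )
    return out


def _evaluate_run(
    set_id: DescriptorSet,
    split: DatasetSplit,
    clustering_seed: int,
    cs: ClusterSet,
    curve: AvgSCurve,
    train_sim: SimilarityMatrix,
    query_sims: np.ndarray,
    queries: Sequence[CompoundRecord],
    by_id: Mapping[str, CompoundRecord],
    config: ProtocolConfig,
    baseline_seed: int,
    metric_rows: list[dict],
    predominance_rows: list[dict],
    prediction_rows: list[dict],
) -> None:
    """Annotate and predict for one (descriptor, split, seed) run."""
    scorers = {
        mode: prediction.ClusterScorer(cs, train_sim, by_id, include_unknown=mode)
        for mode in config.include_unknown_modes
    }
    # per-method query x cluster score matrices (scores are mode-independent)
    any_scorer = next(iter(scorers.values()))
    scores_by_method = {
        m: np.vstack([any_scorer.scores(qs, m) for qs in query_sims])
        for m in config.methods
    }
    predominant_cache = {
        (mode, level): [
            scorer.predominant(ci, level) for ci in range(cs.n_clusters)
        ]
        for mode, scorer in scorers.items()
        for level in config.levels
    }

    for mode, scorer in scorers.items():
        summary = annotation.predominance_summary(
            cs, by_id, config.levels, config.min_sizes, include_unknown=mode
        )
        for row in summary.to_dict("records"):
            predominance_rows.append(
                {
                    "descriptor_set": set_id.value,
                    "split": split.split_index,
                    "clustering_seed": clustering_seed,
                    **row,
                }
            )

    headline = (SearchMethod.CLUSTER_CENTRE, 2, 2.0 / 3.0)
    for mode, scorer in scorers.items():
        for min_size in config.min_sizes:
            eligible = scorer.eligible(min_size)
            for method in config.methods:
                if eligible.size:
                    sub = scores_by_method[method][:, eligible]
                    best_col = np.argmax(sub, axis=1)
                    best_cluster = eligible[best_col]
                    best_score = sub[np.arange(len(sub)), best_col]
                for level in config.levels:
                    labels = predominant_cache[(mode, level)]
                    for threshold in config.thresholds:
                        results: list[PredictionResult] = []
                        n_above = 0
                        for qi, rec in enumerate(queries):
                            if eligible.size == 0:
                                results.append(
                                    PredictionResult(
                                        rec.compound_id, None, float("nan"), None
                                    )
                                )
                                continue
                            ci = int(best_cluster[qi])
                            score = float(best_score[qi])
                            if threshold is not None and score < threshold:
                                results.append(
                                    PredictionResult(rec.compound_id, ci, score, None)
                                )
                                continue
                            n_above += 1
                            label = labels[ci]
                            correct = (
                                label in rec.labels if label is not None else None
                            )
                            results.append(
                                PredictionResult(
                                    rec.compound_id, ci, score, label, correct
                                )
                            )
                        metrics = prediction.evaluate(results, by_id)
                        cfg = PredictionConfig(
                            method=method,
                            min_cluster_size=min_size,
                            level=level,
                            similarity_threshold=threshold,
                            include_unknown=mode,
                        )
                        base = prediction.random_baseline(
                            cs,
                            by_id,
                            queries,
                            cfg,
                            reps=config.baseline_reps,
                            rng=baseline_seed,
                            scorer=scorer,
                        )
                        metric_rows.append(
                            {
                                "descriptor_set": set_id.value,
                                "split": split.split_index,
                                "clustering_seed": clustering_seed,
                                "method": method.value,
                                "min_size": min_size,
                                "level": level,
                                "threshold": threshold,
                                "include_unknown": mode,
                                "chosen_n": cs.n_clusters,
                                "n_above_threshold": n_above,
                                "baseline_analytic_pct": base["analytic_pct_correct"],
                                "baseline_mc_pct": base["mc_pct_correct"],
                                **metrics,
                            }
                        )
                        if (method, min_size, level) == headline:
                            for res in results:
                                prediction_rows.append(
                                    {
                                        "query_id": res.query_id,
                                        "descriptor_set": set_id.value,
                                        "split": split.split_index,
                                        "clustering_seed": clustering_seed,
                                        "method": method.value,
                                        "min_size": min_size,
                                        "level": level,
                                        "threshold": threshold,
                                        "include_unknown": mode,
                                        "cluster_index": res.cluster_index,
                                        "similarity": res.similarity,
                                        "predicted": (
                                            res.predicted.value
                                            if res.predicted
                                            else "ABSTAIN"
                                        ),
                                        "correct": res.correct,
                                    }
                                )


def _partition_similarity_table(
    cluster_sets: Mapping[tuple[str, int, int], ClusterSet]
) -> pd.DataFrame:
    """Pairwise pair-based Tanimoto between every pair of runs.

    Runs from different splits have different training sets, so each pair
    of partitions is first restricted to the compounds both runs share.
    """
    keys = list(cluster_sets)
    labels = ["|".join(map(str, k)) for k in keys]
    universes = {k: set(cluster_sets[k].assignment) for k in keys}
    pair_sets = {
        k: clustering._co_clustered_pairs(cluster_sets[k].assignment) for k in keys
    }
    n = len(keys)
    mat = np.eye(n)
    for i, j in combinations(range(n), 2):
        ki, kj = keys[i], keys[j]
        common = universes[ki] & universes[kj]
        a = sum(1 for p in pair_sets[ki] if p[0] in common and p[1] in common)
        b = sum(1 for p in pair_sets[kj] if p[0] in common and p[1] in common)
        c = len(pair_sets[ki] & pair_sets[kj])
        mat[i, j] = mat[j, i] = 1.0 if a == 0 and b == 0 else c / (a + b - c)
    return pd.DataFrame(mat, index=labels, columns=labels)


def report(bundle: ResultBundle, outdir: str | Path) -> list[Path]:
    """Write the bundle as deterministic CSVs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def write_df(df: pd.DataFrame, name: str, index: bool = False):
        path = outdir / name
        df.to_csv(path, index=index)
        written.append(path)

    write_df(bundle.metrics, "metrics.csv")
    write_df(bundle.metrics_summary(), "metrics_summary.csv")
    write_df(bundle.predominance, "predominance.csv")
    write_df(bundle.avg_s_curves, "avg_s_curves.csv")
    write_df(bundle.predictions, "predictions.csv")
    write_df(bundle.partition_similarity, "partition_similarity.csv", index=True)

    # Average number of queries whose nearest cluster passes the 0.7
    # similarity threshold, by descriptor x minimum cluster size.
    m = bundle.metrics
    thr = m[
        (m["threshold"] == 0.7)
        & (m["method"] == SearchMethod.CLUSTER_CENTRE.value)
        & (m["include_unknown"] == True)  # noqa: E712 - pandas mask
        & np.isclose(m["level"], 2.0 / 3.0)
    ]
    if len(thr):
        table2 = thr.pivot_table(
            index="descriptor_set",
            columns="min_size",
            values="n_above_threshold",
            aggfunc="mean",
        )
        write_df(table2, "queries_above_threshold.csv", index=True)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    written.append(manifest_path)
    return written
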