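"""Scoring fuzzy clusterings against ground-truth classes.

A fuzzy result is first hardened by the maximum-membership rule, then
clusters are aligned with classes by the one-to-one assignment that
maximises the number of matched records; the clustering error is the
percentage of records left unmatched under that optimal alignment. The
multi-run protocol repeats clustering from different random initialisations
and reports the mean and (population) standard deviation of the per-run
errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .data_model import CategoricalDataset
from .engine import ClusteringConfig, ClusteringResult, run_clustering
from .distances import ValueDistanceTable, build_distance_table

#: Above this many clusters/classes, permutation search gives way to the
#: Hungarian assignment algorithm.
EXHAUSTIVE_LIMIT = 8


@dataclass(frozen=True)
class ConfusionMatrix:
    """Class-by-cluster contingency counts."""

    class_labels: tuple[str, ...]
    cluster_ids: tuple[int, ...]
    counts: np.ndarray  # (n_classes, n_clusters) non-negative integers

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class EvaluationReport:
    """Multi-run clustering-quality summary."""

    confusion: ConfusionMatrix  # run closest to the mean error
    mapping: dict[int, str]  # cluster id -> matched class, for that run
    error_percent: float  # error of that representative run
    per_run_errors: tuple[float, ...]
    mean_error: float
    std_error: float

    def to_dict(self) -> dict:
        return {
            "per_run_errors": list(self.per_run_errors),
            "mean_error": self.mean_error,
            "std_error": self.std_error,
            "representative_error": self.error_percent,
            "mapping": {str(k): v for k, v in self.mapping.items()},
            "confusion": {
                "classes": list(self.confusion.class_labels),
                "clusters": list(self.confusion.cluster_ids),
                "counts": self.confusion.counts.tolist(),
            },
        }


def defuzzify(u: np.ndarray) -> np.ndarray:
    """Hard labels by maximum membership; ties go to the lowest cluster index."""
    u = np.asarray(u, dtype=float)
    if u.ndim != 2:
        raise ValueError("membership matrix must be 2-D")
    return np.argmax(u, axis=1)


def confusion_matrix(labels, assignments) -> ConfusionMatrix:
    """Count records per (class, cluster) pair.

    Classes are ordered lexicographically, clusters by id, so the matrix
    layout is deterministic.
    """
    labels = [str(c) for c in labels]
    assignments = np.asarray(assignments, dtype=int)
    if len(labels) != len(assignments):
        raise ValueError("labels and assignments must have equal length")
    classes = tuple(sorted(set(labels)))
    clusters = tuple(sorted(set(assignments.tolist())))
    class_idx = {c: r for r, c in enumerate(classes)}
    cluster_idx = {j: c for c, j in enumerate(clusters)}
    counts = np.zeros((len(classes), len(clusters)), dtype=int)
    for lab, j in zip(labels, assignments):
        counts[class_idx[lab], cluster_idx[int(j)]] += 1
    return ConfusionMatrix(classes, clusters, counts)


def _best_matching(counts: np.ndarray) -> tuple[int, list[tuple[int, int]]]:
    """Maximum total matched count over one-to-one (class row, cluster col) pairs."""
    n_rows, n_cols = counts.shape
    if min(n_rows, n_cols) <= EXHAUSTIVE_LIMIT:
        best, best_pairs = -1, []
        if n_rows <= n_cols:
            for cols in permutations(range(n_cols), n_rows):
                matched = int(sum(counts[r, c] for r, c in enumerate(cols)))
                if matched > best:
                    best = matched
                    best_pairs = list(enumerate(cols))
        else:
            for rows in permutations(range(n_rows), n_cols):
                matched = int(sum(counts[r, c] for c, r in enumerate(rows)))
                if matched > best:
                    best = matched
                    best_pairs = [(r, c) for c, r in enumerate(rows)]
        return best, best_pairs
    rows, cols = linear_sum_assignment(counts, maximize=True)
    return int(counts[rows, cols].sum()), list(zip(rows.tolist(), cols.tolist()))


def clustering_error(cm: ConfusionMatrix) -> tuple[float, dict[int, str]]:
    """Percent of records outside their class's matched cluster.

    Returns the error (0-100) and the optimal cluster -> class mapping.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    matched, pairs = _best_matching(cm.counts)
    mapping = {
        int(cm.cluster_ids[c]): cm.class_labels[r] for r, c in pairs
    }
    error = 100.0 * (cm.total - matched) / cm.total
    return error, mapping


def aggregate_runs(errors) -> tuple[float, float]:
    """Mean and population standard deviation of per-run error percentages."""
    errors = np.asarray(list(errors), dtype=float)
    if errors.size == 0:
        raise ValueError("no per-run errors to aggregate")
    return float(errors.mean()), float(errors.std(ddof=0))


def run_experiment(
    dataset: CategoricalDataset,
    config: ClusteringConfig,
    runs: int = 1,
    table: ValueDistanceTable | None = None,
) -> tuple[EvaluationReport, list[ClusteringResult]]:
    """Repeat clustering from ``runs`` seeded initialisations and score each.

    Run r uses seed ``config.seed + r``. The value-distance table is shared
    across runs (it depends only on the data). The reported confusion matrix
    is that of the run whose error is closest to the mean, since per-run
    matrices cannot be meaningfully averaged.
    """
    if dataset.labels is None:
        raise ValueError("ground-truth labels are required for evaluation")
    if runs < 1:
        raise ValueError("at least one run is required")
    if table is None:
        table = build_distance_table(dataset, config.distance_kind)
    results, errors, matrices, mappings = [], [], [], []
    for r in range(runs):
        cfg = ClusteringConfig(
            k=config.k,
            m=config.m,
            epsilon=config.epsilon,
            max_iter=config.max_iter,
            distance_kind=config.distance_kind,
            centroid_kind=config.centroid_kind,
            seed=config.seed + r,
        )
        result = run_clustering(dataset, cfg, table=table)
        cm = confusion_matrix(dataset.labels, result.hard_labels())
        err, mapping = clustering_error(cm)
        results.append(result)
        errors.append(err)
        matrices.append(cm)
        mappings.append(mapping)
    mean, std = aggregate_runs(errors)
    representative = int(np.argmin(np.abs(np.asarray(errors) - mean)))
    report = EvaluationReport(
        confusion=matrices[representative],
        mapping=mappings[representative],
        error_percent=errors[representative],
        per_run_errors=tuple(errors),
        mean_error=mean,
        std_error=std,
    )
    return report, results
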