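"""Fuzzy clustering of categorical data by alternating optimisation.

The algorithm is fuzzy c-means restructured for categorical features. A
cluster centre is not a single point: per feature it is a weight vector over
that feature's categories (a *fuzzy centroid*), the weight of category
A_{l,k} in cluster c being

    N_{l,k,c} / N_c,   N_{l,k,c} = sum_i 1[x_il = A_{l,k}] u_ic^m,
                       N_c       = sum_i u_ic^m,

where U = (u_ij) is the row-stochastic membership matrix and m > 1 the
fuzzifier. The distance between a record and a centre sums, over features,
the centroid-weighted value distances

    Omega_l(Z, c) = sum_t (N_{l,t,c} / N_c) * delta_l(Z, A_{l,t}),

with delta_l taken from a precomputed :class:`ValueDistanceTable`
(co-occurrence or Hamming). Memberships are then updated by the standard
fuzzy c-means rule u_ij proportional to d_ij^(-1/(m-1)), and the loop stops
when the objective J = sum_ij u_ij^m d_ij changes by at most epsilon.

The classic fuzzy K-modes baseline is the ``mode`` centroid kind: the centre
keeps only the weighted modal category per feature and distances reduce to
Hamming distance to the mode when the Hamming table is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CategoricalDataset
from .distances import DISTANCE_KINDS, ValueDistanceTable, build_distance_table

logger = logging.getLogger(__name__)

CENTROID_KINDS = ("fuzzy", "mode")

#: Below this soft mass a cluster is considered empty and is re-seeded.
EMPTY_CLUSTER_MASS = 1e-12


@dataclass(frozen=True)
class ClusteringConfig:
    """Knobs of one clustering run.

    m is the fuzzifier (> 1; values near 1 give near-hard memberships, the
    headline setting here is 1.1). epsilon is the stopping threshold on the
    change of the objective J between iterations.
    """

    k: int = 2
    m: float = 1.1
    epsilon: float = 1e-6
    max_iter: int = 100
    distance_kind: str = "cooccurrence"
    centroid_kind: str = "fuzzy"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if not self.m > 1.0:
            raise ValueError("the fuzzifier m must be > 1")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.distance_kind not in DISTANCE_KINDS:
            raise ValueError(f"unknown distance kind {self.distance_kind!r}")
        if self.centroid_kind not in CENTROID_KINDS:
            raise ValueError(f"unknown centroid kind {self.centroid_kind!r}")


@dataclass(frozen=True)
class FuzzyCentroid:
    """One cluster centre: per feature, a weight distribution over categories."""

    cluster_index: int
    weights: tuple[np.ndarray, ...]  # one unit-sum vector per feature
    mass: float  # N_c, the cluster's soft record mass

    def weight(self, feature: int, value: str, vocabulary) -> float:
        return float(self.weights[feature][vocabulary.index(value)])


@dataclass
class ClusteringResult:
    memberships: np.ndarray  # (n, K), rows sum to 1
    centroids: list[FuzzyCentroid]
    distances: np.ndarray  # (n, K) point-to-centre distances, final iteration
    objective_trace: list[float]
    iterations: int
    converged: bool
    config: ClusteringConfig
    distance_table: ValueDistanceTable = field(repr=False, default=None)

    def hard_labels(self) -> np.ndarray:
        from .evaluation import defuzzify

        return defuzzify(self.memberships)

    def memberships_frame(self) -> pd.DataFrame:
        k = self.memberships.shape[1]
        return pd.DataFrame(
            self.memberships, columns=[f"cluster_{j}" for j in range(k)]
        )

    def centroids_dict(self, dataset: CategoricalDataset) -> dict:
        """Centroids as {cluster: {feature: {value: weight}}} for JSON export."""
        out = {}
        for centroid in self.centroids:
            feats = {}
            for l, vocab in enumerate(dataset.vocabularies):
                feats[dataset.feature_names[l]] = {
                    value: float(w)
                    for value, w in zip(vocab.values, centroid.weights[l])
                }
            out[str(centroid.cluster_index)] = feats
        return out


def initialize_membership(n: int, k: int, seed: int) -> np.ndarray:
    """Random row-stochastic membership matrix, deterministic given the seed."""
    if n < k:
        raise ValueError("need at least as many records as clusters")
    rng = np.random.default_rng(seed)
    u = rng.random((n, k))
    sums = u.sum(axis=1)
    while (sums == 0).any():  # pragma: no cover - probability zero
        bad = sums == 0
        u[bad] = rng.random((int(bad.sum()), k))
        sums = u.sum(axis=1)
    return u / sums[:, None]


def _weighted_value_counts(
    dataset: CategoricalDataset, u: np.ndarray, m: float
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per feature, the (K, p_l) matrix of N_{l,k,c}; plus the masses N_c."""
    um = u**m
    masses = um.sum(axis=0)
    counts = []
    for l, vocab in enumerate(dataset.vocabularies):
        n_l = np.zeros((vocab.size, um.shape[1]))
        np.add.at(n_l, dataset.codes[:, l], um)
        counts.append(n_l.T)
    return counts, masses


def update_centroids(
    dataset: CategoricalDataset, u: np.ndarray, m: float
) -> list[FuzzyCentroid]:
    """Fuzzy centroids: per cluster and feature, weights N_{l,k,c} / N_c."""
    counts, masses = _weighted_value_counts(dataset, u, m)
    centroids = []
    for j, mass in enumerate(masses):
        if mass < EMPTY_CLUSTER_MASS:
            raise ValueError(f"cluster {j} has (near-)zero soft mass")
        weights = tuple(n_l[j] / mass for n_l in counts)
        centroids.append(FuzzyCentroid(j, weights, float(mass)))
    return centroids


def mode_centroid(
    dataset: CategoricalDataset, u: np.ndarray, m: float
) -> list[tuple[str, ...]]:
    """Hard centres: per cluster and feature, the weighted modal category.

    Ties between equally weighted categories go to the lexicographically
    first (vocabulary order).
    """
    counts, masses = _weighted_value_counts(dataset, u, m)
    centres = []
    for j, mass in enumerate(masses):
        if mass < EMPTY_CLUSTER_MASS:
            raise ValueError(f"cluster {j} has (near-)zero soft mass")
        centres.append(
            tuple(
                dataset.vocabularies[l].values[int(np.argmax(n_l[j]))]
                for l, n_l in enumerate(counts)
            )
        )
    return centres


def point_centroid_distance(
    record, centroid: FuzzyCentroid, table: ValueDistanceTable
) -> float:
    """Distance of one record (a sequence of symbols) to one fuzzy centre."""
    total = 0.0
    for l, value in enumerate(record):
        vocab = table.vocabularies[l]
        row = table.matrices[l][vocab.index(str(value))]
        total += float(row @ centroid.weights[l])
    return total


def update_membership(distances: np.ndarray, m: float) -> np.ndarray:
    """Fuzzy c-means membership update from a (n, K) distance grid.

    Where every distance is positive, u_ij = 1 / sum_k (d_ij / d_ik)^(1/(m-1)).
    A record at distance zero from one or more centres gets its membership
    split equally among those centres (the update is singular there).
    """
    d = np.asarray(distances, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if not m > 1.0:
        raise ValueError("the fuzzifier m must be > 1")
    zero = d == 0.0
    any_zero = zero.any(axis=1)
    # d/d_min is >= 1, so the negative power never overflows; it may
    # underflow to 0 for far clusters, which is the right limit.
    dmin = np.where(any_zero, 1.0, d.min(axis=1))
    # overflow to inf (subnormal dmin) is benign: the far cluster's
    # membership underflows to 0, which is the correct limit.
    with np.errstate(over="ignore", divide="ignore"):
        ratio = d / dmin[:, None]
        u = ratio ** (-1.0 / (m - 1.0))
    u[any_zero] = zero[any_zero].astype(float)
    return u / u.sum(axis=1, keepdims=True)


def compute_objective(u: np.ndarray, distances: np.ndarray, m: float) -> float:
    """J = sum_j sum_i u_ij^m d_ij."""
    u = np.asarray(u, dtype=float)
    d = np.asarray(distances, dtype=float)
    if u.shape != d.shape:
        raise ValueError("membership and distance grids must have equal shape")
    return float((u**m * d).sum())


def _all_distances(
    dataset: CategoricalDataset,
    weights: list[np.ndarray],
    table: ValueDistanceTable,
) -> np.ndarray:
    """Vectorised (n, K) distances; weights[l] has shape (K, p_l)."""
    n = dataset.n
    k = weights[0].shape[0]
    d = np.zeros((n, k))
    for l in range(dataset.s):
        per_value = table.matrices[l] @ weights[l].T  # (p_l, K)
        d += per_value[dataset.codes[:, l]]
    return d


def _mode_seeded_membership(
    dataset: CategoricalDataset, config: ClusteringConfig, table: ValueDistanceTable
) -> np.ndarray:
    """Memberships induced by K random pairwise-distinct records as centres."""
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(dataset.n)
    chosen: list[int] = []
    for i in order:
        if all((dataset.codes[i] != dataset.codes[j]).any() for j in chosen):
            chosen.append(int(i))
        if len(chosen) == config.k:
            break
    if len(chosen) < config.k:  # fewer distinct records than clusters
        chosen = order[: config.k].tolist()
    weights = [
        np.eye(vocab.size)[dataset.codes[chosen, l]]
        for l, vocab in enumerate(dataset.vocabularies)
    ]
    return update_membership(_all_distances(dataset, weights, table), config.m)


def run_clustering(
    dataset: CategoricalDataset,
    config: ClusteringConfig,
    table: ValueDistanceTable | None = None,
    initial_membership: np.ndarray | None = None,
) -> ClusteringResult:
    """Full alternating-optimisation loop.

    The value-distance table is built once (or passed in, e.g. when many
    runs share it) and frozen; only centroids and memberships change per
    iteration. Stops when |J_t - J_{t-1}| <= epsilon or after max_iter
    iterations; non-convergence is reported in the result, not raised.
    ``initial_membership`` overrides the seeded random initialisation.
    """
    if table is None:
        table = build_distance_table(dataset, config.distance_kind)
    elif table.kind != config.distance_kind:
        raise ValueError(
            f"table kind {table.kind!r} does not match config "
            f"distance kind {config.distance_kind!r}"
        )
    n, k, m = dataset.n, config.k, config.m
    if initial_membership is not None:
        u = np.asarray(initial_membership, dtype=float)
        if u.shape != (n, k):
            raise ValueError("initial membership must have shape (n, k)")
        u = u / u.sum(axis=1, keepdims=True)
    elif config.centroid_kind == "mode":
        # A uniform random U gives both clusters the same (global) mode —
        # a degenerate symmetric fixed point of the K-modes update. Use the
        # standard K-modes initialisation instead: K random, pairwise
        # distinct records as initial centres, memberships from their
        # distances.
        u = _mode_seeded_membership(dataset, config, table)
    else:
        u = initialize_membership(n, k, config.seed)
    recovery_rng = np.random.default_rng(config.seed)
    trace: list[float] = []
    converged = False
    j_prev: float | None = None
    iterations = 0
    centroids: list[FuzzyCentroid] = []
    d = np.zeros((n, k))
    for iterations in range(1, config.max_iter + 1):
        counts, masses = _weighted_value_counts(dataset, u, m)
        weights = [n_l / masses[:, None] for n_l in counts]
        empty = np.nonzero(masses < EMPTY_CLUSTER_MASS)[0]
        for j in empty:
            # Re-seed a collapsed cluster at a random record's point mass.
            r = int(recovery_rng.integers(n))
            logger.warning("cluster %d empty; re-seeding at record %d", j, r)
            for l in range(dataset.s):
                weights[l][j] = 0.0
                weights[l][j, dataset.codes[r, l]] = 1.0
            masses[j] = 0.0
        if config.centroid_kind == "mode":
            # Keep only the modal category per feature (argmax takes the
            # first maximum, i.e. vocabulary-order tie-break).
            weights = [
                np.eye(w.shape[1])[np.argmax(w, axis=1)] for w in weights
            ]
        d = _all_distances(dataset, weights, table)
        if j_prev is None:
            # Objective of the initial memberships under the first centres:
            # the baseline the first stopping-rule comparison uses.
            j_prev = compute_objective(u, d, m)
        u = update_membership(d, m)
        j_now = compute_objective(u, d, m)
        trace.append(j_now)
        logger.debug("iteration %d: J = %.10g", iterations, j_now)
        centroids = [
            FuzzyCentroid(j, tuple(w[j] for w in weights), float(masses[j]))
            for j in range(k)
        ]
        if abs(j_now - j_prev) <= config.epsilon:
            converged = True
            break
        j_prev = j_now
    return ClusteringResult(
        memberships=u,
        centroids=centroids,
        distances=d,
        objective_trace=trace,
        iterations=iterations,
        converged=converged,
        config=config,
        distance_table=table,
    )
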