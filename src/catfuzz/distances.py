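"""Distances between category values of a feature.

Two kinds are supported:

* ``hamming`` — 0 for identical values, 1 otherwise (simple matching).
* ``cooccurrence`` — the unsupervised Ahmad-Dey distance. For one co-feature
  j, the distance between values x and y of feature i is the largest gap
  achievable by any event w over feature j's values,

      delta_ij(x, y) = max_w [ p(w | x) + p(not w | y) ] - 1,

  which is exactly the total-variation distance between the conditional
  distributions p(. | x) and p(. | y), computed in closed form as
  (1/2) * sum_v |p(v|x) - p(v|y)|. The distance within feature i is the
  average of delta_ij over the s - 1 other features j.

Both kinds yield, per feature, a symmetric matrix with zero diagonal and
entries in [0, 1] satisfying the triangle inequality. Tables are computed
once on the full dataset and are immutable during clustering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CategoricalDataset, FeatureVocabulary

DISTANCE_KINDS = ("cooccurrence", "hamming")


@dataclass(frozen=True)
class ConditionalProbabilityTable:
    """p(target value | source value) for one ordered pair of features."""

    source_feature: int
    target_feature: int
    source_values: tuple[str, ...]
    target_values: tuple[str, ...]
    probs: np.ndarray  # shape (p_source, p_target), rows sum to 1

    def row(self, source_value: str) -> np.ndarray:
        try:
            idx = self.source_values.index(source_value)
        except ValueError:
            raise KeyError(f"unknown source value {source_value!r}") from None
        return self.probs[idx]


def conditional_probability_table(
    dataset: CategoricalDataset, i: int, j: int
) -> ConditionalProbabilityTable:
    """Estimate p(feature_j = v | feature_i = x) by counting over all records."""
    if i == j:
        raise ValueError("source and target feature must differ")
    vi, vj = dataset.vocabularies[i], dataset.vocabularies[j]
    counts = np.zeros((vi.size, vj.size))
    np.add.at(counts, (dataset.codes[:, i], dataset.codes[:, j]), 1.0)
    marginals = counts.sum(axis=1, keepdims=True)
    # Vocabularies contain only observed values, so every marginal is > 0.
    probs = counts / marginals
    return ConditionalProbabilityTable(
        source_feature=i,
        target_feature=j,
        source_values=vi.values,
        target_values=vj.values,
        probs=probs,
    )


def pairwise_value_distance(
    cpt: ConditionalProbabilityTable, x: str, y: str
) -> tuple[float, frozenset[str]]:
    """Distance between values x and y of the source feature, with witness.

    Returns ``(delta, omega)`` where ``omega`` is the maximising event: the
    set of target values v with p(v|x) > p(v|y). Values with equal
    conditional probability are excluded; including them would not change
    the maximum.
    """
    px, py = cpt.row(x), cpt.row(y)
    delta = float(np.maximum(px, py).sum() - 1.0)
    omega = frozenset(
        v for v, a, b in zip(cpt.target_values, px, py) if a > b
    )
    return delta, omega


class ValueDistanceTable:
    """Per feature, a symmetric matrix of distances between category values."""

    def __init__(
        self,
        kind: str,
        vocabularies: list[FeatureVocabulary],
        matrices: list[np.ndarray],
    ):
        if kind not in DISTANCE_KINDS:
            raise ValueError(f"unknown distance kind {kind!r}")
        if len(vocabularies) != len(matrices):
            raise ValueError("one matrix per feature is required")
        for vocab, mat in zip(vocabularies, matrices):
            if mat.shape != (vocab.size, vocab.size):
                raise ValueError("matrix shape must match vocabulary size")
        self.kind = kind
        self.vocabularies = list(vocabularies)
        self.matrices = [np.asarray(m, dtype=float) for m in matrices]

    @property
    def s(self) -> int:
        return len(self.matrices)

    def delta(self, feature: int, a: str, b: str) -> float:
        vocab = self.vocabularies[feature]
        return float(self.matrices[feature][vocab.index(a), vocab.index(b)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for l, (vocab, mat) in enumerate(zip(self.vocabularies, self.matrices)):
            for a_idx, a in enumerate(vocab.values):
                for b_idx, b in enumerate(vocab.values):
                    if a_idx < b_idx:
                        rows.append((l, a, b, mat[a_idx, b_idx]))
        return pd.DataFrame(rows, columns=["feature", "value_a", "value_b", "delta"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        doc = {
            "kind": self.kind,
            "features": [
                {
                    "feature": l,
                    "values": list(vocab.values),
                    "delta": mat.tolist(),
                }
                for l, (vocab, mat) in enumerate(
                    zip(self.vocabularies, self.matrices)
                )
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as handle:
                handle.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ValueDistanceTable":
        with open(path) as handle:
            doc = json.load(handle)
        vocabularies = [
            FeatureVocabulary(entry["feature"], tuple(entry["values"]))
            for entry in doc["features"]
        ]
        matrices = [np.asarray(entry["delta"], dtype=float) for entry in doc["features"]]
        return cls(doc["kind"], vocabularies, matrices)


def build_distance_table(
    dataset: CategoricalDataset, kind: str = "cooccurrence"
) -> ValueDistanceTable:
    """Compute the per-feature value-distance matrices for the whole dataset.

    For the co-occurrence kind, the distance between two values of feature i
    is the average, over the other s - 1 features, of the total-variation
    distance between their conditional co-occurrence profiles.
    """
    if kind == "hamming":
        matrices = [
            1.0 - np.eye(vocab.size) for vocab in dataset.vocabularies
        ]
        return ValueDistanceTable(kind, dataset.vocabularies, matrices)
    if kind != "cooccurrence":
        raise ValueError(f"unknown distance kind {kind!r}")
    s = dataset.s
    if s < 2:
        raise ValueError("co-occurrence distances require at least two features")
    matrices = []
    for i in range(s):
        p_i = dataset.vocabularies[i].size
        acc = np.zeros((p_i, p_i))
        for j in range(s):
            if j == i:
                continue
            probs = conditional_probability_table(dataset, i, j).probs
            acc += 0.5 * np.abs(probs[:, None, :] - probs[None, :, :]).sum(axis=2)
        matrices.append(acc / (s - 1))
    return ValueDistanceTable(kind, dataset.vocabularies, matrices)
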