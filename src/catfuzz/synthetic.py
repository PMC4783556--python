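"""Synthetic categorical data with known cluster structure.

Records are drawn from a mixture of multinomials: a latent cluster is drawn
from the mixing proportions, then each feature's category is drawn
independently from that cluster's emission distribution. An optional
*redundancy map* post-processes cells by splitting a latent category into
several surface codes with fixed probabilities — the designed stress test
for simple-matching (Hamming) distances: two sibling surface codes are
interchangeable evidence for the same cluster, yet Hamming treats them as
maximally different while their co-occurrence profiles against the other
features coincide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data_model import CategoricalDataset


@dataclass(frozen=True)
class GeneratorSpec:
    """A mixture-of-multinomials generator for categorical records.

    ``emissions[l]`` is a (k_true, p_l) row-stochastic matrix over feature
    l's latent categories ``c0 .. c{p_l-1}``. ``redundancy_map`` optionally
    maps ``feature -> latent code -> {surface code: probability}``.
    """

    n: int
    s: int
    k_true: int
    mixing: tuple[float, ...]
    emissions: tuple  # s matrices, each (k_true, p_l)
    redundancy_map: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.s < 2 or self.k_true < 1:
            raise ValueError("need n >= 1, s >= 2, k_true >= 1")
        mixing = np.asarray(self.mixing, dtype=float)
        if mixing.shape != (self.k_true,) or (mixing < 0).any():
            raise ValueError("mixing must be k_true non-negative proportions")
        if abs(mixing.sum() - 1.0) > 1e-12:
            raise ValueError("mixing proportions must sum to 1")
        if len(self.emissions) != self.s:
            raise ValueError("one emission matrix per feature is required")
        for l, emission in enumerate(self.emissions):
            emission = np.asarray(emission, dtype=float)
            if emission.ndim != 2 or emission.shape[0] != self.k_true:
                raise ValueError(f"feature {l}: emission must be (k_true, p_l)")
            if (emission < 0).any():
                raise ValueError(f"feature {l}: negative emission probability")
            if np.abs(emission.sum(axis=1) - 1.0).max() > 1e-12:
                raise ValueError(f"feature {l}: emission rows must sum to 1")
        for l, splits in self.redundancy_map.items():
            for latent, split in splits.items():
                probs = np.asarray(list(split.values()), dtype=float)
                if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-12:
                    raise ValueError(
                        f"feature {l}, category {latent}: split probabilities "
                        "must be non-negative and sum to 1"
                    )

    def without_redundancy(self) -> "GeneratorSpec":
        return GeneratorSpec(
            n=self.n,
            s=self.s,
            k_true=self.k_true,
            mixing=self.mixing,
            emissions=self.emissions,
            redundancy_map={},
            seed=self.seed,
        )

    def to_json(self, path=None) -> str:
        doc = {
            "n": self.n,
            "s": self.s,
            "k_true": self.k_true,
            "mixing": list(self.mixing),
            "emissions": [np.asarray(e).tolist() for e in self.emissions],
            "redundancy_map": {
                str(l): {
                    latent: dict(split) for latent, split in splits.items()
                }
                for l, splits in self.redundancy_map.items()
            },
            "seed": self.seed,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as handle:
                handle.write(text)
        return text


def generate(spec: GeneratorSpec) -> CategoricalDataset:
    """Draw a dataset from the spec; deterministic given its seed.

    True cluster labels are attached as ``k0 .. k{K-1}``.
    """
    rng = np.random.default_rng(spec.seed)
    z = rng.choice(spec.k_true, size=spec.n, p=np.asarray(spec.mixing, dtype=float))
    cells = np.empty((spec.n, spec.s), dtype=object)
    for l in range(spec.s):
        emission = np.asarray(spec.emissions[l], dtype=float)
        cdf = np.cumsum(emission, axis=1)
        cdf[:, -1] = 1.0
        draws = rng.random(spec.n)
        idx = (draws[:, None] > cdf[z]).sum(axis=1)
        col = np.array([f"c{c}" for c in idx], dtype=object)
        splits = spec.redundancy_map.get(l, {})
        for latent, split in splits.items():
            hit = np.nonzero(col == latent)[0]
            if hit.size == 0:
                continue
            surfaces = list(split.keys())
            probs = np.asarray([split[code] for code in surfaces], dtype=float)
            choice = rng.choice(len(surfaces), size=hit.size, p=probs)
            col[hit] = [surfaces[c] for c in choice]
        cells[:, l] = col
    labels = tuple(f"k{c}" for c in z)
    return CategoricalDataset.from_cells(cells, labels=labels)


def make_separable_scenario(
    n: int, s: int, k_true: int, separation: float, seed: int
) -> GeneratorSpec:
    """Clusters with one preferred category per feature.

    Each cluster puts mass ``1 - separation`` on its own category and
    spreads ``separation`` uniformly over all categories, so separation 0
    gives disjoint supports and separation 1 identical (uniform) emissions.
    """
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must lie in [0, 1]")
    p = max(k_true, 2)
    emission = np.full((k_true, p), separation / p)
    emission[np.arange(k_true), np.arange(k_true)] += 1.0 - separation
    return GeneratorSpec(
        n=n,
        s=s,
        k_true=k_true,
        mixing=tuple([1.0 / k_true] * k_true),
        emissions=tuple([emission.copy() for _ in range(s)]),
        seed=seed,
    )


#: Emission rows of the redundant scenario's two clusters over the latent
#: categories (c0, c1, c2, c3): a *tight* cluster concentrated on c0 and a
#: *diffuse* cluster spreading its mass over c1, c2, c3.
REDUNDANT_TIGHT_EMISSION = (0.85, 0.05, 0.05, 0.05)
REDUNDANT_DIFFUSE_EMISSION = (0.10, 0.54, 0.18, 0.18)
REDUNDANT_MIXING = (0.35, 0.65)


def make_redundant_scenario(n: int, s: int, seed: int) -> GeneratorSpec:
    """Two clusters whose preferred categories are split into sibling codes.

    The latent structure pairs a *tight* cluster (mass 0.85 on its category
    c0) with a *diffuse* one (mass spread over c1, c2, c3) — the shape of
    real diagnostic data, where one group is homogeneous and the other
    heterogeneous. Each cluster's preferred latent category (c0 and c1) is
    then replaced 50/50 by two surface codes at every feature.

    Both traits defeat simple matching while leaving the co-occurrence
    distance intact: sibling surface codes are distance 1 under Hamming yet
    have identical co-occurrence profiles up to sampling noise, and Hamming
    charges a full unit for mismatches among the diffuse cluster's own
    categories, which pulls its records toward the tight cluster, whereas
    the co-occurrence distance between them is small.
    """
    if s < 3:
        raise ValueError("the redundant scenario needs at least three features")
    emission = np.array([REDUNDANT_TIGHT_EMISSION, REDUNDANT_DIFFUSE_EMISSION])
    split = {
        "c0": {"c0a": 0.5, "c0b": 0.5},
        "c1": {"c1a": 0.5, "c1b": 0.5},
    }
    redundancy = {l: {k: dict(v) for k, v in split.items()} for l in range(s)}
    return GeneratorSpec(
        n=n,
        s=s,
        k_true=2,
        mixing=REDUNDANT_MIXING,
        emissions=tuple([emission.copy() for _ in range(s)]),
        redundancy_map=redundancy,
        seed=seed,
    )
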