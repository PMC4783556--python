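# Methods

## Data model

A dataset is an `n × s` grid of category codes. Codes are opaque symbols:
files that store small integers are read as strings, and nothing downstream
orders or subtracts them. Per-feature vocabularies are built from the
observed values only and sorted lexicographically, which makes every index,
tie-break and export reproducible. At least two features are required,
because the co-occurrence distance of a feature is defined against the
other features.

Missing cells (token `?` by default) are replaced once, before clustering,
by their feature's most frequent observed value; ties go to the
lexicographically smallest code. The UCI Wisconsin breast-cancer reader
(`load_wbc`) understands the original headerless 11-column layout (id,
nine features, class 2/4), drops the id, maps the class codes to
benign/malignant, and applies the same imputation. Because vocabularies
are observed-only, the question of whether those features range over 0–10
or 1–10 never arises: the vocabulary is whatever the file contains.

## The co-occurrence value distance

For feature values `x, y` of feature `i` and a co-feature `j`, the
distance is the largest achievable gap over events `w` on `j`'s values,

    δ_ij(x, y) = max_w [ p(w | x) + p(¬w | y) ] − 1 ,

where the conditionals are empirical co-occurrence frequencies over all
records. The maximising event is `{v : p(v|x) > p(v|y)}`, so the maximum
has the closed form `Σ_v max(p(v|x), p(v|y)) − 1`, which is the total
variation distance `½ Σ_v |p(v|x) − p(v|y)|`. The distance within feature
`i` averages `δ_ij` over the `s − 1` co-features (the defining text says
"every other feature"; the feature itself is excluded from the average).
Ties `p(v|x) = p(v|y)` are excluded from the reported witness event; the
value of the maximum is unaffected.

Per feature this yields a symmetric matrix with zero diagonal, entries in
[0, 1], and the triangle inequality (each per-co-feature term is a total
variation distance; averaging preserves metric properties). Tables are
computed once on the full dataset and frozen for the whole clustering run;
per-iteration re-estimation is deliberately out of scope. Since
vocabularies contain only observed values, every conditional row is well
defined. Double precision is used throughout; the test suite checks the
closed form against brute-force subset enumeration at 1e-12.

## Clustering loop

Alternating optimisation with a row-stochastic membership matrix `U`:

1. initialise `U` with uniform random rows (normalised), from the run seed;
2. fuzzy centroid update: weight of category `A_lk` in cluster `c` is
   `N_lkc / N_c`, `N_lkc = Σ_i 1[x_il = A_lk] u_ic^m`, `N_c = Σ_i u_ic^m`;
3. distances `d_ic = Σ_l Σ_t (N_ltc / N_c) δ_l(x_il, A_lt)`;
4. membership update `u_ij ∝ d_ij^(−1/(m−1))`; a record at distance zero
   from one or more centres splits its membership equally among them (the
   update is singular there — the standard fuzzy c-means convention);
5. objective `J = Σ u_ij^m d_ij`; stop when `|J_t − J_{t−1}| ≤ ε` or after
   `max_iter` iterations. The first comparison uses the objective of the
   initial memberships under the first centres, so a huge ε stops after
   one iteration, and non-convergence is reported, never raised.

Numerical notes: memberships are computed from `(d / d_min)^(−1/(m−1))`
with `d_min` the row minimum, so the small exponent at m = 1.1 (power 10)
cannot overflow; far clusters underflow to exactly 0, which is the correct
limit. A cluster whose soft mass `N_c` falls below 1e-12 is re-seeded at
the point-mass profile of a random record (from the run's seed stream)
with a logged warning.

Defaults: `K = 2`, `m = 1.1`, `ε = 1e-6`, `max_iter = 100`,
co-occurrence distance, fuzzy centroids, seed 42. The multi-run driver
derives run `r`'s seed as `seed + r`. The fuzzifier is the main scientific
knob: values near 1 give near-hard partitions (at m = 1.01 on
well-separated data the top membership exceeds 0.99); larger values blur
memberships and, with Hamming's flat geometry, can blur them badly.

**Monotone descent caveat.** The membership update minimises J exactly for
fixed distances, but the fuzzy-centroid update is a defined update rule,
not the minimiser of J in the centroid weights (that minimiser is a point
mass on the per-feature argmin category). J therefore need not decrease at
every step. Empirically the trace is monotone (relative tolerance 1e-8) in
the regimes the suite runs — the separable recovery conditions for both
distance kinds and the redundant scenario under the co-occurrence
distance — and the suite asserts it there; in strongly overlapping
regimes, Hamming runs can show relative increases on the order of 1e-5.
The convergence flag is about the stopping rule, not a claim of descent.

**Fuzzy K-modes initialisation.** The mode-centroid variant replaces the
fuzzy centroid with its per-feature weighted mode (ties to the first
vocabulary value) and measures point–centre distances against that single
value per feature. Initialising it from a uniform random `U` is degenerate:
every cluster then holds essentially half the global counts, all modes
coincide with the global mode, distances to all centres are equal, and `U`
returns to uniform — a symmetric fixed point reached immediately. The
package therefore initialises this variant the way K-modes family
algorithms usually are: `K` random pairwise-distinct records serve as
initial centres and the first memberships derive from their distances.
The fuzzy-centroid variants keep the random-membership initialisation.

## Evaluation

Fuzzy output is hardened by maximum membership (ties to the lowest cluster
index). Clusters are aligned to classes by the one-to-one assignment
maximising the matched count — exhaustive permutation search up to 8
clusters/classes, the Hungarian algorithm beyond — and the clustering
error is `100 · (n − matched) / n`. This is the only operationalisation of
"records not in their desired cluster" that is invariant to cluster
relabelling. Multi-run aggregation reports the mean and the population
standard deviation (divisor = number of runs; at 100 runs the sample
convention differs by under 1%, below reporting precision). Because
per-run confusion matrices cannot be meaningfully averaged, the reported
matrix is that of the run whose error is closest to the mean, alongside
all per-run errors.

## Synthetic data

Records are drawn from a mixture of multinomials: latent cluster from the
mixing proportions, then each feature independently from that cluster's
emission row. Conditional independence given the cluster is the simplest
structure under which the co-occurrence conditionals are consistent
estimators. An optional redundancy map post-processes cells, splitting a
latent category into surface codes with fixed probabilities.

Two ready-made scenarios:

* **Separable** (`make_separable_scenario`): each cluster puts mass
  `1 − separation` on its own category per feature and spreads
  `separation` uniformly over all categories; separation 0 gives disjoint
  supports, 1 gives identical emissions. The standard recovery conditions
  used by the tests are n = 600, s = 9, K = 2, separation 0.1 — trivially
  recoverable (mean error ≤ 2% for both distance kinds), which is the
  point: both metrics must agree when the structure is unambiguous.

* **Redundant** (`make_redundant_scenario`): two clusters over four latent
  categories per feature — a *tight* cluster with emission
  (0.85, 0.05, 0.05, 0.05) and a *diffuse* one with (0.10, 0.54, 0.18,
  0.18), mixed 0.35/0.65 — and each cluster's preferred category (c0, c1)
  split 50/50 into two surface codes at every feature. The design was
  chosen analytically, to make the two distance kinds genuinely disagree.
  With *symmetric* emissions the split alone is not enough: the Hamming
  and co-occurrence point-to-centre scores are then both affine in the
  same per-record statistic (own-category count minus opposite-category
  count), so both algorithms harden to the same partition and their mean
  errors coincide. Asymmetric concentration breaks that equivalence —
  simple matching charges a full unit for mismatches among the diffuse
  cluster's interchangeable codes, overvaluing the tight cluster's
  dominant category and pulling diffuse records into it, while the
  co-occurrence distance rates those codes as near-identical (sibling
  codes land at δ ≈ 0.05–0.08 at n = 2000 where Hamming puts 1) and keeps
  the clusters apart. This tight/diffuse shape mirrors real diagnostic
  data, where one group is homogeneous and the other heterogeneous, and
  the resulting asymmetric confusion (diffuse records absorbed by the
  tight cluster under Hamming) is the same failure mode reported for
  simple matching on the Wisconsin benchmark.

What the generator does **not** emulate: dependence between features
within a cluster, missing data, ordinal structure among codes, and class
imbalance beyond the mixing proportions. Passing the synthetic tests shows
the machinery is correct and that the co-occurrence distance exploits
redundancy/gradedness that simple matching cannot; it does not by itself
certify performance on any particular real dataset — the optional
Wisconsin integration test covers the one external benchmark.

## Problem sizes and determinism

The suites run at desk scale: distance-oracle equivalence on 200 random
small datasets (n ≤ 60, s ≤ 4, ≤ 6 categories), descent/normalisation
invariants over 55 seeded runs (n = 600 and n = 2000), recovery and
Hamming-deficiency demonstrations at their defining sizes (n = 600 and
n = 2000, 20 runs each). Every random draw — generator and clustering —
flows from explicit integer seeds; identical seeds give bit-identical
objective traces and artifacts.

## Known limitations

* The co-occurrence conditionals are full-sample plug-in estimates;
  rarely observed category values get noisy distance rows (visible as the
  sibling-code δ of ~0.05–0.08 at n = 2000 that would vanish in the limit).
* The fuzzy-centroid update has no descent guarantee (above); the
  objective trace is exposed so callers can inspect it.
* Random initialisation only; clever seeding (beyond the K-modes distinct
  record rule) is out of scope.
* Purely categorical: no numeric or mixed-type features, no alternative
  categorical dissimilarities beyond Hamming and co-occurrence, and no
  soft (fuzzy-overlap) evaluation indices.
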