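# catfuzz — fuzzy clustering for categorical data

Clustering tools for tables whose columns are unordered category codes —
the shape of many medical diagnostic datasets (e.g. cytology features
coded 1–10). Most fuzzy clustering algorithms for such data measure the
distance between two category values with simple matching (Hamming): 0 if
equal, 1 otherwise. That throws away the fact that some pairs of codes are
nearly interchangeable while others are strong evidence for different
groups. `catfuzz` implements a fuzzy c-means-style algorithm that replaces
Hamming with an unsupervised **co-occurrence distance** between category
values and represents cluster centres as **fuzzy centroids** (per-feature
weight distributions over categories), alongside the Hamming and fuzzy
K-modes baselines and the cluster-to-class evaluation protocol.

## The model

Given `n` records with `s` categorical features and `K` clusters, the
algorithm minimises

```
J = Σ_j Σ_i  u_ij^m  d(X_i, v_j),        Σ_j u_ij = 1,
```

where `U = (u_ij)` is the fuzzy membership matrix and `m > 1` the
fuzzifier, by alternating three updates:

* **Fuzzy centroid.** Cluster `c`'s centre assigns feature-`l` category
  `A_lk` the weight `N_lkc / N_c` with `N_lkc = Σ_i 1[x_il = A_lk] u_ic^m`
  and `N_c = Σ_i u_ic^m`.
* **Point–centre distance.** Per feature,
  `Ω_l(Z, c) = Σ_t (N_ltc / N_c) · δ_l(Z, A_lt)`, summed over features.
* **Membership.** `u_ij ∝ d_ij^(−1/(m−1))` (standard fuzzy c-means).

The value distance `δ_l(x, y)` is learned from the data: against each
co-feature `j` it is the largest probability gap any event `w` over `j`'s
values can achieve, `max_w [p(w|x) + p(¬w|y)] − 1`, which equals the total
variation distance between the conditional co-occurrence profiles
`p(·|x)` and `p(·|y)`; `δ_l` averages this over the other `s − 1`
features. Two codes that appear in the same contexts get distance ≈ 0
even though they differ; codes typical of different groups get distance
≈ 1. Setting `δ(x,y) = 1[x ≠ y]` instead recovers the Hamming variant,
and replacing the fuzzy centroid with its per-feature weighted mode gives
fuzzy K-modes.

Clusterings are scored against known classes by hardening memberships
(maximum membership), aligning clusters to classes with the optimal
one-to-one assignment, and reporting the percentage of records outside
their matched cluster, aggregated over repeated seeded runs.

## Worked example

The package ships a generator for categorical mixtures, including a
*redundant-category* scenario designed to separate the two distance
kinds: a tight cluster concentrated on one category per feature, a
diffuse cluster spread over several, and each cluster's preferred
category split 50/50 into two interchangeable surface codes.

```bash
catfuzz simulate --scenario redundant --n 2000 --s 9 --seed 1 --output-dir sim
catfuzz cluster sim/redundant.csv --label-column label \
    --distance cooccurrence --runs 20 --seed 7 --output-dir cooc
catfuzz cluster sim/redundant.csv --label-column label \
    --distance hamming --runs 20 --seed 7 --output-dir hamm
```

The metrics JSON of the two runs prints (abridged):

```
cooccurrence: mean_error 0.40  std 0.00  confusion [[684, 8], [0, 1308]]
hamming:      mean_error 1.80  std 0.00  confusion [[691, 1], [35, 1273]]
```

Both numbers are mean clustering error (%) over 20 random
initialisations. The co-occurrence distance misplaces 8 of 2000 records;
Hamming misplaces 36, almost all of them diffuse-cluster records pulled
into the tight cluster (35 in the lower-left confusion cell) because
simple matching charges a full unit for mismatches among the diffuse
cluster's own interchangeable codes. Inspect the learned value distances
with `catfuzz distances sim/redundant.csv --label-column label`: sibling
surface codes come out at δ ≈ 0.05 where Hamming would put 1.

The same driver handles real data: `catfuzz cluster breast-cancer-wisconsin.data --wbc --runs 100` runs the
benchmark protocol on the UCI Wisconsin breast-cancer file (not shipped;
see `tests/test_wbc_integration.py` for where to put it).

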