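# attnquality

Systematic assessment of **intrinsic visual-attention qualities** from the
response stream of a selective-attention cancellation test (an NTT-style
"Ruleout–Ignore–Eliminate" task).  The intended users are human-factors and
aviation-psychology researchers who collect per-participant sequences of
decisions — a symbol in {Y, N, I}, a correctness flag and a reaction time —
and want a reproducible pipeline from those raw sequences to a four-level
quality ranking of participant groups.

## The model

Each participant *p* is summarised by up to three intrinsic qualities:

* **W** (attention span) — the normalized number of decisions,
  `W = (I − I_min) / (I_max − I_min) ∈ [0, 1]`, where *I* is the decision
  count in the fixed 2 × 12-minute session;
* **H** (attention stability) — the Hurst exponent of the reaction-time
  sequence, estimated by rescaled-range (R/S) analysis: the series is cut
  into blocks of length *n*, each block contributes
  `R/S = (max − min of the centred partial sums) / (unbiased SD)`, and
  `(R/S)_n ~ c · n^H` gives *H* as the slope of `log (R/S)_n` on `log n`
  (with an Anis–Lloyd finite-sample correction by default; `H ≈ 0.5` is
  near-random, `H > 0.5` persistent);
* **E** (distribution-shift of attention) — the error rate of decisions,
  `E = #incorrect / #decisions ∈ [0, 1]`.

Feature vectors `[W, H]` or `[W, H, E]` are partitioned with K-means
(K = 4 by default).  Clusters are then compared with second-order
statistics: centroids and Euclidean distances, unbiased standard deviations
and covariance matrices, eigen-features (principal axes), the TrLogDet
divergence/distance `div(A, B) = (1/n)[tr(AB⁻¹) − ln det(AB⁻¹) − n]`, the
information-theoretic metric `ITM = tr(Σ) − ln det(Σ) − n` of each cluster
against the identity, and the within-cluster SSE.  Finally each factor is
ranked across clusters (High/Moderate/Low/Bottom) and the rank-sum maps the
four clusters onto quality levels 1–4 (Excellent, Good, Moderate,
Unqualified).

A synthetic-cohort generator (exact circulant-embedding fractional Gaussian
noise with target Hurst exponent, decision count and error rate, organised
into latent groups) stands in for confidential study data, so the entire
pipeline is testable offline.

## Worked example

```python
from attnquality import (four_level_cohort_spec, generate_cohort,
                         extract_features, kmeans, compute_cluster_stats,
                         rank_factor_labels, assign_levels)

cohort, truth = generate_cohort(four_level_cohort_spec(seed=1, n_per_group=30))
features = extract_features(cohort, dim=3)          # columns W, H, E
part = kmeans(features, k=4, seed=1)
stats, metrics = compute_cluster_stats(features, part.assignments, K=4)
labels = rank_factor_labels(part.centroids)
levels = assign_levels(labels, part.centroids)
```

This prints (via the obvious `print` calls):

```
centroids:
  cluster 0: [0.2734 0.5458 0.0523]  (N=29, ITM=16.292)
  cluster 1: [0.4464 0.6096 0.5887]  (N=30, ITM=14.940)
  cluster 2: [0.684  0.6078 0.0692]  (N=31, ITM=16.554)
  cluster 3: [0.7904 0.6003 0.8628]  (N=30, ITM=16.452)
total SSE = 1.4801
             span stability distribution_shift
cluster
0          Bottom    Bottom               High
1             Low      High                Low
2        Moderate  Moderate           Moderate
3            High       Low             Bottom
         score  level         name
cluster
0            9      4  Unqualified
1            7      2         Good
2            6      1    Excellent
3            8      3     Moderate
```

Cluster 2 — broad span (high W), low error rate, decent stability — earns
Level 1: its members respond quickly, accurately and steadily.  Cluster 0
(slowest responders, unstable reaction-time dynamics) is Level 4 even
though its error rate is the lowest: slow-but-careful is the classic
narrow-span profile.  Clusters are always numbered by ascending centroid W,
so labels are stable across runs.

The same pipeline is available from the shell:

```sh
attnquality simulate --seed 1 --out cohort.csv
attnquality assess --in cohort.csv --dim 3 --k 4 --seed 1 --out report/
```

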