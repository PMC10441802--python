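# Methods

## The model-averaging problem

Different clustering algorithms applied to the same data routinely return
different, individually plausible partitions. Reporting one "best" model
discards the uncertainty that comes from model choice. `clusterbma`
treats the candidate solutions as a model ensemble and averages them in a
Bayesian-model-averaging (BMA) style: each model contributes a quantity
that is comparable across algorithms — its pairwise similarity matrix —
weighted by an approximation of its posterior model probability.

For model m with allocation matrix A^m (N × K_m, rows on the probability
simplex; binary rows for hard algorithms), the similarity matrix is

    S^m = A^m (A^m)^T,   diagonal set to 1.

Entry s_ij is the probability that points i and j are co-assigned under
model m. Working at the level of co-assignment probabilities makes the
ensemble indifferent to cluster labels and to differing K_m across
models.

## Weights from internal validation indices

Marginal likelihoods are unavailable for most clustering algorithms
(many have no likelihood at all), so a clustering internal validation
index (CIVI) stands in for model evidence. With raw scores W_m and equal
model priors 1/M, the normalised weight

    Ŵ_m = W_m / Σ W_m'          (index to be maximised)
    Ŵ_m = (1/W_m) / Σ (1/W_m')  (index to be minimised)

is the approximate posterior model probability of model m. Soft
allocations are crisp-projected (argmax per row, ties to the lowest
index) before computing any index, so partition-based indices apply
uniformly.

Two indices are implemented in-package and recommended:

- **Calinski–Harabasz** (maximise): `[BGSS/(K−1)] / [WGSS/(N−K)]` with
  BGSS = Σ_k n_k‖c_k − c̄‖² and WGSS = Σ_k Σ_{x∈k}‖x − c_k‖². This is
  the standard form, which is what established index libraries compute;
  a variant with the pairwise-centroid numerator
  Σ_{j≠k} n_k d²(c_j, c_k)/(K−1) circulates in parts of the literature
  and is exposed separately as `ch_pairwise_centroid`. The standard form
  is the default everywhere.
- **S_Dbw** (minimise): Scat(K) + Dens_bw(K). Scat is the mean ratio of
  cluster-variance norms to the dataset-variance norm; Dens_bw compares,
  for each ordered cluster pair, the number of points within a threshold
  distance of the pair's midpoint against the larger of the point counts
  within the same threshold of the two centres. The threshold is the
  mean cluster-variance norm (no square root), and variances use the
  population (N-denominator) convention; both choices are deliberate and
  fixed, since conventions differ across published variants. A pair
  whose centres attract no points within the threshold contributes its
  raw midpoint count (degenerate case; essentially never reached on real
  data).

The registry is pluggable (`register_index`); silhouette and
Davies–Bouldin are pre-registered via scikit-learn. Negative raw scores
under a maximise-type index are rejected rather than silently shifted,
because shifting would change weight ratios undocumented.

## Consensus and factorisation

The consensus matrix C = Σ_m Ŵ_m S^m is an elementwise convex
combination — a posterior similarity matrix over the ensemble. Final
allocations come from symmetric simplex matrix factorisation (SSMF):

    minimise_A  Σ_{i≠j} (C_ij − (A Aᵀ)_ij)² + λ‖A‖_F²,
    rows of A on the probability simplex, A ∈ R^{N×K_BMA}.

Numerical choices, all configurable through `SsmfConfig`:

- **Solver.** Projected gradient descent: a gradient step followed by
  Euclidean projection of every row onto the simplex, with an adaptive
  step size (halved until the objective decreases, grown by 1.6× after
  each accepted step). Each iteration costs one O(N²K) product. The
  objective trace is monotone non-increasing by construction.
- **Diagonal.** Excluded from the fit: it is 1 by construction and
  carries no co-assignment information; including it would bias rows
  toward vertices.
- **Initialisation and restarts.** Rows drawn from Dirichlet(1) with the
  configured seed; `n_restarts` (default 5) starts are each descended
  for a 50-iteration pilot and the best pilot objective is run to
  convergence. Screening restarts with a fixed small budget is the same
  multi-start economy used by standard k-means implementations; on
  block-structured consensus matrices the pilot ranking and the
  converged ranking agree.
- **Convergence.** Relative objective change below `tol` (default 1e-8)
  or `max_iter` (default 5000) iterations; non-convergence warns and
  returns the best iterate.
- **Regularisation.** λ (default 0.01) adds an L2 penalty. Redundant
  columns empty primarily through the data term — exactly fitting a
  consensus with fewer than K_BMA blocks forces co-clustered rows onto a
  shared vertex — and the penalty's practical effect is a small O(λ/n_k)
  bias of each row off its vertex. Exactness statements (off-diagonal
  residual below 1e-6 on block consensus) therefore refer to the
  unregularised objective (λ = 0); with the default λ the recovered
  partition is identical and row maxima exceed 0.99.
- **Pruning.** Columns with total mass ≤ `mass_threshold`·N (default
  0.01) are removed and rows renormalised; the surviving column count
  may be smaller than K_BMA.
- **K_BMA.** `choose_k_bma` implements two heuristics: the largest
  input K_m (default) or that plus an increment, leaving headroom for
  sub-cluster structure that differs across models.

Per-point uncertainty is u_i = 1 − max_k A_ik — the probability that the
hardened allocation is not point i's true cluster. It is a point
estimate only; the factorisation provides no posterior distribution over
A.

## Synthetic data

`generate_clusters` plants K spherical unit-variance Gaussian clusters
at the vertices of a regular simplex embedded in the first K−1
coordinates; remaining dimensions are pure noise. The scale is set so
the theoretical pairwise separation index equals `sep_val`: for
unit-variance 1-D projections the quantile separation index
J = (q_L(B) − q_U(A))/(q_U(B) − q_L(A)) at level α = 0.05 has the closed
form J = (δ − 2z)/(δ + 2z), z = Φ⁻¹(0.975), inverted as
δ = 2z(1+J)/(1−J). The empirical `separation_index` estimates the
best-separating direction from sample moments (mean-difference seed,
quasi-Newton polish) and evaluates the index with sample quantiles.

What the generator emulates: multivariate-normal clusters with equal
sizes and a controllable quantile-based separation, i.e. the structure
of the benchmark inputs. What it does not emulate: anisotropic or
heteroscedastic cluster shapes, unequal cluster sizes, outliers, or
non-Gaussian tails. An anisotropic variant (per-cluster random
covariances with eigenvalues in [1, 10] and Haar-random orientations,
nearest-pair calibration of the separation index along the
normal-theory optimal projection) was prototyped during development; it
reproduced the published benchmark no better than the spherical design
and made the high-separation conditions unrealistically easy, so the
spherical design was kept. Passing benchmark tests therefore shows the
method recovers planted spherical Gaussian structure; behaviour on
strongly elongated or unbalanced clusters is exercised only indirectly
(the weighting downweights algorithms that fail on such data).

## The benchmark harness

`run_simulation_study` crosses dimensionalities (2, 10, 50) with
separation values (0.1, −0.05, −0.15), ten replicates each: 1500 points
(3 × 500) per dataset, nine base clusterers at k = 3 (hierarchical
average linkage, DIANA-style divisive, k-means, PAM, affinity
propagation, spectral, Gaussian mixture, 1×k SOM, fuzzy c-means),
Calinski–Harabasz weighting, K_BMA = 3. Reported per condition: mean and
sd of ARI against the planted labels, the same restricted to points with
allocation probability above 0.8, and the proportion of such points.
Seeds for every dataset, algorithm and solver call derive from one
master seed through counter-based `SeedSequence` paths, so the study is
bitwise reproducible and any replicate can be re-run alone.

Adapter notes: affinity propagation does not accept k, so its exemplars
are agglomerated (average linkage on exemplar centres) down to k; the
SOM uses a 1×k grid with principal-axis initialisation so each node is
one cluster; DIANA is approximated by repeatedly 2-means-splitting the
cluster with the largest diameter; PAM uses greedy BUILD initialisation
plus Voronoi iteration on the full distance matrix. Backends otherwise
run with library defaults, recorded per run.

## Known limitations

- Uncertainty is a point estimate; no posterior over allocations.
- The consensus matrix is dense N×N; very large N needs out-of-core or
  random-feature approaches that are out of scope here.
- CIVI-based weights inherit the biases of the chosen index (CH favours
  spherical clusters); the choice of index is the analyst's, by design.
- Benchmark agreement is demonstrated on synthetic Gaussian data at the
  stated scales; it is not evidence about arbitrary real data.
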