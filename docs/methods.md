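# Methods

This note documents the statistical model, the numerical conventions and the
design choices behind `netdiffstat`, in the spirit of the methods sections of
mature statistical packages. It states no empirical number that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model and hypotheses

Each biological state *S_i* (i = 1, …, r; r ≥ 2) contributes *o_i* ≥ 3
samples over one shared set of *n_v* variables. Each state's correlation
network *G_i* is treated as a single realization of a random-graph model for
that state; the question is whether all r networks were generated by the
same model. The networks are summarized either by the kernel-smoothed
density of the scaled adjacency eigenvalues *x_j / n_v* (the spectral
density) or by a vector of node/edge centralities, and the test statistic is

θ = (1/r) Σ_i D_i,

where D_i is the Kullback–Leibler divergence KL(ρ_i ‖ ρ_M) from the mean
density ρ_M (spectral route), the Euclidean distance ‖C_i − M‖ from the mean
centrality vector (vector route), or |C_i^j − M^j| per item j (per-node
route). θ ≥ 0 always, and θ = 0 exactly when the summaries coincide, so the
hypotheses are H₀: θ = 0 vs H₁: θ > 0. For r = 2 the spectral θ reduces
algebraically to the Jensen–Shannon divergence of the two densities.

The null distribution is obtained by permutation: condition labels are
reshuffled over the pooled samples with group sizes fixed (the only
size-preserving reading of resampling observations without replacement),
every network is rebuilt from scratch — correlation, scaling, thresholding
and, for the spectral route, bandwidth selection are all recomputed per
permutation — and p = (1 + #{θ* ≥ θ̂}) / (1 + B). The add-one smoothing
avoids p = 0 and makes the smallest attainable p equal to 1/(B + 1); ties
θ* = θ̂ count toward rejection. An exhaustive mode enumerates all distinct
label assignments instead (p = #/N without smoothing, the identity
assignment being one of the N). Per-node analyses reuse one shared batch of
permutations for every item, which is what makes a per-node sweep affordable
and keeps the items' null samples aligned.

Under the null with exchangeable samples this construction is exact by
symmetry; the type-I-error simulation in the test suite confirms the
empirical rejection rate at nominal 0.05 stays inside the 99% binomial
envelope over 500 runs.

## Network construction

* Correlation methods: Pearson; Spearman (average ranks, p by the t
  approximation); Kendall (tau-b, scipy's exact/asymptotic p). All p-values
  are two-sided.
* Association scales map to [0, 1]: |r|; 1 − p; 1 − q, with BH adjustment
  applied over the n_v(n_v − 1)/2 upper-triangle p-values only.
* Thresholding keeps weights strictly greater than the threshold by default
  (configurable to ≥); unweighted mode binarizes survivors to 1. The
  diagonal is always zero.
* Constant variables have undefined correlations; they get weight 0 and
  p = 1 with a logged warning. This keeps the node set identical across
  groups, which every downstream comparison requires. Missing values are
  dropped pairwise with a minimum of 3 complete pairs (else weight 0 and a
  warning).

## Spectral density and divergences

* Bandwidths: Sturges uses k = ⌈1 + log₂ n⌉ bins and h = range/k;
  Silverman uses h = 0.9 · min(sd, IQR/1.34) · n^(−1/5). Sturges is the
  default. A degenerate sample (zero spread, e.g. the all-zero spectrum of
  an empty graph) falls back to h = 10⁻³ · max(1, max|x|), so identical
  degenerate groups still produce identical densities and θ = 0.
* All compared densities are evaluated on one grid of 1024 equally spaced
  points spanning [min − 3h_max, max + 3h_max] over the union of the
  samples; Gaussian kernels are negligible beyond three bandwidths.
* Quadrature is trapezoidal. KL uses 0 log 0 = 0, and density values below
  10⁻¹² are treated as zero in the support test (a Gaussian KDE never
  produces exact zeros, so without the floor the +∞ branch could never
  fire). Inside θ and the Jensen–Shannon divergence the densities are
  floored *before* averaging and the reference's support test uses exact
  zeros: the mean of floored densities contains each floored density's
  support by construction, so +∞ cannot arise from round-off at grid points
  where the mean dips just under the floor while one group sits just above
  it.
* Grid points where every group's (floored) density coincides are excluded
  from the integrand — their true contribution is log 1 = 0 — and columns of
  identical centralities are likewise given deviation exactly 0. This
  removes pure floating-point round-off of the mean, making θ = 0 *exact*
  for identical groups rather than ≈ 10⁻¹⁶.
* The eigenvalue scaling x_j / n_v is a common factor across the compared
  groups (they share n_v), so it cannot change any test decision; it is kept
  for definiteness.
* Spectral entropy −∫ ρ log ρ dx is provided as a per-group summary.

## Centralities

Six measures on weighted undirected graphs, with shortest-path distance
d = 1/w so stronger association means a shorter path (unweighted graphs keep
unit distances):

* degree = strength (sum of incident weights; edge count when unweighted);
* eigenvector centrality by power iteration on (I + A) from a uniform start,
  normalized to max = 1. The shift guarantees convergence on bipartite
  graphs, and the uniform start gives the symmetric, deterministic limit
  when several components tie for the spectral radius; an empty graph gets
  all zeros.
* closeness = (number of reachable others) / (sum of shortest-path
  distances), which stays defined on the disconnected graphs that
  thresholding frequently produces; isolated nodes get 0;
* betweenness and edge betweenness: standard shortest-path counts
  (endpoints excluded, co-minimal paths split evenly), via networkx;
* clustering: the Barrat weighted generalization,
  c_i = [Σ_{(j,h) adjacent neighbor pairs} (w_ij + w_ih)] / [s_i (k_i − 1)],
  which reduces to the triangle-count coefficient on unweighted graphs;
  nodes with fewer than two neighbors get 0.

For edge measures the centrality vectors are aligned on the union of the
observed groups' edges; an edge absent from one group scores 0 there. During
a per-edge permutation test this universe is fixed at the observed union so
the permuted replicates stay comparable item by item.

Eigenvector normalization (max = 1) and the d = 1/w convention are
implementation choices among several defensible ones; any fixed choice
applied uniformly across groups yields a valid comparison.

## Set-level analysis, FDR, distances

Variable sets (GMT collections) are intersected with the table's variables
in column order; sets with fewer than `min_set_size` members (default 10)
are skipped with a log entry. Each set receives its own permutation stream
seeded from (master seed, CRC32 of the set name), so results do not depend
on iteration order. q-values are BH-adjusted across the analyzed sets of one
run, and separately across the nodes of one per-node analysis — never pooled
across the two levels, mirroring the two distinct output tables.

Pairwise group distances use the Jensen–Shannon divergence (spectral) or
Euclidean distance (centralities); the r × r matrix is clustered by average
linkage (UPGMA) and serialized to newick.

## Synthetic data and the evaluation harness

The generator emulates a pooled omics cohort: a zero-mean multivariate
normal with block-diagonal correlation — by default 30 variables in 5 blocks
with within-block correlation 0.7 — from which each simulation run draws r
disjoint groups of 60 samples out of a fixed pool of 600. Disjoint draws
within a run make the groups exchangeable under the null. The alternative
permutes the sample order of round(γ · n_v) randomly chosen variables in
exactly one group, preserving marginals while destroying that group's
co-expression. Simulations default to Pearson correlation with |r| weights
on a fully weighted (threshold 0) network and the degree feature, 100
permutations per test: the data are Gaussian by construction, so Pearson is
the natural default, and 1/101 p-value resolution suffices for ROC
construction.

These defaults are deliberately smaller than a full cohort-scale study
(hundreds of samples per group, thousands of variables, 1000 permutations);
they keep a 500-run calibration affordable on one CPU while preserving the
design. The power experiment runs, per replicate, one alternative comparison
(all r groups, one perturbed) and one null comparison between two of the
unperturbed groups (for r = 2, two fresh unperturbed groups, since no two
unperturbed groups exist within the comparison); the ROC sweeps a p-value
threshold over both branches and the AUC is trapezoidal. Master seeds fan
out through independent per-run streams for drawing, perturbing and testing,
so group draws match across γ values ("matched seeds") and every experiment
is reproducible bit for bit.

What passing simulations do and do not show: the generator's Gaussian
copula has no heavy tails, no outliers, no block overlap and no
marginal-specific structure, so calibration and power here demonstrate the
test's correctness and sensitivity under clean exchangeability — not its
behavior under the messier distributions of real omics data (where the
rank-based correlation options are the intended guard).

## Numerical conventions and degenerate inputs

* p-value estimator: add-one smoothing, p ≥ 1/(B + 1).
* KL support floor 10⁻¹²; bandwidth floor 10⁻³ · max(1, |x|).
* Thresholds: strict (>) by default; never admit zero-weight pairs.
* Groups need ≥ 3 samples (correlation is undefined below that), sets ≥ 2
  present members.
* Empty graphs: zero spectrum, zero centralities; all-zero graphs give
  eigenvector centrality 0 everywhere.

## Limitations

* One network per condition: populations of graphs per condition are out of
  scope, as are association measures beyond the three correlations (no
  partial correlation or mutual information).
* The spectral test responds to global structure; small localized changes
  (a few edges) are better caught by the per-node/per-edge analyses or by
  edge-level methods.
* Permutation cost grows linearly in B and in r; per-edge analyses on dense
  networks can be large (n_e up to n_v(n_v−1)/2 items).
* The weighted closeness/betweenness convention d = 1/w and the Barrat
  clustering are stated choices; alternatives (e.g. d = 1 − w, Onnela
  clustering) would give different, also defensible, rankings.
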