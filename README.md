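# netdiffstat

Statistical comparison of two or more biological correlation networks —
one network per condition — with permutation tests on whole-network
structure and on individual node/edge centralities.

## The problem

Omics studies routinely produce one samples-by-variables table (genes,
metabolites, proteins) whose rows fall into *r* ≥ 2 biological states:
tumor grades, organs, treatments, developmental stages. Building one
correlation network per state is easy; deciding *statistically* whether the
states' networks differ — and which variables drive the difference — is not,
especially when more than two states must be compared simultaneously and
only one network is available per state.

`netdiffstat` addresses exactly that setting. It is aimed at
systems-biology practitioners comparing co-expression or metabolite
correlation networks across multiple conditions, with pre-defined variable
sets (e.g. MSigDB pathways in GMT format) or over the whole table.

## The method

For each state *S₁, …, S_r* with *o_i* samples, an undirected network *G_i*
is built over the same *n_v* variables: pairwise association by Pearson,
Spearman or Kendall correlation, mapped to an edge weight in [0, 1] (|r|,
1 − p, or 1 − q with Benjamini–Hochberg adjustment), thresholded, and
optionally binarized.

Each network is then summarized and the summaries compared through the
statistic θ, the average distance of each group from the cross-group mean:

* **Spectral density.** The eigenvalues *x_j / n_v* of the weighted
  adjacency matrix are smoothed into a density ρ_{g_i} with a Gaussian
  kernel (Sturges or Silverman bandwidth). With
  ρ_{g_M} = (1/r) Σ_i ρ_{g_i},

      D_i = KL(ρ_{g_i} ‖ ρ_{g_M}),    θ = (1/r) Σ_i D_i ,

  where KL(p‖q) = ∫ p log(p/q) dx (0 log 0 = 0; +∞ when q lacks p's
  support). For r = 2 this θ is exactly the Jensen–Shannon divergence.
* **Centrality vectors.** ρ_{g_i} is replaced by the vector of node (or
  edge) centralities — degree/strength, eigenvector, closeness, betweenness,
  clustering coefficient, or edge betweenness — and D_i by the Euclidean
  distance from the mean vector.
* **Per-node analysis.** For each node *j* with centralities C_i^j and
  mean M^j = (1/r) Σ_i C_i^j,

      θ_j = (1/r) Σ_i |C_i^j − M^j| ,

  so individual variables whose network role changes can be ranked.

Significance of H₀: θ = 0 vs H₁: θ > 0 comes from a permutation null:
condition labels are reshuffled over the pooled samples (group sizes fixed),
all r networks rebuilt, θ recomputed B times, and
p = (1 + #{θ* ≥ θ̂}) / (1 + B). Sets of tests are FDR-controlled with
Benjamini–Hochberg q-values. Pairwise Jensen–Shannon (or Euclidean)
distances between groups feed an average-linkage dendrogram in newick
format.

A Monte-Carlo harness reproduces the method's operating characteristics on
synthetic data: a block-correlated Gaussian pool, disjoint group subsamples
(the null), and an alternative in which the sample order of a fraction γ of
one group's variables is permuted — marginals intact, co-expression
destroyed. Type-I error is read off null rejection rates; power is the AUC
of a ROC built from alternative-branch versus null-branch p-values.

## Worked example

Three groups of 60 samples over 20 variables share one block-correlation
structure; in the third group the sample order of half the variables is
permuted, destroying their co-expression:

```python
import numpy as np
from netdiffstat import (NetworkDifferenceTest, NodeDifferenceTest,
                         SimulationConfig, generate_population, make_alternative)

cfg = SimulationConfig(n_variables=20, n_blocks=4, n_groups=3, seed=0, pool_size=180)
pool = generate_population(cfg)
rng = np.random.default_rng(1)
groups = [pool[:60], pool[60:120], make_alternative(pool[120:180], 0.5, rng)]
X = np.vstack(groups)
y = np.repeat(["control", "treated", "stressed"], 60)

test = NetworkDifferenceTest(method="pearson", feature="pdfg",
                             n_permutations=1000, random_state=0).fit(X, y)
print(f"spectral theta = {test.theta_:.4f}, p = {test.p_value_:.4f}")
print("per-group KL from mean density:", np.round(test.per_group_distance_, 4))

nodes = NodeDifferenceTest(method="pearson", measure="degree",
                           n_permutations=1000, random_state=0).fit(X, y)
print(nodes.results_().head(5).round(3).to_string(index=False))
```

Output:

```
spectral theta = 0.0368, p = 0.0010
per-group KL from mean density: [0.0148 0.0192 0.0765]
name  n_groups measure  theta  p_value  q_value  centrality_control  centrality_treated  centrality_stressed
  v2         3  degree  1.294    0.001    0.010               3.813               4.666                1.329
  v6         3  degree  1.055    0.002    0.013               5.207               3.599                2.067
 v19         3  degree  0.966    0.001    0.010               3.698               4.583                1.967
  v0         3  degree  0.962    0.005    0.025               3.898               4.973                2.271
  v4         3  degree  0.920    0.010    0.040               3.871               5.074                2.403
```

The whole-network test rejects (p = 0.001, the smallest value possible with
B = 1000); the perturbed group carries the largest share of the divergence
(0.0765 vs ≈ 0.02); and the per-node table ranks variables whose
degree/strength collapsed in the "stressed" group (e.g. v2: 3.8 and 4.7 vs
1.3), with q-values controlling the FDR over the 20 nodes.

The same analyses run from the shell:

```sh
netdiffstat analyze   --data table.csv --label-col state --sets pathways.gmt \
                      --feature pdfg --perms 1000 --seed 1 --out sets.csv
netdiffstat nodes     --data table.csv --label-col state --feature degree \
                      --perms 1000 --seed 1 --out nodes.csv
netdiffstat distances --data table.csv --label-col state --feature pdfg \
                      --out dist.csv        # also writes dist.nwk
netdiffstat simulate  --gamma 0.5 --groups 5 --runs 100 --seed 1 --out sim
```

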