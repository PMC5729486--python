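# necknet

Anatomical network analysis (AnNA) of the mammalian neck musculoskeletal
system: from adjacency matrices of bones, ligaments and muscles to network
parameters, connectivity modules, and phylogenetic comparative statistics.

## Who this is for

Morphologists and evolutionary biologists who model anatomy as a graph —
nodes are skeletal and muscular elements, links are physical contacts
(articulations and attachments) — and want to quantify how that
organization varies across species and through evolutionary time.

## What it computes

**Network parameters** (per species, for a binary undirected anatomical
network):

| symbol | definition | morphological reading |
|---|---|---|
| N | node count | number of anatomical elements |
| K | link count | anatomical dependences (burden/constraint) |
| D | 2K / (N(N−1)) | morphological complexity |
| C | mean local clustering coefficient | integration by co-dependency |
| L | mean shortest path length over node pairs | integration by effective proximity |
| H | σ_K / μ_K of node degrees | anisomerism (heterogeneity) |
| P | 1 − Σ_m (N_m/N)² over modules m | degree of parcellation |

**Connectivity modules**: partitions maximizing Newman–Girvan modularity
Q = Σ_m [l_m/K − (d_m/2K)²] via simulated annealing (the objective of the
spin-glass community model at γ = 1), with a delete-one-link jackknife
standard error of Q, the strong-modularity rule Q − Q_error > 0.3, and a
one-sided Wilcoxon rank-sum test of each module's internal vs external
links.

**Comparative statistics** on the species × parameter matrix with a
calibrated phylogeny: Blomberg's K and multivariate Kmult, Abouheif's
Cmean (all with permutation p-values), BM / single-optimum OU / Early-burst
model comparison by AIC weights, PGLS and multivariate distance-based
PGLS (RRPP permutation inference), phylomorphospace (standardized PCA with
BM ancestral states), coefficient-of-variation analysis (bootstrap CIs,
signed-likelihood-ratio and Feltz–Miller equality tests), and disparity
through time with a Brownian-motion null envelope and the morphological
disparity index (MDI).

**Synthetic data**: a generator of neck-like musculoskeletal networks
(serial vertebral backbone, girdle/ventral bones, bilateral muscles),
pure-birth calibrated trees, and BM/OU/EB trait simulations, so the whole
pipeline is testable without any external download.

The package ships the published 48-species × 7-parameter table
(`necknet.load_neck_parameters()`), transcribed at its printed precision.

## Worked example

```python
import necknet as nn

# a synthetic neck: 7 cervical vertebrae, clavicles, bilateral muscles
net = nn.generate_network(seed=11)
print(nn.compute_all(net).rounded())
# {'N': 116, 'K': 311, 'D': 0.047, 'C': 0.44, 'L': 2.895, 'H': 1.332}

best, co = nn.consensus_modules(net, n_seeds=8, seed=1)
print(f"Q={best.Q:.3f} +/- {best.Q_error:.3f}, modules={best.n_modules}")
# Q=0.476 +/- 0.025, modules=4          -> strongly modular (Q - err > 0.3)
print(f"P={nn.parcellation(best.assignment):.3f}")
# P=0.742
```

The four modules recovered are the canonical neck regions: a mid-cervical
block (C1–C3 with their segmental muscles), a lower-cervical block
(C4–C7), a cranio-pectoral/thoracic block (cranium, scapulae, clavicles,
nuchal ligament, thoracic spine and the dorsal tract muscles) and a
ventral block (sternum, hyoid, thyroid, mandible, ribs, strap muscles and
scalenes).

On the published parameter table:

```python
t2 = nn.load_neck_parameters()
print(f"CV(N)={nn.cv(t2['N']):.3f}")                       # 0.097
print(nn.cv_bootstrap_ci(t2['N'], n_boot=10_000, seed=1))  # (0.077, 0.114)
stat, p = nn.mslrt_equal_cv([t2[c] for c in t2.columns])
print(f"MSLRT={stat:.2f}, p={p:.2g}")                      # 139.26, 1.4e-27
```

The CV of the node count is 0.097 with a bootstrap 95% CI of
(0.077, 0.114): species differ modestly in how many elements build the
neck. The CV-equality test rejects strongly — connectivity (K), density
(D) and clustering (C) are far more variable across mammals than path
length (L), heterogeneity (H) or parcellation (P). A standardized PCA of
the seven parameters puts 44% of the variance on PC1 and 27% on PC2.

The same analyses are scriptable from the shell:

```sh
necknet simulate network --seed 11 --out neck.csv
necknet modules --matrix neck.csv --seeds 8 --seed 1 --out partition.json
necknet run-all --matrices matrices/ --tree tree.nwk --outdir results/
```

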