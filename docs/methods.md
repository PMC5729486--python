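# Methods

## The network model

A species' neck musculoskeletal system is modeled as an undirected,
unweighted simple graph. Nodes are bones (cranium, cervical vertebrae
C1–Cn, thoracic spine, ribs, sternum, hyoid, scapulae, clavicles, humeri
when involved, mandible when involved), other passive elements (nuchal
ligament, thyroid cartilage) and the muscles moving head and neck. Links
are physical contacts: bone–bone articulations and the attachments of
muscles onto bones and ligaments. Bilateral elements carry an `l`/`r`
suffix; tissue type and side are inferred from a packaged, editable
abbreviation vocabulary, with unknown labels defaulting to muscle (the
open class) under a warning.

Input matrices must be square, labeled and 0/1. Asymmetric cells are
symmetrized by logical OR and nonzero diagonals dropped, each with a
warning rather than an error, because hand-curated supplementary matrices
commonly contain such slips; non-binary cells and duplicated labels are
hard errors. A disconnected network is a warning at read time but a hard
error where a computation (mean path length, module detection) is
undefined on fragments.

## Network parameters

Definitions as in the README table. Numerical conventions that required a
choice:

* **L** is the mean shortest-path distance over unordered node pairs.
  A sum form normalized by N−1 circulates in print but is inconsistent
  with published values of L ≈ 2.6–3.1 on ~100-node networks; the literal
  form remains available as `convention="table_sum"`.
* **H** uses the population standard deviation of degrees by default
  (`ddof=1` available). The choice cannot be discriminated against the
  published table without the original matrices; both are exposed.
* Local clustering of degree-0/1 nodes counts as 0 in the average
  (switchable), matching the common convention.
* Values are computed at full precision and rounded only for reporting
  (3 decimals).

## Connectivity modules

Partitions are scored with Newman–Girvan Q and found by simulated
annealing on −Q, which coincides with the spin-glass community model at
coupling γ = 1. The annealer starts from singleton modules; a sweep
proposes N single-node reassignments (90% to a random neighbor's module,
else to a random or fresh module) plus N/10 merge/split moves, accepted
by the Metropolis rule. The initial temperature is calibrated so roughly
half of sampled uphill moves are accepted; cooling is geometric (0.995
per sweep) and the search stops after 50 sweeps without improvement. All
schedule constants live in `AnnealingSchedule`. Because annealing is
stochastic, reported partitions come from a consensus helper that reruns
under several seeds, returns the best-Q partition and a co-assignment
frequency matrix; a post-process can fuse left/right mirror-image
modules, which bilateral anatomies often split.

Uncertainty in Q is a delete-one-link jackknife: each link is removed in
turn with the partition held fixed, and the standard error is
sqrt((K−1)/K · Σ(Q₍₋ₑ₎ − mean)²). A network counts as strongly modular
when Q − Q_error > 0.3 (strict). Module significance is a one-sided
Wilcoxon rank-sum test of the per-node internal versus external link
counts (alternative: internal > external), exact when both samples are
≤ 25 without ties, tie-corrected normal approximation otherwise; modules
of fewer than two nodes report no p-value. No multiple-testing correction
is applied across modules.

## Comparative statistics

The tree is parsed by dendropy; shared branch lengths give the
Brownian-motion covariance matrix C used throughout.

* **Blomberg's K**: observed MSE₀/MSE about the GLS (phylogenetic) mean
  over its BM expectation (tr C − n/Σ C⁻¹)/(n−1); p from tip-shuffling
  randomization, (count+1)/(n_perm+1). **Kmult** generalizes the ratio to
  trait matrices via traces and reduces exactly to K for one trait;
  permutation shuffles tip rows. An option z-scores the columns first —
  relevant because the network parameters span two orders of magnitude —
  and the package default is the raw-scale statistic.
* **Abouheif's Cmean**: Moran-type autocorrelation under the topological
  proximity matrix whose (i, j) entry is the product of 1/(number of
  direct descendants) over the internal nodes joining tips i and j; tested
  one-sided by tip permutation. On a star tree the statistic is flagged
  degenerate.
* **Evolutionary models**: BM, single-optimum OU and Early-burst fits
  share one likelihood with a model-specific tree transform (OU:
  fixed-root covariance on an ultrametric tree; EB: (e^{rt}−1)/r, r ≤ 0,
  recovering BM as r→0). The trait covariance matrix and root state are
  profiled out analytically; the single transform parameter is optimized
  by a 10-point grid plus bounded refinement. AIC weights compare the
  three. Parameter counts: p + p(p+1)/2 (+1 for OU/EB).
* **PGLS**: GLS by Cholesky whitening; F tests the predictor block
  against the intercept-only model. On a star tree with equal branches
  this is OLS exactly.
* **D-PGLS**: data and design whitened by C^{−1/2}; F from sums of
  squares of transformed residuals; p by residual randomization of the
  reduced model (RRPP), (count+1)/(n_perm+1).
* **Phylomorphospace**: PCA of the standardized (correlation) trait
  matrix by default — the parameters' scales differ too much for raw
  covariance to be meaningful — with covariance PCA behind a flag.
  Internal-node positions are BM best linear unbiased predictions given
  the GLS root, projected with the tip standardization and rotation.

## Variability of parameters

CV = sample (n−1) standard deviation over the mean. Confidence intervals
are percentile bootstrap over 10,000 resamples by default (BCa behind a
flag). Global equality of CVs across parameters uses a
signed-likelihood-ratio test under normal models with a common CV: given
the common CV τ, each group mean solves a quadratic, τ is profiled
numerically, and 2(l₁ − l₀) is referred to χ²(k−1). The default applies a
degrees-of-freedom (n−1) weighting of the variance terms as a small-sample
adjustment; `modified=False` gives the plain ML statistic. Pairwise
comparisons use the Feltz–Miller asymptotic χ² test with Bonferroni
correction capped at 1. On the shipped table the global statistic is
139.26 (plain ML: 142.22); third-decimal agreement with full-precision
source data is not expected since the table is printed at 3 decimals.

## Disparity through time

Disparity is the average squared pairwise Euclidean distance between
trait vectors (PC scores). Walking from the root toward the present, at
each internal-node time the curve records the mean relative disparity
(subclade disparity over whole-radiation disparity) of the lineages
present in the interval ending at that event; the root contributes 1 by
construction and the present 0. The null envelope comes from simulating
BM tip data with the ML rate matrix estimated from the observations;
MDI is the signed trapezoid area between the observed curve and the
simulated median, and its p-value the fraction of simulations whose own
area is at least the observed one. Fewer than 100 simulations trigger an
instability warning.

## Synthetic data

The network generator emulates the composition of real neck networks: a
serial bone chain (cranium–C1..Cn–thoracic spine) with girdle, ventral
and accessory bones, and a blueprint of ~40 bilateral muscles organized
into the five anatomical regions that recur across mammals
(cranio-pectoral, ventral, mid-cervical, lower cervical, thoracic
attachment patterns). Species-level variation comes from optional-muscle
presence sampling and per-muscle attachment noise (add/drop one vertebral
attachment, probability 0.3 per instance), making the two sides nearly
but not perfectly symmetric. A zero-noise template is fully
deterministic. Fidelity is statistical, not anatomical: over 100 seeds
the default 7-vertebra template yields N in ~[100, 126], K in
~[265, 333], D in ~[0.042, 0.054] and H in ~[1.19, 1.43], inside (or at
the edge of) the empirically observed ranges; it does not reproduce any
real species' wiring. What passing tests on generated data show is that
the pipeline's statistics behave correctly on networks of realistic size,
density and modular structure — not that any biological conclusion holds.

Trees are pure-birth (Yule) simulations rescaled to a root age of 170
(interpretable as Ma for a mammal-wide radiation), with tip branches
extended by one exponential waiting time so sampling falls strictly
between speciation events. Trait simulation draws matrix-normal data
with tree covariance from the chosen model (BM/OU/EB) and an arbitrary
trait covariance.

## Problem sizes in the test suite

Simulation-based checks use sizes chosen to keep the default suite fast
while preserving statistical resolution: exhaustive-search verification
of the annealer on graphs of up to 10 nodes (the set-partition count
grows as the Bell numbers, so larger graphs use planted-optimum
fixtures at N = 12); 500 Brownian replicates on 100-tip trees for the
K calibration; 1000 null simulations with 99 permutations each for the
Abouheif and D-PGLS calibrations; 30 meta-replicates of 200-simulation
DTT runs for the MDI self-consistency check. Monte-Carlo acceptance
bands are set at the 3-sigma level of the corresponding binomial noise.

## Known limitations

* Networks are binary and undirected; no weighted or directed variants.
* OU fitting assumes an ultrametric tree; only a single optimum.
* No overlapping or hierarchical community detection; annealing is
  heuristic, and on large weakly modular networks different seeds may
  return slightly different near-optimal partitions (hence the consensus
  helper).
* The jackknife treats links as independent observations, the convention
  of the modularity literature it follows, not a model of anatomical
  sampling error.
* The MSLRT assumes normal within-group variation; network counts are
  only approximately so.
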