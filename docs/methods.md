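# Methods

This note documents the models and procedures implemented in
`seapattern`, the parameters that matter, the synthetic data the tests
run on, and the design choices made where the design was genuinely open.

## OTU clustering with neighbor seeds (NbHClust)

**Model of the error process.** Pyrosequencing mis-calls the length of
homopolymer runs far more often than it substitutes bases.  A read whose
only defect is a ±1 run-length slip can fall below the species-level 97%
identity threshold against its true cluster seed (a single indel on a
70 nt read costs ~1.4 identity points), found a spurious cluster, and
inflate the OTU count.

**Procedure.** Reads are dereplicated (identical sequences merged,
multiplicities summed) and visited in abundance order — copies
descending, id ascending — so that the most abundant sequence of each
true OTU, normally the error-free one, founds its cluster.  A read joins
the first cluster whose *neighbor-seed set* contains a sequence at
identity ≥ threshold.  The neighbor-seed set of a seed is the seed plus
every sequence obtained by changing the length of exactly one
homopolymer run by up to ±`max_run_delta` (run lengths never drop below
1).  A read that matches nothing founds a new cluster.  Afterwards,
clusters smaller than `min_cluster_size` (counting pre-dereplication
reads) are dissolved and their members reassigned to the surviving
cluster with the most similar seed (ties: larger cluster, then lower
founding index).  The result is a deterministic partition of the read
ids, independent of input order.

**Pairwise identity** is matches / alignment columns of the optimal
global alignment with free end gaps (match +1, mismatch −1, gap −2) —
the standard parameterization for amplicon comparison, configurable in
principle through the module-level aligner.  Arguments are ordered
canonically before aligning because co-optimal alignments can differ in
their match/column split; without the canonical order the function would
not be exactly symmetric.  A cheap provable upper bound (length ratio
plus a q-gram count) optionally skips alignments that cannot reach the
threshold; it is tested to never change the output.

**Parameters.**

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.97 | greedy identity cutoff (species level) |
| `max_run_delta` | 1 | homopolymer radius of neighbor seeds; ±1 covers the dominant error mode |
| `min_cluster_size` | 2 | refinement floor; 2 dissolves singletons only |

`min_cluster_size` is the inflation-control knob.  The library default
(2) is the weakest nontrivial setting; the recovery experiments in the
test suite use 5 — 10% of the per-species read depth they simulate — so
that clusters founded by multi-error reads are folded back into the true
OTUs.  On real data it should scale with sequencing depth.

## Abundance processing

Relative abundance x<sub>μs</sub> = N<sub>μs</sub>/N<sub>s</sub>; cells
with fewer than `min_count` = 5 reads are zeroed (sequencing-effort
bias), OTU rows with fewer than `min_nonzero` = 3 nonzero entries are
dropped (two vectors that are zero almost everywhere correlate
spuriously), environmental rows are exempt from the sparsity filter.
Rows are then z-scored (mean 0, population SD 1).  "Zero-mean
normalization" is read as full z-scoring rather than a bare mean shift;
the choice is consequence-free downstream because plug-in MI over
equal-width bins is invariant under affine rescaling of either variable
(the bins move with the data) — a property asserted in the tests.

## Mutual-information network

Each variable's observed range is split into M equal-width bins (last
bin closed); entropies are plug-in estimates from bin frequencies with
0·log 0 = 0, in nats.  I(X, Y) = H(X) + H(Y) − H(X, Y), clamped at 0
against rounding.

* **Bin count.** Default M = ⌈√S⌉ (M = 4–5 for the 15–24 samples per
  season this method was designed around).  There is no universally
  right M; it is the most prominently configurable parameter.
* **Permutation test.** The second variable is shuffled `n_perm` = 1000
  times (permuting one side is equivalent in law to permuting both);
  p = (1 + #{I_perm ≥ I_obs})/(1 + n_perm).  The add-one rank keeps
  p ≥ 1/(n_perm+1) and the test exactly super-uniform under the null.
  Permuted MI values within 1e−12 of the observed value count as ties:
  distinct contingency tables frequently share an MI value exactly, and
  float noise must not break those ties in the observed value's favor.
  Only the joint entropy is recomputed per permutation — the marginals
  are permutation-invariant.
* **Thresholds.** p ≤ 0.01 for pairs involving an OTU, p ≤ 0.05 for
  environment–environment pairs, applied to raw per-edge p-values; an
  optional Benjamini–Hochberg flag exists but is off by default to match
  the protocol's raw thresholds.  With 1000 permutations the smallest
  attainable p is ~0.001, so the 0.01 threshold is meaningfully
  resolvable.
* **Determinism.** Each pair derives its RNG from the global seed plus
  CRC32 hashes of the (sorted) pair labels, and the permuted member of
  the pair is chosen by label order, so the network is invariant to row
  order and reproducible for a fixed seed.

## Symmetric NMF and community selection

Communities are found by minimizing F_G(O, W) = ½‖O − WᵀW‖²_F over
W ≥ 0 (r × n), where O is the network's feature matrix — by default the
adjacency A itself, since the MI weights already measure node–node
similarity; a symmetrically degree-normalized alternative
D^{−1/2}AD^{−1/2} is provided for hub-dominated networks.

**Update rule.** W is updated multiplicatively as

    W ← W ∘ ( ½ + ½ (W O) ⊘ (W WᵀW + ε) ),

with ε = 2⁻⁵² guarding the division.  The fixed points are exactly those
of the undamped rule W ← W ∘ (WO) ⊘ (WWᵀW) — both are stationary
precisely when WO = WWᵀW on the support of W — but the ½ damping is what
makes F_G provably non-increasing at every step for the *symmetric*
factorization.  In our experiments the undamped rule routinely overshoots
and increases the objective; the damped rule is monotone to machine
precision, which the test suite asserts on random symmetric inputs.

**Initialization and restarts.** W starts elementwise uniform on (0, 1]
scaled by √(mean(O)/r) so WᵀW matches O's magnitude from the first
iteration.  Multiplicative updates only reach local optima, so each r is
run from `restarts` = 10 seeded initializations and the lowest-F_G run
kept.  Iteration stops when the relative decrease of F_G falls below
`tol` = 1e−6 or after `max_iter` = 500 iterations; exact-factorization
experiments in the tests run with `tol` = 0 to reach machine-precision
fits.

**Model selection.** Column-normalizing W gives the fuzzy membership
matrix U (all-zero columns become uniform 1/r with a warning); hard
labels are per-column argmax with ties to the smallest clique index.
For r in [`r_min` = 2, `r_max` = min(n, 20)] the model with the highest
fuzzy modularity Q_f wins, ties to smaller r.  Q_f uses weighted degrees
and total edge weight by default (the network is weighted); an
unweighted toggle binarizes A for comparison with edge-count-based
reports.  For one-hot U, Q_f is exactly Newman modularity — verified
against a brute-force oracle over all partitions of small graphs.

## Topology report

Six statistics: node count, edge count, average degree 2E/N, average
unweighted local clustering coefficient (weights binarized, degree < 2
contributes 0), the degree-distribution power-law exponent, and the
fuzzy modularity of the selected community model.  The exponent is the
magnitude of the least-squares slope of log frequency vs log degree over
positive-degree, positive-frequency bins — the classic log-log
regression reading of "average power-law degree"; a Clauset-style MLE is
available as an option.  Regular degree sequences have no defined
exponent; `report` records NaN there.  The random reference is the
uniform G(n, m) graph with matching node and edge counts (degree counts
match by construction, so the comparison isolates structure), seeded and
exact in its edge count.

## Synthetic data: what it emulates and what it does not

* `simulate_reads` draws each read from a template, slipping every
  homopolymer run by ±1 with probability `homopolymer_error_rate` (0.1
  by default; a length-1 run can only grow) and substituting bases at
  `substitution_rate` (0 by default).  `random_templates` builds
  homopolymer-rich templates of 16 runs with lengths 1–8 (~72 nt) —
  short-hypervariable-region scale with the long runs that make
  pyrosequencing error-prone — and rejects template pairs above 90%
  identity.  At these defaults a read carries 1.6 slips on average and
  the error-free sequence remains each template's most abundant
  dereplicated read, which is the regime deep amplicon sequencing
  operates in and the regime the greedy abundance-ordered pass relies
  on.  Reads are assigned to samples uniformly at random, giving
  realistic multinomial count variation.  Not modelled: chimeras,
  quality scores, phylogenetically structured template sets, and
  abundance skew across species — so passing recovery tests shows the
  homopolymer mechanism works, not that real community composition is
  recovered.
* `simulate_abundance` produces standardized Gaussian rows with planted
  linearly linked pairs (b = ρa + √(1−ρ²)ε) — it emulates the
  *post-normalization* matrix, not counts, so it exercises the MI and
  permutation machinery but not compositionality or zero inflation.
* `planted_graph` is a stochastic block model with optional uniform
  (0.5–1.5) edge weights; real MI networks have heavier-tailed weight
  and degree distributions.

All generators are pure functions of (spec, seed).

## Problem sizes in tests and the acceptance script

The statistical suites run at sizes chosen to make their expected
behavior sharp while keeping the whole suite interactive: MI oracle
checks on 200 instances (S ≤ 20, M ≤ 4), permutation calibration on
1000 replicates of 99 permutations, community recovery on 20
planted-partition graphs of 60 nodes, OTU recovery on 10 simulations of
150 reads.  The acceptance script uses the same designs at 5–10
replicates each.

## Known limitations

* Greedy clustering depends on an abundant near-error-free founder per
  OTU; when every read of a species is multi-error (shallow sequencing
  of long, run-dense amplicons) clusters can fragment, and only the
  size-based refinement — with an appropriately scaled
  `min_cluster_size` — repairs this.
* Plug-in MI is biased upward at small S; the permutation test absorbs
  the bias for significance decisions but reported MI edge weights are
  not bias-corrected.
* s-NMF reaches local optima; the restart count bounds, but does not
  eliminate, selection noise in Q_f near ties.
* The pipeline aborts (with a named stage error) when the association
  network has no edges; there is no degenerate-network community output.
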