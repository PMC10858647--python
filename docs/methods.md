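# Methods

## Model

`gwasprop` treats disease-gene discovery from GWAS summary statistics as a
ranked-retrieval problem on a molecular network. An undirected gene network
with positive edge weights is converted to a column-stochastic transition
matrix

    W[i, j] = w(i, j) / deg_w(j),

where `deg_w(j)` is the weighted degree of gene *j*. The random walk with
restart (RWR, equivalently personalized PageRank or insulated diffusion)
starting from an initial probability vector `p0` has the stationary
distribution

    ps = (1 − α) (I − α W)⁻¹ p0,

with `α ∈ [0, 1)` the probability of continuing the walk at each step; the
walk restarts to `p0` with probability `1 − α`. This convention is stated
prominently because tools disagree on it: here **α = 0 means no propagation**
(`ps = p0` exactly) and α close to 1 diffuses far from the initial support.
Because W is column-stochastic (spectral radius 1), `I − αW` is invertible
for every α < 1 and the damped iteration `p ← αWp + (1 − α)p0` contracts
with factor α.

Two initial states are supported. `seed_binary` places mass `1/|S|` on each
seed gene in the network — the classical use of prior disease genes.
`pvalue_score` sets `p0(g) ∝ −log10 P(g)`, so every gene contributes
evidence proportional to its association strength. `p0` is always
renormalized to sum 1; the ranking is invariant to that scaling.

Column normalization by weighted degree was chosen over the symmetric
`D^{−1/2} A D^{−1/2}` variant: it makes W a proper Markov transition
matrix, so the restart-walk simulator and the linear-algebra solver are two
routes to the *same* distribution — an equivalence the test suite exploits —
and stationary mass is interpretable as termination frequency.

### Seeds, targets and evaluation

Seed genes are those with gene-level `P ≤ nominal_level / n_genes`
(Bonferroni; nominal level 0.01 by default, comparison inclusive at exact
equality). Target genes are catalog entries with `P < 5×10⁻⁸` (strict, per
the usual genome-wide convention) minus the seeds, so that evaluation
counts only genes *not* already known from the input study. By default seed
genes are also removed from the candidate ranking before scoring
(`exclude_seeds`); retaining them is supported and tested.

Rankings are deterministic: stationary mass descending, ties broken by
gene identifier. Retrieval quality is Precision@K and

    AP@K = (1 / min(K, M)) Σ_{N=1..K} P@N · rel(N),

with M the number of targets; the `min(K, M)` normalization keeps AP@K in
[0, 1] for every query. mAP@K is the arithmetic mean over disease–network
queries; confidence intervals across queries use a normal approximation by
default (bootstrap available). Targets absent from the evaluated network
stay in M — a small network is *penalized* for genes it cannot rank, and a
diagnostic reports the uncoverable count. K defaults to {20, 50, 100}.

### Multilayer and ensemble propagation

The supra-adjacency matrix stacks the layers' adjacencies block-diagonally
and links every pair of copies of the same gene across layers with a
coupling weight (default 1.0, all-pairs topology — the simplest reading of
"connect the same gene in different networks"; exposed as config). Initial
mass for a gene is split equally among its layer copies; after the walk the
copies' stationary masses are summed per gene (max and mean offered), so
total mass remains 1 under the sum rule. The supra system is always solved
by power iteration (tolerance 1e−12): the coupling pattern induces severe
fill-in in a direct sparse factorization, while the iteration needs only
tens of sparse matvecs.

Avg. Rank averages a gene's integer rank across per-network rankings,
restricted to genes present in at least two networks; absent networks
contribute nothing. Ties are broken by the number of supporting networks
(more first), then by identifier. Raw ranks are the default; a
`normalize_ranks` option divides by network size for ensembles of very
unequal networks.

## The restart-walk simulator

The simulator makes the restart decision **before** each move: with
probability 1 − α the current node is recorded as a termination and the
walk resets to the start gene, otherwise it moves to a neighbour chosen
proportionally to edge weight. A termination after zero moves is a
self-termination. This is the unique convention under which the empirical
termination frequency converges to the stationary RWR distribution with
`p0` the start-gene indicator, which the tests verify in total variation.
Hop histograms bin non-self terminations by unweighted shortest-path
distance at 1, 2, 3 and ≥ 4 (the last bin added so fractions always sum
to 1). Walk lengths are drawn geometrically and all active walks advance in
lock-step with grouped vectorized neighbour sampling, so 10⁵ restarts take
well under a second on small networks.

## Synthetic data: what it emulates

The generators reproduce the statistical structure the benchmark rests on,
not the biology itself:

* **Background network** — preferential attachment (default m = 3)
  mimicking the heavy-tailed degree distributions and ~0.003–0.017
  densities of real interactomes; Erdős–Rényi offered for density sweeps.
  Labels are assigned in RNG-permuted order so hub identity is random per
  instance — with a fixed mapping the same genes would be hubs in every
  layer of a multilayer instance, an artifactual cross-layer correlation.
* **Planted module** — `n_module_genes = 40` of `n_genes = 1000`, wired
  pairwise with probability `module_density = 0.08` on top of the
  background: about three intra-module partners per disease gene, an order
  of magnitude above background density. Interactome studies consistently
  find disease modules enriched but far from cliques; a much denser module
  would make topology alone sufficient to recover it, a regime in which
  comparing initialization strategies is uninformative.
* **P-values** — non-module genes draw `Uniform(0, 1)`; module genes draw
  `Beta(a, 1)` with `signal_strength a = 0.1` (median ≈ 10⁻³), the
  "sufficient quality" GWAS regime. With a = 1 the signal vanishes exactly
  and the test suite checks that retrieval falls to chance level.
* **Seed/target split** — a `seed_fraction = 0.2` of module genes is forced
  below the Bonferroni threshold (uniformly in (0, threshold], avoiding
  ties), matching the seed:target ratios (≈ 0.04–0.36) of published GWAS
  benchmark diseases; the remaining module genes are the hidden targets.
* **SNP tables** — each gene receives 1–50 SNPs drawn independently from
  the gene's null or signal distribution, reproducing the minSNP
  gene-length bias (E[min of k uniforms] = 1/(k + 1)).
* **Multilayer instances** — each layer keeps a uniform random
  `node_overlap = 0.8` fraction of all genes (module genes included: as
  with real networks, a layer may simply not contain some disease genes)
  and draws its own background; the module edge set is drawn once and
  shared across layers, restricted to the genes a layer covers.

All generators are pure functions of `(config, rng_seed)` with independent
named substreams, so partial re-runs reproduce exactly.

What the generator does **not** emulate: linkage disequilibrium and its
correlation of SNP P-values, gene length/SNP-density coupling beyond the
uniform SNP-count range, effect-size architecture, assay-specific edge
biases (study bias, bait selection), or overlapping/multiple disease
modules. Passing tests therefore demonstrate correctness of the machinery
and the qualitative behaviour of the methods under clean planted-signal
conditions, not performance on real GWAS data.

## Numerical choices

* Sparse direct solve (`spsolve`) up to 50 000 nodes, power iteration
  (L1 tolerance 1e−10, max 10 000 iterations) above; the supra matrix is
  always iterated (see above). The two solvers agree to L1 < 1e−8 on random
  graphs up to 2000 nodes (tested on 100 graphs).
* α = 0 short-circuits to `ps = p0` exactly, avoiding round-off from a
  trivial solve.
* Isolated nodes give all-zero columns in W and are flagged; inside the
  solvers they receive a unit diagonal entry so initial mass placed on them
  is retained in place rather than leaking — total mass is conserved for
  any network, and a warning reports isolated nodes carrying initial mass.
* P-values are validated into (0, 1]; for the −log₁₀ transform, values
  below the floor 1e−300 are clamped (summary-statistics files routinely
  contain P = 0); clamping can be disabled, in which case P = 0 raises.
* Edge weights are used when present (`binarize` drops them); duplicate
  edges in input files collapse to the maximum weight; self-loops are
  dropped with a logged count.
* Tiny negative round-off in the direct solve is clipped to zero (the exact
  solution is non-negative).

## Benchmark sizes

The shipped tests and the acceptance script run on instances of 1000 genes
(five layers of 800 for multilayer runs), 30 replicates per stochastic
comparison, 100 000 restarts per walk simulation, and 100 random graphs up
to 2000 nodes for solver agreement. These sizes give sampling error well
below the effect sizes being demonstrated while keeping a full run in the
order of a minute; all of them scale up through configuration.

## Known limitations

* Only undirected simple graphs; no heat-kernel diffusion, no
  degree-corrected RWR variants, no heterogeneous (multi-entity) networks.
* minSNP is the only built-in SNP aggregation; LD-aware gene scores
  (PEGASUS, MAGMA, VEGAS and relatives) must be computed externally and
  supplied as gene-level tables, which the pipeline accepts directly.
* The normal-approximation CI on mAP@K is crude for small query counts;
  prefer the bootstrap option when queries are few.
* Numerical equality with other PageRank implementations is not claimed —
  normalization conventions differ between libraries; equality is claimed
  (and tested) against the closed form above.
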