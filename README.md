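# gwasprop

Network propagation benchmark for GWAS gene discovery.

A genome-wide association study (GWAS) yields per-variant *P*-values, yet
many true disease genes fall short of genome-wide significance. Network
propagation spreads the association signal over a molecular network
(protein–protein interactions, co-expression, functional links) so that
genes embedded in a "hot" neighbourhood rise in the ranking even when their
own *P*-value is unremarkable. `gwasprop` provides a tested, reusable
implementation of the full benchmark pipeline for this approach — for
method developers who want a controlled test-bed and for analysts who want
to run propagation on their own summary statistics and networks.

## What it computes

**Gene scoring.** SNP-level *P*-values are aggregated per gene by the
minimum-*P* rule (minSNP); gene scores are −log₁₀ *P*. *Seed genes* are the
genes significant after a Bonferroni correction (nominal level 1% divided
by the number of tested genes) — the prior knowledge. *Target genes* are
externally catalogued disease genes at genome-wide significance
(*P* < 5×10⁻⁸) minus the seeds, so evaluation rewards only new knowledge.

**Propagation.** Random walk with restart (personalized PageRank) on the
column-stochastic transition matrix W (W_ij = w_ij / deg_w(j)):

    p_s = (1 − α) (I − α W)⁻¹ p₀

α is the probability of *continuing* the walk at each step (restart
probability 1 − α); α = 0 skips propagation entirely. p₀ is either uniform
over the seed genes (`seed_binary`) or proportional to the −log₁₀ *P*
scores (`pvalue_score`). Solvers: sparse direct solve and damped power
iteration, with a deterministic ranking (ties broken by gene identifier).

**Ensembles.** Several networks can be combined by (i) RWR on the
multilayer supra-adjacency matrix — block-diagonal layer adjacencies plus
inter-layer edges linking copies of the same gene — or (ii) averaging each
gene's rank across per-network rankings (Avg. Rank, genes present in ≥ 2
networks).

**Evaluation.** Ranked retrieval against the target set:
AP@K = (1/min(K, M)) Σ_{N≤K} P@N · rel(N), averaged over disease–network
queries into mAP@K, plus network density D = E / (N(N−1)/2).

**Walk simulation.** A Monte-Carlo simulator tallies where walks terminate
(restart) and bins the non-self terminations by hop distance from the
start gene — a practical criterion for choosing α by the desired depth of
network exploration.

**Synthetic data.** Generators produce preferential-attachment or
Erdős–Rényi networks with a planted disease module, gene/SNP *P*-value
tables (uniform null, Beta(a, 1) signal, forced Bonferroni-significant
seeds), catalog-style target tables and multilayer instances — so the whole
pipeline is testable without downloading anything.

## Worked example

```python
import gwasprop as gp

cfg = gp.SyntheticConfig(rng_seed=42)          # 1000 genes, 40-gene module
net, truth = gp.make_disease_network(cfg)
pv = gp.make_gene_pvalues(truth, cfg)

seeds = gp.select_seed_genes(pv, cfg.nominal_seed_level)
targets = gp.build_target_set(gp.make_target_catalog(truth, cfg), 5e-8, seeds)
scores = gp.neglog10_scores(pv)

for alpha in (0.0, 0.1, 0.3):
    rwr = gp.RandomWalkRestart(alpha=alpha).fit(net)
    ranking = rwr.rank(scores=scores, exclude=seeds.genes)
    ap = gp.average_precision_at_k(ranking, targets.genes, 50)
    print(f"alpha={alpha:.1f}  AP@50={ap:.3f}  top-5: {ranking[:5]}")
```

prints

```
alpha=0.0  AP@50=0.391  top-5: ['G970', 'G061', 'G147', 'G900', 'G973']
alpha=0.1  AP@50=0.433  top-5: ['G970', 'G147', 'G061', 'G973', 'G339']
alpha=0.3  AP@50=0.437  top-5: ['G147', 'G970', 'G973', 'G339', 'G061']
```

This instance has 17 seed genes (threshold 10⁻⁵) and 23 hidden targets.
At α = 0 the ranking is just the raw −log₁₀ *P* order (AP@50 = 0.391, four
of the top five are hidden targets); a conservative walk (α = 0.1–0.3)
borrows evidence from network neighbours and lifts AP@50 to ≈ 0.43, with
all five top genes true hidden targets. `RandomWalkRestart` is a
scikit-learn estimator — `get_params`/`set_params`/`clone` work, and
`transform` propagates rows of initial-mass vectors for pipeline use.

The same operations are exposed as a CLI:

```bash
gwasprop simulate --n-genes 1000 --seed 42 -o sim/
gwasprop score --scores sim/gene_scores.tsv --catalog sim/catalog.tsv \
         --seeds-out sim/seeds.txt --targets-out sim/targets.txt
gwasprop propagate --network sim/network.tsv --scores sim/gene_scores.tsv \
         --alpha 0.1 --exclude sim/seeds.txt -o sim/ranking.tsv
gwasprop evaluate --ranking sim/ranking.tsv --targets sim/targets.txt -k 50
gwasprop walksim --network sim/network.tsv --seeds sim/seeds.txt \
         --alpha 0.1 --alpha 0.3 --restarts 100000 --seed 1 -o sim/hops.tsv
gwasprop benchmark -c config.yaml     # full disease x network x alpha grid
```

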