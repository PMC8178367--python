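# pathperturb

Topology-aware pathway perturbation analysis for two-condition expression
studies (e.g. drug-treated vs vehicle-treated cell lines profiled on
expression microarrays).

Differential gene lists alone often miss coordinated, sub-threshold changes:
a signaling pathway can be strongly perturbed even when few of its genes
individually clear a fold-change/p-value filter.  `pathperturb` addresses
this by treating each pathway as a graph P = (G, I) of genes and their
interactions and scoring *connected subgraphs* with the Liptak–Stouffer
combination of per-gene z-scores,

    Z(S) = Σᵢ wᵢ zᵢ / √(Σᵢ wᵢ²),   i ∈ S,

searching for the **most perturbed subpathway** (the connected subgraph
maximizing Z), and assigning significance via a gene-label permutation null
with Bonferroni correction.  Around this core the package provides the full
supporting pipeline: equal-variance t-tests with volcano up/down/unchanged
calls, hypergeometric over-representation (DE/All tabulation), exon-level
splicing-index analysis, and Venn-style alignment of two experiments'
significant genes and pathways.  A synthetic-data generator with planted
ground truth makes every stage testable end to end.

Intended users: bioinformaticians analysing two-condition transcriptome
experiments who want pathway-level perturbation calls with explicit,
reproducible statistics — and a planted-truth simulator to validate the
whole chain.

## Worked example

Simulate a study (2000 genes, triplicates, 5% DE at |log2FC| = 2, twenty
20-gene pathways of which five carry a planted 8-gene perturbed subgraph),
then run every stage:

```sh
pathperturb all --out demo --seed 1 --n-genes 2000 --n-pathways 20 \
    --n-perturbed 5 --permutations 1000
```

which prints:

```
simulated 2000 genes, 20 pathways -> demo
up=57 down=37 unchanged=1906
tested=20 significant_at_bonferroni_0.05=3
tested=20 sets; smallest p=0.241
exons=800 significant_at_0.05=21
pipeline complete -> demo
```

and the head of `demo/pathway_perturbation.tsv` (selected columns):

```
pathway_id  Z        p_perm       p_bonferroni
pw013       9.17328  0.000999001  0.01998
pw004       8.35414  0.000999001  0.01998
pw000       8.33753  0.000999001  0.01998
pw009       7.63492  0.00599401   0.11988
pw011       7.43029  0.014985     0.2997
pw014       6.25512  0.0959041    1
```

Reading: the volcano filter (FC ≥ 2, p < 0.01) calls 94 of 2000 genes —
mostly the strongly planted DE genes, since the five planted subpathways'
genes sit at mean |z| ≈ 2.5 (p ≈ 0.012), just *below* the per-gene filter.
That is exactly the regime the topology-aware score is for: flat
over-representation sees nothing (smallest p = 0.241), yet the five
pathways carrying planted subgraphs (`pw000, pw004, pw009, pw011, pw013`
in `demo/truth.json`) occupy the top five ranks of the perturbation table,
three of them clearing Bonferroni-corrected permutation significance at
0.05 even against a null contaminated by the 100 unrelated strongly-DE
background genes.  The splicing scan flags 21 of 800 exons, dominated by
the 16 planted 4.65-fold exon-loss events.

Two runs can be aligned Venn-style:

```sh
pathperturb compare --a runA --b runB --alpha 0.05 --out comparison
# -> venn_genes.tsv, venn_pathways.tsv, top_table.tsv
```

The same functionality is available as a library:

```python
import pathperturb as pp

matrix, truth = pp.simulate_expression(2000, 3, 0.05, 2.0, 0.25, seed=1)
pathways, truth = pp.simulate_pathways(20, 20, 0.15, 5, 8, matrix, truth, seed=2)
stats = pp.compute_gene_stats(matrix, pp.RunConfig())
results = pp.analyze_pathways(pathways, stats, pp.RunConfig(permutations=1000, rng_seed=3))
print(results[0].pathway_id, results[0].Z, results[0].p_bonferroni)
```

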