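# Methods

## Overview

`pathperturb` implements a topology-aware meta-analysis of two-condition
expression experiments.  Given a log2-scale expression matrix with treated and
control replicates and a collection of pathways (gene sets, optionally with
gene–gene interaction edges), the pipeline:

1. computes per-gene differential statistics and volcano calls,
2. scores each pathway by the Liptak–Stouffer combination of its genes'
   z-scores over connected subgraphs, locating the *most perturbed
   subpathway*, with a permutation null and Bonferroni correction,
3. tabulates gene-set over-representation of the DE genes (DE/All),
4. runs an exon-level splicing-index scan, and
5. aligns two experiments' significant genes and pathways (Venn partitions
   and a ranked top table).

A synthetic-data module generates every input with known planted truth, so
each stage's recovery behaviour is measurable.

## Per-gene statistics

The test is the pooled-variance (equal-variance) two-tailed Student's t-test
with df = nₐ + n_b − 2.  Fold changes are computed from log2 means, i.e. as
ratios of geometric means — the usual convention for normalized microarray
intensities.  A gene is called *up* when FC ≥ `fc_threshold` (default 2) and
p < `p_threshold` (default 0.01), *down* when FC ≤ 1/`fc_threshold` with the
same p cut, otherwise *unchanged*; the threshold is applied symmetrically on
the ratio scale, matching a two-sided volcano filter.  No per-gene
multiple-testing correction is applied at this stage (the filter operates on
raw p); pathway-level correction happens downstream.

Signed z-scores are two-sided conversions, z = sign(log2FC) · Φ⁻¹(1 − p/2),
with z = 0 at p = 1.  Zero-pooled-variance genes are resolved by policy
rather than NaN: equal means give (t = 0, p = 1); unequal means give p = 0
with a degeneracy flag, and the z-score is clamped at ±38 (the inverse normal
diverges; 38 is beyond any attainable double-precision quantile).  The
z/p consistency identity Φ(|z|) = 1 − p/2 therefore holds exactly for all
0 < p < 1.

Two bench-assay formulas used alongside the expression analysis are included
for completeness: MTT cell survival CS% = (mean A_treated / mean A_control) ×
100 (absorbance at 490 nm), and the flow-cytometry apoptosis percentage,
the double-positive (annexin V / PI) fraction with drug minus without drug.
A negative apoptosis difference is reported with a warning rather than
rejected.

## Subpathway perturbation scoring

A pathway is a graph P = (G, I): gene set G with interaction edges I.  Edges
are undirected for connectivity purposes; signs (+1 activation, −1
inhibition, 0 unknown) are carried through but do not enter the default
score, since the combination statistic is sign-agnostic under the default
|z| scoring.  Unmeasured genes are removed *without* contracting edges —
contraction would assert interactions the input never stated.

A connected subgraph S is scored by the Liptak–Stouffer statistic

    Z(S) = Σᵢ wᵢ sᵢ / √(Σᵢ wᵢ²),  i ∈ S,

with sᵢ = |zᵢ| by default (`use_absolute_z`), since perturbed pathways mix
up- and downregulated members and perturbation is treated as magnitude;
signed mode is available.  Weights are unit by default (plain Stouffer);
an `abs_log2fc` scheme is offered (weights floored at 10⁻⁶ to stay
positive).  Z is invariant to rescaling all weights by a constant.

### Search

The most perturbed subpathway is located by a deterministic seed-and-grow
search with local refinement:

1. **Seeds:** the k = `search_seeds` (default 5) measured genes with highest
   |z|.
2. **Growth:** from each seed, repeatedly add the neighbouring gene that
   maximizes the new Z; grow to the full connected component while recording
   the best-scoring prefix.  Ties break to the lexicographically smallest
   gene id.
3. **Refinement:** the recorded prefix is then improved by a greedy local
   search that repeatedly applies the single best move — adding a
   neighbouring gene or removing a member whose removal keeps the subgraph
   connected — while Z strictly increases.  The growth phase is myopic
   around low-|z| *bridge* genes (it may enter a better-looking side branch
   before crossing the bridge, after which every recorded prefix carries the
   detour); the trim moves repair exactly this failure mode and make the
   search exact on chain- and star-shaped pathways.
4. The best result over all seeds is returned; with |z| scoring it is never
   below the best single measured gene (the top seed's own singleton is a
   recorded prefix).

On 200 random connected graphs with ≤ 12 measured nodes the search attains
≥ 98% of the exhaustively enumerated optimum (worst case), and is exact on
all tested chains and stars (see `scripts/acceptance.py`).

Pathways with no edges at all are treated as fully connected gene sets: the
whole set and each singleton are scored and the best returned.  Pathways
with fewer than `min_measured_genes` (default 3) measured genes are skipped
with a logged reason.

### Null model and correction

Pathway significance uses a gene-label permutation null: in each of B
(default 1000) permutations the measured genes' (z, weight) pairs are
resampled without replacement from the measured background, the search is
re-run, and the add-one estimator p = (1 + #{Z_b ≥ Z_obs}) / (1 + B) is
reported.  This null is conservative and fully seedable; sampling falls back
to with-replacement (with a warning) if the background is smaller than the
pathway.  The Bonferroni multiplier is the number of pathways actually
tested (eligible), not supplied.  A normal upper-tail p for Z is also
emitted for reference, but under |z| scoring and subgraph selection it is
not calibrated; the permutation p is authoritative.

Note the granularity implied by the add-one estimator: with B = 200 the
smallest attainable p is 1/201 ≈ 0.005, so Bonferroni significance at 0.05
is only reachable when at most 10 pathways are tested.  Production runs
should use B = 1000 or more.

Per-pathway permutation streams are spawned from the run seed via
`numpy.random.SeedSequence`, so results do not depend on evaluation order.

## Over-representation (DE/All)

Standard one-sided upper-tail hypergeometric ORA: with N measured background
genes of which n are DE, a pathway covering K measured genes with k DE
members gets p = P(X ≥ k), X ~ Hypergeom(N, K, n), Bonferroni-corrected by
the number of sets tested.  The background is the measured genes — what a
matrix-based run can know — not the genome.  The DE/All fraction k/K is the
tabulated reporting unit.

## Splicing index

For each exon, the splicing index contrasts the exon/gene signal ratio
between conditions:

    SI = log2( (exon_t/gene_t) / (exon_c/gene_c) ),

with per-condition ratios over geometric means of raw replicate signals;
fold = 2^|SI| ≥ 1 and direction is *reduced* when SI < 0 beyond a 10⁻⁹
tolerance.  Significance is the pooled-variance t-test on per-replicate
log2(exon/gene) values, Bonferroni-corrected within each gene by its number
of tested exons.  Because SI is a ratio of ratios, any gene-wide shift
affecting exons and gene alike cancels exactly.  Exons with missing parent
genes or non-positive signals are skipped with a logged reason.

## Cross-experiment alignment

Significant genes (call ≠ unchanged) and pathways (Bonferroni p < α) of two
experiments are partitioned into shared / unique-to-A / unique-to-B.
"Shared" means significant in both regardless of direction by default — a
perturbed pathway can move opposite ways in two cell lines and still be
commonly impaired; a `same_direction` mode additionally requires the up/down
call to agree.  The top table ranks the union of significant genes by the
smaller of the two p-values (ties by gene id) and is truncated to 15 rows by
default.

## Synthetic data

The generators emulate a triplicate two-condition microarray design:

* **Expression** — per-gene log2 baselines uniform on [4, 12], Gaussian
  replicate noise (sd `sigma`, default 0.25 — a typical normalized-array
  residual spread); exactly ⌊n_genes · de_fraction⌋ genes (default 5%)
  receive a ±`effect_log2fc` (default 2) treated-mean shift with random
  sign.  `sigma = 0` is allowed and makes every empirical log2FC equal its
  planted value exactly.
* **Pathways** — gene sets sampled from the matrix; random edges at
  `edge_prob` plus a random spanning tree, so every pathway graph is
  connected.  Planted perturbations grow a random connected subgraph
  (seeded breadth-first expansion — connected by construction, no rejection
  sampling) of `subpath_size` genes and re-shift those genes' treated rows
  so the empirical log2FC equals the shift implied by the target mean |z|
  (default 2.5).  The shift is derived by inverting the z ← p ← t chain at
  the expected t statistic, using the pooled within-condition sd estimated
  from the matrix itself.
* **Exon tables** — gene baselines uniform on [6, 12] log2 units, exon
  offsets uniform [−1, 1], shared gene-level noise plus exon-level noise;
  planted (gene, exon) pairs have the treated exon signal divided by
  `si_fold` (default 4.65, mirroring a strong exon-loss event), giving a
  noise-free SI of exactly −log2(si_fold).

What the generators do *not* emulate: probe-level effects, batch effects,
intensity-dependent variance, correlated genes outside the planted
subgraphs, and annotation noise.  Passing recovery tests therefore
demonstrates correctness of the statistical machinery under its own model
assumptions, not performance on real arrays.

## Validation experiments and problem sizes

The repeatable measurements in `scripts/acceptance.py` (and mirrored in the
test suite) use the following designs, chosen to isolate each property:

* **Search optimality:** 200 random connected graphs with 5–12 nodes
  (plus 50 chains and 50 stars), compared against exhaustive enumeration of
  all connected subgraphs.
* **Null calibration:** 10 collections × 20 pathways over null matrices
  (500 genes, no planted signal), B = 200; the Bonferroni-significant
  fraction at 0.05 is checked against the binomial bound.
* **Power/recovery:** 10 seeds × 10 pathways (5 perturbed, 8-of-20-gene
  planted subpaths at mean |z| = 2.5), 2000-gene matrices, B = 200.  The
  background matrix carries no other planted signal: a power experiment
  measures detection of the effect under test against an otherwise null
  background.  When the background additionally contains many strongly-DE
  genes unrelated to the pathways, the gene-label permutation null absorbs
  them and pathway detection becomes deliberately conservative — that is
  the intended behaviour of the null, not a failure of the search.
* **DE recovery:** 20 seeds × 2000 genes, 5% planted at |log2FC| = 2,
  σ = 0.25, 3 replicates.
* **Splicing recovery:** noise-free exactness of the planted 4.65-fold
  loss, and sensitivity/false-rate at σ = 0.15 over 10 seeds.
* **Determinism:** the full CLI pipeline run twice at a reduced size
  (300 genes, 6 pathways, B = 50) must produce byte-identical tables;
  determinism is independent of problem size.

## Numerical choices and degenerate inputs

* Add-one permutation estimator — never returns 0, unbiased-conservative.
* Bonferroni everywhere (pathways, gene sets, within-gene exons), capped at 1;
  chosen over FDR for stringency and simplicity of the reporting unit.
* Ties in the search break to lexicographically smallest gene (set);
  all-zero z returns the lexicographically smallest singleton.
* Result tables serialize floats at 6 significant digits and round-trip.
* Missing/non-numeric expression cells: the whole gene row is dropped with a
  logged count (`drop_incomplete`, default on); strict mode raises instead.
* Gene identifiers match by exact, case-sensitive string equality; no alias
  resolution is attempted.

## Open design points

* The GMT + SIF input dialect is this package's choice of pathway encoding;
  any interaction source that can be flattened to signed pairs works.
* Whether interaction signs should modulate the score is left open; they are
  parsed and preserved so a signed scoring variant can be added without
  format changes.
* The splicing scan operates at whatever row granularity the exon table
  provides (exon- or probeset-level rows both work; per-row records and
  their per-gene maxima are reported).

## Known limitations

* The permutation null permutes gene labels only; it does not preserve
  gene–gene correlation, so on real data with strong co-expression the null
  is anti-conservative in principle (standard for this class of methods).
* The seed-and-grow search is a heuristic: optimality is guaranteed only
  empirically (≥ 0.95 × exhaustive optimum on small graphs, exact on chains
  and stars in all tested instances).
* Equal-variance t-tests with 3 replicates per arm are low-powered for
  subtle effects; no variance moderation (limma-style shrinkage) is applied,
  by design, to keep the per-gene statistic the plain textbook test.
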