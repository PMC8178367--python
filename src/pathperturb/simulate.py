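"""Synthetic two-condition microarray data with known planted truth.

Three generators cover the pipeline's inputs: a log2-scale expression matrix
with planted fold changes, connected pathway graphs with planted perturbed
subgraphs, and exon/gene signal tables with planted exon-specific signal loss.
All generators are pure functions of their parameters and seed: the same seed
yields bit-identical output.

The noise model is Gaussian on the log2 scale, the standard assumption for
normalized microarray intensities; baselines are uniform on [4, 12] log2
units.  ``sigma = 0`` is allowed and produces noise-free data whose empirical
effects equal the planted truth exactly (useful for exactness tests).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .models import CONTROL, TREATED, ExpressionMatrix, PathwayGraph, SyntheticTruth

log = logging.getLogger("pathperturb")


def _sample_names(replicates: int) -> tuple[list[str], list[str]]:
    treated = [f"{TREATED}_{i + 1}" for i in range(replicates)]
    control = [f"{CONTROL}_{i + 1}" for i in range(replicates)]
    return treated, control


def conditions_for(sample_ids) -> dict[str, str]:
    """Condition map for generator-style sample names (``treated_1`` ...)."""
    out = {}
    for s in sample_ids:
        prefix = s.rsplit("_", 1)[0]
        if prefix not in (TREATED, CONTROL):
            raise ParameterError(f"cannot infer condition from sample id {s!r}")
        out[s] = prefix
    return out


def simulate_expression(
    n_genes: int,
    replicates: int = 3,
    de_fraction: float = 0.05,
    effect_log2fc: float = 2.0,
    sigma: float = 0.25,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-condition log2 expression matrix with planted fold changes.

    Exactly ``floor(n_genes * de_fraction)`` genes get their treated mean
    shifted by +/- ``effect_log2fc`` (sign random, recorded in the truth);
    every value carries Gaussian replicate noise with sd ``sigma``.
    """
    if n_genes < 10:
        raise ParameterError("n_genes must be >= 10")
    if replicates < 2:
        raise ParameterError("replicates must be >= 2")
    if not 0 <= de_fraction < 1:
        raise ParameterError("de_fraction must be in [0, 1)")
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(n_genes)]
    baseline = rng.uniform(4.0, 12.0, size=n_genes)

    n_de = int(math.floor(n_genes * de_fraction))
    de_idx = rng.permutation(n_genes)[:n_de]
    signs = rng.choice([-1.0, 1.0], size=n_de)
    shift = np.zeros(n_genes)
    shift[de_idx] = signs * effect_log2fc

    treated = baseline[:, None] + shift[:, None] + sigma * rng.standard_normal((n_genes, replicates))
    control = baseline[:, None] + sigma * rng.standard_normal((n_genes, replicates))

    t_names, c_names = _sample_names(replicates)
    values = pd.DataFrame(
        np.hstack([treated, control]), index=genes, columns=t_names + c_names
    )
    matrix = ExpressionMatrix(values, conditions_for(values.columns))
    truth = SyntheticTruth(
        de_genes={genes[i]: float(shift[i]) for i in de_idx},
        rng_seed=seed,
    )
    return matrix, truth


def _estimate_sigma(matrix: ExpressionMatrix) -> float:
    """Pooled within-condition replicate sd across all genes."""
    parts = []
    for cond in (TREATED, CONTROL):
        vals = matrix.group_values(cond)
        parts.append(vals - vals.mean(axis=1, keepdims=True))
    resid = np.hstack(parts)
    dof = resid.shape[0] * (resid.shape[1] - 2)  # n_genes * (reps-1) per condition
    return float(np.sqrt((resid**2).sum() / max(dof, 1)))


def shift_for_target_z(mean_abs_z: float, sigma: float, replicates: int) -> float:
    """Log2 mean shift whose expected t-test z magnitude is ``mean_abs_z``.

    Inverts the z <- p <- t chain at the expected t statistic:
    |t| = isf_t(sf_normal(mean_abs_z), df), delta = |t| * sigma * sqrt(2/n).
    Returns an arbitrary 1.0 log2 shift when sigma is 0 (any nonzero shift is
    then infinitely significant).
    """
    if sigma == 0:
        return 1.0
    df = 2 * replicates - 2
    tail = stats.norm.sf(mean_abs_z)
    t_target = float(stats.t.isf(tail, df))
    return t_target * sigma * math.sqrt(2.0 / replicates)


def _random_connected_graph(nodes: list[str], edge_prob: float, rng) -> list[tuple[str, str, int]]:
    """Random edges at ``edge_prob`` plus a random spanning tree for connectivity."""
    n = len(nodes)
    edges: dict[frozenset, int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                edges[frozenset((nodes[i], nodes[j]))] = int(rng.choice([1, -1]))
    order = rng.permutation(n)
    for pos in range(1, n):
        a = nodes[order[pos]]
        b = nodes[order[int(rng.integers(0, pos))]]
        edges.setdefault(frozenset((a, b)), int(rng.choice([1, -1])))
    return [(*sorted(pair), sign) for pair, sign in edges.items()]


def _grow_connected_subset(adj: dict[str, set[str]], size: int, rng) -> frozenset[str]:
    """Seeded random breadth-first expansion; connectivity by construction."""
    nodes = sorted(adj)
    start = nodes[int(rng.integers(0, len(nodes)))]
    members = {start}
    frontier = set(adj[start])
    while len(members) < size:
        pick = sorted(frontier)[int(rng.integers(0, len(frontier)))]
        members.add(pick)
        frontier |= adj[pick]
        frontier -= members
    return frozenset(members)


def simulate_pathways(
    n_pathways: int,
    genes_per_pathway: int,
    edge_prob: float,
    n_perturbed: int,
    subpath_size: int,
    matrix: ExpressionMatrix,
    truth: SyntheticTruth,
    mean_abs_z: float = 2.5,
    seed: int = 0,
) -> tuple[list[PathwayGraph], SyntheticTruth]:
    """Connected random pathway graphs with planted perturbed subgraphs.

    Pathway gene sets are sampled from the matrix's genes.  In each of
    ``n_perturbed`` pathways a random connected subgraph of ``subpath_size``
    genes has its treated rows re-shifted **in place** in ``matrix`` so the
    empirical log2 fold change equals the shift implied by ``mean_abs_z``
    exactly (expected per-gene |z| ~ mean_abs_z under the matrix's noise).
    The truth is updated with the planted subgraphs and shifts.
    """
    if subpath_size > genes_per_pathway:
        raise ParameterError("subpath_size must be <= genes_per_pathway")
    if n_perturbed > n_pathways:
        raise ParameterError("n_perturbed must be <= n_pathways")
    if genes_per_pathway > len(matrix.gene_ids):
        raise ParameterError("genes_per_pathway exceeds number of genes in matrix")
    if subpath_size < 1 or n_pathways < 1:
        raise ParameterError("sizes must be >= 1")

    rng = np.random.default_rng(seed)
    gene_ids = np.array(matrix.gene_ids)
    replicates = len(matrix.samples_for(TREATED))
    sigma = _estimate_sigma(matrix)
    delta = shift_for_target_z(mean_abs_z, sigma, replicates)
    t_cols = matrix.samples_for(TREATED)
    c_cols = matrix.samples_for(CONTROL)

    perturbed_ids = set(rng.choice(n_pathways, size=n_perturbed, replace=False).tolist())
    pathways: list[PathwayGraph] = []
    for p in range(n_pathways):
        members = sorted(rng.choice(gene_ids, size=genes_per_pathway, replace=False).tolist())
        edges = _random_connected_graph(members, edge_prob, rng)
        pid = f"pw{p:03d}"
        pw = PathwayGraph(pid, f"synthetic pathway {p}", frozenset(members), tuple(edges))
        pathways.append(pw)
        if p in perturbed_ids:
            planted = _grow_connected_subset(pw.adjacency(), subpath_size, rng)
            for gene in sorted(planted):
                sign = float(rng.choice([-1.0, 1.0]))
                row_t = matrix.values.loc[gene, t_cols].to_numpy(dtype=float)
                row_c = matrix.values.loc[gene, c_cols].to_numpy(dtype=float)
                current = row_t.mean() - row_c.mean()
                matrix.values.loc[gene, t_cols] = row_t + (sign * delta - current)
                truth.de_genes[gene] = sign * delta
            truth.perturbed_pathways[pid] = planted
    return pathways, truth


def simulate_exon_table(
    n_genes: int,
    exons_per_gene: int = 8,
    replicates: int = 3,
    spliced_fraction: float = 0.02,
    si_fold: float = 4.65,
    sigma: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Raw-scale exon and gene signal tables with planted exon-level loss.

    Signals are generated on the log2 scale (gene baseline uniform [6, 12],
    exon offsets uniform [-1, 1], Gaussian noise sd ``sigma``) and returned as
    raw (2**log2) positive values.  For each planted (gene, exon) pair the
    treated exon signal is divided by ``si_fold`` so the exon/gene ratio drops
    by exactly that factor in expectation (exactly when sigma = 0).
    """
    if exons_per_gene < 2:
        raise ParameterError("exons_per_gene must be >= 2")
    if si_fold < 1:
        raise ParameterError("si_fold must be >= 1")
    if replicates < 2:
        raise ParameterError("replicates must be >= 2")
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    genes = [f"sg{i:0{width}d}" for i in range(n_genes)]
    t_names, c_names = _sample_names(replicates)
    samples = t_names + c_names

    base = rng.uniform(6.0, 12.0, size=n_genes)
    offsets = rng.uniform(-1.0, 1.0, size=(n_genes, exons_per_gene))

    total = n_genes * exons_per_gene
    n_spliced = int(math.floor(total * spliced_fraction))
    flat = rng.permutation(total)[:n_spliced]
    spliced = {(int(f // exons_per_gene), int(f % exons_per_gene)) for f in flat}

    gene_log2 = base[:, None] + sigma * rng.standard_normal((n_genes, 2 * replicates))
    exon_rows = []
    truth_spliced: dict[tuple[str, str], float] = {}
    for gi, gene in enumerate(genes):
        for ei in range(exons_per_gene):
            exon_id = f"e{ei + 1}"
            row = (
                gene_log2[gi]
                + offsets[gi, ei]
                + sigma * rng.standard_normal(2 * replicates)
            )
            if (gi, ei) in spliced:
                row = row.copy()
                row[:replicates] -= math.log2(si_fold)  # treated columns first
                truth_spliced[(gene, exon_id)] = float(si_fold)
            exon_rows.append([gene, exon_id, *np.exp2(row)])

    exon_df = pd.DataFrame(exon_rows, columns=["gene", "exon_id", *samples])
    gene_df = pd.DataFrame(np.exp2(gene_log2), index=pd.Index(genes, name="gene"), columns=samples)
    truth = SyntheticTruth(spliced_exons=truth_spliced, rng_seed=seed)
    return exon_df, gene_df, truth
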