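"""Gene-set over-representation (DE/All tabulation).

The statistic is the standard one-sided upper-tail hypergeometric test: with
N measured background genes of which n are differentially expressed, a
pathway covering K measured genes containing k DE genes gets
p = P(X >= k), X ~ Hypergeom(N, K, n).  The background is the set of
measured genes (what a matrix-based run can know), not the genome.
Bonferroni correction multiplies by the number of gene sets tested.
"""

from __future__ import annotations

import logging
from typing import Sequence

from scipy import stats

from .errors import ParameterError
from .models import EnrichmentRecord, GeneStat, PathwayGraph, RunConfig

log = logging.getLogger("pathperturb")


def hypergeometric_enrichment(
    pathway_genes: frozenset[str] | set[str],
    de_genes: frozenset[str] | set[str],
    background: frozenset[str] | set[str],
    pathway_id: str = "",
    n_tests: int = 1,
) -> EnrichmentRecord:
    """Upper-tail hypergeometric over-representation for one gene set."""
    if not background:
        raise ParameterError("background gene set is empty")
    if not set(pathway_genes) <= set(background):
        raise ParameterError("pathway genes must be a subset of the background")
    if not set(de_genes) <= set(background):
        raise ParameterError("DE genes must be a subset of the background")
    N = len(background)
    K = len(pathway_genes)
    n = len(de_genes)
    k = len(set(pathway_genes) & set(de_genes))
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 0.0), 1.0)
    return EnrichmentRecord(
        pathway_id=pathway_id,
        de_count=k,
        pathway_size=K,
        background_de=n,
        background_size=N,
        p_hyper=p,
        p_adjusted=min(1.0, p * n_tests),
    )


def enrichment_table(
    pathways: Sequence[PathwayGraph],
    stats_list: Sequence[GeneStat],
    config: RunConfig,
) -> list[EnrichmentRecord]:
    """One record per pathway, restricted to measured genes.

    Pathways with no measured genes are skipped (logged).  Bonferroni uses
    the number of sets tested; records are sorted ascending by raw p then id.
    """
    background = frozenset(s.gene for s in stats_list)
    de = frozenset(s.gene for s in stats_list if s.call != "unchanged")
    tested = []
    for pw in pathways:
        measured = pw.genes & background
        if not measured:
            log.info("pathway %s skipped for enrichment: no measured genes", pw.pathway_id)
            continue
        tested.append((pw.pathway_id, measured))
    m = len(tested)
    records = [
        hypergeometric_enrichment(measured, de, background, pathway_id=pid, n_tests=m)
        for pid, measured in tested
    ]
    records.sort(key=lambda r: (r.p_hyper, r.pathway_id))
    return records
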