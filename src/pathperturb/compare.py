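"""Cross-experiment alignment of differentially expressed genes and
significantly perturbed pathways (Venn-style partitions and a ranked top
table over the union of significant genes).

"Significant" means call != unchanged for genes and Bonferroni-corrected
permutation p < alpha for pathways.  By default significance in both
experiments suffices regardless of direction; ``same_direction`` requires
the up/down call to agree as well.
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple, Sequence

from .models import AlignmentReport, GeneStat, SubpathwayResult, TopTableRecord

log = logging.getLogger("pathperturb")


def _significant_genes(stats_list: Sequence[GeneStat]) -> dict[str, GeneStat]:
    return {s.gene: s for s in stats_list if s.call != "unchanged"}


def align_experiments(
    genes_a: Sequence[GeneStat],
    pathways_a: Sequence[SubpathwayResult],
    genes_b: Sequence[GeneStat],
    pathways_b: Sequence[SubpathwayResult],
    alpha: float = 0.05,
    top_n: int = 15,
    same_direction: bool = False,
) -> AlignmentReport:
    """Partition significant genes/pathways of two experiments into
    shared / unique-to-A / unique-to-B, and rank the union by p-value."""
    sig_a = _significant_genes(genes_a)
    sig_b = _significant_genes(genes_b)
    set_a, set_b = set(sig_a), set(sig_b)
    shared = set_a & set_b
    if same_direction:
        shared = {g for g in shared if sig_a[g].call == sig_b[g].call}
    if not shared and set_a and set_b and not (set_a & set_b):
        log.warning("experiments share no significant genes (disjoint identifier spaces?)")

    pw_a = {r.pathway_id for r in pathways_a if r.p_bonferroni < alpha}
    pw_b = {r.pathway_id for r in pathways_b if r.p_bonferroni < alpha}

    p_a = {s.gene: s for s in genes_a}
    p_b = {s.gene: s for s in genes_b}
    union = set_a | set_b
    rows = []
    for gene in union:
        a = p_a.get(gene)
        b = p_b.get(gene)
        rows.append(
            TopTableRecord(
                gene=gene,
                p_a=a.p_value if a else math.nan,
                fold_a=a.fold_change if a else math.nan,
                p_b=b.p_value if b else math.nan,
                fold_b=b.fold_change if b else math.nan,
            )
        )

    def rank_key(rec: TopTableRecord):
        candidates = [p for p in (rec.p_a, rec.p_b) if not math.isnan(p)]
        return (min(candidates) if candidates else math.inf, rec.gene)

    rows.sort(key=rank_key)
    return AlignmentReport(
        shared_genes=frozenset(shared),
        unique_to_a=frozenset(set_a - shared),
        unique_to_b=frozenset(set_b - shared),
        shared_pathways=frozenset(pw_a & pw_b),
        unique_pathways_a=frozenset(pw_a - pw_b),
        unique_pathways_b=frozenset(pw_b - pw_a),
        top_table=rows[:top_n],
    )


class VennTriple(NamedTuple):
    a_only: int
    shared: int
    b_only: int


class VennCounts(NamedTuple):
    genes: VennTriple
    pathways: VennTriple


def venn_counts(report: AlignmentReport) -> VennCounts:
    """(|A only|, |shared|, |B only|) for genes and for pathways."""
    return VennCounts(
        genes=VennTriple(
            len(report.unique_to_a), len(report.shared_genes), len(report.unique_to_b)
        ),
        pathways=VennTriple(
            len(report.unique_pathways_a),
            len(report.shared_pathways),
            len(report.unique_pathways_b),
        ),
    )
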