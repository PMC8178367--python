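"""Exon-level splicing-index analysis.

The splicing index of an exon contrasts its exon/gene signal ratio between
conditions:

    SI = log2( (exon_t / gene_t) / (exon_c / gene_c) ),

with each condition's ratio taken over geometric means of the replicate
signals (signals are raw positive intensities).  ``fold`` = 2**|SI| >= 1, and
the direction is ``reduced`` when SI < 0 beyond a small tolerance.
Significance comes from the pooled-variance two-tailed t-test on the
per-replicate log2(exon/gene) values, Bonferroni-corrected within each gene
by the number of exons tested for that gene.  Because the index is a ratio
of ratios, any gene-wide signal shift affecting exons and gene alike cancels
exactly.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import equal_variance_t_test
from .errors import ParameterError
from .models import CONTROL, TREATED, RunConfig, SplicingIndexRecord

log = logging.getLogger("pathperturb")

SI_TOLERANCE = 1e-9

REDUCED, INCREASED, UNCHANGED = "reduced", "increased", "unchanged"


def splicing_index(
    exon_signals: Mapping[str, Sequence[float]],
    gene_signals: Mapping[str, Sequence[float]],
    gene: str = "",
    exon_id: str = "",
    n_tests: int = 1,
) -> SplicingIndexRecord:
    """Splicing-index record for one exon.

    ``exon_signals`` / ``gene_signals`` map condition -> per-replicate raw
    signals (> 0, >= 2 replicates per condition, pairwise by replicate).
    """
    ratios: dict[str, np.ndarray] = {}
    for cond in (TREATED, CONTROL):
        e = np.asarray(exon_signals[cond], dtype=float)
        g = np.asarray(gene_signals[cond], dtype=float)
        if e.size < 2 or g.size < 2:
            raise ParameterError(f"condition {cond!r} needs >= 2 replicates")
        if e.size != g.size:
            raise ParameterError(f"condition {cond!r}: exon and gene replicate counts differ")
        if np.any(e <= 0) or np.any(g <= 0):
            raise ParameterError(f"condition {cond!r}: non-positive signal")
        ratios[cond] = np.log2(e) - np.log2(g)

    log_ratio_t = float(ratios[TREATED].mean())
    log_ratio_c = float(ratios[CONTROL].mean())
    si = log_ratio_t - log_ratio_c
    t_res = equal_variance_t_test(ratios[TREATED], ratios[CONTROL])
    if si < -SI_TOLERANCE:
        direction = REDUCED
    elif si > SI_TOLERANCE:
        direction = INCREASED
    else:
        direction = UNCHANGED
    return SplicingIndexRecord(
        gene=gene,
        exon_id=exon_id,
        ratio_control=float(2.0 ** log_ratio_c),
        ratio_treated=float(2.0 ** log_ratio_t),
        si=float(si),
        fold=float(2.0 ** abs(si)),
        direction=direction,
        p_value=t_res.p,
        p_adjusted=min(1.0, t_res.p * n_tests),
    )


def splice_scan(
    exon_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    condition_of: Mapping[str, str],
    config: RunConfig,
) -> list[SplicingIndexRecord]:
    """One record per exon row, with within-gene Bonferroni correction.

    ``exon_table`` has columns ``gene``, ``exon_id`` plus one per sample;
    ``gene_table`` is gene-indexed with the same sample columns.  Exons whose
    gene is absent from the gene table, and exons with non-positive signals,
    are skipped with a logged reason.
    """
    samples = [c for c in exon_table.columns if c not in ("gene", "exon_id")]
    t_cols = [s for s in samples if condition_of.get(s) == TREATED]
    c_cols = [s for s in samples if condition_of.get(s) == CONTROL]
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ParameterError("need >= 2 replicates per condition in the exon table")

    raw: list[tuple[str, str, SplicingIndexRecord]] = []
    per_gene_tested: dict[str, int] = {}
    for row in exon_table.itertuples(index=False):
        gene, exon_id = row.gene, row.exon_id
        if gene not in gene_table.index:
            log.warning("exon %s/%s skipped: gene not in gene table", gene, exon_id)
            continue
        exon = {
            TREATED: [getattr(row, s) for s in t_cols],
            CONTROL: [getattr(row, s) for s in c_cols],
        }
        gvals = {
            TREATED: gene_table.loc[gene, t_cols].to_numpy(dtype=float),
            CONTROL: gene_table.loc[gene, c_cols].to_numpy(dtype=float),
        }
        try:
            rec = splicing_index(exon, gvals, gene=gene, exon_id=exon_id)
        except ParameterError as exc:
            log.warning("exon %s/%s skipped: %s", gene, exon_id, exc)
            continue
        raw.append((gene, exon_id, rec))
        per_gene_tested[gene] = per_gene_tested.get(gene, 0) + 1

    out = [
        SplicingIndexRecord(
            gene=rec.gene,
            exon_id=rec.exon_id,
            ratio_control=rec.ratio_control,
            ratio_treated=rec.ratio_treated,
            si=rec.si,
            fold=rec.fold,
            direction=rec.direction,
            p_value=rec.p_value,
            p_adjusted=min(1.0, rec.p_value * per_gene_tested[gene]),
        )
        for gene, exon_id, rec in raw
    ]
    out.sort(key=lambda r: (r.gene, r.exon_id))
    return out


def significant_exons(records: Sequence[SplicingIndexRecord], alpha: float) -> list[SplicingIndexRecord]:
    """Exons whose within-gene-adjusted p clears ``alpha``."""
    return [r for r in records if r.p_adjusted < alpha]
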