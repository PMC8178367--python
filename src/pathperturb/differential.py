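"""Per-gene two-condition statistics and volcano classification.

The test throughout is the pooled-variance (equal-variance) two-tailed
Student's t-test.  Genes are called ``up`` when fold change >= fc_threshold
and p < p_threshold, ``down`` when fold change <= 1/fc_threshold and
p < p_threshold, otherwise ``unchanged``.  Fold changes are computed from
log2-scale means, i.e. they are ratios of geometric means of raw intensities.

Two small assay formulas used alongside the expression analysis live here as
well: MTT cell survival (treated/control absorbance x 100) and the flow
cytometry apoptosis percentage (drug minus vehicle double-positive fraction).
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError
from .models import (
    CONTROL,
    TREATED,
    Z_DEGENERATE,
    ExpressionMatrix,
    GeneStat,
    RunConfig,
)

log = logging.getLogger("pathperturb")

UP, DOWN, UNCHANGED = "up", "down", "unchanged"


class TTestResult(NamedTuple):
    t: float
    p: float
    degenerate: bool


def equal_variance_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Pooled-variance two-tailed t-test with df = n_a + n_b - 2.

    Degenerate zero-variance inputs are resolved by policy rather than NaN:
    equal means give (t=0, p=1); unequal means give p=0 with the
    ``degenerate`` flag set.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs >= 2 values")
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, 1.0, False)
        return TTestResult(math.copysign(math.inf, diff), 0.0, True)
    t = diff / math.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(float(t), min(p, 1.0), False)


def classify(fold_change: float, p_value: float, config: RunConfig) -> str:
    if p_value < config.p_threshold:
        if fold_change >= config.fc_threshold:
            return UP
        if fold_change <= 1.0 / config.fc_threshold:
            return DOWN
    return UNCHANGED


def compute_gene_stats(matrix: ExpressionMatrix, config: RunConfig) -> list[GeneStat]:
    """One :class:`GeneStat` per gene (vectorised over the whole matrix).

    z_score = sign(log2fc) * inverse-normal(1 - p/2), 0 when p = 1 and
    clamped to +/-38 when p underflows (degenerate zero-variance genes, which
    are counted and logged but never abort the batch).
    """
    a = matrix.group_values(TREATED)
    b = matrix.group_values(CONTROL)
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    diff = mean_a - mean_b
    pooled_var = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    np.minimum(p, 1.0, out=p)

    degenerate = pooled_var == 0.0
    p[degenerate & (diff == 0.0)] = 1.0
    p[degenerate & (diff != 0.0)] = 0.0
    n_degen = int((degenerate & (diff != 0.0)).sum())
    if n_degen:
        log.warning("%d gene(s) with zero pooled variance and unequal means (p set to 0)", n_degen)

    sign = np.sign(diff)
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(p / 2.0)
    z = np.where(p >= 1.0, 0.0, np.clip(z, None, Z_DEGENERATE))
    z = np.where(sign < 0, -z, z)

    stats_out: list[GeneStat] = []
    for i, gene in enumerate(matrix.gene_ids):
        fold = float(2.0 ** diff[i])
        stats_out.append(
            GeneStat(
                gene=gene,
                mean_treated=float(mean_a[i]),
                mean_control=float(mean_b[i]),
                log2fc=float(diff[i]),
                fold_change=fold,
                p_value=float(p[i]),
                z_score=float(z[i]),
                call=classify(fold, float(p[i]), config),
            )
        )
    return stats_out


class VolcanoCounts(NamedTuple):
    n_up: int
    n_down: int
    n_unchanged: int


def volcano_counts(stats_list: Sequence[GeneStat]) -> VolcanoCounts:
    """Up/down/unchanged tally; the triple always sums to the gene count."""
    if not stats_list:
        raise ParameterError("empty gene statistics list")
    n_up = sum(1 for s in stats_list if s.call == UP)
    n_down = sum(1 for s in stats_list if s.call == DOWN)
    return VolcanoCounts(n_up, n_down, len(stats_list) - n_up - n_down)


def cell_survival_percent(mean_abs_treated: float, mean_abs_control: float) -> float:
    """MTT cell survival: (mean treated absorbance / mean control) x 100."""
    if mean_abs_control <= 0:
        raise ParameterError("control absorbance must be positive")
    return mean_abs_treated / mean_abs_control * 100.0


def apoptosis_percent(dp_with_drug: float, dp_without_drug: float) -> float:
    """Apoptosis %: double-positive fraction with drug minus without drug."""
    for name, value in (("dp_with_drug", dp_with_drug), ("dp_without_drug", dp_without_drug)):
        if not 0.0 <= value <= 100.0:
            raise ParameterError(f"{name} must be in [0, 100], got {value}")
    result = dp_with_drug - dp_without_drug
    if result < 0:
        log.warning("negative apoptosis percentage (%.3g): drug below vehicle baseline", result)
    return result
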