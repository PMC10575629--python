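"""Expression-threshold gene classification and Polycomb-dependence filters.

Genes are called expressed in a sample group when the replicate mean TPM
exceeds 1 and the coefficient of variation (sample SD / mean) is below
0.67; genes below 1 TPM are off, the rest are variable.  On top of that
sit the filters used to identify genes whose post-stem-cell
downregulation depends on the H3K27 methyltransferase E(z): either
strongly overexpressed in the E(z) germline knockdown (GLKD) relative to
wild type at stage 6, or downregulated noticeably less in the knockdown
than in wild type.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: Mean TPM above which a gene counts as expressed.
EXPRESSION_THRESHOLD_TPM = 1.0
#: CV (SD/mean) below which replicate agreement counts as consistent.
CV_THRESHOLD = 0.67
#: Floor applied to denominators of TPM ratios (below the expression
#: threshold, so it only guards silent genes against infinities).
DETECTION_FLOOR_TPM = 0.1


def _group_matrix(table: pd.DataFrame, group: str) -> pd.DataFrame:
    """Replicate columns of one sample group from a (group, replicate)
    MultiIndex-column table."""
    if isinstance(table.columns, pd.MultiIndex):
        if group not in table.columns.get_level_values(0):
            raise ValueError(f"group {group!r} not in table")
        return table[group]
    return table       # already a genes x replicates matrix


def classify_expressed(table: pd.DataFrame, group: str | None = None
                       ) -> pd.Series:
    """Per-gene expression call in one group: expressed / off / variable.

    expressed: mean TPM > 1 and SD/mean < 0.67; off: mean TPM < 1 (a
    zero mean is off — the CV is never evaluated there); variable:
    adequately abundant but inconsistent across replicates.  With a
    single replicate the CV criterion is skipped with a warning.
    """
    sub = _group_matrix(table, group) if group is not None else table
    values = sub.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("TPM values must be nonnegative")
    mean = values.mean(axis=1)
    if values.shape[1] < 2:
        warnings.warn("single replicate: CV criterion skipped, "
                      "threshold-only classification")
        labels = np.where(mean > EXPRESSION_THRESHOLD_TPM, "expressed", "off")
        return pd.Series(labels, index=sub.index, name="call")
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.inf)
    labels = np.where(
        mean <= EXPRESSION_THRESHOLD_TPM, "off",
        np.where(cv < CV_THRESHOLD, "expressed", "variable"))
    return pd.Series(labels, index=sub.index, name="call")


def set_expressed_fraction(table: pd.DataFrame, group: str,
                           gene_set) -> tuple[int, int, float]:
    """(expressed count, set size, fraction) for a gene set in a group.

    Genes absent from the table count as not expressed.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    calls = classify_expressed(table, group)
    absent = [g for g in gene_set if g not in calls.index]
    if absent:
        warnings.warn(f"{len(absent)} gene(s) absent from the table counted "
                      "as not expressed")
    n_expr = sum(1 for g in gene_set
                 if g in calls.index and calls[g] == "expressed")
    return n_expr, len(gene_set), n_expr / len(gene_set)


def fold_change_category(expr_a: float, expr_b: float,
                         floor: float = DETECTION_FLOOR_TPM) -> str:
    """Symmetric fold-change bin: within_2x, within_4x or gt_4x.

    The ratio is max/min with the minimum floored at the detection floor.
    """
    if expr_a < 0 or expr_b < 0:
        raise ValueError("TPM values must be nonnegative")
    if expr_a == 0 and expr_b == 0:
        raise ValueError("both values are zero; fold change undefined")
    hi = max(expr_a, expr_b)
    lo = max(min(expr_a, expr_b), floor)
    r = hi / lo
    if r <= 2:
        return "within_2x"
    if r <= 4:
        return "within_4x"
    return "gt_4x"


def ez_dependent_filter(gsc: float, wt_s6: float, glkd_s6: float,
                        floor: float = DETECTION_FLOOR_TPM,
                        fold_threshold: float = 3.0,
                        rescue_fraction: float = 0.8) -> set[str]:
    """E(z)-dependence call for one gene from group-mean TPMs.

    A gene expressed in the stem cell (mean > 1 TPM) is called dependent
    when (1) its knockdown stage-6 level exceeds ``fold_threshold`` times
    the wild-type stage-6 level, or (2) its decrease from the stem cell
    to stage 6 under knockdown is at most ``rescue_fraction`` of the
    wild-type decrease (both decreases must be genuine downregulation).
    Returns the satisfied criteria, or {"not_dependent"}.
    """
    for v in (gsc, wt_s6, glkd_s6):
        if v < 0:
            raise ValueError("TPM values must be nonnegative")
    flags: set[str] = set()
    if gsc > EXPRESSION_THRESHOLD_TPM:
        if glkd_s6 / max(wt_s6, floor) > fold_threshold:
            flags.add("dependent_c1")
        wt_drop = gsc - wt_s6
        glkd_drop = gsc - glkd_s6
        if wt_drop > 0 and glkd_drop > 0 and \
                glkd_drop <= rescue_fraction * wt_drop:
            flags.add("dependent_c2")
    return flags or {"not_dependent"}


def ez_contribution(gsc: float, wt_s6: float, glkd_s6: float) -> float:
    """Percent of a gene's wild-type downregulation attributable to E(z).

    Defined as the fraction of the stem-cell-to-stage-6 decrease restored
    in the knockdown, 100 * (glkd - wt) / (gsc - wt), clamped to
    [0, 100].  Undefined for genes not downregulated (gsc <= wt).
    """
    if gsc <= wt_s6:
        raise ValueError("gene is not downregulated (gsc <= wt_s6); "
                         "contribution undefined")
    pct = 100.0 * (glkd_s6 - wt_s6) / (gsc - wt_s6)
    return float(np.clip(pct, 0.0, 100.0))
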