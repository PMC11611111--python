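"""Rank-sum marker discovery with expression, fold-change and multiple-testing
filters.

The statistical core is the two-sample Wilcoxon/Mann-Whitney rank-sum test:
midranks for ties, tie-corrected normal approximation without continuity
correction, and exact enumeration of all group labelings when the pooled
sample has at most :data:`EXACT_ENUMERATION_MAX` observations. Genes are
prefiltered for moderate expression in the foreground group (mean
ln(UMI/10K+1) > 0.1 and > 5% positive cells by default) before testing, and
the multiplicity correction counts only the genes actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .atlas_io import NormalizedMatrix

__all__ = [
    "MarkerCriteria",
    "wilcoxon_rank_sum",
    "exact_rank_sum_p",
    "adjust_pvalues",
    "find_markers",
    "build_pan_glial_background",
]

#: Pooled-sample size at or below which the exact permutation distribution of
#: the rank sum is enumerated instead of the normal approximation.
EXACT_ENUMERATION_MAX = 10

MARKER_TABLE_COLUMNS = [
    "gene", "group_mean", "background_mean", "fraction_positive",
    "fold_change", "U", "z", "pvalue", "adjusted_pvalue", "passed",
]


@dataclass(frozen=True)
class MarkerCriteria:
    """Filters a gene must clear to be called a marker.

    ``min_mean_expression`` and the positivity fraction are evaluated on the
    ln(UMI/10K+1) scale in the foreground group before testing;
    ``min_fold_change`` compares de-logged (linear-scale) group means.
    """

    min_mean_expression: float = 0.1
    min_fraction_positive: float = 0.05
    min_fold_change: float | None = 3.0
    alpha: float = 0.05
    correction: str = "bonferroni"
    alternative: str = "two_sided"
    log_scale_fold: bool = False

    def __post_init__(self) -> None:
        if self.correction not in ("bonferroni", "benjamini_hochberg"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.alternative not in ("two_sided", "right_tailed"):
            raise ValueError(f"unknown alternative {self.alternative!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def _u_statistic(ranks: np.ndarray, n_x: int) -> float:
    # U for the first sample from midranks of the pooled sample.
    return float(ranks[:n_x].sum() - n_x * (n_x + 1) / 2.0)


def exact_rank_sum_p(x, y, alternative: str = "two_sided") -> float:
    """Exact rank-sum p by enumerating every assignment of the pooled values.

    Valid for any tie pattern; intended for small pooled samples (the number
    of labelings is C(n_x + n_y, n_x)).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n_x, n = len(x), len(pooled)
    u_obs = _u_statistic(ranks, n_x)
    mu = n_x * (n - n_x) / 2.0
    total = 0
    hits = 0
    for comb in combinations(range(n), n_x):
        u = float(ranks[list(comb)].sum() - n_x * (n_x + 1) / 2.0)
        total += 1
        if alternative == "right_tailed":
            hits += u >= u_obs - 1e-12
        else:
            hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
    return hits / total


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided"):
    """Two-sample rank-sum test; returns ``(U, z, p)``.

    U is the Mann-Whitney statistic of ``x`` computed with midranks. For
    pooled samples of more than :data:`EXACT_ENUMERATION_MAX` observations the
    p-value uses the tie-corrected normal approximation with no continuity
    correction; smaller samples are enumerated exactly (z is still reported
    from the normal approximation for reference). When every pooled value is
    identical there is no ordering information: z = 0 and p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = len(x), len(y)
    n = n_x + n_y
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = _u_statistic(ranks, n_x)
    mu = n_x * n_y / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u, 0.0, 1.0
    z = (u - mu) / np.sqrt(var)
    if n <= EXACT_ENUMERATION_MAX:
        p = exact_rank_sum_p(x, y, alternative)
    elif alternative == "right_tailed":
        p = float(norm.sf(z))
    else:
        p = float(2.0 * norm.sf(abs(z)))
    return u, float(z), min(p, 1.0)


def adjust_pvalues(pvalues, method: str = "benjamini_hochberg") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment, preserving input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "benjamini_hochberg":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        # step-up: enforce monotonicity from the largest p downwards
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adjusted = np.empty(m)
        adjusted[order] = np.minimum(1.0, ranked)
        return adjusted
    raise ValueError(f"unknown method {method!r}")


def find_markers(norm: NormalizedMatrix, group_cells, background_cells,
                 criteria: MarkerCriteria | None = None) -> pd.DataFrame:
    """Test every moderately expressed gene for enrichment in ``group_cells``.

    Genes failing the expression prefilter (foreground mean and positive
    fraction) are excluded before testing and before the correction counts
    them. Fold change is the ratio of de-logged means,
    (mean(expm1 x)_group + eps) / (mean(expm1 x)_background + eps), unless
    ``criteria.log_scale_fold`` asks for the difference of log-scale means.
    ``passed`` requires adjusted p < alpha and, when set, the fold threshold.
    """
    criteria = criteria or MarkerCriteria()
    group_cells = list(group_cells)
    background_cells = list(background_cells)
    if not group_cells or not background_cells:
        raise ValueError("group and background must be non-empty")
    if set(group_cells) & set(background_cells):
        raise ValueError("group and background cells must be disjoint")

    gmat = norm.subset_cells(group_cells).values
    bmat = norm.subset_cells(background_cells).values
    n_g, n_b = len(group_cells), len(background_cells)

    group_mean = np.asarray(gmat.mean(axis=1)).ravel()
    frac_pos = np.asarray((gmat > 0).sum(axis=1)).ravel() / n_g
    keep = np.flatnonzero(
        (group_mean > criteria.min_mean_expression)
        & (frac_pos > criteria.min_fraction_positive)
    )
    if keep.size == 0:
        return pd.DataFrame(columns=MARKER_TABLE_COLUMNS)

    gdense = gmat[keep].toarray()
    bdense = bmat[keep].toarray()
    eps = 1e-9
    g_lin = np.expm1(gdense).mean(axis=1)
    b_lin = np.expm1(bdense).mean(axis=1)
    bg_mean = bdense.mean(axis=1)
    if criteria.log_scale_fold:
        fold = gdense.mean(axis=1) - bg_mean
    else:
        fold = (g_lin + eps) / (b_lin + eps)

    rows = []
    for i, gi in enumerate(keep):
        u, z, p = wilcoxon_rank_sum(gdense[i], bdense[i], criteria.alternative)
        rows.append((norm.genes[gi], group_mean[gi], bg_mean[i],
                     frac_pos[gi], fold[i], u, z, p))
    table = pd.DataFrame(rows, columns=MARKER_TABLE_COLUMNS[:8])
    table["adjusted_pvalue"] = adjust_pvalues(
        table["pvalue"].to_numpy(), criteria.correction
    )
    passed = table["adjusted_pvalue"] < criteria.alpha
    if criteria.min_fold_change is not None:
        passed &= table["fold_change"] >= criteria.min_fold_change
    table["passed"] = passed
    # stable, input-order-independent output
    return table.sort_values("gene", kind="stable", ignore_index=True)


def build_pan_glial_background(cells: pd.DataFrame,
                               compartments: dict,
                               label_column: str | None = None) -> list:
    """Background cells for pan-glial marker discovery.

    Returns the non-glial cells of the atlas minus the immune and germ
    compartments (keeping epithelial, stromal, endothelial, and non-glial
    neural cells). ``compartments`` maps annotation labels to compartment
    names; the annotation is read from ``truth_label`` when present, else
    ``prior_annotation``.
    """
    if label_column is None:
        for candidate in ("truth_label", "prior_annotation"):
            if candidate in cells.columns and cells[candidate].notna().any():
                label_column = candidate
                break
    if label_column is None:
        raise ValueError(
            "no annotation column available; configure a label_column mapping "
            "cells to compartments"
        )
    comp = cells[label_column].map(compartments)
    if comp.isna().all():
        raise ValueError(
            "no annotation maps to a compartment; extend the compartments table"
        )
    keep = ~comp.isin(["glia", "immune", "germ"]) & comp.notna()
    return list(cells.loc[keep, "cell"])
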