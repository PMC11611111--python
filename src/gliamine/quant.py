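"""Proportion estimates, confidence intervals, and two-proportion z tests for
in-situ cell-count tables.

A count table is rows of ``(label, k, n)``; each row yields a point estimate
with a 95% Wilson score interval by default (Wald optional) and a percentage
rounded half-up to a stated precision. Pairwise comparisons use the pooled
two-proportion z test with no continuity correction and no multiplicity
adjustment.

The package ships curated in-situ tallies for peripheral lung and bladder
glia (class census, neurosensory-body contact patterns, GFAP / GFRA3 / MBP
co-expression by class, nerve-fiber association, bladder wall layers) as
``data/insitu_counts.tsv`` and the comparison pairs with reported
significance bounds as ``data/insitu_pairs.tsv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ProportionResult",
    "proportion_ci",
    "round_half_up",
    "two_proportion_z",
    "pairwise_tests",
    "load_count_table",
    "insitu_counts",
    "insitu_pairs",
]


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero (the convention printed figures use)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProportionResult:
    label: str
    k: int
    n: int
    estimate: float
    percent: float
    ci_low: float
    ci_high: float
    level: float
    method: str


def proportion_ci(k: int, n: int, level: float = 0.95,
                  method: str = "wilson", label: str = "",
                  percent_decimals: int = 0) -> ProportionResult:
    """Point estimate and confidence interval for a binomial proportion.

    Wilson score interval by default (well behaved at k=0 and k=n); Wald
    optional with bounds clipped to [0, 1]. ``percent`` is 100*k/n rounded
    half-up to ``percent_decimals``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("k must satisfy 0 <= k <= n")
    if method not in ("wilson", "wald"):
        raise ValueError(f"unknown CI method {method!r}")
    alpha = 1.0 - level
    sm_method = "wilson" if method == "wilson" else "normal"
    low, high = proportion_confint(k, n, alpha=alpha, method=sm_method)
    est = k / n
    # clip to [0,1] and absorb floating-point slack so low <= estimate <= high
    low = float(np.clip(min(low, est), 0.0, 1.0))
    high = float(np.clip(max(high, est), 0.0, 1.0))
    return ProportionResult(
        label=label, k=int(k), n=int(n), estimate=est,
        percent=round_half_up(100.0 * est, percent_decimals),
        ci_low=low, ci_high=high, level=level, method=method,
    )


def two_proportion_z(k1: int, n1: int, k2: int, n2: int):
    """Pooled two-proportion z test; returns ``(z, two-sided p, degenerate)``.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p pooled; no continuity
    correction. When the pooled proportion is 0 or 1 the statistic is
    undefined: the degenerate flag is set with z = 0 and p = 1.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not (0 <= k <= n):
            raise ValueError("each group needs 0 <= k <= n with n >= 1")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0, 1.0, True
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    return float(z), float(2.0 * norm.sf(abs(z))), False


def pairwise_tests(table: pd.DataFrame, pairs, alpha: float = 0.05) -> pd.DataFrame:
    """Two-proportion z test for each requested pair of count-table rows.

    ``table`` needs columns label/k/n; ``pairs`` is an iterable of label
    pairs. No multiplicity correction is applied. Unknown labels are errors.
    """
    rows = {str(r["label"]): (int(r["k"]), int(r["n"])) for _, r in table.iterrows()}
    out = []
    for a, b in pairs:
        if a not in rows or b not in rows:
            raise KeyError(f"unknown label in pair ({a!r}, {b!r})")
        (k1, n1), (k2, n2) = rows[a], rows[b]
        z, p, degenerate = two_proportion_z(k1, n1, k2, n2)
        out.append((a, b, z, p, bool(p < alpha) and not degenerate, degenerate))
    return pd.DataFrame(
        out, columns=["label_1", "label_2", "z", "pvalue", "significant", "degenerate"],
    )


def load_count_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("label", "k", "n"):
        if col not in table.columns:
            raise ValueError(f"count table missing column {col!r}")
    if ((table["k"] < 0) | (table["k"] > table["n"]) | (table["n"] < 1)).any():
        raise ValueError("count table rows must satisfy 0 <= k <= n, n >= 1")
    return table


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("gliamine.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def insitu_counts() -> pd.DataFrame:
    """The curated in-situ count tallies (panel, label, k, n, printed value)."""
    return _load_packaged("insitu_counts.tsv")


def insitu_pairs() -> pd.DataFrame:
    """Curated pairwise comparisons with their reported significance bounds."""
    return _load_packaged("insitu_pairs.tsv")
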