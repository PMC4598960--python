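"""Rank correlations: miRNA abundance vs target counts, and gene regulation
counts vs cis/promoter element counts.

Read-count and degree distributions are heavy-tailed and non-normal (a
Shapiro–Wilk check is reported alongside every correlation), so Spearman's
rank correlation with average-rank tie handling is used throughout.  The
two-sided p-value uses the t approximation for n > 10 and the exact
permutation distribution for small samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .errors import EstimationError
from .io import AbundanceRecord, CisElementCounts

__all__ = [
    "CorrelationResult",
    "spearman",
    "abundance_correlation",
    "subset_correlation",
    "cis_element_correlation",
]

_EXACT_N_MAX = 10
_SHAPIRO_N_MAX = 5000


@dataclass(frozen=True)
class CorrelationResult:
    variable_pair: str
    rho: float
    p_value: float
    n: int
    normality_p: float  # min of the per-variable Shapiro-Wilk p-values


def _shapiro_p(x: np.ndarray) -> float:
    if x.size < 3 or np.all(x == x[0]):
        return float("nan")
    if x.size > _SHAPIRO_N_MAX:
        # Shapiro-Wilk is defined for n <= 5000; use a deterministic evenly
        # spaced subsample of the input order
        idx = np.linspace(0, x.size - 1, _SHAPIRO_N_MAX).astype(int)
        x = x[idx]
    return float(stats.shapiro(x).pvalue)


def _exact_perm_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p-value for Spearman's rho at small n:
    enumerate all pairings of y's ranks against x's."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = x.size
    perms = np.array(list(permutations(range(n))), dtype=np.int64)
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        rhos = (ry_c @ rx_c) / denom
    rhos = rhos[np.isfinite(rhos)]
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x: "np.ndarray | list", y: "np.ndarray | list",
             pair_name: str = "x_vs_y") -> CorrelationResult:
    """Spearman rank correlation with average-rank ties; exact permutation
    p for n <= 10, t approximation above."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 3:
        raise EstimationError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise EstimationError("a constant variable has no rank correlation")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if n <= _EXACT_N_MAX:
        p = _exact_perm_p(x, y, rho)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    norm_p = float(np.nanmin([_shapiro_p(x), _shapiro_p(y)]))
    return CorrelationResult(pair_name, rho, p, n, norm_p)


def abundance_correlation(
    records: list[AbundanceRecord],
    target_counts: dict[str, int],
    which: str = "mature",
    drop_zero_reads: bool = False,
) -> CorrelationResult:
    """Spearman correlation between per-miRNA target counts and read
    counts (``which`` selects mature or stem-loop).  Zero-read miRNAs are
    retained by default (rank methods tolerate them); ``drop_zero_reads``
    exists for sensitivity analysis."""
    if which not in ("mature", "stemloop"):
        raise ValueError("which must be 'mature' or 'stemloop'")
    counts = []
    reads = []
    for r in records:
        if r.mirna_id not in target_counts:
            continue
        value = r.mature_reads if which == "mature" else r.stemloop_reads
        if drop_zero_reads and value == 0:
            continue
        counts.append(target_counts[r.mirna_id])
        reads.append(value)
    if len(counts) < 3:
        raise EstimationError("need >= 3 miRNAs present in both inputs")
    return spearman(counts, reads, pair_name=f"target_count_vs_{which}_reads")


def subset_correlation(
    records: list[AbundanceRecord],
    target_counts: dict[str, int],
    subset: set[str],
    which: str = "mature",
) -> CorrelationResult:
    """Abundance correlation restricted to a miRNA subset (e.g. the
    disease-implicated miRNAs only)."""
    sub_records = [r for r in records if r.mirna_id in subset]
    sub_counts = {m: c for m, c in target_counts.items() if m in subset}
    result = abundance_correlation(sub_records, sub_counts, which)
    return CorrelationResult(
        f"{result.variable_pair}_subset", result.rho, result.p_value,
        result.n, result.normality_p,
    )


def cis_element_correlation(
    cis: list[CisElementCounts],
    regulation_counts: dict[str, int],
) -> list[CorrelationResult]:
    """Spearman correlations of per-gene miRNA-regulation count against
    the numbers of cis and promoter elements (two results)."""
    reg, n_cis, n_prom = [], [], []
    for rec in cis:
        if rec.gene not in regulation_counts:
            continue
        reg.append(regulation_counts[rec.gene])
        n_cis.append(rec.n_cis)
        n_prom.append(rec.n_promoter)
    if len(reg) < 3:
        raise EstimationError("need >= 3 genes present in both inputs")
    return [
        spearman(reg, n_cis, pair_name="regulation_count_vs_n_cis"),
        spearman(reg, n_prom, pair_name="regulation_count_vs_n_promoter"),
    ]
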