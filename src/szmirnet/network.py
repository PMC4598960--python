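"""Bipartite miRNA -> gene network, miRNA ranking and top-N coverage.

The network is restricted to a gene tier of interest (all differentially
methylated genes, or the nested disease-annotated subsets).  miRNAs are
ranked by target count; the headline statistic is the fraction of all
miRNA-regulated genes in the tier that are covered by the targets of the
top-N miRNAs, with resampling error bars obtained by repeatedly subsampling
genes and recomputing the ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError
from .io import TargetEdge

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteNetwork",
    "CoverageResult",
    "build_network",
    "rank_mirnas",
    "topn_coverage",
    "coverage_bootstrap",
    "regulated_fraction",
]


@dataclass
class BipartiteNetwork:
    """Directed miRNA -> gene network with degree views.

    ``mirnas``/``genes`` preserve first-occurrence order; ``out_degree``
    maps each miRNA to its target count, ``in_degree`` each gene to the
    number of miRNAs regulating it.
    """

    mirnas: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    edges: list[TargetEdge] = field(default_factory=list)
    out_degree: dict[str, int] = field(default_factory=dict)
    in_degree: dict[str, int] = field(default_factory=dict)
    targets: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class CoverageResult:
    n_top: int
    ratio: float
    boot_sd: float = 0.0
    n_reps: int = 0
    denominator: int = 0


def build_network(edges: list[TargetEdge], tier: set[str] | None = None) -> BipartiteNetwork:
    """Keep only edges whose gene lies in ``tier`` (None keeps all); drop
    miRNAs with no surviving target; compute degree maps."""
    net = BipartiteNetwork()
    seen_genes: set[str] = set()
    for e in edges:
        if tier is not None and e.gene not in tier:
            continue
        net.edges.append(e)
        if e.mirna_id not in net.targets:
            net.targets[e.mirna_id] = set()
            net.mirnas.append(e.mirna_id)
        net.targets[e.mirna_id].add(e.gene)
        net.out_degree[e.mirna_id] = net.out_degree.get(e.mirna_id, 0) + 1
        net.in_degree[e.gene] = net.in_degree.get(e.gene, 0) + 1
        if e.gene not in seen_genes:
            seen_genes.add(e.gene)
            net.genes.append(e.gene)
    return net


def rank_mirnas(net: BipartiteNetwork) -> list[tuple[str, int]]:
    """miRNAs sorted by descending target count, ties broken
    lexicographically by id (stable and order-independent)."""
    return sorted(net.out_degree.items(), key=lambda kv: (-kv[1], kv[0]))


def _top_union(net: BipartiteNetwork, n_top: int) -> set[str]:
    ranked = rank_mirnas(net)
    union: set[str] = set()
    for mirna, _ in ranked[:n_top]:
        union |= net.targets[mirna]
    return union


def topn_coverage(net: BipartiteNetwork, n_top: int) -> CoverageResult:
    """Fraction of miRNA-regulated genes covered by the top-N miRNAs'
    targets.  The denominator is the number of genes with in-degree >= 1
    (every gene node of the restricted network)."""
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    regulated = len(net.genes)
    if regulated == 0:
        raise EstimationError("coverage undefined on an empty network")
    covered = _top_union(net, n_top)
    return CoverageResult(n_top=n_top, ratio=len(covered) / regulated,
                          denominator=regulated)


def coverage_bootstrap(
    net: BipartiteNetwork,
    full_gene_pool: set[str],
    sample_size: int,
    n_top: int,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> CoverageResult:
    """Error bars for the top-N coverage ratio by gene subsampling.

    The top-N miRNA set is ranked once on the full network and held fixed.
    Each replicate draws ``sample_size`` genes uniformly without
    replacement from ``full_gene_pool`` and recomputes the coverage ratio
    over the sampled genes that are regulated at all; replicates that
    sample zero regulated genes contribute ratio 0 (logged).  ``boot_sd``
    is the standard deviation across replicates (0 by convention for a
    single replicate).
    """
    pool = sorted(full_gene_pool)
    if sample_size > len(pool):
        raise ValueError("sample_size exceeds the gene pool")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    covered = _top_union(net, n_top)
    regulated = set(net.genes)
    pool_arr = np.array(pool, dtype=object)
    is_reg = np.array([g in regulated for g in pool], dtype=bool)
    is_cov = np.array([g in covered for g in pool], dtype=bool)
    ratios = np.empty(reps)
    n_zero = 0
    for r in range(reps):
        idx = rng.choice(len(pool_arr), size=sample_size, replace=False)
        n_reg = int(is_reg[idx].sum())
        if n_reg == 0:
            ratios[r] = 0.0
            n_zero += 1
        else:
            ratios[r] = is_cov[idx].sum() / n_reg
    if n_zero:
        logger.warning("%d/%d replicates sampled zero regulated genes", n_zero, reps)
    full = topn_coverage(net, n_top)
    sd = float(np.std(ratios, ddof=1)) if reps > 1 else 0.0
    return CoverageResult(n_top=n_top, ratio=full.ratio, boot_sd=sd, n_reps=reps,
                          denominator=full.denominator)


def regulated_fraction(net: BipartiteNetwork, tier: set[str]) -> float:
    """Fraction of tier genes regulated by at least one miRNA (the
    53%-style statistic)."""
    if not tier:
        raise EstimationError("regulated_fraction undefined for an empty tier")
    regulated = set(net.genes)
    return len(tier & regulated) / len(tier)
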