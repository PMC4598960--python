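"""miRNA-miRNA shared-target projection and small-world testing.

Two miRNAs are linked when their target sets intersect; the edge weight is
the intersection size.  Small-worldness is judged against a matched
Erdős–Rényi ensemble (same node count, same mean degree): a small-world
network has a clustering coefficient well above the random expectation
(C_ER = p) while its characteristic path length stays comparable
(L_ER ≈ 2 − p for dense graphs of diameter 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .errors import EstimationError
from .network import BipartiteNetwork

__all__ = [
    "GraphStats",
    "SmallWorldReport",
    "project",
    "clustering_coefficient",
    "characteristic_path_length",
    "graph_stats",
    "er_null_ensemble",
    "small_world_test",
]


@dataclass(frozen=True)
class GraphStats:
    n: int
    mean_degree: float
    clustering: float
    path_length: float


@dataclass(frozen=True)
class SmallWorldReport:
    real: GraphStats
    er_mean: GraphStats
    er_sd: GraphStats
    n_replicates: int
    c_margin: float
    l_tolerance: float
    is_small_world: bool


def project(net: BipartiteNetwork) -> nx.Graph:
    """Weighted miRNA-miRNA graph: edge iff two miRNAs share >= 1 target,
    weight = number of shared targets."""
    g = nx.Graph()
    g.add_nodes_from(net.mirnas)
    by_gene: dict[str, list[str]] = {}
    for mirna, targets in net.targets.items():
        for gene in targets:
            by_gene.setdefault(gene, []).append(mirna)
    for members in by_gene.values():
        members = sorted(members)
        for a, b in combinations(members, 2):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return g


def clustering_coefficient(g: nx.Graph) -> float:
    """Average local clustering coefficient (Watts–Strogatz): nodes with
    degree < 2 contribute 0."""
    if g.number_of_nodes() == 0:
        raise EstimationError("clustering undefined on an empty graph")
    return float(nx.average_clustering(g))


def characteristic_path_length(g: nx.Graph) -> float:
    """Mean shortest-path length over ordered pairs of distinct nodes in
    the largest connected component."""
    if g.number_of_edges() == 0:
        raise EstimationError("path length undefined on an edgeless graph")
    if nx.is_connected(g):
        component = g
    else:
        component = g.subgraph(max(nx.connected_components(g), key=len))
    return float(nx.average_shortest_path_length(component))


def graph_stats(g: nx.Graph) -> GraphStats:
    n = g.number_of_nodes()
    mean_degree = 2.0 * g.number_of_edges() / n if n else 0.0
    return GraphStats(
        n=n,
        mean_degree=mean_degree,
        clustering=clustering_coefficient(g),
        path_length=characteristic_path_length(g),
    )


def er_null_ensemble(
    n: int,
    mean_degree: float,
    n_replicates: int = 200,
    seed: int | np.random.Generator = 0,
) -> tuple[GraphStats, GraphStats]:
    """Matched Erdős–Rényi ensemble: G(n, p) with p = mean_degree/(n-1).

    Returns per-statistic means and standard deviations across replicates.
    """
    if n < 2:
        raise EstimationError("need n >= 2 nodes")
    if not 0.0 <= mean_degree <= n - 1:
        raise EstimationError("mean_degree must lie in [0, n-1]")
    p = mean_degree / (n - 1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stats = np.empty((n_replicates, 3))
    for r in range(n_replicates):
        g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        stats[r, 0] = 2.0 * g.number_of_edges() / n
        stats[r, 1] = nx.average_clustering(g)
        stats[r, 2] = characteristic_path_length(g)
    mean = stats.mean(axis=0)
    sd = stats.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros(3)
    er_mean = GraphStats(n, float(mean[0]), float(mean[1]), float(mean[2]))
    er_sd = GraphStats(n, float(sd[0]), float(sd[1]), float(sd[2]))
    return er_mean, er_sd


def small_world_test(
    real: GraphStats,
    er_mean: GraphStats,
    er_sd: GraphStats,
    n_replicates: int = 0,
    c_margin: float = 1.5,
    l_tolerance: float = 0.25,
) -> SmallWorldReport:
    """Small-world decision: clustering at least ``c_margin`` times the
    random expectation AND path length within ``l_tolerance`` (relative) of
    the random one.  The margins are explicit because "bigger" and
    "approximately equal" need operational definitions."""
    c_ok = real.clustering >= c_margin * er_mean.clustering
    l_ok = abs(real.path_length - er_mean.path_length) <= l_tolerance * er_mean.path_length
    return SmallWorldReport(
        real=real,
        er_mean=er_mean,
        er_sd=er_sd,
        n_replicates=n_replicates,
        c_margin=c_margin,
        l_tolerance=l_tolerance,
        is_small_world=bool(c_ok and l_ok),
    )
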