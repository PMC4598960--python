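"""PPI-density enrichment: observed/null densities, Wilcoxon, subnetwork."""

import numpy as np
import pytest
from scipy.special import comb

from szmirnet.errors import EstimationError
from szmirnet.io import MethylProbe, PpiEdge, TargetEdge
from szmirnet.network import build_network
from szmirnet.ppi import (
    EnrichmentRow,
    build_subnetwork,
    enrichment_table,
    null_densities,
    observed_density,
    wilcoxon_enrichment,
)
from szmirnet.synth import SynthConfig, gen_bipartite, gen_ppi


def P(a, b, s):
    return PpiEdge(*sorted((a, b)), s)


class TestObservedDensity:
    def test_enumerated_example_with_cutoff(self):
        edges, density = observed_density(
            {"A", "B", "C"}, [P("A", "B", 0.5), P("B", "C", 0.3)], cutoff=0.4)
        assert (edges, density) == (1, pytest.approx(1 / 3))

    def test_complete_high_score_triangle(self):
        ppi = [P("A", "B", 0.9), P("B", "C", 0.9), P("A", "C", 0.9)]
        assert observed_density({"A", "B", "C"}, ppi)[1] == 1.0

    def test_no_qualifying_edges(self):
        assert observed_density({"A", "B"}, [P("A", "B", 0.1)])[1] == 0.0

    def test_fewer_than_two_genes_errors(self):
        with pytest.raises(EstimationError):
            observed_density({"A"}, [])


class TestNullDensities:
    def test_edgeless_universe_all_zero(self):
        nulls = null_densities(3, {"A", "B", "C", "D"}, [], reps=50, seed=1)
        assert np.all(nulls == 0.0)

    def test_m_equal_universe_degenerate(self):
        ppi = [P("A", "B", 0.9), P("C", "D", 0.9)]
        nulls = null_densities(4, {"A", "B", "C", "D"}, ppi, reps=30, seed=2)
        assert np.all(nulls == nulls[0])

    def test_m_exceeding_universe_errors(self):
        with pytest.raises(EstimationError):
            null_densities(5, {"A", "B"}, [], reps=10, seed=0)

    def test_mean_matches_analytic_expectation(self):
        """E[sample density] equals the universe edge density (each edge is
        included with probability m(m-1)/(N(N-1)))."""
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(10)]
        ppi = [P(a, b, 0.9) for i, a in enumerate(genes) for b in genes[i + 1:]
               if rng.random() < 0.4]
        m, reps = 4, 2000
        nulls = null_densities(m, set(genes), ppi, reps=reps, seed=4)
        expected = len(ppi) / comb(10, 2)
        se = nulls.std(ddof=1) / np.sqrt(reps)
        assert abs(nulls.mean() - expected) < 3 * se

    def test_reproducible_and_seed_sensitive(self):
        genes = {f"G{i}" for i in range(8)}
        ppi = [P("G0", "G1", 0.9), P("G2", "G3", 0.9)]
        a = null_densities(3, genes, ppi, reps=100, seed=5)
        b = null_densities(3, genes, ppi, reps=100, seed=5)
        c = null_densities(3, genes, ppi, reps=100, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestEnrichmentTable:
    """Planted-signal experiments use a controlled bipartite layer (fixed
    out-degree, sparse co-targeting) so the per-miRNA densities are
    informative; heavy-tailed degrees at small gene universes saturate
    co-targeting and wash the contrast out."""

    @staticmethod
    def _rows(boost, seed, reps=300, n_mirna=20, n_genes=800, k=25):
        rng = np.random.default_rng(seed)
        edges = [TargetEdge(f"m{i:03d}", f"GENE{j + 1:05d}")
                 for i in range(n_mirna)
                 for j in sorted(rng.choice(n_genes, size=k, replace=False))]
        cfg = SynthConfig(seed=seed, n_mirna=n_mirna, n_genes=n_genes,
                          ppi_base_density=0.02, ppi_cotarget_boost=boost)
        ppi = gen_ppi(cfg, edges)
        net = build_network(edges, None)
        universe = {f"GENE{j + 1:05d}" for j in range(n_genes)}
        return enrichment_table(net, universe, ppi, cutoff=0.0, reps=reps,
                                seed=seed + 1)

    def test_planted_boost_recovered(self):
        rows = self._rows(boost=3.0, seed=7)
        diffs = [r.diff for r in rows]
        assert len(rows) >= 6
        assert np.median(diffs) > 0
        assert wilcoxon_enrichment(rows)[1] < 0.05

    def test_null_boost_centred_at_zero(self):
        from scipy import stats
        rows = self._rows(boost=1.0, seed=8)
        diffs = np.array([r.diff for r in rows])
        n_pos = int((diffs > 0).sum())
        n = int((diffs != 0).sum())
        assert stats.binomtest(n_pos, n, 0.5).pvalue > 0.01

    def test_single_mirna_network(self):
        net = build_network([TargetEdge("m1", "A"), TargetEdge("m1", "B")], None)
        ppi = [P("A", "B", 0.9)]
        rows = enrichment_table(net, {"A", "B"}, ppi, reps=20, seed=1)
        assert len(rows) == 1 and rows[0].observed_density == 1.0

    def test_diffs_bounded(self):
        rows = self._rows(boost=3.0, seed=9, reps=100)
        assert all(-1.0 <= r.diff <= 1.0 for r in rows)


class TestWilcoxon:
    @staticmethod
    def _row(i, diff):
        return EnrichmentRow(f"m{i}", 3, 1, 0.3, 0.3 - diff, diff, 100)

    def test_ten_positive_diffs_exact_p(self):
        rows = [self._row(i, 0.01 * (i + 1)) for i in range(10)]
        _, p = wilcoxon_enrichment(rows)
        assert p == pytest.approx(2 / 1024)

    def test_symmetric_pairs_p_one(self):
        diffs = [0.01, -0.01, 0.02, -0.02, 0.03, -0.03]
        rows = [self._row(i, d) for i, d in enumerate(diffs)]
        _, p = wilcoxon_enrichment(rows)
        assert p == pytest.approx(1.0)

    def test_five_rows_precondition_error(self):
        rows = [self._row(i, 0.01) for i in range(5)]
        with pytest.raises(EstimationError):
            wilcoxon_enrichment(rows)

    def test_all_zero_diffs_error(self):
        rows = [self._row(i, 0.0) for i in range(10)]
        with pytest.raises(EstimationError):
            wilcoxon_enrichment(rows)


class TestBuildSubnetwork:
    def test_shading_is_mean_mval(self):
        probes = [MethylProbe("cg1", "A", 0.2, "set1"),
                  MethylProbe("cg2", "A", 0.4, "set1")]
        sub = build_subnetwork({"A", "B"}, [P("A", "B", 0.9)], probes=probes)
        assert sub.shading["A"] == pytest.approx(0.3)
        assert "B" not in sub.shading
        assert "B" in sub.nodes  # retained despite no probes

    def test_isolated_node_retained(self):
        sub = build_subnetwork({"A", "B", "C"}, [P("A", "B", 0.9)])
        assert set(sub.nodes) == {"A", "B", "C"}
        assert sub.hubs[0][0] in {"A", "B"} and sub.hubs[-1] == ("C", 0)

    @pytest.mark.parametrize("seed", range(4))
    def test_induced_subgraph_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(30)]
        ppi = [P(a, b, float(rng.random())) for i, a in enumerate(genes)
               for b in genes[i + 1:] if rng.random() < 0.2]
        union = set(rng.choice(genes, size=12, replace=False))
        sub = build_subnetwork(union, ppi, cutoff=0.4)
        expected = [e for e in ppi if e.combined_score >= 0.4
                    and e.gene_a in union and e.gene_b in union]
        assert sorted(sub.edges, key=str) == sorted(expected, key=str)
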