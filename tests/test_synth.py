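"""Generator contracts: determinism, planted structure, marginals."""

import numpy as np
import pytest
from scipy import stats

from szmirnet.errors import ConfigError
from szmirnet.synth import (
    SynthConfig,
    gen_abundance,
    gen_bipartite,
    gen_cis_counts,
    gen_methyl,
    gen_ppi,
    gen_tiers,
)


def out_degrees(edges):
    d = {}
    for e in edges:
        d[e.mirna_id] = d.get(e.mirna_id, 0) + 1
    return d


class TestBipartite:
    def test_exponent_recovered_by_mle(self):
        from szmirnet.powerlaw import fit_mle
        cfg = SynthConfig(seed=1, n_mirna=2000, n_genes=20000, powerlaw_c=2.14)
        fit = fit_mle(list(out_degrees(gen_bipartite(cfg)).values()), xmin=1)
        assert fit.c == pytest.approx(2.14, abs=0.05)

    def test_single_mirna_targets_distinct(self):
        cfg = SynthConfig(seed=2, n_mirna=1, n_genes=50, tier_sizes=(50, 5, 1))
        edges = gen_bipartite(cfg)
        genes = [e.gene for e in edges]
        assert len(genes) == len(set(genes)) >= 1

    def test_same_seed_identical(self, small_cfg):
        assert gen_bipartite(small_cfg) == gen_bipartite(small_cfg)

    def test_different_seed_differs(self, small_cfg):
        import dataclasses
        other = dataclasses.replace(small_cfg, seed=small_cfg.seed + 1)
        assert gen_bipartite(small_cfg) != gen_bipartite(other)


class TestTiers:
    def test_sizes_and_nesting(self, small_cfg):
        tiers = gen_tiers(small_cfg, gen_bipartite(small_cfg))
        assert (len(tiers.tier1), len(tiers.tier2), len(tiers.tier3)) == (300, 60, 10)
        assert tiers.tier3 <= tiers.tier2 <= tiers.tier1

    def test_all_tiers_equal_universe_boundary(self):
        cfg = SynthConfig(seed=3, n_mirna=5, n_genes=20, tier_sizes=(20, 20, 20))
        tiers = gen_tiers(cfg, gen_bipartite(cfg))
        assert tiers.tier1 == tiers.tier2 == tiers.tier3
        assert len(tiers.tier1) == 20

    @pytest.mark.parametrize("seed", range(0, 50, 7))
    def test_nesting_property_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 100))
        n1 = int(rng.integers(1, n + 1))
        n2 = int(rng.integers(0, n1 + 1))
        n3 = int(rng.integers(0, n2 + 1))
        cfg = SynthConfig(seed=seed, n_mirna=5, n_genes=n, tier_sizes=(n1, n2, n3))
        tiers = gen_tiers(cfg, gen_bipartite(cfg))
        assert tiers.tier3 <= tiers.tier2 <= tiers.tier1

    def test_oversized_tier_is_config_error(self):
        with pytest.raises(ConfigError):
            SynthConfig(seed=0, n_genes=10, tier_sizes=(11, 2, 1))


class TestPpi:
    @staticmethod
    def _cotarget_codes(edges, n):
        idx = lambda g: int(g[4:]) - 1  # GENExxxxx -> index
        by_m = {}
        for e in edges:
            by_m.setdefault(e.mirna_id, set()).add(idx(e.gene))
        codes = set()
        for targets in by_m.values():
            t = sorted(targets)
            for i, a in enumerate(t):
                for b in t[i + 1:]:
                    codes.add(a * n + b)
        return codes

    def test_boost_three_cotarget_rate(self):
        cfg = SynthConfig(seed=4, n_mirna=60, n_genes=250,
                          tier_sizes=(250, 50, 5),
                          ppi_base_density=0.02, ppi_cotarget_boost=3.0)
        edges = gen_bipartite(cfg)
        ppi = gen_ppi(cfg, edges)
        ct = self._cotarget_codes(edges, cfg.n_genes)
        edge_codes = {(int(e.gene_a[4:]) - 1) * cfg.n_genes + (int(e.gene_b[4:]) - 1)
                      for e in ppi}
        n_ct = len(ct)
        hits = len(ct & edge_codes)
        rate = hits / n_ct
        se = np.sqrt(0.06 * 0.94 / n_ct)
        assert abs(rate - 0.06) < 3 * se

    def test_boost_one_independence(self):
        cfg = SynthConfig(seed=5, n_mirna=40, n_genes=200, tier_sizes=(200, 40, 5),
                          ppi_base_density=0.05, ppi_cotarget_boost=1.0)
        edges = gen_bipartite(cfg)
        ppi = gen_ppi(cfg, edges)
        n = cfg.n_genes
        ct = self._cotarget_codes(edges, n)
        edge_codes = {(int(e.gene_a[4:]) - 1) * n + (int(e.gene_b[4:]) - 1) for e in ppi}
        n_pairs = n * (n - 1) // 2
        a = len(ct & edge_codes)
        b = len(ct) - a
        c = len(edge_codes) - a
        d = n_pairs - len(ct) - c
        _, p, _, _ = stats.chi2_contingency([[a, b], [c, d]])
        assert p > 0.01

    def test_zero_density_no_edges(self, small_cfg):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, ppi_base_density=0.0)
        assert gen_ppi(cfg, gen_bipartite(cfg)) == []

    def test_infeasible_boost_rejected(self):
        with pytest.raises(ConfigError):
            SynthConfig(seed=0, ppi_base_density=0.5, ppi_cotarget_boost=3.0)


class TestMethyl:
    def test_mean_shift_matches_parameter(self):
        cfg = SynthConfig(seed=6, n_probes=3000, repeat_fraction=0.3, repeat_shift=0.3)
        probes, hits = gen_methyl(cfg)
        rep_ids = {h.probe_id for h in hits}
        set1 = [p for p in probes if p.set_label == "set1"]
        rep = np.array([p.mval_diff for p in set1 if p.probe_id in rep_ids])
        non = np.array([p.mval_diff for p in set1 if p.probe_id not in rep_ids])
        se = np.sqrt(rep.var() / rep.size + non.var() / non.size)
        assert abs((rep.mean() - non.mean()) - 0.3) < 3 * se

    def test_zero_shift_indistinguishable(self):
        cfg = SynthConfig(seed=7, n_probes=2000, repeat_fraction=0.3, repeat_shift=0.0)
        probes, hits = gen_methyl(cfg)
        rep_ids = {h.probe_id for h in hits}
        set1 = [p for p in probes if p.set_label == "set1"]
        rep = [p.mval_diff for p in set1 if p.probe_id in rep_ids]
        non = [p.mval_diff for p in set1 if p.probe_id not in rep_ids]
        assert stats.ttest_ind(rep, non).pvalue > 0.01

    def test_all_negative_mixture(self):
        from szmirnet.repeats import bin_mvals
        cfg = SynthConfig(seed=8, n_probes=500, mval_mix=(1.0, 0.5, 0.05),
                          repeat_shift=0.0)
        probes, _ = gen_methyl(cfg)
        hist = bin_mvals([p.mval_diff for p in probes if p.set_label == "set3"])
        negative_mass = sum(v for c, v in zip(hist.bin_centers, hist.values) if c < 0)
        assert negative_mass == pytest.approx(100.0)

    def test_set3_not_shifted(self):
        cfg = SynthConfig(seed=9, n_probes=3000, repeat_fraction=0.3, repeat_shift=0.5)
        probes, hits = gen_methyl(cfg)
        rep_ids = {h.probe_id for h in hits}
        set3 = [p for p in probes if p.set_label == "set3"]
        rep = [p.mval_diff for p in set3 if p.probe_id in rep_ids]
        non = [p.mval_diff for p in set3 if p.probe_id not in rep_ids]
        assert stats.ttest_ind(rep, non).pvalue > 0.01


class TestAbundance:
    @staticmethod
    def _sample_rho(cfg, which="mature"):
        edges = gen_bipartite(cfg)
        deg = out_degrees(edges)
        recs = gen_abundance(cfg, edges)
        reads = [r.mature_reads if which == "mature" else r.stemloop_reads for r in recs]
        return stats.spearmanr([deg[r.mirna_id] for r in recs], reads).statistic

    def test_null_rho(self):
        cfg = SynthConfig(seed=10, n_mirna=2000, n_genes=20000, abundance_rho=0.0)
        assert abs(self._sample_rho(cfg)) < 0.1

    def test_copula_rho_09(self):
        cfg = SynthConfig(seed=11, n_mirna=2000, n_genes=20000, abundance_rho=0.9)
        assert 0.8 <= self._sample_rho(cfg) <= 0.95

    def test_rho_one_exact(self):
        cfg = SynthConfig(seed=12, n_mirna=300, abundance_rho=1.0)
        assert self._sample_rho(cfg) == pytest.approx(1.0)
        assert self._sample_rho(cfg, which="stemloop") == pytest.approx(1.0)


class TestCisCounts:
    def test_independent_of_target_counts(self):
        cfg = SynthConfig(seed=13, n_mirna=300, n_genes=2000)
        edges = gen_bipartite(cfg)
        in_deg = {}
        for e in edges:
            in_deg[e.gene] = in_deg.get(e.gene, 0) + 1
        cis = gen_cis_counts(cfg)
        pairs = [(in_deg.get(c.gene, 0), c.n_cis) for c in cis]
        rho = stats.spearmanr(*zip(*pairs)).statistic
        assert abs(rho) < 0.1

    def test_zero_mean_all_zero(self):
        cfg = SynthConfig(seed=14, n_genes=100, cis_mean=0.0, promoter_mean=0.0)
        assert all(c.n_cis == 0 and c.n_promoter == 0 for c in gen_cis_counts(cfg))

    def test_negative_binomial_moments(self):
        cfg = SynthConfig(seed=15, n_genes=20000, cis_mean=30.0, cis_dispersion=1.0)
        vals = np.array([c.n_cis for c in gen_cis_counts(cfg)])
        expected_var = 30.0 + 30.0**2 / 1.0
        assert vals.mean() == pytest.approx(30.0, rel=0.05)
        assert vals.var() == pytest.approx(expected_var, rel=0.10)


def test_full_determinism_across_generators(small_cfg):
    """Identical config (incl. seed) reproduces every output exactly."""
    edges = gen_bipartite(small_cfg)
    first = (edges, gen_tiers(small_cfg, edges), gen_ppi(small_cfg, edges),
             gen_methyl(small_cfg), gen_abundance(small_cfg, edges),
             gen_cis_counts(small_cfg))
    edges2 = gen_bipartite(small_cfg)
    second = (edges2, gen_tiers(small_cfg, edges2), gen_ppi(small_cfg, edges2),
              gen_methyl(small_cfg), gen_abundance(small_cfg, edges2),
              gen_cis_counts(small_cfg))
    assert first[0] == second[0]
    assert first[1].tier1 == second[1].tier1
    assert first[2] == second[2]
    assert first[3] == second[3]
    assert first[4] == second[4]
    assert first[5] == second[5]
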