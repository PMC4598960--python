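"""Best-hit filtering, M-value histograms and repeat-vs-full t-tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from szmirnet.errors import EstimationError
from szmirnet.io import MethylProbe, RepeatHit
from szmirnet.repeats import (
    best_hits,
    bin_mvals,
    compare_repeat_vs_full,
    enrichment_by_element,
)
from szmirnet.synth import SynthConfig, gen_methyl


class TestBestHits:
    def test_lowest_evalue_wins(self):
        hits = [RepeatHit("cg1", "ALUY", 1e-6, 80.0),
                RepeatHit("cg1", "L1HS", 1e-8, 70.0)]
        assert best_hits(hits)["cg1"].repeat_name == "L1HS"

    def test_threshold_excludes_weak_hits(self):
        assert best_hits([RepeatHit("cg1", "ALUY", 1e-4, 80.0)]) == {}

    def test_tie_broken_by_bitscore_then_name(self):
        hits = [RepeatHit("cg1", "ALUY", 1e-8, 80.0),
                RepeatHit("cg1", "L1HS", 1e-8, 95.0)]
        assert best_hits(hits)["cg1"].bitscore == 95.0
        tied = [RepeatHit("cg1", "MIR3", 1e-8, 95.0),
                RepeatHit("cg1", "ALUY", 1e-8, 95.0)]
        assert best_hits(tied)["cg1"].repeat_name == "ALUY"

    @given(st.permutations(list(range(6))))
    def test_order_independent_and_idempotent(self, order):
        hits = [RepeatHit("cg1", f"R{i}", 10.0 ** -(6 + i), 50.0 + i)
                for i in range(3)]
        hits += [RepeatHit("cg2", f"R{i}", 1e-9, 50.0 + i) for i in range(3)]
        shuffled = [hits[i] for i in order]
        result = best_hits(shuffled)
        assert result == best_hits(hits)
        assert best_hits(list(result.values())) == result


class TestBinMvals:
    def test_single_zero_in_center_bin(self):
        hist = bin_mvals([0.0])
        assert hist.values[10] == 100.0 and hist.bin_centers[10] == 0.0

    def test_terminal_values_split(self):
        hist = bin_mvals([-1.0, 1.0])
        assert hist.values[0] == 50.0 and hist.values[20] == 50.0

    def test_outliers_clipped_into_terminal_bins(self):
        hist = bin_mvals([-5.0, 5.0, 0.0])
        assert hist.n_clipped == 2
        assert hist.values[0] == hist.values[20] == pytest.approx(100 / 3)

    def test_uniform_draws_match_interval_count_oracle(self, rng):
        vals = rng.uniform(-1, 1, size=10_000)
        hist = bin_mvals(vals)
        for c, v in zip(hist.bin_centers, hist.values):
            lo, hi = c - 0.05, c + 0.05
            expected = np.sum((vals >= lo) & (vals < hi)) if c < 1.0 else np.sum(
                (vals >= lo) & (vals <= 1.0))
            assert v == pytest.approx(100 * expected / vals.size)

    def test_empty_input_errors(self):
        with pytest.raises(EstimationError):
            bin_mvals([])

    @given(st.lists(st.floats(min_value=-50, max_value=50, allow_nan=False),
                    min_size=1, max_size=200))
    def test_always_21_bins_summing_to_100(self, values):
        hist = bin_mvals(values)
        assert len(hist.values) == len(hist.bin_centers) == 21
        assert sum(hist.values) == pytest.approx(100.0, abs=1e-9)


class TestCompareRepeatVsFull:
    @staticmethod
    def _probes(n, shift, seed, frac=0.3):
        rng = np.random.default_rng(seed)
        sign = np.where(rng.random(n) < 0.5, -1, 1)
        mval = sign * 0.4 + rng.normal(0, 0.15, n)
        is_rep = rng.random(n) < frac
        mval = mval + np.where(is_rep, shift, 0.0)
        probes = [MethylProbe(f"cg{i}", "", float(mval[i]), "set1") for i in range(n)]
        rep_ids = {f"cg{i}" for i in range(n) if is_rep[i]}
        return probes, rep_ids

    def test_repeat_equal_full_gives_null(self):
        probes, _ = self._probes(500, 0.0, 1, frac=1.0)
        ids = {p.probe_id for p in probes}
        res = compare_repeat_vs_full(probes, ids, side="all")
        assert abs(res.t_stat) < 1e-9 and res.p_value > 0.999

    def test_planted_shift_detected_with_positive_direction(self):
        detected = 0
        for seed in range(20):
            probes, ids = self._probes(500, 0.3, seed)
            res = compare_repeat_vs_full(probes, ids, side="all")
            if res.p_value < 1e-3 and res.direction > 0:
                detected += 1
        assert detected >= 19  # >= 95% of runs

    def test_type_one_error_controlled(self):
        rejections = 0
        runs = 60
        for seed in range(runs):
            probes, ids = self._probes(500, 0.0, 1000 + seed)
            if compare_repeat_vs_full(probes, ids, side="all").p_value < 0.05:
                rejections += 1
        assert rejections / runs <= 0.15  # ~5% expected

    def test_side_filtering_excludes_zeros(self):
        probes = [MethylProbe("cg1", "", 0.0, "set1")] + \
                 [MethylProbe(f"cgn{i}", "", -0.3 - 0.01 * i, "set1") for i in range(5)] + \
                 [MethylProbe(f"cgp{i}", "", 0.3 + 0.01 * i, "set1") for i in range(5)]
        ids = {p.probe_id for p in probes}
        neg = compare_repeat_vs_full(probes, ids, side="negative")
        pos = compare_repeat_vs_full(probes, ids, side="positive")
        assert neg.n_full == 5 and pos.n_full == 5  # the exact zero dropped

    def test_insufficient_group_errors_name_side(self):
        probes = [MethylProbe(f"cg{i}", "", 0.5, "set1") for i in range(10)]
        with pytest.raises(EstimationError, match="negative"):
            compare_repeat_vs_full(probes, {"cg0"}, side="negative")

    def test_generator_integration_set1_shifted_set3_not(self):
        cfg = SynthConfig(seed=5, n_probes=1500, repeat_fraction=0.3, repeat_shift=0.3)
        probes, hits = gen_methyl(cfg)
        best = best_hits(hits)
        set1 = [p for p in probes if p.set_label == "set1"]
        set3 = [p for p in probes if p.set_label == "set3"]
        r1 = compare_repeat_vs_full(set1, best, side="all")
        r3 = compare_repeat_vs_full(set3, best, side="all")
        assert r1.p_value < 1e-3 and r1.direction > 0
        assert r3.p_value > 0.01


class TestEnrichmentByElement:
    def test_single_element(self):
        best = {"cg1": RepeatHit("cg1", "ALUY", 1e-8, 80.0),
                "cg2": RepeatHit("cg2", "ALUY", 1e-9, 90.0)}
        assert enrichment_by_element(best) == [("ALUY", 2)]

    def test_empty_mapping(self):
        assert enrichment_by_element({}) == []

    def test_counts_match_brute_force(self, rng):
        names = ["ALUY", "L1HS", "MIR3"]
        best = {f"cg{i}": RepeatHit(f"cg{i}", names[rng.integers(3)], 1e-8, 50.0)
                for i in range(200)}
        table = dict(enrichment_by_element(best))
        for name in names:
            assert table.get(name, 0) == sum(
                1 for h in best.values() if h.repeat_name == name)
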