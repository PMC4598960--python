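"""Rank miRNAs by target count and measure top-N coverage with error bars.

The headline statistic: what fraction of all miRNA-regulated genes do the
targets of the top-N miRNAs cover?  Error bars come from resampling genes
without replacement and recomputing the ratio.
"""

from szmirnet.network import (
    build_network,
    coverage_bootstrap,
    rank_mirnas,
    regulated_fraction,
)
from szmirnet.synth import SynthConfig, gen_bipartite, gen_tiers

cfg = SynthConfig(seed=42)
edges = gen_bipartite(cfg)
tiers = gen_tiers(cfg, edges)
net = build_network(edges, tiers.tier1)

print("top five miRNAs by target count:")
for mirna, k in rank_mirnas(net)[:5]:
    print(f"  {mirna}  {k} targets")

frac = regulated_fraction(net, tiers.tier1)
print(f"\nfraction of tier-1 genes regulated by >=1 miRNA: {frac:.2f}")

pool = tiers.tier1
for n_top in (1, 2, 5, 10):
    res = coverage_bootstrap(net, pool, max(2, len(pool) // 10), n_top,
                             reps=1000, seed=1)
    print(f"top-{n_top:2d} coverage: {res.ratio:.3f} +/- {res.boot_sd:.3f} "
          f"(of {res.denominator} regulated genes)")
print("\nCoverage is non-decreasing in N; under a power-law out-degree the "
      "top ten miRNAs already cover about half of the regulated genes here, "
      "and heavier tails concentrate coverage further.")
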