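"""Do co-targeted genes interact more than random disease-gene sets?

For each miRNA, the PPI edge density among its targets is compared with the
mean density of equally sized random gene draws; a one-sample Wilcoxon
signed-rank test summarises the per-miRNA differences.  The generator
plants a 3x edge-probability boost among co-targeted pairs, which the
procedure should recover.
"""

import numpy as np

from szmirnet.io import TargetEdge
from szmirnet.network import build_network
from szmirnet.ppi import enrichment_table, wilcoxon_enrichment
from szmirnet.synth import SynthConfig, gen_ppi

rng = np.random.default_rng(42)
n_mirna, n_genes, k = 25, 1500, 30
edges = [TargetEdge(f"miR-{i:03d}", f"GENE{j + 1:05d}")
         for i in range(n_mirna)
         for j in sorted(rng.choice(n_genes, size=k, replace=False))]
cfg = SynthConfig(seed=42, n_mirna=n_mirna, n_genes=n_genes,
                  ppi_base_density=0.02, ppi_cotarget_boost=3.0)
ppi = gen_ppi(cfg, edges)
net = build_network(edges, None)
universe = {f"GENE{j + 1:05d}" for j in range(n_genes)}

rows = enrichment_table(net, universe, ppi, cutoff=0.0, reps=500, seed=1)
stat, p = wilcoxon_enrichment(rows)

print(f"{len(rows)} miRNAs with >= 2 targets in the PPI universe")
print("first rows (observed vs null density):")
for r in rows[:5]:
    print(f"  {r.mirna_id}: m={r.m}  observed={r.observed_density:.4f}  "
          f"null={r.null_mean_density:.4f}  diff={r.diff:+.4f}")
print(f"\nmedian diff = {np.median([r.diff for r in rows]):+.4f}")
print(f"Wilcoxon signed-rank: statistic={stat:.1f}, p={p:.2e}")
print("A small p with positive diffs means co-targeted genes are more "
      "densely connected than random gene sets of the same size.")
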