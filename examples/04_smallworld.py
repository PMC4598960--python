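"""Project miRNAs onto a shared-target graph and test small-worldness.

Two miRNAs are linked when they regulate at least one common gene.  A
small-world network has clustering well above a matched Erdős–Rényi
ensemble while keeping a comparable characteristic path length.  A compact
gene universe is used so that target sets overlap appreciably, as they do
in the curated data.
"""

from szmirnet.network import build_network
from szmirnet.smallworld import er_null_ensemble, graph_stats, project, small_world_test
from szmirnet.synth import SynthConfig, gen_bipartite

cfg = SynthConfig(seed=7, n_mirna=80, n_genes=150, powerlaw_c=1.6)
net = build_network(gen_bipartite(cfg), None)
g = project(net)
real = graph_stats(g)

er_mean, er_sd = er_null_ensemble(real.n, real.mean_degree, 200, seed=1)
report = small_world_test(real, er_mean, er_sd, n_replicates=200)

print(f"projection: {real.n} miRNAs, mean degree {real.mean_degree:.1f}")
print(f"real    C = {real.clustering:.3f}   L = {real.path_length:.3f}")
print(f"ER null C = {er_mean.clustering:.3f}   L = {er_mean.path_length:.3f}"
      f"   (SD {er_sd.clustering:.3f}/{er_sd.path_length:.3f}, 200 replicates)")
print(f"small world (C >= {report.c_margin}x ER and L within "
      f"{report.l_tolerance:.0%}): {report.is_small_world}")
print("\nShared-target projections are clique-rich (every gene's regulator "
      "set forms a clique), which inflates C over the ER null at equal L.")
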