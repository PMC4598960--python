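"""Does miRNA abundance track target count?  Do cis elements?

Spearman rank correlation (read counts are heavy-tailed; Shapiro-Wilk
confirms non-normality) between per-miRNA target counts and read counts,
and between per-gene miRNA-regulation counts and cis/promoter element
counts.  The generator couples abundance at rank correlation 0.67 and
leaves cis counts independent.
"""

from szmirnet.correlate import abundance_correlation, cis_element_correlation
from szmirnet.network import build_network
from szmirnet.synth import SynthConfig, gen_abundance, gen_bipartite, gen_cis_counts

cfg = SynthConfig(seed=42, n_mirna=2000, n_genes=20000, abundance_rho=0.67)
edges = gen_bipartite(cfg)
net = build_network(edges, None)
records = gen_abundance(cfg, edges)

for which in ("mature", "stemloop"):
    res = abundance_correlation(records, net.out_degree, which)
    print(f"target count vs {which:8s} reads: rho={res.rho:.3f}  "
          f"p={res.p_value:.2e}  n={res.n}  (Shapiro-Wilk p={res.normality_p:.1e})")

for res in cis_element_correlation(gen_cis_counts(cfg), net.in_degree):
    print(f"{res.variable_pair}: rho={res.rho:+.3f}  p={res.p_value:.2f}")

print("\nAbundance recovers the planted rank correlation (supporting the "
      "competing-endogenous-RNA picture); cis/promoter element counts show "
      "no correlation, matching their independent construction.")
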