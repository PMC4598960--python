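# szmirnet

Network analysis of microRNA regulation over differentially methylated
disease genes — built for, and demonstrated on, the schizophrenia setting
where a curated set of disease-implicated miRNAs is crossed with
differentially methylated genes, protein–protein interactions, repeat
elements and miRNA abundances.

The package is aimed at computational biologists who want each of these
analyses as a tested, reusable, deterministic building block rather than a
one-off script:

- **Bipartite miRNA→target networks** restricted to nested disease-gene
  tiers, miRNA ranking by target count, and top-N coverage ratios with
  gene-resampling error bars.
- **Discrete power-law fitting**: the out-degree model P(k) ~ k^−c with the
  zeta normaliser ζ(c, x_min), exponent by maximum likelihood, x_min fixed
  or chosen by minimal Kolmogorov–Smirnov distance, and a semiparametric KS
  bootstrap goodness-of-fit p-value (the fraction of model-generated
  samples whose refitted KS distance exceeds the empirical one).
- **Small-world testing** of the miRNA–miRNA shared-target projection:
  clustering coefficient C and characteristic path length L against a
  matched Erdős–Rényi G(n, p) ensemble with p = ⟨k⟩/(n−1).
- **PPI-density enrichment**: per-miRNA interaction density among
  co-targeted genes (STRING-style combined score ≥ 0.4) versus a
  permutation null of equally sized random disease-gene draws, summarised
  by a one-sample Wilcoxon signed-rank test; plus the induced top-miRNA
  PPI subnetwork with per-gene methylation shading.
- **Repeat-element methylation**: best BLAST hit per probe (e-value ≤
  1e-5), 21-bin histograms of M-value differences normalised to 100, and
  repeat-vs-full Student's t-tests split by sign.
- **Rank correlations**: miRNA abundance vs target count (Spearman, with
  Shapiro–Wilk normality reporting) and gene regulation count vs
  cis/promoter element counts.
- **A synthetic-data generator** that plants exactly these structures
  (power-law degrees, nested tiers, boosted co-target PPI density, bimodal
  shifted M-values, copula-coupled abundance), so the full pipeline runs
  and is testable without any external database.

## Worked example

Fit the out-degree power law on a synthetic network generated at the
study's scale (129 miRNAs, 2931 genes, exponent 2.14):

```sh
python examples/03_powerlaw_fit.py
```

```
n = 129 miRNAs, max out-degree 39
fitted exponent c = 1.943  (generator used 2.14)
KS statistic      = 0.0295
bootstrap GOF p   = 0.612  (2500 synthetic sets)
power law plausible at threshold 0.1: True
```

The exponent estimate is within sampling error of the generating value at
n = 129 (the standard error of the zeta MLE is roughly (c−1)/√n ≈ 0.1),
the KS distance is small, and the bootstrap p-value well above 0.1 says
the power law cannot be ruled out.  The other scripts in `examples/` walk
through each capability — input simulation, coverage ratios, small-world
testing, PPI enrichment, repeat methylation, correlations — each printing
the numbers it computes and what they mean.

The same analyses run end to end from the shell:

```sh
szmirnet simulate --input-dir inputs --seed 1
szmirnet run-all  --input-dir inputs --out-dir results --seed 1
```

writing plot-ready TSVs (`degrees.tsv`, `coverage.tsv`, `powerlaw.tsv`,
`smallworld.tsv`, `ppi_enrichment.tsv`, `histograms.tsv`,
`correlations.tsv`) plus a `manifest.json` echoing the seed and config;
identical configs reproduce every output byte for byte.

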