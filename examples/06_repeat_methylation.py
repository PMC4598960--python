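"""Are repeat-matched probes differentially methylated?

Probe sequences matched to a repeat library (BLAST e-value <= 1e-5, best
hit per probe) are compared with the full probe set: 21-bin normalised
histograms of M-value differences, and two-sample Student's t-tests split
by sign to respect the bimodal distributions.  The generator shifts
repeat-matched probes by +0.3 in set1/set2 and leaves set3 unshifted.
"""

from szmirnet.repeats import best_hits, bin_mvals, compare_repeat_vs_full
from szmirnet.synth import SynthConfig, gen_methyl

cfg = SynthConfig(seed=42, n_probes=2000, repeat_fraction=0.15, repeat_shift=0.3)
probes, hits = gen_methyl(cfg)
best = best_hits(hits, evalue_max=1e-5)
print(f"{len(best)} of {len(probes)} probes matched a repeat element")

for label in ("set1", "set2", "set3"):
    subset = [p for p in probes if p.set_label == label]
    hist = bin_mvals([p.mval_diff for p in subset])
    positive_mass = sum(v for c, v in zip(hist.bin_centers, hist.values) if c > 0)
    res = compare_repeat_vs_full(subset, best, side="all")
    print(f"{label}: positive-bin mass {positive_mass:5.1f}/100, "
          f"t={res.t_stat:+6.2f}, p={res.p_value:.2e}, "
          f"direction={'hyper' if res.direction > 0 else 'hypo'}methylated")

print("\nset1/set2 repeats test strongly hypermethylated (the planted "
      "shift); set3 shows no repeat effect, matching its null construction.")
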