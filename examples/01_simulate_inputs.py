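"""Generate a complete synthetic input bundle and list what was produced.

The generator plants the statistical structure the downstream analyses
assume: power-law miRNA out-degrees, nested disease-gene tiers, a PPI with
elevated density among co-targeted genes, bimodal M-value differences with
a hypermethylation shift for repeat-matched probes, and read counts
rank-coupled to target counts.
"""

from szmirnet.pipeline import RunConfig, simulate
from szmirnet.synth import SynthConfig

cfg = RunConfig(input_dir="example_inputs", synth=SynthConfig(seed=42), seed=42)
paths = simulate(cfg)

for name, path in sorted(paths.items()):
    n_rows = sum(1 for line in open(path) if not line.startswith("#")) - (
        0 if name == "blast" else 1)
    print(f"{name:10s} {path}  ({n_rows} rows)")
print("\nEach table round-trips through szmirnet.io and passes its reader's "
      "validation; rerunning with the same seed reproduces identical files.")
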