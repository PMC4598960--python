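"""End-to-end orchestration: simulate inputs, run every analysis stage,
write plot-ready TSV outputs plus a run manifest.

Stages and their file products:

==============  =========================================
network         degrees.tsv, coverage.tsv
powerlaw        powerlaw.tsv
smallworld      smallworld.tsv
ppi             ppi_enrichment.tsv, ppi_subnetwork.tsv
repeats         histograms.tsv, repeat_tests.tsv
correlations    correlations.tsv
==============  =========================================

All randomised stages derive their substreams from the single run seed, so
re-running an identical config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, correlate, io, network, powerlaw, ppi, repeats, smallworld
from .errors import ConfigError, DependencyError
from .synth import (
    SynthConfig,
    gen_abundance,
    gen_bipartite,
    gen_cis_counts,
    gen_methyl,
    gen_ppi,
    gen_tiers,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "simulate", "run_all", "INPUT_FILES", "STAGES"]

STAGES = ("network", "powerlaw", "smallworld", "ppi", "repeats", "correlations")

INPUT_FILES = {
    "edges": "target_edges.tsv",
    "tiers": "gene_tiers.tsv",
    "ppi": "ppi_edges.tsv",
    "probes": "probes.tsv",
    "blast": "repeat_hits.blast6.tsv",
    "abundance": "abundance.tsv",
    "cis": "cis_counts.tsv",
}

_STAGE_DEPS = {
    "powerlaw": ("network",),
    "smallworld": ("network",),
    "ppi": ("network",),
    "correlations": ("network",),
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs.  The replicate counts default to
    the study's values (1000 coverage bootstrap replicates, 3000 null
    draws, 2500 goodness-of-fit sets) and the cutoffs to the published
    ones (PPI combined score 0.4, repeat e-value 1e-5, GOF threshold
    0.1)."""

    input_dir: str | Path = "inputs"
    out_dir: str | Path = "results"
    synth: SynthConfig | None = None
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    ppi_cutoff: float = 0.4
    evalue_max: float = 1e-5
    gof_threshold: float = 0.1
    boot_reps: int = 1000
    null_reps: int = 3000
    gof_sets: int = 2500
    er_reps: int = 200
    top_ns: tuple[int, ...] = (1, 2, 5, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ppi_cutoff <= 1.0:
            raise ConfigError("ppi_cutoff must lie in [0,1]")
        if self.evalue_max <= 0:
            raise ConfigError("evalue_max must be positive")
        if not 0.0 <= self.gof_threshold <= 1.0:
            raise ConfigError("gof_threshold must lie in [0,1]")
        for name, count in (("boot_reps", self.boot_reps), ("null_reps", self.null_reps),
                            ("gof_sets", self.gof_sets), ("er_reps", self.er_reps)):
            if count < 1:
                raise ConfigError(f"{name} must be >= 1")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)

    def rng(self, stage: str) -> np.random.Generator:
        key = STAGES.index(stage) + 100
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------


def simulate(config: RunConfig) -> dict[str, Path]:
    """Generate every input table from the synthetic model and write it
    under ``config.input_dir``."""
    if config.synth is None:
        raise ConfigError("simulate requires a SynthConfig")
    cfg = config.synth
    indir = Path(config.input_dir)
    indir.mkdir(parents=True, exist_ok=True)
    edges = gen_bipartite(cfg)
    tiers = gen_tiers(cfg, edges)
    ppi_edges = gen_ppi(cfg, edges)
    probes, hits = gen_methyl(cfg)
    abundance = gen_abundance(cfg, edges)
    cis = gen_cis_counts(cfg)
    paths = {k: indir / v for k, v in INPUT_FILES.items()}
    io.write_target_edges(paths["edges"], edges)
    io.write_gene_tiers(paths["tiers"], tiers)
    io.write_ppi_edges(paths["ppi"], ppi_edges)
    io.write_probe_table(paths["probes"], probes)
    io.write_blast_tab(paths["blast"], hits)
    io.write_abundance(paths["abundance"], abundance)
    io.write_cis_counts(paths["cis"], cis)
    return paths


def _load_inputs(config: RunConfig) -> dict:
    indir = Path(config.input_dir)
    return {
        "edges": io.read_target_edges(indir / INPUT_FILES["edges"]),
        "tiers": io.read_gene_tiers(indir / INPUT_FILES["tiers"]),
        "ppi": io.read_ppi_edges(indir / INPUT_FILES["ppi"], score_scale="unit"),
        "probes": io.read_probe_table(indir / INPUT_FILES["probes"]),
        "blast": io.read_blast_tab(indir / INPUT_FILES["blast"]),
        "abundance": io.read_abundance(indir / INPUT_FILES["abundance"]),
        "cis": io.read_cis_counts(indir / INPUT_FILES["cis"]),
    }


def _require(config: RunConfig, stage: str) -> None:
    for dep in _STAGE_DEPS.get(stage, ()):
        if not config.stages.get(dep, True):
            raise DependencyError(f"stage '{stage}' requires stage '{dep}' to be enabled")


def run_all(config: RunConfig) -> dict:
    """Run every enabled stage; write per-stage TSVs and a manifest.

    Raises on the first stage failure, leaving partial outputs in place and
    recording the failure point in the manifest.
    """
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "config": _config_echo(config),
        "stages": {},
    }
    report: dict = {}
    current = ""
    try:
        if config.synth is not None and not all(
            (Path(config.input_dir) / f).exists() for f in INPUT_FILES.values()
        ):
            simulate(config)
        data = _load_inputs(config)
        for stage in STAGES:
            if not config.stages.get(stage, True):
                manifest["stages"][stage] = "skipped"
                continue
            current = stage
            _require(config, stage)
            _RUNNERS[stage](config, data, report, outdir)
            manifest["stages"][stage] = "ok"
    except Exception as exc:
        manifest["failure"] = {"stage": current or "load-inputs", "error": str(exc)}
        _write_manifest(outdir, manifest)
        raise
    _write_manifest(outdir, manifest)
    return report


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["input_dir"] = str(echo["input_dir"])
    echo["out_dir"] = str(echo["out_dir"])
    return echo


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


# ---------------------------------------------------------------------------
# Stage runners


def _run_network(config: RunConfig, data: dict, report: dict, outdir: Path) -> None:
    tiers: io.GeneTiers = data["tiers"]
    rng = config.rng("network")
    nets = {level: network.build_network(data["edges"], tiers.tier(level))
            for level in (1, 2, 3)}
    report["networks"] = nets
    ranked = network.rank_mirnas(nets[1])
    _write_tsv(outdir / "degrees.tsv", ["mirna_id", "out_degree"],
               [[m, d] for m, d in ranked])
    cov_rows = []
    pool1 = sorted(set(nets[1].genes))  # regulated genes in the widest tier
    sample_sizes = {1: max(2, len(pool1) // 10), 2: len(tiers.tier2), 3: len(tiers.tier3)}
    for level in (1, 2, 3):
        net = nets[level]
        if not net.genes:
            logger.warning("tier %d network is empty; coverage skipped", level)
            continue
        pool = tiers.tier(level)
        size = min(sample_sizes[level], len(pool))
        for n_top in config.top_ns:
            res = network.coverage_bootstrap(net, pool, size, n_top,
                                             reps=config.boot_reps, seed=rng)
            cov_rows.append([level, n_top, res.ratio, res.boot_sd, res.denominator,
                             res.n_reps])
        report.setdefault("regulated_fraction", {})[level] = network.regulated_fraction(
            net, pool)
    _write_tsv(outdir / "coverage.tsv",
               ["tier", "n_top", "ratio", "boot_sd", "denominator", "n_reps"], cov_rows)


def _run_powerlaw(config: RunConfig, data: dict, report: dict, outdir: Path) -> None:
    net = report["networks"][1]
    degrees = list(net.out_degree.values())
    fit = powerlaw.fit_mle(degrees, xmin=1)
    gof_p = powerlaw.gof_bootstrap(degrees, fit, n_boot=config.gof_sets,
                                   seed=config.rng("powerlaw"))
    plausible = powerlaw.decide_plausible(gof_p, config.gof_threshold)
    report["powerlaw"] = dataclasses.replace(fit, gof_p=gof_p, n_boot=config.gof_sets)
    _write_tsv(outdir / "powerlaw.tsv",
               ["c", "xmin", "ks_stat", "n_tail", "gof_p", "n_boot", "plausible"],
               [[fit.c, fit.xmin, fit.ks_stat, fit.n_tail, gof_p, config.gof_sets,
                 plausible]])


def _run_smallworld(config: RunConfig, data: dict, report: dict, outdir: Path) -> None:
    net = report["networks"][1]
    g = smallworld.project(net)
    real = smallworld.graph_stats(g)
    er_mean, er_sd = smallworld.er_null_ensemble(real.n, real.mean_degree,
                                                 config.er_reps,
                                                 seed=config.rng("smallworld"))
    sw = smallworld.small_world_test(real, er_mean, er_sd, config.er_reps)
    report["smallworld"] = sw
    _write_tsv(outdir / "smallworld.tsv",
               ["graph", "n", "mean_degree", "clustering", "path_length"],
               [["real", real.n, real.mean_degree, real.clustering, real.path_length],
                ["er_mean", er_mean.n, er_mean.mean_degree, er_mean.clustering,
                 er_mean.path_length],
                ["er_sd", er_sd.n, er_sd.mean_degree, er_sd.clustering,
                 er_sd.path_length],
                ["is_small_world", sw.is_small_world, "", "", ""]])


def _run_ppi(config: RunConfig, data: dict, report: dict, outdir: Path) -> None:
    # widest tier: the disease-gene universe with enough targets per miRNA
    net = report["networks"][1]
    tiers: io.GeneTiers = data["tiers"]
    rows = ppi.enrichment_table(net, tiers.tier1, data["ppi"], config.ppi_cutoff,
                                reps=config.null_reps, seed=config.rng("ppi"))
    report["ppi_rows"] = rows
    _write_tsv(outdir / "ppi_enrichment.tsv",
               ["mirna_id", "m", "observed_edges", "observed_density",
                "null_mean_density", "diff", "n_null_reps"],
               [[r.mirna_id, r.m, r.observed_edges, r.observed_density,
                 r.null_mean_density, r.diff, r.n_null_reps] for r in rows])
    stat, p = ppi.wilcoxon_enrichment(rows)
    report["ppi_wilcoxon"] = (stat, p)
    ranked = network.rank_mirnas(net)
    top2 = set()
    for mirna, _ in ranked[:2]:
        top2 |= net.targets[mirna]
    sub = ppi.build_subnetwork(top2, data["ppi"], config.ppi_cutoff, data["probes"])
    report["ppi_subnetwork"] = sub
    sub_rows = [[g, deg, sub.shading.get(g, "")] for g, deg in sub.hubs]
    with open(outdir / "ppi_subnetwork.tsv", "w", encoding="utf-8") as fh:
        fh.write(f"# wilcoxon_statistic={stat:.6g}\twilcoxon_p={p:.6g}\n")
        fh.write("gene\tdegree\tshading\n")
        for row in sub_rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _run_repeats(config: RunConfig, data: dict, report: dict, outdir: Path) -> None:
    best = repeats.best_hits(data["blast"], config.evalue_max)
    hist_rows: list[list] = []
    test_rows: list[list] = []
    report["repeat_tests"] = []
    for set_label in ("set1", "set2", "set3"):
        probes = [p for p in data["probes"] if p.set_label == set_label]
        if not probes:
            continue
        full_hist = repeats.bin_mvals([p.mval_diff for p in probes])
        rep_vals = [p.mval_diff for p in probes if p.probe_id in best]
        for name, hist in (("full", full_hist),
                           ("repeat", repeats.bin_mvals(rep_vals) if rep_vals else None)):
            if hist is None:
                continue
            for center, value in zip(hist.bin_centers, hist.values):
                hist_rows.append([set_label, name, center, value, hist.n_probes])
        for side in ("all", "negative", "positive"):
            res = repeats.compare_repeat_vs_full(probes, best, side)
            report["repeat_tests"].append(res)
            test_rows.append([set_label, side, res.t_stat, res.p_value, res.n_repeat,
                              res.n_full, res.direction])
    _write_tsv(outdir / "histograms.tsv",
               ["set_label", "subset", "bin_center", "value", "n_probes"], hist_rows)
    _write_tsv(outdir / "repeat_tests.tsv",
               ["set_label", "side", "t_stat", "p_value", "n_repeat", "n_full",
                "direction"], test_rows)


def _run_correlations(config: RunConfig, data: dict, report: dict, outdir: Path) -> None:
    full_net = network.build_network(data["edges"], tier=None)
    results = [
        correlate.abundance_correlation(data["abundance"], full_net.out_degree, which)
        for which in ("mature", "stemloop")
    ]
    results.extend(correlate.cis_element_correlation(data["cis"], full_net.in_degree))
    report["correlations"] = results
    _write_tsv(outdir / "correlations.tsv",
               ["variable_pair", "rho", "p_value", "n", "normality_p"],
               [[r.variable_pair, r.rho, r.p_value, r.n, r.normality_p]
                for r in results])


_RUNNERS = {
    "network": _run_network,
    "powerlaw": _run_powerlaw,
    "smallworld": _run_smallworld,
    "ppi": _run_ppi,
    "repeats": _run_repeats,
    "correlations": _run_correlations,
}
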