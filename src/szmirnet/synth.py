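"""Synthetic input generator with the statistical structure the analysis assumes.

Every downstream stage of the pipeline can be exercised without any external
database: miRNA out-degrees follow a discrete power law (default exponent
2.14, the value estimated for the real network), disease-gene tiers are
nested (all differentially methylated genes ⊇ disease-annotated ⊇
high-confidence, default sizes 2931 ⊇ 253 ⊇ 19), the PPI is a sparse random
graph with a planted density boost among co-targeted gene pairs, M-value
differences are a symmetric ±mu Gaussian mixture with an additive
hypermethylation shift for repeat-matched probes in set1/set2, and read
counts are rank-coupled to target counts through a calibrated Gaussian
copula.

Determinism: one seed drives a named substream per generator, so adding a
generator never perturbs the outputs of the others, and identical configs
produce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .errors import ConfigError
from .io import (
    AbundanceRecord,
    CisElementCounts,
    GeneTiers,
    MethylProbe,
    PpiEdge,
    RepeatHit,
    TargetEdge,
)
from .powerlaw import sample_zeta

__all__ = [
    "SynthConfig",
    "gen_bipartite",
    "gen_tiers",
    "gen_ppi",
    "gen_methyl",
    "gen_abundance",
    "gen_cis_counts",
]

# small synthetic repeat catalogue, names in the Repbase style
_REPEAT_NAMES = ("ALUY", "L1HS", "L1PA2", "MIR3", "LTR7", "HERVK", "SVA_A", "MER41B")

_STREAMS = {
    "bipartite": 1,
    "tiers": 2,
    "ppi": 3,
    "methyl": 4,
    "abundance": 5,
    "cis": 6,
}


@dataclass(frozen=True)
class SynthConfig:
    """Study-scale defaults: 129 miRNAs over 2931 differentially methylated
    genes, out-degree exponent 2.14, nested tiers 2931/253/19."""

    seed: int = 0
    n_mirna: int = 129
    n_genes: int = 2931
    powerlaw_c: float = 2.14
    # None derives the study-proportioned default (n_genes, <=253, <=19)
    tier_sizes: tuple[int, int, int] | None = None
    ppi_base_density: float = 0.02
    ppi_cotarget_boost: float = 3.0
    mval_mix: tuple[float, float, float] = (0.5, 0.4, 0.15)  # weight_neg, mu, sigma
    repeat_fraction: float = 0.15
    repeat_shift: float = 0.3
    abundance_rho: float = 0.67
    # log-normal read-count scale (log-space mean and sd)
    abundance_log_mu: float = 6.0
    abundance_log_sigma: float = 1.5
    n_probes: int = 2000  # per differential-methylation set
    cis_mean: float = 30.0
    promoter_mean: float = 5.0
    cis_dispersion: float = 1.0  # negative-binomial size parameter

    def __post_init__(self) -> None:
        if self.tier_sizes is None:
            object.__setattr__(
                self,
                "tier_sizes",
                (self.n_genes, min(253, self.n_genes), min(19, self.n_genes)),
            )
        n1, n2, n3 = self.tier_sizes
        if not (0 <= n3 <= n2 <= n1 <= self.n_genes):
            raise ConfigError("tier sizes must satisfy n3 <= n2 <= n1 <= n_genes")
        if self.powerlaw_c <= 1.0:
            raise ConfigError("powerlaw_c must exceed 1")
        if not 0.0 <= self.ppi_base_density <= 1.0:
            raise ConfigError("ppi_base_density must lie in [0,1]")
        if self.ppi_cotarget_boost < 1.0:
            raise ConfigError("ppi_cotarget_boost must be >= 1")
        if self.ppi_base_density * self.ppi_cotarget_boost > 1.0:
            raise ConfigError("boosted PPI edge probability exceeds 1")
        w, _, sigma = self.mval_mix
        if not 0.0 <= w <= 1.0 or sigma <= 0:
            raise ConfigError("mval_mix requires weight in [0,1] and sigma > 0")
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ConfigError("repeat_fraction must lie in [0,1]")
        if not -1.0 <= self.abundance_rho <= 1.0:
            raise ConfigError("abundance_rho must lie in [-1,1]")
        if self.n_mirna < 1 or self.n_genes < 1:
            raise ConfigError("n_mirna and n_genes must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )


def _mirna_name(i: int) -> str:
    return f"hsa-miR-{i + 1:04d}-5p"


def _gene_name(j: int) -> str:
    return f"GENE{j + 1:05d}"


def _probe_name(i: int) -> str:
    return f"cg{i + 1:08d}"


# ---------------------------------------------------------------------------


def gen_bipartite(cfg: SynthConfig) -> list[TargetEdge]:
    """Draw each miRNA's out-degree from the zeta distribution (exponent
    ``powerlaw_c``, xmin 1, truncated at ``n_genes`` by redraw) and attach
    that many distinct uniformly chosen target genes."""
    rng = cfg.rng("bipartite")
    degrees = sample_zeta(cfg.powerlaw_c, cfg.n_mirna, rng, xmin=1, kmax=cfg.n_genes)
    edges: list[TargetEdge] = []
    for i, k in enumerate(degrees):
        targets = rng.choice(cfg.n_genes, size=int(k), replace=False)
        mirna = _mirna_name(i)
        edges.extend(TargetEdge(mirna, _gene_name(int(j))) for j in np.sort(targets))
    return edges


def gen_tiers(cfg: SynthConfig, edges: list[TargetEdge]) -> GeneTiers:
    """Uniformly sample nested tiers from the gene universe."""
    n1, n2, n3 = cfg.tier_sizes
    rng = cfg.rng("tiers")
    universe = [_gene_name(j) for j in range(cfg.n_genes)]
    t1 = rng.choice(cfg.n_genes, size=n1, replace=False)
    t2 = rng.choice(t1, size=n2, replace=False)
    t3 = rng.choice(t2, size=n3, replace=False)
    tiers = GeneTiers(
        tier1={universe[j] for j in t1},
        tier2={universe[j] for j in t2},
        tier3={universe[j] for j in t3},
    )
    tiers.validate()
    return tiers


def gen_ppi(cfg: SynthConfig, edges: list[TargetEdge]) -> list[PpiEdge]:
    """Sparse PPI over the gene universe with a planted signal: any
    unordered pair is an edge with probability ``ppi_base_density``,
    multiplied by ``ppi_cotarget_boost`` when the two genes share at least
    one regulating miRNA.  Scores are uniform on [0,1]."""
    rng = cfg.rng("ppi")
    n = cfg.n_genes
    base = cfg.ppi_base_density
    if base == 0.0:
        return []

    gene_idx = {_gene_name(j): j for j in range(n)}
    by_mirna: dict[str, list[int]] = {}
    for e in edges:
        by_mirna.setdefault(e.mirna_id, []).append(gene_idx[e.gene])
    cotarget: set[int] = set()
    for targets in by_mirna.values():
        t = sorted(set(targets))
        for a_pos, a in enumerate(t):
            for b in t[a_pos + 1 :]:
                cotarget.add(a * n + b)

    n_pairs = n * (n - 1) // 2
    chosen: list[int] = []
    # planted co-targeted pairs: boosted Bernoulli on the explicit list
    ct = np.fromiter(cotarget, dtype=np.int64, count=len(cotarget))
    ct.sort()
    if ct.size:
        keep = rng.random(ct.size) < base * cfg.ppi_cotarget_boost
        chosen.extend(ct[keep].tolist())
    # background pairs: draw the Binomial count, then sample distinct codes
    n_bg_pairs = n_pairs - ct.size
    n_bg_edges = rng.binomial(n_bg_pairs, base)
    ct_set = set(ct.tolist())
    bg: set[int] = set()
    while len(bg) < n_bg_edges:
        need = n_bg_edges - len(bg)
        i = rng.integers(0, n, size=2 * need + 16)
        j = rng.integers(0, n, size=2 * need + 16)
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        codes = lo * n + hi
        for code in codes[lo != hi]:
            code = int(code)
            if code not in ct_set and code not in bg:
                bg.add(code)
                if len(bg) == n_bg_edges:
                    break
    chosen.extend(sorted(bg))
    chosen.sort()
    scores = rng.random(len(chosen))
    return [
        PpiEdge(_gene_name(code // n), _gene_name(code % n), float(s))
        for code, s in zip(chosen, scores)
    ]


def gen_methyl(cfg: SynthConfig) -> tuple[list[MethylProbe], list[RepeatHit]]:
    """Per set (set1..set3): ``n_probes`` probes with M-value differences
    from the mixture ``w*N(-mu, sigma) + (1-w)*N(+mu, sigma)``; a
    ``repeat_fraction`` subset gets a best repeat hit (e-value log-uniform
    on [1e-30, 1e-6]) and, for set1/set2 only, an additive hypermethylation
    shift of ``repeat_shift``."""
    rng = cfg.rng("methyl")
    w_neg, mu, sigma = cfg.mval_mix
    probes: list[MethylProbe] = []
    hits: list[RepeatHit] = []
    counter = 0
    for set_label in ("set1", "set2", "set3"):
        n = cfg.n_probes
        signs = np.where(rng.random(n) < w_neg, -1.0, 1.0)
        mvals = signs * mu + rng.normal(0.0, sigma, size=n)
        is_repeat = rng.random(n) < cfg.repeat_fraction
        if set_label in ("set1", "set2"):
            mvals = mvals + np.where(is_repeat, cfg.repeat_shift, 0.0)
        gene_idx = rng.integers(0, cfg.n_genes, size=n)
        has_gene = rng.random(n) < 0.9
        log_ev = rng.uniform(np.log(1e-30), np.log(1e-6), size=n)
        rep_choice = rng.integers(0, len(_REPEAT_NAMES), size=n)
        for i in range(n):
            pid = _probe_name(counter)
            counter += 1
            gene = _gene_name(int(gene_idx[i])) if has_gene[i] else ""
            probes.append(MethylProbe(pid, gene, float(mvals[i]), set_label))
            if is_repeat[i]:
                evalue = float(np.exp(log_ev[i]))
                # bit score tracks alignment strength: roughly 2 bits per
                # e-value decade plus noise
                bitscore = float(40.0 - 2.0 * np.log10(evalue))
                hits.append(
                    RepeatHit(pid, _REPEAT_NAMES[int(rep_choice[i])], evalue, bitscore)
                )
    return probes, hits


# ---------------------------------------------------------------------------
# Abundance: rank coupling through a calibrated Gaussian copula


def _tie_groups(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per observation: group mid-CDF ``a`` and its normal score; plus the
    per-group probabilities (for calibration)."""
    vals, inverse, group_n = np.unique(counts, return_counts=True, return_inverse=True)
    p = group_n / counts.size
    cum = np.cumsum(p)
    a = cum - p / 2.0  # mid-rank on the uniform scale
    return a[inverse], p, a


def _asymptotic_spearman(latent_rho: float, p: np.ndarray, a: np.ndarray) -> float:
    """Large-sample Spearman correlation between a tied discrete variable
    (tie groups with probabilities ``p``, mid-CDF values ``a``) and the
    continuous variable ``w = rho*z + sqrt(1-rho^2)*eps`` built on the
    groups' mid-rank normal scores ``z``.

    ``w``'s marginal is the normal mixture over groups, so its CDF
    evaluated at the group means gives
    ``E[G(w)|k] = sum_j p_j Phi(rho (z_k - z_j) / (sqrt(2) sqrt(1-rho^2)))``
    and Spearman = 12 E[a * G(w)] - 3.
    """
    z = ndtri(a)
    s = np.sqrt(1.0 - latent_rho * latent_rho)
    scale = latent_rho / (np.sqrt(2.0) * s)
    g = ndtr(scale * (z[:, None] - z[None, :])) @ p  # E[G(w) | group k]
    cov_scaled = 12.0 * np.sum(p * a * g) - 3.0
    # Spearman with ties is the Pearson correlation of mid-ranks, so the
    # tied variable's reduced rank variance enters the normalisation
    var_a = 12.0 * (np.sum(p * a * a) - 0.25)
    return float(cov_scaled / np.sqrt(var_a))


def _calibrate_latent_rho(target: float, p: np.ndarray, a: np.ndarray) -> float:
    """Latent Gaussian correlation whose induced Spearman correlation with
    the given tie structure equals ``target`` (saturating at the
    tie-limited maximum)."""
    sign = 1.0 if target >= 0 else -1.0
    t = abs(target)
    hi = 0.999999
    if _asymptotic_spearman(hi, p, a) <= t:
        return sign * hi
    return sign * brentq(lambda r: _asymptotic_spearman(r, p, a) - t, 0.0, hi,
                         xtol=1e-10)


def gen_abundance(cfg: SynthConfig, edges: list[TargetEdge]) -> list[AbundanceRecord]:
    """Log-normal read counts rank-coupled to each miRNA's target count.

    ``abundance_rho`` is the target Spearman correlation between target
    count and read count.  Target counts are heavily tied (most miRNAs have
    one target under a power law), so the latent Gaussian-copula
    correlation is calibrated against the empirical tie structure to make
    the realised rank correlation match the requested value; requests above
    the tie-limited maximum saturate there.  ``abundance_rho = +/-1`` takes
    an exact monotone no-noise path.  Mature and stem-loop counts use the
    same construction with independent noise.
    """
    rng = cfg.rng("abundance")
    counts: dict[str, int] = {}
    for e in edges:
        counts[e.mirna_id] = counts.get(e.mirna_id, 0) + 1
    mirnas = sorted(counts)
    t = np.array([counts[m] for m in mirnas], dtype=np.int64)
    a_obs, p, a_groups = _tie_groups(t)
    z = ndtri(np.clip(a_obs, 1e-12, 1 - 1e-12))

    def reads(latent_rho: float, noise: np.ndarray) -> np.ndarray:
        w = latent_rho * z + np.sqrt(1.0 - latent_rho**2) * noise
        return np.exp(cfg.abundance_log_mu + cfg.abundance_log_sigma * w)

    if abs(cfg.abundance_rho) == 1.0:
        sign = cfg.abundance_rho
        mature = np.exp(cfg.abundance_log_mu + cfg.abundance_log_sigma * sign * z)
        stemloop = mature.copy()
    else:
        latent = _calibrate_latent_rho(cfg.abundance_rho, p, a_groups)
        mature = reads(latent, rng.standard_normal(t.size))
        stemloop = reads(latent, rng.standard_normal(t.size))
    return [
        AbundanceRecord(m, float(mature[i]), float(stemloop[i]))
        for i, m in enumerate(mirnas)
    ]


def gen_cis_counts(cfg: SynthConfig) -> list[CisElementCounts]:
    """Cis-regulatory and promoter element counts, negative-binomial and
    independent of everything else (the null structure: regulation counts
    should not correlate with them)."""
    rng = cfg.rng("cis")
    n = cfg.n_genes

    def draw(mean: float) -> np.ndarray:
        if mean == 0.0:
            return np.zeros(n, dtype=np.int64)
        size = cfg.cis_dispersion
        prob = size / (size + mean)
        return rng.negative_binomial(size, prob, size=n)

    cis = draw(cfg.cis_mean)
    prom = draw(cfg.promoter_mean)
    return [
        CisElementCounts(_gene_name(j), int(cis[j]), int(prom[j])) for j in range(n)
    ]
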