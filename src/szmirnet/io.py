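"""Readers and writers for every external table the pipeline touches.

All tables are UTF-8, tab-delimited, one header line; lines starting with
``#`` are comments.  The one exception is the STRING protein-links dialect,
which may be space- or tab-separated.  Readers validate against the domain
invariants and normalise deterministically (gene symbols uppercased,
duplicate edges merged); rows with unparseable numerics are skipped with a
logged warning so large noisy tables degrade gracefully, except where the
format contract demands a hard error (BLAST numerics, PPI score scale).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TargetEdge",
    "PpiEdge",
    "MethylProbe",
    "RepeatHit",
    "AbundanceRecord",
    "CisElementCounts",
    "GeneTiers",
    "read_target_edges",
    "write_target_edges",
    "read_ppi_edges",
    "write_ppi_edges",
    "read_blast_tab",
    "write_blast_tab",
    "read_probe_table",
    "write_probe_table",
    "read_abundance",
    "write_abundance",
    "read_gene_tiers",
    "write_gene_tiers",
    "read_cis_counts",
    "write_cis_counts",
    "read_probe_fasta",
]


# ---------------------------------------------------------------------------
# Domain records


@dataclass(frozen=True)
class TargetEdge:
    """A directed miRNA -> gene regulation edge (experimentally validated)."""

    mirna_id: str
    gene: str


@dataclass(frozen=True)
class PpiEdge:
    """Undirected protein-protein interaction with a combined confidence
    score on [0, 1]; stored with ``gene_a < gene_b`` lexicographically."""

    gene_a: str
    gene_b: str
    combined_score: float


@dataclass(frozen=True)
class MethylProbe:
    """A CpG probe with its patients-minus-controls M-value difference.

    ``set_label`` identifies one of the three differential-methylation
    comparisons (set1: patients vs controls; set2: age/PMI-adjusted;
    set3: between patient subgroups).
    """

    probe_id: str
    gene: str  # may be "" when the probe maps to no annotated gene
    mval_diff: float
    set_label: str


@dataclass(frozen=True)
class RepeatHit:
    """A nucleotide-alignment hit of a probe sequence against a repeat
    library entry."""

    probe_id: str
    repeat_name: str
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class AbundanceRecord:
    """Read counts for a miRNA: processed (mature) and precursor
    (stem-loop) forms."""

    mirna_id: str
    mature_reads: float
    stemloop_reads: float


@dataclass(frozen=True)
class CisElementCounts:
    """Counts of distal cis-regulatory and promoter elements for a gene."""

    gene: str
    n_cis: int
    n_promoter: int


@dataclass
class GeneTiers:
    """Nested gene universes: tier1 (all differentially methylated genes)
    contains tier2 (disease-annotated) contains tier3 (high-confidence
    disease-annotated)."""

    tier1: set[str] = field(default_factory=set)
    tier2: set[str] = field(default_factory=set)
    tier3: set[str] = field(default_factory=set)

    def validate(self) -> None:
        bad2 = self.tier2 - self.tier1
        bad3 = self.tier3 - self.tier2
        if bad2 or bad3:
            offenders = sorted(bad2 | bad3)
            raise ValidationError(
                f"tier nesting violated for genes: {', '.join(offenders)}"
            )

    def tier(self, level: int) -> set[str]:
        return {1: self.tier1, 2: self.tier2, 3: self.tier3}[level]


# ---------------------------------------------------------------------------
# Low-level helpers


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line) skipping blanks/comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _header_index(
    header: str, required: tuple[str, ...], path: str | Path, sep: str | None = "\t"
) -> dict[str, int]:
    cols = header.split(sep) if sep else header.split()
    idx = {c.strip(): i for i, c in enumerate(cols)}
    for col in required:
        if col not in idx:
            raise FormatError(f"{path}: missing required column '{col}'")
    return idx


def _parse_float(token: str) -> float | None:
    try:
        value = float(token)
    except ValueError:
        return None
    return value if math.isfinite(value) else None


# ---------------------------------------------------------------------------
# miRNA -> target edges


def read_target_edges(path: str | Path) -> list[TargetEdge]:
    """Read a miRNA->gene edge list (columns ``mirna_id``, ``gene``).

    Gene symbols are uppercased, duplicates dropped, file order of first
    occurrence preserved.  An empty file after the header yields an empty
    list.
    """
    rows = iter(_data_lines(path))
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header line")
    idx = _header_index(header, ("mirna_id", "gene"), path)
    seen: set[tuple[str, str]] = set()
    edges: list[TargetEdge] = []
    for lineno, line in rows:
        parts = line.split("\t")
        try:
            mirna = parts[idx["mirna_id"]].strip()
            gene = parts[idx["gene"]].strip().upper()
        except IndexError:
            raise FormatError(f"{path}:{lineno}: too few columns")
        if not mirna or not gene:
            logger.warning("%s:%d: empty identifier, row skipped", path, lineno)
            continue
        key = (mirna, gene)
        if key not in seen:
            seen.add(key)
            edges.append(TargetEdge(mirna, gene))
    return edges


def write_target_edges(path: str | Path, edges: Iterable[TargetEdge]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tgene\n")
        for e in edges:
            fh.write(f"{e.mirna_id}\t{e.gene}\n")


# ---------------------------------------------------------------------------
# PPI edges (STRING protein-links dialect)

ScoreScale = Literal["unit", "string999"]


def read_ppi_edges(path: str | Path, score_scale: ScoreScale = "string999") -> list[PpiEdge]:
    """Read protein-protein interactions with combined confidence scores.

    ``string999`` declares integer scores on 0-999 (divided by 1000 on
    read); ``unit`` declares real scores already on [0, 1].  Self-loops are
    dropped; duplicate undirected pairs keep the maximum score.  The file
    may be space- or tab-separated.
    """
    if score_scale not in ("unit", "string999"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    rows = iter(_data_lines(path))
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header line")
    idx = _header_index(header, ("gene_a", "gene_b", "combined_score"), path, sep=None)
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for lineno, line in rows:
        parts = line.split()
        try:
            a = parts[idx["gene_a"]].strip().upper()
            b = parts[idx["gene_b"]].strip().upper()
            raw = parts[idx["combined_score"]]
        except IndexError:
            raise FormatError(f"{path}:{lineno}: too few columns")
        score = _parse_float(raw)
        if score is None:
            logger.warning("%s:%d: unparseable score %r, row skipped", path, lineno, raw)
            continue
        if score_scale == "string999":
            if not (score.is_integer() and 0 <= score <= 999):
                raise FormatError(
                    f"{path}:{lineno}: score {raw} outside declared string999 scale (integer 0-999)"
                )
            score /= 1000.0
        elif not 0.0 <= score <= 1.0:
            raise FormatError(
                f"{path}:{lineno}: score {raw} outside declared unit scale [0,1]"
            )
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if key not in best:
            best[key] = score
            order.append(key)
        elif score > best[key]:
            best[key] = score
    return [PpiEdge(a, b, best[(a, b)]) for a, b in order]


def write_ppi_edges(
    path: str | Path, edges: Iterable[PpiEdge], score_scale: ScoreScale = "unit"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tcombined_score\n")
        for e in edges:
            if score_scale == "string999":
                fh.write(f"{e.gene_a}\t{e.gene_b}\t{round(e.combined_score * 1000)}\n")
            else:
                fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.combined_score:.6g}\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

_BLAST_COLS = 12


def read_blast_tab(path: str | Path) -> list[RepeatHit]:
    """Parse a 12-column BLAST tabular (outfmt 6) file of probe-vs-repeat
    hits.  Query id is the probe, subject id the repeat element; columns 11
    and 12 are e-value and bit score.  No filtering is applied here."""
    hits: list[RepeatHit] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < _BLAST_COLS:
            raise FormatError(
                f"{path}:{lineno}: expected {_BLAST_COLS} tab-separated columns, got {len(parts)}"
            )
        evalue = _parse_float(parts[10])
        bitscore = _parse_float(parts[11])
        if evalue is None or bitscore is None:
            raise FormatError(f"{path}:{lineno}: non-numeric evalue/bitscore")
        if evalue <= 0:
            # BLAST prints 0.0 for underflowed e-values; clamp to a tiny
            # positive number so downstream log-scale filtering is defined.
            evalue = 1e-300
        hits.append(RepeatHit(parts[0], parts[1], evalue, bitscore))
    return hits


def write_blast_tab(path: str | Path, hits: Iterable[RepeatHit]) -> None:
    """Write hits as minimal plausible outfmt-6 rows (alignment geometry
    columns are synthesised since only probe, subject, e-value and bit
    score are modelled)."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            length = 100
            fh.write(
                f"{h.probe_id}\t{h.repeat_name}\t95.00\t{length}\t5\t0\t"
                f"1\t{length}\t1\t{length}\t{h.evalue:.2e}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Probe / abundance / tier / cis tables


def read_probe_table(path: str | Path) -> list[MethylProbe]:
    """Read probe M-value differences (columns ``probe_id``, ``gene``,
    ``mval_diff``, ``set_label``).  Rows with unparseable ``mval_diff``
    (e.g. "NA") are skipped with a warning."""
    rows = iter(_data_lines(path))
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header line")
    idx = _header_index(header, ("probe_id", "gene", "mval_diff", "set_label"), path)
    probes: list[MethylProbe] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in rows:
        parts = line.split("\t")
        try:
            pid = parts[idx["probe_id"]].strip()
            gene = parts[idx["gene"]].strip().upper()
            raw = parts[idx["mval_diff"]]
            label = parts[idx["set_label"]].strip()
        except IndexError:
            raise FormatError(f"{path}:{lineno}: too few columns")
        mval = _parse_float(raw)
        if mval is None:
            logger.warning("%s:%d: unparseable mval_diff %r, row skipped", path, lineno, raw)
            continue
        if label not in ("set1", "set2", "set3"):
            raise FormatError(f"{path}:{lineno}: unknown set_label {label!r}")
        key = (pid, label)
        if key in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate probe_id {pid!r} within {label}")
        seen.add(key)
        probes.append(MethylProbe(pid, gene, mval, label))
    return probes


def write_probe_table(path: str | Path, probes: Iterable[MethylProbe]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tgene\tmval_diff\tset_label\n")
        for p in probes:
            fh.write(f"{p.probe_id}\t{p.gene}\t{p.mval_diff:.6g}\t{p.set_label}\n")


def read_abundance(path: str | Path) -> list[AbundanceRecord]:
    rows = iter(_data_lines(path))
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header line")
    idx = _header_index(header, ("mirna_id", "mature_reads", "stemloop_reads"), path)
    records: list[AbundanceRecord] = []
    for lineno, line in rows:
        parts = line.split("\t")
        try:
            mirna = parts[idx["mirna_id"]].strip()
            mature = _parse_float(parts[idx["mature_reads"]])
            stemloop = _parse_float(parts[idx["stemloop_reads"]])
        except IndexError:
            raise FormatError(f"{path}:{lineno}: too few columns")
        if mature is None or stemloop is None:
            logger.warning("%s:%d: unparseable read count, row skipped", path, lineno)
            continue
        if mature < 0 or stemloop < 0:
            raise ValidationError(f"{path}:{lineno}: negative read count")
        records.append(AbundanceRecord(mirna, mature, stemloop))
    return records


def write_abundance(path: str | Path, records: Iterable[AbundanceRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tmature_reads\tstemloop_reads\n")
        for r in records:
            fh.write(f"{r.mirna_id}\t{r.mature_reads:.6g}\t{r.stemloop_reads:.6g}\n")


def read_gene_tiers(path: str | Path) -> GeneTiers:
    """Read tier memberships (columns ``gene``, ``tier``; one row per
    membership, tiers 1..3).  Nesting is validated: every tier-3 gene must
    also appear at tier 2, and every tier-2 gene at tier 1."""
    rows = iter(_data_lines(path))
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header line")
    idx = _header_index(header, ("gene", "tier"), path)
    tiers = GeneTiers()
    for lineno, line in rows:
        parts = line.split("\t")
        try:
            gene = parts[idx["gene"]].strip().upper()
            raw = parts[idx["tier"]].strip()
        except IndexError:
            raise FormatError(f"{path}:{lineno}: too few columns")
        if raw not in ("1", "2", "3"):
            raise FormatError(f"{path}:{lineno}: tier must be 1, 2 or 3, got {raw!r}")
        tiers.tier(int(raw)).add(gene)
    tiers.validate()
    return tiers


def write_gene_tiers(path: str | Path, tiers: GeneTiers) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\ttier\n")
        for level in (1, 2, 3):
            for gene in sorted(tiers.tier(level)):
                fh.write(f"{gene}\t{level}\n")


def read_cis_counts(path: str | Path) -> list[CisElementCounts]:
    rows = iter(_data_lines(path))
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header line")
    idx = _header_index(header, ("gene", "n_cis", "n_promoter"), path)
    records: list[CisElementCounts] = []
    for lineno, line in rows:
        parts = line.split("\t")
        try:
            gene = parts[idx["gene"]].strip().upper()
            n_cis = int(parts[idx["n_cis"]])
            n_prom = int(parts[idx["n_promoter"]])
        except IndexError:
            raise FormatError(f"{path}:{lineno}: too few columns")
        except ValueError:
            logger.warning("%s:%d: unparseable count, row skipped", path, lineno)
            continue
        if n_cis < 0 or n_prom < 0:
            raise ValidationError(f"{path}:{lineno}: negative element count")
        records.append(CisElementCounts(gene, n_cis, n_prom))
    return records


def write_cis_counts(path: str | Path, records: Iterable[CisElementCounts]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tn_cis\tn_promoter\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.n_cis}\t{r.n_promoter}\n")


# ---------------------------------------------------------------------------
# Optional probe-sequence FASTA reader

_PROBE_LENGTHS = (120, 121)


def read_probe_fasta(path: str | Path) -> tuple[dict[str, str], set[int]]:
    """Read probe sequences from FASTA; 120-nt and 121-nt probes are both
    accepted (array annotations disagree on whether the queried CpG sits
    after position 60 or exactly in the middle of 121).  Returns the
    sequences and the set of lengths observed."""
    seqs: dict[str, str] = {}
    lengths: set[int] = set()
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal name, chunks
        if name is None:
            return
        seq = "".join(chunks).upper()
        if len(seq) not in _PROBE_LENGTHS:
            raise ValidationError(
                f"{path}: probe {name!r} has length {len(seq)}, expected one of {_PROBE_LENGTHS}"
            )
        seqs[name] = seq
        lengths.add(len(seq))
        name, chunks = None, []

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
            else:
                chunks.append(line)
    flush()
    return seqs, lengths
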