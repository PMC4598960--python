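"""Repeat-element methylation: best-hit filtering, histograms, t-tests.

Probes are matched to a repeat library by nucleotide alignment; hits at
e-value <= 1e-5 are filtered to the single best repeat per probe.  M-value
differences are binned into 21 bins centred on -1.0, -0.9, ..., +1.0 and
normalised to sum to 100, and repeat-matched probes are compared with the
full probe set by a two-sample Student's t-test, optionally restricted to
the negative or positive side to sidestep the bimodality of the
distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import EstimationError
from .io import MethylProbe, RepeatHit

logger = logging.getLogger(__name__)

__all__ = [
    "HistogramResult",
    "RepeatTestResult",
    "best_hits",
    "bin_mvals",
    "compare_repeat_vs_full",
    "enrichment_by_element",
]

DEFAULT_EVALUE_MAX = 1e-5

N_BINS = 21
BIN_CENTERS = np.round(np.arange(-10, 11) / 10.0, 1)


@dataclass(frozen=True)
class HistogramResult:
    bin_centers: tuple[float, ...]
    values: tuple[float, ...]  # normalised to sum to 100
    n_probes: int
    n_clipped: int = 0


@dataclass(frozen=True)
class RepeatTestResult:
    set_label: str
    side: str  # all | negative | positive
    t_stat: float
    p_value: float
    n_repeat: int
    n_full: int
    direction: int  # sign of (repeat mean - full mean)


def best_hits(
    hits: list[RepeatHit], evalue_max: float = DEFAULT_EVALUE_MAX
) -> dict[str, RepeatHit]:
    """Per probe, the best repeat hit among those with e-value <=
    ``evalue_max``: minimal e-value, ties broken by maximal bit score, then
    lexicographic repeat name.  Probes with no qualifying hit are absent
    from the mapping; the result is independent of input order."""
    best: dict[str, RepeatHit] = {}
    for h in hits:
        if h.evalue > evalue_max:
            continue
        cur = best.get(h.probe_id)
        if cur is None:
            best[h.probe_id] = h
            continue
        key_new = (h.evalue, -h.bitscore, h.repeat_name)
        key_cur = (cur.evalue, -cur.bitscore, cur.repeat_name)
        if key_new < key_cur:
            best[h.probe_id] = h
    return best


def bin_mvals(values: "list[float] | np.ndarray") -> HistogramResult:
    """Bin M-value differences into 21 bins centred on multiples of 0.1
    from -1.0 to +1.0 (width 0.1, half-open [c-0.05, c+0.05), final bin
    closed); values beyond the range are clipped into the terminal bins
    (count logged).  Counts are scaled to sum to 100."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EstimationError("cannot bin an empty value list")
    if not np.isfinite(arr).all():
        raise EstimationError("M-values must be finite")
    n_clipped = int(((arr < -1.05) | (arr >= 1.05)).sum())
    if n_clipped:
        logger.warning("%d value(s) outside [-1.05, 1.05) clipped into terminal bins",
                       n_clipped)
    clipped = np.clip(arr, -1.0, 1.0)
    edges = np.arange(-1.05, 1.06, 0.1)
    counts, _ = np.histogram(clipped, bins=edges)
    assert counts.size == N_BINS
    vals = counts * (100.0 / arr.size)
    return HistogramResult(
        bin_centers=tuple(float(c) for c in BIN_CENTERS),
        values=tuple(float(v) for v in vals),
        n_probes=int(arr.size),
        n_clipped=n_clipped,
    )


def _side_filter(values: np.ndarray, side: str) -> np.ndarray:
    if side == "all":
        return values
    if side == "negative":
        return values[values < 0]
    if side == "positive":
        return values[values > 0]
    raise ValueError(f"unknown side {side!r}")


def compare_repeat_vs_full(
    full: list[MethylProbe],
    repeat_ids: "dict[str, RepeatHit] | set[str]",
    side: str = "all",
    equal_var: bool = True,
) -> RepeatTestResult:
    """Two-sample Student's t-test of the repeat-matched probes' M-value
    differences against the full set's.

    ``side`` restricts both groups to negative or positive values (exact
    zeros are excluded from either side) to avoid the complications of the
    bimodal distribution.  Equal-variance Student's t by default; set
    ``equal_var=False`` for Welch.
    """
    if not full:
        raise EstimationError("no probes supplied")
    ids = set(repeat_ids)
    full_vals = np.array([p.mval_diff for p in full])
    rep_vals = np.array([p.mval_diff for p in full if p.probe_id in ids])
    full_side = _side_filter(full_vals, side)
    rep_side = _side_filter(rep_vals, side)
    if rep_side.size < 3 or full_side.size < 3:
        raise EstimationError(
            f"side {side!r}: need >= 3 values per group, got repeat={rep_side.size}, "
            f"full={full_side.size}"
        )
    res = stats.ttest_ind(rep_side, full_side, equal_var=equal_var)
    direction = int(np.sign(rep_side.mean() - full_side.mean()))
    label = full[0].set_label if len({p.set_label for p in full}) == 1 else "mixed"
    return RepeatTestResult(
        set_label=label,
        side=side,
        t_stat=float(res.statistic),
        p_value=float(res.pvalue),
        n_repeat=int(rep_side.size),
        n_full=int(full_side.size),
        direction=direction,
    )


def enrichment_by_element(
    best: dict[str, RepeatHit],
    background: list[RepeatHit] | None = None,
) -> list[tuple[str, int]]:
    """Per-repeat-element probe counts among best hits, descending.

    This is a descriptive tally: without a declared background probe
    universe no statistical enrichment call is made (the ``background``
    argument is accepted for symmetry and future extension).
    """
    counts: dict[str, int] = {}
    for hit in best.values():
        counts[hit.repeat_name] = counts.get(hit.repeat_name, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
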