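"""Windowed chromatin-state annotation of TSSs and H3K4me3-gain detection.

A TSS is called positive for a mark in a cell line when at least one peak
interval overlaps a symmetric window around the TSS: +/-2 kb for the
promoter-associated H3K4me3 mark, +/-5 kb for the broad H3K27me3 and H3K79me2
marks. Overlap is half-open; a single shared base suffices. Gain after DNA
demethylation compares the parent tumor line against its demethylated
derivative, either as pure presence/absence (binary mode) or additionally by
peak-signal ratio (quantitative mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .io_genomics import GenomicInterval, PeakSet, TssRecord

__all__ = [
    "ChromatinCall",
    "GainCall",
    "K4_HALFWIDTH",
    "BROAD_HALFWIDTH",
    "tss_window",
    "call_mark",
    "detect_gain",
    "h3k4_universe",
    "status_table",
]

logger = logging.getLogger(__name__)

K4_HALFWIDTH = 2_000
BROAD_HALFWIDTH = 5_000

GAIN_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class ChromatinCall:
    transcript_id: str
    mark: str
    cell_line: str
    positive: bool
    signal: float = 0.0

    def __post_init__(self) -> None:
        if self.signal > 0 and not self.positive:
            raise ValueError("signal > 0 requires a positive call")


@dataclass(frozen=True)
class GainCall:
    transcript_id: str
    gained: bool
    mode: str
    ratio: Optional[float] = None


def tss_window(tss: TssRecord, halfwidth: int) -> GenomicInterval:
    """Symmetric, strand-independent window [tss - h, tss + h), clamped at 0."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    return GenomicInterval(tss.chrom, max(0, tss.tss - halfwidth), tss.tss + halfwidth)


def _peak_trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in peaks.intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, iv.score if iv.score is not None else 0.0
        )
    return trees


def call_mark(
    tss_list: Sequence[TssRecord], peaks: PeakSet, halfwidth: int
) -> list[ChromatinCall]:
    """One call per TSS: positive iff any peak overlaps the window; signal is
    the maximum peak score among overlapping peaks (0 when negative).

    Chromosomes present in the annotation but absent from the peak set yield
    all-negative calls (logged), not an error: an empty chromosome must not
    abort a genome-wide scan.
    """
    trees = _peak_trees(peaks)
    missing = {t.chrom for t in tss_list} - set(trees)
    if missing:
        logger.info(
            "%s/%s: no peaks on chromosome(s) %s; calls there are negative",
            peaks.mark,
            peaks.cell_line,
            ", ".join(sorted(missing)),
        )
    calls = []
    for t in tss_list:
        win = tss_window(t, halfwidth)
        hits = trees[t.chrom].overlap(win.start, win.end) if t.chrom in trees else ()
        if hits:
            signal = max(h.data for h in hits)
            calls.append(ChromatinCall(t.transcript_id, peaks.mark, peaks.cell_line, True, signal))
        else:
            calls.append(ChromatinCall(t.transcript_id, peaks.mark, peaks.cell_line, False, 0.0))
    return calls


def _aligned(
    parent_calls: Sequence[ChromatinCall], derivative_calls: Sequence[ChromatinCall]
) -> list[tuple[ChromatinCall, ChromatinCall]]:
    par = {c.transcript_id: c for c in parent_calls}
    der = {c.transcript_id: c for c in derivative_calls}
    if set(par) != set(der):
        odd = sorted(set(par) ^ set(der))
        raise ValueError(f"transcript universes differ between call lists: {odd[:10]}")
    return [(par[tid], der[tid]) for tid in par]


def detect_gain(
    parent_calls: Sequence[ChromatinCall],
    derivative_calls: Sequence[ChromatinCall],
    mode: str = "quantitative",
    min_ratio: float = 2.0,
) -> list[GainCall]:
    """Detect TSSs that acquire (or, in quantitative mode, upregulate) the
    mark in the demethylated derivative relative to the parent line.

    binary:       gained = not parent.positive and derivative.positive
    quantitative: gained = derivative.positive and
                           (not parent.positive or ratio >= min_ratio)
    where ratio = (derivative.signal + 1) / (parent.signal + 1).
    """
    if mode not in ("binary", "quantitative"):
        raise ValueError(f"unknown gain mode {mode!r}")
    out = []
    for p, d in _aligned(parent_calls, derivative_calls):
        ratio = (d.signal + GAIN_PSEUDOCOUNT) / (p.signal + GAIN_PSEUDOCOUNT)
        if mode == "binary":
            gained = (not p.positive) and d.positive
            out.append(GainCall(p.transcript_id, gained, mode, None))
        else:
            gained = d.positive and ((not p.positive) or ratio >= min_ratio)
            out.append(GainCall(p.transcript_id, gained, mode, ratio))
    return out


def h3k4_universe(
    parent_calls: Sequence[ChromatinCall], derivative_calls: Sequence[ChromatinCall]
) -> set[str]:
    """Transcripts positive for the mark in either cell line."""
    pairs = _aligned(parent_calls, derivative_calls)
    return {p.transcript_id for p, d in pairs if p.positive or d.positive}


def status_table(
    parent_calls: Sequence[ChromatinCall], derivative_calls: Sequence[ChromatinCall]
) -> dict[str, int]:
    """2x2 presence/absence table across the two cell lines."""
    table = {"both": 0, "parent_only": 0, "derivative_only": 0, "neither": 0}
    for p, d in _aligned(parent_calls, derivative_calls):
        if p.positive and d.positive:
            table["both"] += 1
        elif p.positive:
            table["parent_only"] += 1
        elif d.positive:
            table["derivative_only"] += 1
        else:
            table["neither"] += 1
    return table
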