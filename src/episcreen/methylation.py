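"""Promoter methylation summary, five-bin stratification, and the
cancer-specific methylation / CpG-island filters.

Promoter = [tss - 500, tss + 500) by default, the same window used for the
CGI-overlap requirement. Per-promoter methylation is the unweighted mean of
per-CpG levels among CpGs passing the depth filter; a promoter is "available"
only when enough CpGs survive, which models the partial genome coverage of
reduced-representation bisulfite sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .io_genomics import CpGCall, GenomicInterval, TssRecord
from .chromatin import tss_window

__all__ = [
    "BIN_LABELS",
    "PROMOTER_HALFWIDTH",
    "PromoterMethylation",
    "MethylationFilterResult",
    "summarize_promoter",
    "bin_level",
    "cancer_specific_filter",
    "cgi_overlap",
]

PROMOTER_HALFWIDTH = 500

# Lower-inclusive, upper-exclusive; top bin closed at 100.
BIN_LABELS = ("0–20%", "20–40%", "40–60%", "60–80%", "80–100%")
_BIN_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)


@dataclass(frozen=True)
class PromoterMethylation:
    transcript_id: str
    tissue: str
    mean_level: Optional[float]  # percent; None when unavailable
    n_cpgs: int
    available: bool
    bin: Optional[str]


@dataclass(frozen=True)
class MethylationFilterResult:
    transcript_id: str
    evaluable: bool
    tumor_high: Optional[bool] = None
    normals_low: Optional[bool] = None
    has_cgi: Optional[bool] = None

    @property
    def passes(self) -> bool:
        return bool(
            self.evaluable
            and self.tumor_high
            and self.normals_low
            and (self.has_cgi is not False)
        )


def summarize_promoter(
    cpg_calls: Sequence[CpGCall],
    tss: TssRecord,
    halfwidth: int = PROMOTER_HALFWIDTH,
    min_depth: int = 10,
    min_cpgs: int = 3,
) -> PromoterMethylation:
    """Summarize one tissue's CpG calls over the promoter window of one TSS.

    CpGs with total_reads < min_depth are excluded; the promoter is available
    only when >= min_cpgs CpGs survive. The mean is unweighted across CpGs
    (read-weighting would let one deep site dominate the region estimate).
    """
    tissues = {c.tissue for c in cpg_calls}
    if len(tissues) > 1:
        raise ValueError(f"calls from multiple tissues: {sorted(tissues)}")
    win = tss_window(tss, halfwidth)
    levels = [
        c.level
        for c in cpg_calls
        if c.chrom == win.chrom and win.start <= c.pos < win.end and c.total_reads >= min_depth
    ]
    n = len(levels)
    if n < min_cpgs:
        return PromoterMethylation(tss.transcript_id, _only(tissues), None, n, False, None)
    mean = 100.0 * sum(levels) / n
    return PromoterMethylation(tss.transcript_id, _only(tissues), mean, n, True, bin_level(mean))


def bin_level(mean_level: float) -> str:
    """Map a percent methylation level to one of the five stratification bins."""
    if not 0 <= mean_level <= 100:
        raise ValueError(f"methylation percent out of range: {mean_level}")
    for lo, hi, label in zip(_BIN_EDGES[:-1], _BIN_EDGES[1:], BIN_LABELS):
        if lo <= mean_level < hi:
            return label
    return BIN_LABELS[-1]  # 100.0 falls in the closed top bin


def cancer_specific_filter(
    tumor: PromoterMethylation,
    normals: Sequence[PromoterMethylation],
    tumor_min: float = 60.0,
    normal_max: float = 40.0,
    normals_mode: str = "all",
) -> MethylationFilterResult:
    """Cancer-specific methylation rule: strictly > tumor_min percent in the
    tumor line and strictly < normal_max percent in normal tissues.

    normals_mode "all" (default) requires every available normal tissue to be
    low; "any" requires at least one. Unavailable normals are ignored. When
    the tumor promoter is unavailable, or no normal is, the result is
    not-evaluable — distinct from a failing filter.
    """
    if normals_mode not in ("all", "any"):
        raise ValueError(f"unknown normals_mode {normals_mode!r}")
    avail_normals = [n for n in normals if n.available]
    if not tumor.available or not avail_normals:
        return MethylationFilterResult(tumor.transcript_id, evaluable=False)
    tumor_high = tumor.mean_level > tumor_min
    low_flags = [n.mean_level < normal_max for n in avail_normals]
    normals_low = all(low_flags) if normals_mode == "all" else any(low_flags)
    return MethylationFilterResult(
        tumor.transcript_id, evaluable=True, tumor_high=tumor_high, normals_low=normals_low
    )


def cgi_overlap(
    tss: TssRecord,
    cgi_intervals: Sequence[GenomicInterval] | IntervalTree,
    halfwidth: int = PROMOTER_HALFWIDTH,
) -> bool:
    """True iff any CpG island overlaps the promoter window of the TSS."""
    win = tss_window(tss, halfwidth)
    if isinstance(cgi_intervals, IntervalTree):
        return bool(cgi_intervals.overlap(win.start, win.end))
    return any(win.overlaps(cgi) for cgi in cgi_intervals)


def _only(tissues: set[str]) -> str:
    return next(iter(tissues)) if tissues else ""
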