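"""Orchestration of the full silencing screen and the staged funnel report.

Stage order follows the screen's narrative: the full TSS universe is narrowed
to TSSs H3K4me3-positive in either cell line, then to those gaining H3K4me3
in the demethylated derivative, then to those with promoter bisulfite
coverage, then to cancer-specifically methylated promoters, then to those
with a promoter CpG island, and finally to genes passing both expression
criteria. Later stages are evaluated only for survivors of earlier stages;
non-survivors carry ``None`` ("not evaluated") for later flags, distinct
from an evaluated False.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

from intervaltree import IntervalTree

from . import chromatin, expression, methylation
from .io_genomics import (
    CpGCall,
    ExpressionMeasure,
    GenomicInterval,
    PeakSet,
    TssRecord,
)

__all__ = [
    "ScreenConfig",
    "ScreenInputs",
    "ScreenRecord",
    "FunnelReport",
    "run_screen",
    "format_fraction",
    "collapse_to_genes",
]

STAGES = (
    "universe",
    "k4_positive_any",
    "k4_gained",
    "rrbs_available",
    "meth_pass",
    "cgi_pass",
    "expr_pass",
)


@dataclass(frozen=True)
class ScreenConfig:
    """Every screen threshold, with the published defaults."""

    k4_halfwidth: int = chromatin.K4_HALFWIDTH
    broad_halfwidth: int = chromatin.BROAD_HALFWIDTH
    promoter_halfwidth: int = methylation.PROMOTER_HALFWIDTH
    min_depth: int = 10
    min_cpgs: int = 3
    tumor_min: float = 60.0
    normal_max: float = 40.0
    normals_mode: str = "all"
    fold_min: float = 2.0
    expressed_min: float = 0.01
    gain_mode: str = "quantitative"
    min_ratio: float = 2.0
    b_mode: str = "or"
    collapse_mode: str = "any_tss"


@dataclass
class ScreenInputs:
    """The complete input bundle the screen consumes."""

    tss: list[TssRecord]
    cgis: list[GenomicInterval]
    peaks: dict[tuple[str, str], PeakSet]  # (mark, cell_line) -> PeakSet
    tumor_cpgs: list[CpGCall]
    normal_cpgs: dict[str, list[CpGCall]]  # tissue name -> calls
    expression: list[ExpressionMeasure]
    parent_line: str = "HCT116"
    derivative_line: str = "DKO2"


@dataclass
class ScreenRecord:
    transcript_id: str
    gene_id: str
    k4_positive_any: bool = False
    k4_gained: Optional[bool] = None
    k27_parent: bool = False
    rrbs_available: Optional[bool] = None
    meth_pass: Optional[bool] = None
    cgi_pass: Optional[bool] = None
    expr_pass: Optional[bool] = None
    final_hit: bool = False


@dataclass
class FunnelReport:
    stages: list[dict]  # name, count, pct_of_previous, pct_of_universe
    k4_status_table: dict[str, int]
    k27_fraction_of_gained: Optional[float]
    gene_level_hits: list[str]
    collapse_mode: str

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FunnelReport":
        return cls(**d)


def format_fraction(numerator: int, denominator: int) -> str:
    """Percent string with one decimal, rounded half away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator > denominator or numerator < 0:
        raise ValueError("numerator must lie in [0, denominator]")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return f"{pct.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"


def collapse_to_genes(
    records: Sequence[ScreenRecord], mode: str = "any_tss"
) -> dict[str, bool]:
    """Gene-level hit flags: OR over a gene's transcripts (any_tss, default)
    or AND (all_tss)."""
    if mode not in ("any_tss", "all_tss"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    out: dict[str, bool] = {}
    for r in records:
        if r.gene_id not in out:
            out[r.gene_id] = r.final_hit
        elif mode == "any_tss":
            out[r.gene_id] = out[r.gene_id] or r.final_hit
        else:
            out[r.gene_id] = out[r.gene_id] and r.final_hit
    return out


def run_screen(
    inputs: ScreenInputs, config: ScreenConfig = ScreenConfig()
) -> tuple[list[ScreenRecord], FunnelReport]:
    """Run every stage of the screen and assemble the funnel report."""
    tss_list = sorted(inputs.tss, key=lambda t: t.transcript_id)
    records = {t.transcript_id: ScreenRecord(t.transcript_id, t.gene_id) for t in tss_list}
    if len(records) != len(tss_list):
        raise ValueError("duplicate transcript_ids in annotation")

    def peakset(mark: str, cell: str) -> PeakSet:
        try:
            return inputs.peaks[(mark, cell)]
        except KeyError:
            raise ValueError(f"missing peak set for ({mark}, {cell})") from None

    # chromatin stage
    k4_parent = chromatin.call_mark(
        tss_list, peakset("H3K4me3", inputs.parent_line), config.k4_halfwidth
    )
    k4_deriv = chromatin.call_mark(
        tss_list, peakset("H3K4me3", inputs.derivative_line), config.k4_halfwidth
    )
    k27_parent = chromatin.call_mark(
        tss_list, peakset("H3K27me3", inputs.parent_line), config.broad_halfwidth
    )
    universe = chromatin.h3k4_universe(k4_parent, k4_deriv)
    gains = {
        g.transcript_id: g
        for g in chromatin.detect_gain(k4_parent, k4_deriv, config.gain_mode, config.min_ratio)
    }
    for call in k27_parent:
        records[call.transcript_id].k27_parent = call.positive
    for tid, rec in records.items():
        rec.k4_positive_any = tid in universe
        if rec.k4_positive_any:
            rec.k4_gained = gains[tid].gained

    gained_tss = [t for t in tss_list if records[t.transcript_id].k4_gained]

    # methylation stage (only for gained survivors)
    tumor_by_chrom = _group_calls(inputs.tumor_cpgs)
    normals_by_chrom = {t: _group_calls(c) for t, c in inputs.normal_cpgs.items()}
    cgi_tree = _cgi_trees(inputs.cgis)
    meth_survivors: list[TssRecord] = []
    for t in gained_tss:
        rec = records[t.transcript_id]
        tumor_summary = methylation.summarize_promoter(
            tumor_by_chrom.get(t.chrom, []),
            t,
            config.promoter_halfwidth,
            config.min_depth,
            config.min_cpgs,
        )
        normal_summaries = [
            methylation.summarize_promoter(
                by_chrom.get(t.chrom, []),
                t,
                config.promoter_halfwidth,
                config.min_depth,
                config.min_cpgs,
            )
            for by_chrom in normals_by_chrom.values()
        ]
        filt = methylation.cancer_specific_filter(
            tumor_summary,
            normal_summaries,
            config.tumor_min,
            config.normal_max,
            config.normals_mode,
        )
        rec.rrbs_available = filt.evaluable
        if not filt.evaluable:
            continue
        rec.meth_pass = bool(filt.tumor_high and filt.normals_low)
        if not rec.meth_pass:
            continue
        rec.cgi_pass = methylation.cgi_overlap(
            t, cgi_tree.get(t.chrom, IntervalTree()), config.promoter_halfwidth
        )
        if rec.cgi_pass:
            meth_survivors.append(t)

    # expression stage (gene-level, only for CGI survivors)
    expr_by_gene: dict[str, list[ExpressionMeasure]] = {}
    for m in inputs.expression:
        expr_by_gene.setdefault(m.gene_id, []).append(m)
    for t in meth_survivors:
        rec = records[t.transcript_id]
        measures = expr_by_gene.get(t.gene_id)
        if not measures:
            rec.expr_pass = None  # no expression data: not evaluated
            continue
        verdict = expression.judge_gene(
            measures,
            fold_min=config.fold_min,
            expressed_min=config.expressed_min,
            b_mode=config.b_mode,
        )
        rec.expr_pass = verdict.passes if verdict.evaluable else None
        rec.final_hit = bool(rec.expr_pass)

    record_list = [records[t.transcript_id] for t in tss_list]
    report = _build_report(record_list, k4_parent, k4_deriv, config)
    return record_list, report


def _build_report(
    records: list[ScreenRecord],
    k4_parent,
    k4_deriv,
    config: ScreenConfig,
) -> FunnelReport:
    counts = {
        "universe": len(records),
        "k4_positive_any": sum(r.k4_positive_any for r in records),
        "k4_gained": sum(bool(r.k4_gained) for r in records),
        "rrbs_available": sum(bool(r.rrbs_available) for r in records),
        "meth_pass": sum(bool(r.meth_pass) for r in records),
        "cgi_pass": sum(bool(r.cgi_pass) for r in records),
        "expr_pass": sum(bool(r.expr_pass) for r in records),
    }
    stages = []
    prev = counts["universe"]
    for name in STAGES:
        c = counts[name]
        stages.append(
            {
                "name": name,
                "count": c,
                "pct_of_previous": format_fraction(c, prev) if prev else None,
                "pct_of_universe": (
                    format_fraction(c, counts["universe"]) if counts["universe"] else None
                ),
            }
        )
        prev = c if c else prev  # avoid zero denominators downstream

    n_gained = counts["k4_gained"]
    k27_frac = (
        sum(1 for r in records if r.k4_gained and r.k27_parent) / n_gained
        if n_gained
        else None
    )
    gene_hits = sorted(
        g for g, hit in collapse_to_genes(records, config.collapse_mode).items() if hit
    )
    return FunnelReport(
        stages=stages,
        k4_status_table=chromatin.status_table(k4_parent, k4_deriv),
        k27_fraction_of_gained=k27_frac,
        gene_level_hits=gene_hits,
        collapse_mode=config.collapse_mode,
    )


def _group_calls(calls: Sequence[CpGCall]) -> dict[str, list[CpGCall]]:
    out: dict[str, list[CpGCall]] = {}
    for c in calls:
        out.setdefault(c.chrom, []).append(c)
    return out


def _cgi_trees(cgis: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in cgis:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees
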