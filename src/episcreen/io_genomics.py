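"""Coordinate primitives and readers/writers for the pipeline's file formats.

All coordinates are 0-based, half-open (BED-native) throughout the package;
any 1-based source must be converted at the boundary. The TSS of a minus-strand
transcript is ``end - 1``, i.e. the biological 5' end under UCSC conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "TssRecord",
    "PeakSet",
    "CpGCall",
    "ExpressionMeasure",
    "ClinicalSample",
    "ParseError",
    "MARKS",
    "CONDITIONS",
    "CLINICAL_GROUPS",
    "read_bed",
    "write_bed",
    "read_cpg_coverage",
    "write_cpg_coverage",
    "read_tss_annotation",
    "write_tss_annotation",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "write_report",
    "read_report",
]

MARKS = ("H3K4me3", "H3K27me3", "H3K79me2")
CONDITIONS = ("normal_colon", "tumor_line", "tumor_line_aza", "demethylated_line")
CLINICAL_GROUPS = ("normal", "adenoma", "advanced_adenoma", "carcinoma")

MISSING = "."


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.score is not None and self.score < 0:
            raise ValueError(f"negative score: {self.score}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap: one shared base suffices."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: the 5'-most base of a transcript model."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"negative TSS position: {self.tss}")


@dataclass
class PeakSet:
    """Peak intervals for one histone mark in one cell line.

    Peaks are consumed as inputs (already called); intervals are kept sorted
    by (chrom, start).
    """

    mark: str
    cell_line: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {MARKS}")
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start))


@dataclass(frozen=True)
class CpGCall:
    """Bisulfite read counts at one CpG site in one tissue (strand-collapsed)."""

    chrom: str
    pos: int
    meth_reads: int
    total_reads: int
    tissue: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position: {self.pos}")
        if self.total_reads <= 0:
            raise ValueError(f"total_reads must be positive, got {self.total_reads}")
        if not 0 <= self.meth_reads <= self.total_reads:
            raise ValueError(
                f"meth_reads {self.meth_reads} outside [0, {self.total_reads}]"
            )

    @property
    def level(self) -> float:
        return self.meth_reads / self.total_reads


@dataclass(frozen=True)
class ExpressionMeasure:
    """Relative expression of one gene in one condition (housekeeping-normalized)."""

    gene_id: str
    condition: str
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"negative expression value: {self.value}")


@dataclass(frozen=True)
class ClinicalSample:
    """One clinical observation: cohort group, promoter methylation percent,
    optional expression, optional right-censored survival."""

    sample_id: str
    group: str
    methylation: float
    expression: Optional[float] = None
    surv_time: Optional[float] = None
    event: Optional[int] = None

    def __post_init__(self) -> None:
        if self.group not in CLINICAL_GROUPS:
            raise ValueError(
                f"unknown group {self.group!r}; expected one of {CLINICAL_GROUPS}"
            )
        if not 0 <= self.methylation <= 100:
            raise ValueError(f"methylation percent out of range: {self.methylation}")
        if self.expression is not None and self.expression < 0:
            raise ValueError(f"negative expression: {self.expression}")
        if (self.surv_time is None) != (self.event is None):
            raise ValueError("surv_time and event must be present together")
        if self.surv_time is not None and self.surv_time <= 0:
            raise ValueError(f"surv_time must be positive, got {self.surv_time}")
        if self.event is not None and self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals; track/browser/comment lines are skipped."""
    intervals: list[GenomicInterval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != MISSING else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] != MISSING:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] != MISSING else None
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                cols.append(iv.name if iv.name is not None else MISSING)
                cols.append(_fmt(iv.score) if iv.score is not None else MISSING)
                cols.append(iv.strand if iv.strand is not None else MISSING)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# CpG coverage (Bismark-coverage-style: chrom, start, end, meth, total)


def read_cpg_coverage(path: str | Path, tissue: str) -> list[CpGCall]:
    """Read per-CpG bisulfite counts. Duplicate positions within one tissue
    are an error (they indicate an upstream aggregation bug), and rows with
    zero coverage or meth > total are rejected."""
    calls: list[CpGCall] = []
    seen: set[tuple[str, int]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                meth, total = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field") from exc
            if end != start + 1:
                raise ParseError(f"{path}:{lineno}: CpG row must span one base")
            key = (chrom, start)
            if key in seen:
                raise ParseError(f"{path}:{lineno}: duplicate CpG site {chrom}:{start}")
            seen.add(key)
            try:
                calls.append(CpGCall(chrom, start, meth, total, tissue))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return calls


def write_cpg_coverage(calls: Iterable[CpGCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.pos}\t{c.pos + 1}\t{c.meth_reads}\t{c.total_reads}\n")


# ---------------------------------------------------------------------------
# TSS annotation (TSV with header)

_TSS_COLUMNS = ["transcript_id", "gene_id", "chrom", "start", "end", "strand"]


def read_tss_annotation(path: str | Path) -> list[TssRecord]:
    """Read a transcript table and derive each TSS from the interval + strand:
    ``tss = start`` on +, ``tss = end - 1`` on - (0-based half-open input)."""
    records: list[TssRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = _column_index(header, _TSS_COLUMNS, path)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            tid = fields[idx["transcript_id"]]
            if tid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate transcript_id {tid!r}")
            seen.add(tid)
            strand = fields[idx["strand"]]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            try:
                start, end = int(fields[idx["start"]]), int(fields[idx["end"]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not 0 <= start < end:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            tss = start if strand == "+" else end - 1
            records.append(
                TssRecord(tid, fields[idx["gene_id"]], fields[idx["chrom"]], strand, tss)
            )
    return records


def write_tss_annotation(
    records: Sequence[TssRecord], path: str | Path, transcript_length: int = 1000
) -> None:
    """Write TSS records back as transcript intervals (inverse of the strand
    convention used by the reader); a nominal transcript length is used since
    only the 5' end is meaningful downstream."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSS_COLUMNS) + "\n")
        for r in records:
            if r.strand == "+":
                start, end = r.tss, r.tss + transcript_length
            else:
                start, end = max(0, r.tss + 1 - transcript_length), r.tss + 1
            fh.write(f"{r.transcript_id}\t{r.gene_id}\t{r.chrom}\t{start}\t{end}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Expression / clinical tables (TSV with header, "." for missing)


def read_expression(path: str | Path) -> list[ExpressionMeasure]:
    measures: list[ExpressionMeasure] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = _column_index(header, ["gene_id", "condition", "value"], path)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            try:
                value = float(fields[idx["value"]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value") from exc
            try:
                measures.append(
                    ExpressionMeasure(fields[idx["gene_id"]], fields[idx["condition"]], value)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return measures


def write_expression(measures: Iterable[ExpressionMeasure], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tcondition\tvalue\n")
        for m in measures:
            fh.write(f"{m.gene_id}\t{m.condition}\t{_fmt(m.value)}\n")


def read_clinical(path: str | Path) -> list[ClinicalSample]:
    samples: list[ClinicalSample] = []
    required = ["sample_id", "group", "methylation"]
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = _column_index(header, required, path)
        opt = {c: header.index(c) for c in ("expression", "surv_time", "event") if c in header}
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")

            def _opt_float(col: str) -> Optional[float]:
                if col not in opt:
                    return None
                v = fields[opt[col]]
                return None if v in (MISSING, "") else float(v)

            try:
                expression = _opt_float("expression")
                surv_time = _opt_float("surv_time")
                ev = _opt_float("event")
                event = int(ev) if ev is not None else None
                samples.append(
                    ClinicalSample(
                        fields[idx["sample_id"]],
                        fields[idx["group"]],
                        float(fields[idx["methylation"]]),
                        expression=expression,
                        surv_time=surv_time,
                        event=event,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return samples


def write_clinical(samples: Iterable[ClinicalSample], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\tmethylation\texpression\tsurv_time\tevent\n")
        for s in samples:
            fh.write(
                "\t".join(
                    [
                        s.sample_id,
                        s.group,
                        _fmt(s.methylation),
                        _fmt(s.expression) if s.expression is not None else MISSING,
                        _fmt(s.surv_time) if s.surv_time is not None else MISSING,
                        str(s.event) if s.event is not None else MISSING,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Reports (JSON)


def write_report(report, path: str | Path) -> None:
    """Serialize a report (an object with ``to_dict`` or a plain dict) to JSON.

    Round-trip safe: reading the file back reproduces all counts and flags.
    """
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------


def _column_index(header: list[str], required: list[str], path) -> dict[str, int]:
    missing = [c for c in required if c not in header]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return {c: header.index(c) for c in required}


def _fmt(x: float) -> str:
    """Deterministic numeric formatting (repr of float is stable in py3)."""
    if x == int(x):
        return str(int(x))
    return repr(float(x))
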