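"""Synthetic epigenome bundle with a planted truth set of silenced genes.

Generates, on a single synthetic chromosome, everything the screen consumes:
a transcript annotation, CpG-island intervals, peak sets for three histone
marks in a parent tumor line and its demethylated derivative, per-CpG
bisulfite counts for the tumor line and five normal gastrointestinal
tissues, a four-condition expression table, and clinical cohorts with
methylation percentages and right-censored survival.

Planted silenced genes carry the full silencing signature: a hypermethylated
promoter CGI in the tumor line (low methylation in every normal tissue), no
H3K4me3 peak in the parent line but one in the demethylated derivative, an
H3K27me3 mark in the parent for a configurable fraction, strong expression
in normal colon, reduced expression in the tumor line, and reactivation
under both demethylating treatments. Non-silenced genes fall into three
classes: active everywhere, inactive-unmethylated, and tissue-silent; a
fraction of the tissue-silent class gains H3K4me3 on demethylation without
promoter methylation, so the funnel's gain-to-methylation attrition is
non-trivial.

CpG counts follow a beta-binomial observation model: each site's methylation
level is Beta-distributed around the planted promoter mean and reads are
binomial at Poisson-distributed depth — the standard bisulfite noise model,
giving realistic sampling variance the filters must tolerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .funnel import ScreenInputs
from .io_genomics import (
    ClinicalSample,
    CpGCall,
    ExpressionMeasure,
    GenomicInterval,
    PeakSet,
    TssRecord,
    write_bed,
    write_clinical,
    write_cpg_coverage,
    write_expression,
    write_tss_annotation,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "SyntheticBundle",
    "NORMAL_TISSUES",
    "generate_bundle",
    "generate_null_clinical",
    "generate_survival_cohort",
    "write_bundle",
]

NORMAL_TISSUES = (
    "colonic_mucosa",
    "rectal_mucosa",
    "rectal_smooth_muscle",
    "duodenum_mucosa",
    "stomach_smooth_muscle",
)

PARENT_LINE = "HCT116"
DERIVATIVE_LINE = "DKO2"
TUMOR_TISSUE = "HCT116"


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 200
    n_silenced: int = 20
    chrom: str = "chrSim"
    chrom_length: int = 10_000_000
    promoter_halfwidth: int = 500
    tumor_meth_high: float = 0.85
    meth_low: float = 0.05
    meth_concentration: float = 50.0
    cpgs_per_promoter: float = 12.0
    read_depth: float = 30.0
    expr_base: float = 0.0  # log-location of normal-colon expression
    expr_sigma: float = 0.15  # multiplicative log-normal noise
    silencing_fold: float = 8.0
    reactivation_fold: float = 6.0
    k27_fraction: float = 0.39
    active_frac: float = 0.55  # of non-silenced genes
    inactive_frac: float = 0.20
    tissue_silent_gain_prob: float = 0.5
    n_normal: int = 46
    n_adenoma: int = 38
    n_advanced: int = 41
    n_carcinoma: int = 101
    clinical_means: tuple[float, float, float, float] = (5.0, 12.0, 30.0, 35.0)
    clinical_concentration: float = 8.0
    hazard_ratio: float = 2.0
    median_survival: float = 40.0  # months, baseline group
    censor_horizon: float = 60.0

    def __post_init__(self) -> None:
        if self.n_silenced > self.n_genes:
            raise ValueError("n_silenced cannot exceed n_genes")
        for m in (self.tumor_meth_high, self.meth_low):
            if not 0 < m < 1:
                raise ValueError("Beta means must lie in (0, 1)")
        if self.silencing_fold <= 1 or self.reactivation_fold <= 1:
            raise ValueError("fold parameters must exceed 1")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "clinical_means" in raw:
            raw["clinical_means"] = tuple(raw["clinical_means"])
        return cls(**raw)


@dataclass
class TruthSet:
    silenced_gene_ids: set[str]
    planted_params: dict[str, dict] = field(default_factory=dict)


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    tss: list[TssRecord]
    cgis: list[GenomicInterval]
    peaks: dict[tuple[str, str], PeakSet]
    tumor_cpgs: list[CpGCall]
    normal_cpgs: dict[str, list[CpGCall]]
    expression: list[ExpressionMeasure]
    clinical: list[ClinicalSample]
    truth: TruthSet
    gene_classes: dict[str, str] = field(default_factory=dict)

    def screen_inputs(self) -> ScreenInputs:
        return ScreenInputs(
            tss=self.tss,
            cgis=self.cgis,
            peaks=self.peaks,
            tumor_cpgs=self.tumor_cpgs,
            normal_cpgs=self.normal_cpgs,
            expression=self.expression,
            parent_line=PARENT_LINE,
            derivative_line=DERIVATIVE_LINE,
        )


def generate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Deterministic (per seed) generation of the full input bundle."""
    rng = np.random.default_rng(config.seed)
    cfg = config

    spacing = cfg.chrom_length // (cfg.n_genes + 1)
    if spacing < 6 * cfg.promoter_halfwidth:
        raise ValueError("chromosome too short for the requested gene count")

    # class assignment: planted silenced genes are a random subset
    classes = _assign_classes(rng, cfg)

    tss_records: list[TssRecord] = []
    cgis: list[GenomicInterval] = []
    peak_lists: dict[tuple[str, str], list[GenomicInterval]] = {
        (mark, cell): []
        for mark in ("H3K4me3", "H3K27me3", "H3K79me2")
        for cell in (PARENT_LINE, DERIVATIVE_LINE)
    }
    tumor_cpgs: list[CpGCall] = []
    normal_cpgs: dict[str, list[CpGCall]] = {t: [] for t in NORMAL_TISSUES}
    expression: list[ExpressionMeasure] = []
    truth = TruthSet(silenced_gene_ids=set())
    gene_classes: dict[str, str] = {}

    conc = cfg.meth_concentration
    for i in range(cfg.n_genes):
        gene_id = f"SIMG{i:04d}"
        tid = f"{gene_id}.1"
        cls = classes[i]
        gene_classes[gene_id] = cls
        tss = (i + 1) * spacing
        strand = "+" if rng.random() < 0.5 else "-"
        tss_records.append(TssRecord(tid, gene_id, cfg.chrom, strand, tss))

        # --- promoter CpGs, shared positions across tissues
        n_cpg = int(rng.poisson(cfg.cpgs_per_promoter))
        lo, hi = tss - cfg.promoter_halfwidth, tss + cfg.promoter_halfwidth
        positions = np.sort(
            rng.choice(np.arange(lo, hi), size=min(n_cpg, hi - lo), replace=False)
        )
        tumor_mean = cfg.tumor_meth_high if cls == "silenced" else cfg.meth_low
        tumor_cpgs.extend(
            _cpg_calls(rng, cfg, positions, tumor_mean, conc, TUMOR_TISSUE)
        )
        for tissue in NORMAL_TISSUES:
            normal_cpgs[tissue].extend(
                _cpg_calls(rng, cfg, positions, cfg.meth_low, conc, tissue)
            )

        # --- CpG island
        has_cgi = {
            "silenced": True,
            "active": rng.random() < 0.8,
            "inactive_unmethylated": rng.random() < 0.5,
            "tissue_silent": rng.random() < 0.3,
        }[cls]
        if has_cgi:
            cgis.append(GenomicInterval(cfg.chrom, tss - 300, tss + 350))

        # --- peaks
        tissue_silent_gains = cls == "tissue_silent" and rng.random() < cfg.tissue_silent_gain_prob
        k27_in_parent = cls == "silenced" and rng.random() < cfg.k27_fraction
        score = lambda: float(np.round(rng.lognormal(3.5, 0.4), 3))  # noqa: E731
        k4_interval = lambda: GenomicInterval(  # noqa: E731
            cfg.chrom, max(0, tss - 400), tss + 900, score=score()
        )
        if cls == "active":
            peak_lists[("H3K4me3", PARENT_LINE)].append(k4_interval())
            peak_lists[("H3K4me3", DERIVATIVE_LINE)].append(k4_interval())
            peak_lists[("H3K79me2", PARENT_LINE)].append(
                GenomicInterval(cfg.chrom, tss, tss + 3000, score=score())
            )
            peak_lists[("H3K79me2", DERIVATIVE_LINE)].append(
                GenomicInterval(cfg.chrom, tss, tss + 3000, score=score())
            )
        elif cls == "silenced" or tissue_silent_gains:
            peak_lists[("H3K4me3", DERIVATIVE_LINE)].append(k4_interval())
        if k27_in_parent:
            peak_lists[("H3K27me3", PARENT_LINE)].append(
                GenomicInterval(cfg.chrom, max(0, tss - 2000), tss + 2000, score=score())
            )

        # --- expression (four conditions, gene level)
        noise = lambda: float(rng.lognormal(0.0, cfg.expr_sigma))  # noqa: E731
        base = float(rng.lognormal(cfg.expr_base, 0.3))
        if cls == "silenced":
            normal = base
            tumor = base / cfg.silencing_fold * noise()
            aza = tumor * cfg.reactivation_fold * noise()
            ko = tumor * cfg.reactivation_fold * noise()
            truth.silenced_gene_ids.add(gene_id)
            truth.planted_params[gene_id] = {
                "tumor_meth_mean": cfg.tumor_meth_high,
                "silencing_fold": cfg.silencing_fold,
                "reactivation_fold": cfg.reactivation_fold,
            }
        elif cls == "active":
            normal, tumor = base, base * noise()
            aza, ko = tumor * noise(), tumor * noise()
        elif cls == "inactive_unmethylated":
            normal = tumor = aza = ko = 0.0
        else:  # tissue_silent
            normal = base
            tumor = base / 6.0 * noise()
            if tissue_silent_gains:
                aza, ko = tumor * 4.0 * noise(), tumor * 4.0 * noise()
            else:
                aza, ko = tumor * noise(), tumor * noise()
        for cond, val in (
            ("normal_colon", normal),
            ("tumor_line", tumor),
            ("tumor_line_aza", aza),
            ("demethylated_line", ko),
        ):
            expression.append(ExpressionMeasure(gene_id, cond, round(val, 6)))

    peaks = {
        key: PeakSet(mark=key[0], cell_line=key[1], intervals=ivs)
        for key, ivs in peak_lists.items()
    }
    clinical = _generate_clinical(rng, cfg)
    return SyntheticBundle(
        config=cfg,
        tss=tss_records,
        cgis=cgis,
        peaks=peaks,
        tumor_cpgs=tumor_cpgs,
        normal_cpgs=normal_cpgs,
        expression=expression,
        clinical=clinical,
        truth=truth,
        gene_classes=gene_classes,
    )


def _assign_classes(rng: np.random.Generator, cfg: SimulationConfig) -> list[str]:
    n_other = cfg.n_genes - cfg.n_silenced
    n_active = int(round(cfg.active_frac * n_other))
    n_inactive = int(round(cfg.inactive_frac * n_other))
    n_tissue = n_other - n_active - n_inactive
    classes = (
        ["silenced"] * cfg.n_silenced
        + ["active"] * n_active
        + ["inactive_unmethylated"] * n_inactive
        + ["tissue_silent"] * n_tissue
    )
    perm = rng.permutation(cfg.n_genes)
    return [classes[j] for j in perm]


def _cpg_calls(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    positions: np.ndarray,
    mean: float,
    conc: float,
    tissue: str,
) -> list[CpGCall]:
    a, b = mean * conc, (1 - mean) * conc
    calls = []
    for pos in positions:
        level = rng.beta(a, b)
        depth = max(1, int(rng.poisson(cfg.read_depth)))
        meth = int(rng.binomial(depth, level))
        calls.append(CpGCall(cfg.chrom, int(pos), meth, depth, tissue))
    return calls


def _generate_clinical(rng: np.random.Generator, cfg: SimulationConfig) -> list[ClinicalSample]:
    groups = (
        ("normal", cfg.n_normal, cfg.clinical_means[0]),
        ("adenoma", cfg.n_adenoma, cfg.clinical_means[1]),
        ("advanced_adenoma", cfg.n_advanced, cfg.clinical_means[2]),
        ("carcinoma", cfg.n_carcinoma, cfg.clinical_means[3]),
    )
    samples: list[ClinicalSample] = []
    for group, n, mean in groups:
        a = (mean / 100.0) * cfg.clinical_concentration
        b = (1 - mean / 100.0) * cfg.clinical_concentration
        meth = 100.0 * rng.beta(a, b, size=n)
        # expression anti-correlates with promoter methylation
        expr = np.exp(-meth / 25.0) * rng.lognormal(0.0, 0.2, size=n)
        if group == "carcinoma":
            median = float(np.median(meth))
            rate = np.log(2) / cfg.median_survival
            rates = np.where(meth > median, rate * cfg.hazard_ratio, rate)
            t_raw = rng.exponential(1.0 / rates)
            t_obs = np.minimum(t_raw, cfg.censor_horizon)
            events = (t_raw <= cfg.censor_horizon).astype(int)
        for i in range(n):
            surv_time = event = None
            if group == "carcinoma":
                surv_time = round(float(max(t_obs[i], 0.01)), 3)
                event = int(events[i])
            samples.append(
                ClinicalSample(
                    sample_id=f"{group[:3].upper()}{i:03d}",
                    group=group,
                    methylation=round(float(meth[i]), 3),
                    expression=round(float(expr[i]), 6),
                    surv_time=surv_time,
                    event=event,
                )
            )
    return samples


def generate_null_clinical(config: SimulationConfig, n: int) -> list[ClinicalSample]:
    """Cohort in which methylation is independent of survival — the null for
    characterizing minimal-p optimism of the cutoff scan."""
    if n < 20:
        raise ValueError("null cohort needs n >= 20")
    rng = np.random.default_rng(config.seed)
    meth = rng.uniform(0.0, 100.0, size=n)
    rate = np.log(2) / config.median_survival
    t_raw = rng.exponential(1.0 / rate, size=n)
    t_obs = np.minimum(t_raw, config.censor_horizon)
    events = (t_raw <= config.censor_horizon).astype(int)
    return [
        ClinicalSample(
            sample_id=f"NULL{i:04d}",
            group="carcinoma",
            methylation=round(float(meth[i]), 3),
            surv_time=round(float(max(t_obs[i], 0.01)), 3),
            event=int(events[i]),
        )
        for i in range(n)
    ]


def generate_survival_cohort(
    seed: int,
    n: int = 200,
    low_mean: float = 15.0,
    high_mean: float = 45.0,
    concentration: float = 60.0,
    hazard_ratio: float = 2.0,
    median_survival: float = 40.0,
    censor_horizon: float = 60.0,
) -> tuple[list[ClinicalSample], tuple[float, float]]:
    """Two-group cohort with a planted methylation separation and hazard
    ratio; returns the samples and the planted (low, high) group means."""
    rng = np.random.default_rng(seed)
    n_low = n // 2
    means = np.array([low_mean] * n_low + [high_mean] * (n - n_low)) / 100.0
    a, b = means * concentration, (1 - means) * concentration
    meth = 100.0 * rng.beta(a, b)
    rate = np.log(2) / median_survival
    rates = np.where(np.arange(n) >= n_low, rate * hazard_ratio, rate)
    t_raw = rng.exponential(1.0 / rates)
    t_obs = np.minimum(t_raw, censor_horizon)
    events = (t_raw <= censor_horizon).astype(int)
    samples = [
        ClinicalSample(
            sample_id=f"HR{i:04d}",
            group="carcinoma",
            methylation=round(float(meth[i]), 3),
            surv_time=round(float(max(t_obs[i], 0.01)), 3),
            event=int(events[i]),
        )
        for i in range(n)
    ]
    return samples, (low_mean, high_mean)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component in the pipeline's external formats,
    plus the truth set and resolved config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["annotation"] = outdir / "annotation.tsv"
    write_tss_annotation(bundle.tss, paths["annotation"])
    paths["cgi"] = outdir / "cgi.bed"
    write_bed(bundle.cgis, paths["cgi"])
    for (mark, cell), ps in sorted(bundle.peaks.items()):
        key = f"peaks_{mark}_{cell}"
        paths[key] = outdir / f"{key}.bed"
        write_bed(ps.intervals, paths[key])
    paths["tumor_cov"] = outdir / f"meth_{TUMOR_TISSUE}.cov.tsv"
    write_cpg_coverage(bundle.tumor_cpgs, paths["tumor_cov"])
    for tissue, calls in sorted(bundle.normal_cpgs.items()):
        key = f"meth_{tissue}"
        paths[key] = outdir / f"{key}.cov.tsv"
        write_cpg_coverage(calls, paths[key])
    paths["expression"] = outdir / "expression.tsv"
    write_expression(bundle.expression, paths["expression"])
    paths["clinical"] = outdir / "clinical.tsv"
    write_clinical(bundle.clinical, paths["clinical"])

    paths["truth"] = outdir / "truth.tsv"
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("gene_id\tis_silenced\tclass\ttumor_meth_mean\tsilencing_fold\treactivation_fold\n")
        for t in bundle.tss:
            g = t.gene_id
            silenced = g in bundle.truth.silenced_gene_ids
            params = bundle.truth.planted_params.get(g, {})
            fh.write(
                f"{g}\t{int(silenced)}\t{bundle.gene_classes.get(g, '.')}"
                f"\t{params.get('tumor_meth_mean', '.')}"
                f"\t{params.get('silencing_fold', '.')}"
                f"\t{params.get('reactivation_fold', '.')}\n"
            )
    paths["config"] = outdir / "config.yaml"
    bundle.config.to_yaml(paths["config"])
    return paths
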