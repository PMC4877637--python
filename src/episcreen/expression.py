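"""Expression-based validation of candidate silenced genes.

Two criteria define epigenetic silencing at the expression level:
(a) the gene is expressed in normal colon and downregulated (> 2-fold) in the
    tumor line;
(b) the gene is reactivated (> 2-fold up relative to the tumor line) by
    pharmacological demethylation (5-aza-dC) or by genetic DNMT depletion
    (the demethylated derivative line).
A shared pseudocount keeps fold changes finite when a condition is fully
silent and makes fold_change(x, x) = 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .io_genomics import ExpressionMeasure

__all__ = ["ExpressionVerdict", "fold_change", "judge_gene"]

DEFAULT_EPSILON = 1e-3


@dataclass(frozen=True)
class ExpressionVerdict:
    gene_id: str
    evaluable: bool
    expressed_in_normal: Optional[bool] = None
    down_in_tumor: Optional[bool] = None
    reactivated_aza: Optional[bool] = None
    reactivated_ko: Optional[bool] = None
    fold_down: Optional[float] = None
    fold_aza: Optional[float] = None
    fold_ko: Optional[float] = None
    b_mode: str = "or"

    @property
    def criterion_a(self) -> bool:
        return bool(self.expressed_in_normal and self.down_in_tumor)

    @property
    def criterion_b(self) -> bool:
        if self.b_mode == "and":
            return bool(self.reactivated_aza and self.reactivated_ko)
        return bool(self.reactivated_aza or self.reactivated_ko)

    @property
    def passes(self) -> bool:
        return self.evaluable and self.criterion_a and self.criterion_b


def fold_change(numerator: float, denominator: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """(numerator + eps) / (denominator + eps); strictly positive."""
    if numerator < 0 or denominator < 0:
        raise ValueError("expression values must be non-negative")
    return (numerator + epsilon) / (denominator + epsilon)


def judge_gene(
    measures: Sequence[ExpressionMeasure],
    fold_min: float = 2.0,
    expressed_min: float = 0.01,
    epsilon: float = DEFAULT_EPSILON,
    b_mode: str = "or",
) -> ExpressionVerdict:
    """Apply criteria (a) and (b) to one gene's measurements.

    Requires values for conditions normal_colon and tumor_line; the
    reactivation conditions (tumor_line_aza, demethylated_line) are optional
    and count as not-reactivated when missing. All comparisons are strict
    (exactly fold_min-fold never passes). b_mode "or" (default) accepts either
    reactivation route; "and" requires both (sensitivity analysis).
    """
    if b_mode not in ("or", "and"):
        raise ValueError(f"unknown b_mode {b_mode!r}")
    genes = {m.gene_id for m in measures}
    if len(genes) != 1:
        raise ValueError(f"measures must cover exactly one gene, got {sorted(genes)}")
    gene_id = next(iter(genes))
    by_cond: dict[str, float] = {}
    for m in measures:
        if m.condition in by_cond:
            raise ValueError(f"duplicate condition {m.condition!r} for {gene_id}")
        by_cond[m.condition] = m.value

    if "normal_colon" not in by_cond or "tumor_line" not in by_cond:
        return ExpressionVerdict(gene_id, evaluable=False)

    normal, tumor = by_cond["normal_colon"], by_cond["tumor_line"]
    fold_down = fold_change(normal, tumor, epsilon)
    verdict = dict(
        expressed_in_normal=normal >= expressed_min,
        down_in_tumor=fold_down > fold_min,
        fold_down=fold_down,
    )

    for cond, key in (("tumor_line_aza", "aza"), ("demethylated_line", "ko")):
        if cond in by_cond:
            f = fold_change(by_cond[cond], tumor, epsilon)
            verdict[f"reactivated_{key}"] = f > fold_min
            verdict[f"fold_{key}"] = f
        else:
            verdict[f"reactivated_{key}"] = False
            verdict[f"fold_{key}"] = None

    return ExpressionVerdict(gene_id, evaluable=True, b_mode=b_mode, **verdict)
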