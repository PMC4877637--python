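"""Clinical-cohort statistics downstream of the screen.

Covers the elevated-methylation classification of pyrosequencing percentages,
unpaired two-group comparisons, methylation-expression Pearson correlation,
Kaplan-Meier estimation, the two-group log-rank test, and optimal-cutoff
survival dichotomization (minimal log-rank p over admissible cutoffs).

The cutoff scan deliberately reports the minimal p-value UNCORRECTED for the
multiple candidate cutoffs examined; on a null cohort the distribution of the
minimal p is strongly sub-uniform, which callers must keep in mind when
interpreting it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .io_genomics import ClinicalSample

__all__ = [
    "CorrelationResult",
    "SurvivalCutoffResult",
    "classify_elevated",
    "elevated_frequency",
    "two_group_ttest",
    "pearson",
    "km_estimate",
    "logrank",
    "find_cutoff",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    alpha: float = 0.01

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass
class SurvivalCutoffResult:
    """Outcome of the minimal-log-rank-p cutoff scan.

    ``scan`` holds one row per admissible candidate cutoff (columns: cutoff,
    n_low, n_high, chi2, p). ``p_at_best`` is uncorrected for the multiple
    looks over candidate cutoffs.
    """

    best_cutoff: float
    logrank_chi2: float
    p_at_best: float
    n_low: int
    n_high: int
    scan: pd.DataFrame = field(repr=False)
    km_low: pd.DataFrame = field(repr=False)
    km_high: pd.DataFrame = field(repr=False)
    method: str = "minimal log-rank p (uncorrected)"


def classify_elevated(methylation: float, threshold: float = 15.0) -> bool:
    """True iff methylation percent strictly exceeds the threshold."""
    if not 0 <= methylation <= 100:
        raise ValueError(f"methylation percent out of range: {methylation}")
    return methylation > threshold


def elevated_frequency(
    samples: Sequence[ClinicalSample], threshold: float = 15.0
) -> dict[str, tuple[int, int]]:
    """Per-group (elevated count, total) under the strict > threshold rule."""
    out: dict[str, list[int]] = {}
    for s in samples:
        num, den = out.setdefault(s.group, [0, 0])
        out[s.group] = [num + classify_elevated(s.methylation, threshold), den + 1]
    return {g: (num, den) for g, (num, den) in out.items()}


def two_group_ttest(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Unpaired two-tailed Student's t test (pooled variance by default;
    Welch available via equal_var=False)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if equal_var and np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def pearson(x: Sequence[float], y: Sequence[float], alpha: float = 0.01) -> CorrelationResult:
    """Product-moment correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x), alpha)


def km_estimate(
    times: Sequence[float], events: Sequence[int]
) -> pd.DataFrame:
    """Product-limit survival estimate under right censoring.

    Returns a step-function support table (columns: time, survival) starting
    at S(0) = 1; survival is non-increasing.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty survival input")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be 0 (censored) or 1 (death)")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.values, "survival": sf.iloc[:, 0].values})


def logrank(
    group_a: tuple[Sequence[float], Sequence[int]],
    group_b: tuple[Sequence[float], Sequence[int]],
) -> tuple[float, float]:
    """1-df log-rank chi-square comparing two right-censored samples.

    Sums observed-minus-expected events in group A over distinct event times,
    with the standard hypergeometric variance; p from chi-square(1).
    """
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], int)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events: log-rank statistic undefined")
    chi2 = _logrank_chi2(ta, ea, tb, eb)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _logrank_chi2(
    ta: np.ndarray, ea: np.ndarray, tb: np.ndarray, eb: np.ndarray
) -> float:
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb]).astype(bool)
    in_a = np.zeros(len(times), dtype=bool)
    in_a[: len(ta)] = True

    event_times = np.unique(times[events])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        dying = events & (times == t)
        d = dying.sum()
        d_a = (dying & in_a).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e**2 / var)


def find_cutoff(
    samples: Sequence[ClinicalSample], min_group_frac: float = 0.10
) -> SurvivalCutoffResult:
    """Optimal methylation cutoff for survival dichotomization.

    Candidate cutoffs are midpoints between consecutive distinct methylation
    values whose split leaves at least ``min_group_frac`` of the cohort in
    each arm; each candidate is scored by the two-group log-rank test and the
    minimal p wins (ties broken toward the more balanced split). The full
    scan table is returned alongside the winner and the Kaplan-Meier support
    of both arms at the winning cutoff.
    """
    surv = [s for s in samples if s.surv_time is not None]
    if len(surv) < 20:
        raise ValueError("need >= 20 samples with survival data")
    meth = np.array([s.methylation for s in surv])
    times = np.array([s.surv_time for s in surv], dtype=float)
    events = np.array([s.event for s in surv], dtype=int)

    distinct = np.unique(meth)
    if len(distinct) < 2:
        raise ValueError("need >= 2 distinct methylation values")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0

    min_n = min_group_frac * len(surv)
    rows = []
    for c in candidates:
        high = meth > c
        n_high, n_low = int(high.sum()), int((~high).sum())
        if n_high < min_n or n_low < min_n:
            continue
        if events[~high].sum() + events[high].sum() == 0:
            continue
        chi2 = _logrank_chi2(times[~high], events[~high], times[high], events[high])
        rows.append((float(c), n_low, n_high, chi2, float(stats.chi2.sf(chi2, df=1))))
    if not rows:
        raise ValueError("no admissible cutoff under the group-size constraint")
    scan = pd.DataFrame(rows, columns=["cutoff", "n_low", "n_high", "chi2", "p"])

    best_p = scan["p"].min()
    tied = scan[scan["p"] == best_p]
    # break ties toward the more balanced split
    imbalance = (tied["n_low"] - tied["n_high"]).abs()
    best = tied.loc[imbalance.idxmin()]

    high = meth > best["cutoff"]
    return SurvivalCutoffResult(
        best_cutoff=float(best["cutoff"]),
        logrank_chi2=float(best["chi2"]),
        p_at_best=float(best["p"]),
        n_low=int(best["n_low"]),
        n_high=int(best["n_high"]),
        scan=scan,
        km_low=km_estimate(times[~high], events[~high]),
        km_high=km_estimate(times[high], events[high]),
    )
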