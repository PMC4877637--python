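"""Clinical statistics: elevation rule, t-test, Pearson, KM, log-rank,
and the optimal-cutoff scan (checked against a brute-force oracle and
against lifelines' log-rank implementation)."""

import math

import numpy as np
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from episcreen.clinical import (
    classify_elevated,
    elevated_frequency,
    find_cutoff,
    km_estimate,
    logrank,
    pearson,
    two_group_ttest,
)
from episcreen.io_genomics import ClinicalSample
from episcreen.synthetic import SimulationConfig, generate_null_clinical


class TestClassifyElevated:
    @pytest.mark.parametrize("value,expected", [(15.0, False), (15.1, True), (0.0, False), (100.0, True)])
    def test_strict_threshold(self, value, expected):
        assert classify_elevated(value) is expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_elevated(101.0)

    def test_cohort_frequency(self):
        samples = [ClinicalSample(f"s{i}", "carcinoma", m) for i, m in enumerate([10, 20, 30])]
        assert elevated_frequency(samples) == {"carcinoma": (2, 3)}


class TestTTest:
    def test_identical_groups(self):
        t, p = two_group_ttest([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        t1, p1 = two_group_ttest([0, 0, 1, 1], [1, 1, 2, 2])
        t2, p2 = two_group_ttest([1, 1, 2, 2], [0, 0, 1, 1])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_hand_computed_example(self):
        """(0,0,1,1) vs (1,1,2,2): pooled variance 1/3, so t = -sqrt(6)."""
        t, p = two_group_ttest([0, 0, 1, 1], [1, 1, 2, 2])
        assert t == pytest.approx(-math.sqrt(6), abs=1e-12)
        assert p == pytest.approx(0.0499, abs=5e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            two_group_ttest([1, 1], [1, 1])


class TestPearson:
    def test_perfect_correlations(self):
        assert pearson([0, 1, 2], [0, 1, 2]).r == pytest.approx(1.0, abs=1e-12)
        assert pearson([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_half(self):
        """(1,2,3) vs (1,3,2): covariance 1/2, both sd 1, so r = 1/2."""
        res = pearson([1, 2, 3], [1, 3, 2])
        assert res.r == pytest.approx(0.5, abs=1e-12)
        assert res.n == 3

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        assert pearson(x, 3.5 * x - 2).r == pytest.approx(1.0)
        assert pearson(x, -0.2 * x + 7).r == pytest.approx(-1.0)

    def test_significance_flag(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 1, 50)
        noisy = x + rng.normal(scale=0.05, size=50)
        assert pearson(x, noisy).significant

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


class TestKaplanMeier:
    def test_no_censoring_example(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        s = dict(zip(km["time"], km["survival"]))
        assert s[1] == pytest.approx(2 / 3) and s[2] == pytest.approx(1 / 3) and s[3] == 0

    def test_all_censored(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_censoring_removes_from_risk_set_only(self):
        """Times (1, 2+, 3): S(1) = 2/3 and S(3) = 2/3 * (1 - 1/1) = 0."""
        km = km_estimate([1, 2, 3], [1, 0, 1])
        s = dict(zip(km["time"], km["survival"]))
        assert s[1] == pytest.approx(2 / 3) and s[3] == pytest.approx(0.0)

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            times = rng.exponential(10, size=rng.integers(3, 40))
            km = km_estimate(times, np.ones_like(times, dtype=int))
            for t, s in zip(km["time"], km["survival"]):
                if t == 0:
                    continue
                assert s == pytest.approx((times > t).mean())

    def test_empty_input(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups(self):
        chi2, p = logrank(([1, 2, 3], [1, 1, 1]), ([1, 2, 3], [1, 1, 1]))
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        a = ([1, 3, 5, 8], [1, 1, 0, 1])
        b = ([2, 4, 6], [1, 0, 1])
        assert logrank(a, b) == pytest.approx(logrank(b, a))

    def test_hand_built_oe_table(self):
        """A (1,3,5) vs B (2,4,6), all events: O_A - E_A = 23/30 and
        V = 1091/900, so chi2 = 529/1091."""
        chi2, _ = logrank(([1, 3, 5], [1, 1, 1]), ([2, 4, 6], [1, 1, 1]))
        assert chi2 == pytest.approx(529 / 1091, abs=1e-12)

    def test_matches_lifelines_on_random_cohorts(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            na, nb = rng.integers(5, 30, size=2)
            ta, tb = rng.exponential(10, na), rng.exponential(14, nb)
            ea, eb = rng.integers(0, 2, na), rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                continue
            chi2, p = logrank((ta, ea), (tb, eb))
            ref = lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank(([1, 2], [0, 0]), ([3], [0]))


def brute_force_scan(samples, min_group_frac=0.10):
    """Independent enumeration of every admissible midpoint cutoff."""
    surv = [s for s in samples if s.surv_time is not None]
    meth = np.array([s.methylation for s in surv])
    times = np.array([s.surv_time for s in surv])
    events = np.array([s.event for s in surv])
    distinct = sorted(set(meth))
    rows = []
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        c = (lo + hi) / 2
        mask = meth > c
        if mask.sum() < min_group_frac * len(surv) or (~mask).sum() < min_group_frac * len(surv):
            continue
        if events.sum() == 0:
            continue
        res = lifelines_logrank(
            times[~mask], times[mask], event_observed_A=events[~mask], event_observed_B=events[mask]
        )
        rows.append((c, float(res.test_statistic), float(res.p_value)))
    return rows


def _null_cohort(seed, n=30):
    return generate_null_clinical(SimulationConfig(seed=seed), n)


class TestFindCutoff:
    def test_scan_equals_brute_force(self):
        for seed in range(5):
            samples = _null_cohort(seed, n=30)
            res = find_cutoff(samples)
            expected = brute_force_scan(samples)
            assert len(res.scan) == len(expected)
            for (c, chi2, p), row in zip(expected, res.scan.itertuples(index=False)):
                assert row.cutoff == pytest.approx(c)
                assert row.chi2 == pytest.approx(chi2, rel=1e-9)
                assert row.p == pytest.approx(p, rel=1e-9)

    def test_best_p_is_scan_minimum(self):
        res = find_cutoff(_null_cohort(3, n=40))
        assert res.p_at_best == res.scan["p"].min()
        assert (res.scan["p"] >= res.p_at_best).all()

    def test_group_size_constraint(self):
        res = find_cutoff(_null_cohort(4, n=50), min_group_frac=0.2)
        assert res.n_low >= 10 and res.n_high >= 10

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            find_cutoff(_null_cohort(0, n=30)[:10])

    def test_flags_uncorrected_p(self):
        res = find_cutoff(_null_cohort(5, n=30))
        assert "uncorrected" in res.method
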