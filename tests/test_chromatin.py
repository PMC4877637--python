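"""Chromatin-state calls: windows, half-open overlap, gain detection.

The overlap caller is checked against a per-base brute-force scan, the
stated independent oracle for interval work in this package.
"""

import numpy as np
import pytest

from episcreen.chromatin import (
    ChromatinCall,
    call_mark,
    detect_gain,
    h3k4_universe,
    status_table,
    tss_window,
)
from episcreen.io_genomics import GenomicInterval, PeakSet, TssRecord


def _tss(tid, pos, chrom="chr1"):
    return TssRecord(tid, f"g_{tid}", chrom, "+", pos)


def brute_force_positive(tss, peaks, halfwidth):
    """Per-base overlap scan: the window and a peak share >= 1 base."""
    win_bases = set(range(max(0, tss.tss - halfwidth), tss.tss + halfwidth))
    for iv in peaks.intervals:
        if iv.chrom == tss.chrom and win_bases & set(range(iv.start, iv.end)):
            return True
    return False


class TestTssWindow:
    @pytest.mark.parametrize(
        "pos,halfwidth,expected",
        [(10_000, 2_000, (8_000, 12_000)), (10_000, 5_000, (5_000, 15_000)), (300, 2_000, (0, 2_300))],
    )
    def test_window_bounds(self, pos, halfwidth, expected):
        win = tss_window(_tss("t", pos), halfwidth)
        assert (win.start, win.end) == expected

    def test_strand_independence(self):
        plus = tss_window(TssRecord("a", "g", "chr1", "+", 500), 200)
        minus = tss_window(TssRecord("b", "g", "chr1", "-", 500), 200)
        assert (plus.start, plus.end) == (minus.start, minus.end)

    def test_rejects_nonpositive_halfwidth(self):
        with pytest.raises(ValueError):
            tss_window(_tss("t", 100), 0)


class TestCallMark:
    @pytest.mark.parametrize(
        "peak_start,peak_end,positive",
        [(11_999, 12_500, True), (12_000, 12_500, False), (7_500, 8_001, True), (7_500, 8_000, False)],
    )
    def test_half_open_boundaries(self, peak_start, peak_end, positive):
        peaks = PeakSet("H3K4me3", "HCT116", [GenomicInterval("chr1", peak_start, peak_end)])
        (call,) = call_mark([_tss("t", 10_000)], peaks, 2_000)
        assert call.positive is positive

    def test_missing_chromosome_gives_negative_calls(self):
        peaks = PeakSet("H3K4me3", "HCT116", [GenomicInterval("chr2", 0, 100)])
        (call,) = call_mark([_tss("t", 50, chrom="chr1")], peaks, 100)
        assert not call.positive and call.signal == 0.0

    def test_signal_is_max_overlapping_score(self):
        peaks = PeakSet(
            "H3K4me3",
            "HCT116",
            [
                GenomicInterval("chr1", 9_000, 9_500, score=5.0),
                GenomicInterval("chr1", 9_800, 10_200, score=12.0),
                GenomicInterval("chr1", 50_000, 50_100, score=99.0),
            ],
        )
        (call,) = call_mark([_tss("t", 10_000)], peaks, 2_000)
        assert call.positive and call.signal == 12.0

    def test_brute_force_oracle(self):
        """1,000 randomized TSS/peak configurations, including windows
        clamped at 0 and single-base overlaps, against the per-base scan."""
        rng = np.random.default_rng(42)
        for _ in range(1_000):
            halfwidth = int(rng.integers(1, 60))
            tss = _tss("t", int(rng.integers(0, 300)))
            n_peaks = int(rng.integers(0, 8))
            ivs = []
            for _ in range(n_peaks):
                s = int(rng.integers(0, 350))
                ivs.append(GenomicInterval("chr1", s, s + int(rng.integers(1, 40))))
            peaks = PeakSet("H3K4me3", "HCT116", ivs)
            (call,) = call_mark([tss], peaks, halfwidth)
            assert call.positive == brute_force_positive(tss, peaks, halfwidth)

    def test_halfwidth_monotonicity(self):
        """Enlarging the window never turns a positive call negative."""
        rng = np.random.default_rng(7)
        tss_list = [_tss(f"t{i}", int(rng.integers(0, 5_000))) for i in range(50)]
        ivs = [
            GenomicInterval("chr1", s, s + int(rng.integers(1, 200)))
            for s in rng.integers(0, 5_000, size=30)
        ]
        peaks = PeakSet("H3K4me3", "HCT116", ivs)
        small = {c.transcript_id: c.positive for c in call_mark(tss_list, peaks, 100)}
        large = {c.transcript_id: c.positive for c in call_mark(tss_list, peaks, 800)}
        for tid in small:
            assert not small[tid] or large[tid]


def _call(tid, positive, signal=0.0, cell="HCT116"):
    return ChromatinCall(tid, "H3K4me3", cell, positive, signal)


class TestDetectGain:
    def test_de_novo_gain_both_modes(self):
        parent, deriv = [_call("t", False)], [_call("t", True, 5.0, "DKO2")]
        for mode in ("binary", "quantitative"):
            (g,) = detect_gain(parent, deriv, mode)
            assert g.gained

    def test_quantitative_ratio_with_pseudocount(self):
        parent = [_call("t", True, 10.0)]
        deriv = [_call("t", True, 30.0, "DKO2")]
        (g,) = detect_gain(parent, deriv, "quantitative", min_ratio=2.0)
        assert g.gained and g.ratio == pytest.approx(31 / 11)
        (gb,) = detect_gain(parent, deriv, "binary")
        assert not gb.gained  # parent already positive

    def test_both_negative_not_gained(self):
        (g,) = detect_gain([_call("t", False)], [_call("t", False, cell="DKO2")], "binary")
        assert not g.gained

    def test_universe_mismatch_is_error(self):
        with pytest.raises(ValueError, match="universes"):
            detect_gain([_call("a", True, 1.0)], [_call("b", True, 1.0, "DKO2")])

    def test_infinite_min_ratio_reduces_to_binary(self):
        rng = np.random.default_rng(3)

        def random_call(tid, cell):
            positive = bool(rng.random() < 0.5)
            signal = float(rng.integers(1, 20)) if positive else 0.0
            return ChromatinCall(tid, "H3K4me3", cell, positive, signal)

        parent = [random_call(f"t{i}", "HCT116") for i in range(200)]
        deriv = [random_call(f"t{i}", "DKO2") for i in range(200)]
        binary = {g.transcript_id: g.gained for g in detect_gain(parent, deriv, "binary")}
        quant = {g.transcript_id: g.gained for g in detect_gain(parent, deriv, "quantitative", float("inf"))}
        assert binary == quant


class TestUniverseAndStatus:
    def test_union_and_table(self):
        parent = [_call("A", True, 1.0), _call("B", False), _call("C", False)]
        deriv = [_call("A", True, 1.0, "DKO2"), _call("B", True, 2.0, "DKO2"), _call("C", False, cell="DKO2")]
        assert h3k4_universe(parent, deriv) == {"A", "B"}
        assert status_table(parent, deriv) == {
            "both": 1,
            "parent_only": 0,
            "derivative_only": 1,
            "neither": 1,
        }

    def test_empty_inputs(self):
        assert h3k4_universe([], []) == set()
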