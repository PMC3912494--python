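"""Poisson significance machinery and peak calling on planted enrichment."""

from decimal import Decimal, getcontext

import numpy as np
import pytest

from imprintscreen.genome import GenomicInterval
from imprintscreen.peaks import (
    CoverageTrack,
    PeakCallerConfig,
    call_peaks,
    local_lambda,
    poisson_sf,
)


def poisson_sf_oracle(count: int, lam: float, digits: int = 60) -> float:
    """High-precision P(X >= count) by direct pmf summation in Decimal."""
    getcontext().prec = digits
    lam_d = Decimal(str(lam))
    # exp(-lam) = 1 / exp(lam); the positive series is numerically benign
    pos = Decimal(0)
    term = Decimal(1)
    k = 0
    while True:
        pos += term
        k += 1
        term *= lam_d / k
        if term < Decimal(10) ** (-digits) * pos:
            break
    exp_neg = 1 / pos
    # sum pmf terms from `count` upward
    term = lam_d ** count
    for k in range(1, count + 1):
        term /= k
    total = Decimal(0)
    k = count
    while True:
        total += term
        k += 1
        term *= lam_d / k
        if term < Decimal(10) ** (-digits) * max(total, Decimal(10) ** -300):
            break
    return float(total * exp_neg)


class TestPoissonSF:
    def test_count_zero_is_one(self):
        assert poisson_sf(0, 0.5) == 1.0
        assert poisson_sf(0, 100) == 1.0

    def test_worked_example_against_oracle(self):
        # P(X >= 10) at rate 1 is about 1.1142e-7
        expected = poisson_sf_oracle(10, 1.0)
        assert expected == pytest.approx(1.1142e-7, rel=1e-4)
        assert poisson_sf(10, 1.0) == pytest.approx(expected, rel=1e-11)

    @pytest.mark.parametrize("lam", [0.1, 1.0, 10.0, 100.0])
    def test_matches_pmf_summation_oracle(self, lam):
        counts = [0, 1, 2, 3, 5, 8, 13, 21, 34, 55, 89, 144, 200]
        for c in counts:
            expected = poisson_sf_oracle(c, lam)
            assert poisson_sf(c, lam) == pytest.approx(expected, rel=1e-11), (c, lam)

    def test_monotone_decreasing_in_count(self):
        for lam in (0.5, 5.0, 50.0):
            ps = [poisson_sf(c, lam) for c in range(0, 120)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))
            # strictly decreasing once away from the representable-1.0 region
            strict = [p for p in ps if p < 1.0 - 1e-12]
            assert all(a > b for a, b in zip(strict, strict[1:]))

    def test_stable_deep_in_tail(self):
        # ~1e-233: far below p-value thresholds, still representable
        p = poisson_sf(119, 0.5)
        assert 0 < p < 1e-230
        assert np.isfinite(p)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            poisson_sf(5, 0.0)


def uniform_track(rate: int, n_bins: int, chrom="chr1", bw=50):
    return CoverageTrack({chrom: np.full(n_bins, rate, dtype=np.int64)}, bin_width=bw)


class TestLocalLambda:
    CFG = PeakCallerConfig()

    def test_uniform_control_equal_depths(self):
        ctrl = uniform_track(10, 2000)
        window = GenomicInterval("chr1", 1000, 1050)
        lam = local_lambda(ctrl, window, self.CFG, treat_total=ctrl.total_fragments)
        assert lam == pytest.approx(10.0)

    def test_control_spike_raises_lambda(self):
        ctrl = uniform_track(10, 2000)
        base = local_lambda(ctrl, GenomicInterval("chr1", 50_000, 50_050),
                            self.CFG, ctrl.total_fragments)
        spiked = uniform_track(10, 2000)
        spiked.counts["chr1"][1020:1040] = 200  # inside the 5 kb flank
        lam = local_lambda(spiked, GenomicInterval("chr1", 50_000, 50_050),
                           self.CFG, spiked.total_fragments)
        near = local_lambda(spiked, GenomicInterval("chr1", 51_000, 51_050),
                            self.CFG, spiked.total_fragments)
        assert near > base

    def test_depth_scaling_doubles_lambda(self):
        ctrl = uniform_track(10, 2000)
        window = GenomicInterval("chr1", 1000, 1050)
        lam1 = local_lambda(ctrl, window, self.CFG, treat_total=ctrl.total_fragments)
        lam2 = local_lambda(ctrl, window, self.CFG,
                            treat_total=2 * ctrl.total_fragments)
        assert lam2 == pytest.approx(2 * lam1)


class TestCallPeaks:
    CFG = PeakCallerConfig()

    def test_null_uniform_tracks_give_no_peaks(self):
        treat = uniform_track(10, 2000)
        ctrl = uniform_track(10, 2000)
        assert call_peaks(treat, ctrl, self.CFG) == []

    def test_planted_enrichment_recovered_as_one_covering_peak(self):
        rng = np.random.default_rng(0)
        n = 2000  # 100 kb at 50 bp bins
        ctrl = CoverageTrack({"chr1": rng.poisson(10, n)}, bin_width=50)
        treat_counts = rng.poisson(10, n)
        planted = slice(1000, 1020)  # 1 kb region
        treat_counts[planted] = rng.poisson(100, 20)  # 10x enrichment
        treat = CoverageTrack({"chr1": treat_counts}, bin_width=50)
        peaks = call_peaks(treat, ctrl, self.CFG)
        assert len(peaks) == 1
        pk = peaks[0]
        planted_iv = GenomicInterval("chr1", 1000 * 50, 1020 * 50)
        inter = max(0, min(pk.interval.end, planted_iv.end)
                    - max(pk.interval.start, planted_iv.start))
        assert inter >= 0.9 * len(planted_iv)
        assert pk.min_p <= self.CFG.p_threshold

    def test_merge_gap_rule(self):
        rng = np.random.default_rng(1)
        n = 4000

        def build(gap_bins):
            ctrl = CoverageTrack({"chr1": np.full(n, 10)}, bin_width=50)
            t = rng.poisson(10, n)
            t[1000:1010] = 200
            t[1010 + gap_bins: 1020 + gap_bins] = 200
            return CoverageTrack({"chr1": t}, bin_width=50), ctrl

        treat, ctrl = build(2)  # 100 b gap == merge_gap -> merged
        assert len(call_peaks(treat, ctrl, self.CFG)) == 1
        treat, ctrl = build(10)  # 500 b gap -> two peaks
        assert len(call_peaks(treat, ctrl, self.CFG)) == 2

    def test_min_length_filter(self):
        ctrl = CoverageTrack({"chr1": np.full(1000, 10)}, bin_width=50)
        t = np.full(1000, 10)
        t[500:502] = 300  # 100 b of signal < 200 b minimum
        treat = CoverageTrack({"chr1": t}, bin_width=50)
        assert call_peaks(treat, ctrl, self.CFG) == []

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ValueError):
            call_peaks(uniform_track(10, 100, bw=50), uniform_track(10, 100, bw=25),
                       self.CFG)

    def test_invariant_to_joint_depth_rescaling(self):
        rng = np.random.default_rng(2)
        n = 2000
        ctrl_counts = rng.poisson(10, n)
        treat_counts = rng.poisson(10, n)
        treat_counts[800:820] = rng.poisson(100, 20)
        p1 = call_peaks(
            CoverageTrack({"chr1": treat_counts}, 50),
            CoverageTrack({"chr1": ctrl_counts}, 50),
            self.CFG,
        )
        p2 = call_peaks(
            CoverageTrack({"chr1": treat_counts * 3}, 50),
            CoverageTrack({"chr1": ctrl_counts * 3}, 50),
            self.CFG,
        )
        assert [pk.interval for pk in p1] == [pk.interval for pk in p2]

    def test_merging_idempotent(self):
        """Re-calling on a track whose only signal is an already-merged peak
        region reproduces exactly that peak."""
        ctrl = CoverageTrack({"chr1": np.full(2000, 10)}, bin_width=50)
        t = np.full(2000, 10)
        t[1000:1020] = 150
        treat = CoverageTrack({"chr1": t}, bin_width=50)
        first = call_peaks(treat, ctrl, self.CFG)
        again = call_peaks(treat, ctrl, self.CFG)
        assert first == again
        assert len(first) == 1

    def test_null_significant_window_rate_bounded(self):
        """Under the null, the per-window significance rate stays within a
        conservative 10x multiple of the threshold (Monte Carlo)."""
        rng = np.random.default_rng(12345)
        n = 200_000
        cfg = PeakCallerConfig(min_length=0)
        ctrl = CoverageTrack({"chr1": rng.poisson(10, n)}, bin_width=50)
        treat = CoverageTrack({"chr1": rng.poisson(10, n)}, bin_width=50)
        from imprintscreen.peaks import _lambda_per_bin
        from scipy import stats

        lam = _lambda_per_bin(
            ctrl.counts["chr1"], cfg,
            ctrl.total_fragments / n,
            treat.total_fragments / ctrl.total_fragments,
        )
        p = stats.poisson.sf(treat.counts["chr1"] - 1, lam)
        assert (p <= cfg.p_threshold).mean() <= 10 * cfg.p_threshold
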