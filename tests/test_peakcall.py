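import math

import numpy as np
import pytest
from scipy import stats

from ripfoot.io_formats import CoverageTrack, GenomeLayout, ReadAlignment
from ripfoot.peakcall import (
    CallerParams,
    call_peaks,
    call_peaks_from_tracks,
    local_lambda,
    pileup,
    raw_coverage,
)


def track_from(genome, strand, arrays):
    return CoverageTrack(genome, strand, {c: np.asarray(a, dtype=float) for c, a in arrays.items()})


class TestPileup:
    def test_plus_read_extends_from_five_prime(self):
        genome = GenomeLayout({"c": 200})
        params = CallerParams(extsize=75)
        track = pileup([ReadAlignment("c", "+", 10, 40)], genome, params, "+")
        arr = track["c"]
        assert arr[10:85].tolist() == [1.0] * 75
        assert arr[:10].sum() == 0 and arr[85:].sum() == 0

    def test_duplicates_retained(self):
        genome = GenomeLayout({"c": 200})
        params = CallerParams(extsize=75)
        reads = [ReadAlignment("c", "+", 10, 40)] * 2
        track = pileup(reads, genome, params, "+")
        assert track["c"][10:85].tolist() == [2.0] * 75

    def test_minus_read_extends_upstream_of_three_prime(self):
        genome = GenomeLayout({"c": 200})
        params = CallerParams(extsize=75)
        track = pileup([ReadAlignment("c", "-", 100, 130)], genome, params, "-")
        arr = track["c"]
        assert arr[55:130].tolist() == [1.0] * 75
        assert arr[:55].sum() == 0 and arr[130:].sum() == 0

    def test_clipping_at_bounds(self):
        genome = GenomeLayout({"c": 50})
        params = CallerParams(extsize=75)
        track = pileup([ReadAlignment("c", "+", 40, 45)], genome, params, "+")
        assert track["c"][40:].tolist() == [1.0] * 10


class TestLocalLambda:
    def test_flat_control(self):
        genome = GenomeLayout({"c": 1000})
        track = track_from(genome, "+", {"c": np.full(1000, 2.0)})
        lam = local_lambda(track, "c", 500, CallerParams(), global_mean=2.0)
        assert lam == pytest.approx(2.0)

    def test_spike_takes_max_window(self):
        genome = GenomeLayout({"c": 1000})
        arr = np.zeros(1000)
        arr[490:510] = 30.0  # 600 coverage units in both windows
        track = track_from(genome, "+", {"c": arr})
        params = CallerParams(lambda_windows=(75, 100))
        lam = local_lambda(track, "c", 500, params, global_mean=0.0)
        # 75bp window mean = 600/75 = 8; 100bp window mean = 6; max wins
        assert lam == pytest.approx(8.0)

    def test_empty_control_floors(self):
        genome = GenomeLayout({"c": 1000})
        track = track_from(genome, "+", {"c": np.zeros(1000)})
        lam = local_lambda(track, "c", 500, CallerParams(lambda_floor=0.1), global_mean=0.0)
        assert lam == pytest.approx(0.1)


def brute_force_call(ip_arr, ctrl_arr, n_ip, n_ctrl, params):
    """Independent per-bp Poisson + step-up BH oracle for one chromosome."""
    n = len(ip_arr)
    scale = n_ip / n_ctrl
    gmean = ctrl_arr.mean()
    pvals = []
    for i in range(n):
        lam = gmean
        for w in params.lambda_windows:
            lo, hi = max(0, i - w // 2), min(n, i + (w - w // 2))
            lam = max(lam, ctrl_arr[lo:hi].mean())
        lam = max(lam * scale, params.lambda_floor)
        k = int(round(ip_arr[i]))
        # upper tail P(X >= k) for X ~ Poisson(lam)
        pvals.append(1.0 - stats.poisson.cdf(k - 1, lam))
    # step-up BH by hand
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, pvals[i] * n / rank_from_top)
        q[i] = prev
    sig = [i for i in range(n) if q[i] <= params.fdr]
    # merge with gaps <= max_gap, drop short
    intervals = []
    for i in sig:
        if intervals and i - intervals[-1][1] <= params.max_gap:
            intervals[-1][1] = i + 1
        else:
            intervals.append([i, i + 1])
    return [(s, e) for s, e in intervals if e - s >= params.min_length]


class TestCallPeaks:
    def test_ip_identical_to_scaled_control_gives_no_peaks(self):
        genome = GenomeLayout({"c": 2000})
        rng = np.random.default_rng(0)
        reads = [
            ReadAlignment("c", "+", int(s), int(s) + 60)
            for s in rng.integers(0, 1900, size=300)
        ]
        peaks = call_peaks(reads, list(reads), genome, CallerParams())
        assert peaks == []

    def test_single_enriched_region_matches_oracle(self):
        genome = GenomeLayout({"c": 3000})
        params = CallerParams()
        rng = np.random.default_rng(1)
        ip = [ReadAlignment("c", "+", 1500 + int(rng.integers(-5, 6)), 1560) for _ in range(50)]
        ip += [ReadAlignment("c", "+", int(s), int(s) + 60) for s in rng.integers(0, 2900, size=450)]
        ctrl = [ReadAlignment("c", "+", int(s), int(s) + 60) for s in rng.integers(0, 2900, size=500)]
        peaks = call_peaks(ip, ctrl, genome, params, strands=("+",))
        ip_arr = pileup(ip, genome, params, "+")["c"]
        ctrl_arr = pileup(ctrl, genome, params, "+")["c"]
        expected = brute_force_call(ip_arr, ctrl_arr, len(ip), len(ctrl), params)
        assert [(p.start, p.end) for p in peaks] == expected
        assert len(peaks) >= 1
        assert any(p.start <= 1500 <= p.end for p in peaks)

    @pytest.mark.parametrize("gap,n_expected", [(15, 2), (8, 1)])
    def test_gap_merge_rule(self, gap, n_expected):
        genome = GenomeLayout({"c": 500})
        params = CallerParams(max_gap=10, min_length=10, lambda_floor=0.5)
        ip_arr = np.zeros(500)
        ip_arr[100:140] = 50.0
        ip_arr[140 + gap:180 + gap] = 50.0
        ip = track_from(genome, "+", {"c": ip_arr})
        ctrl = track_from(genome, "+", {"c": np.full(500, 0.5)})
        peaks = call_peaks_from_tracks(ip, ctrl, 500, 500, params)
        assert len(peaks) == n_expected

    def test_summit_is_leftmost_maximum(self):
        genome = GenomeLayout({"c": 500})
        params = CallerParams(lambda_floor=0.5)
        ip_arr = np.zeros(500)
        ip_arr[100:160] = 40.0  # flat top: leftmost max
        ip = track_from(genome, "+", {"c": ip_arr})
        ctrl = track_from(genome, "+", {"c": np.full(500, 0.5)})
        (peak,) = call_peaks_from_tracks(ip, ctrl, 500, 500, params)
        assert peak.summit == 100
        assert peak.summit_coverage == 40.0

    def test_read_order_invariance_and_determinism(self):
        genome = GenomeLayout({"c": 2000})
        rng = np.random.default_rng(3)
        ip = [ReadAlignment("c", "+", 900 + int(rng.integers(-8, 9)), 960) for _ in range(60)]
        ctrl = [ReadAlignment("c", "+", int(s), int(s) + 60) for s in rng.integers(0, 1900, size=200)]
        p1 = call_peaks(ip, ctrl, genome, strands=("+",))
        p2 = call_peaks(list(reversed(ip)), ctrl, genome, strands=("+",))
        assert p1 == p2

    def test_monotone_in_ip_coverage(self):
        """Scaling IP coverage up (same recorded depth) never removes a peak."""
        genome = GenomeLayout({"c": 1000})
        params = CallerParams(lambda_floor=0.5)
        rng = np.random.default_rng(4)
        base = rng.poisson(1.0, size=1000).astype(float)
        base[400:460] += 12
        ctrl = track_from(genome, "+", {"c": np.full(1000, 1.0)})
        peaks_lo = call_peaks_from_tracks(track_from(genome, "+", {"c": base}), ctrl, 100, 100, params)
        peaks_hi = call_peaks_from_tracks(track_from(genome, "+", {"c": base * 2}), ctrl, 100, 100, params)
        for p in peaks_lo:
            assert any(h.start <= p.start and h.end >= p.end for h in peaks_hi)

    def test_empty_library_is_error(self):
        genome = GenomeLayout({"c": 100})
        with pytest.raises(ValueError):
            call_peaks([], [ReadAlignment("c", "+", 0, 10)], genome)

    def test_read_count_counts_extended_overlaps(self):
        genome = GenomeLayout({"c": 1000})
        params = CallerParams(lambda_floor=0.2)
        ip = [ReadAlignment("c", "+", 500, 560)] * 30
        ctrl = [ReadAlignment("c", "+", int(s), int(s) + 60)
                for s in np.random.default_rng(5).integers(0, 900, size=50)]
        (peak,) = call_peaks(ip, ctrl, genome, params, strands=("+",))
        assert peak.read_count == 30.0


def test_raw_coverage_uses_alignment_span():
    genome = GenomeLayout({"c": 100})
    track = raw_coverage([ReadAlignment("c", "+", 10, 40)], genome, "+")
    assert track["c"][10:40].tolist() == [1.0] * 30
    assert track["c"].sum() == 30
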