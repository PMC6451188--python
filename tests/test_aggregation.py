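"""Aggregation profiles, replication-time averaging, KS utilities and the
deterministic classification rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svchrom.core import Interval, SignalTrack
from svchrom.aggregation import (
    classify_nonhomologous,
    classify_pseudogene_periodicity,
    element_boundary_anchors,
    element_boundary_profile,
    ks_cluster,
    ks_two_sample,
    mean_replication_time,
    peak_aggregation,
    regulatory_aggregation,
    signal_aggregation,
)


def brute_force_peak_profile(anchors, peaks, window, bin_size, chrom_len=None):
    """Per-base oracle: fraction of each bin's bases covered by any peak."""
    k = window // bin_size
    offsets = np.arange(-k, k) * bin_size
    total = np.zeros(offsets.size)
    for chrom, pos in anchors:
        for bi, off in enumerate(offsets):
            covered = 0
            for base in range(pos + off, pos + off + bin_size):
                if base < 0 or (chrom_len is not None and base >= chrom_len):
                    continue
                if any(p.chrom == chrom and p.start <= base < p.end for p in peaks):
                    covered += 1
            total[bi] += covered / bin_size
    return offsets, total / len(anchors)


class TestPeakAggregation:
    def test_no_peaks_all_zero(self):
        prof = peak_aggregation([("c", 1000)], [], window=500, bin_size=100)
        assert np.all(prof.values == 0)

    def test_peak_covering_whole_window_is_one(self):
        prof = peak_aggregation(
            [("c", 1000)], [Interval("c", 0, 5000)], window=500, bin_size=100
        )
        assert np.all(prof.values == 1.0)

    def test_empty_anchors_rejected(self):
        with pytest.raises(ValueError):
            peak_aggregation([], [Interval("c", 0, 10)])

    def test_chromosome_end_truncation_uses_full_bin_width(self):
        # anchor 50 bp before the end: right bins have only partial bases
        prof = peak_aggregation(
            [("c", 950)],
            [Interval("c", 0, 1000)],
            window=200,
            bin_size=100,
            chrom_lengths={"c": 1000},
        )
        vals = dict(zip(prof.offsets, prof.values))
        assert vals[-100] == 1.0
        assert vals[0] == 0.5  # 50 available covered bases over 100 bp bin
        assert vals[100] == 0.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chrom_len = 800
        peaks = [
            Interval("c", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 700, 8), rng.integers(5, 120, 8))
        ]
        anchors = [("c", int(p)) for p in rng.integers(0, chrom_len, 4)]
        prof = peak_aggregation(
            anchors, peaks, window=100, bin_size=20, chrom_lengths={"c": chrom_len}
        )
        _, oracle = brute_force_peak_profile(anchors, peaks, 100, 20, chrom_len)
        np.testing.assert_allclose(prof.values, oracle, atol=1e-12)

    def test_anchor_order_invariance(self):
        peaks = [Interval("c", 100, 400)]
        anchors = [("c", 150), ("c", 900), ("c", 300)]
        a = peak_aggregation(anchors, peaks, window=200, bin_size=50)
        b = peak_aggregation(anchors[::-1], peaks, window=200, bin_size=50)
        np.testing.assert_array_equal(a.values, b.values)


class TestRegulatoryAggregation:
    def test_midpoint_convention(self):
        # site 100-111 (odd length): midpoint = (100+111)//2 = 105
        site = Interval("c", 100, 111)
        prof = regulatory_aggregation([site], [site], window=20, bin_size=10)
        vals = dict(zip(prof.offsets, prof.values))
        assert vals[0] == 0.6  # bases 105-115: 105..110 covered
        assert vals[-10] == 0.5  # bases 95-105: 100..104 covered

    def test_identical_peaks_cover_center(self):
        sites = [Interval("c", 1000, 1200)]
        prof = regulatory_aggregation(sites, sites, window=100, bin_size=10)
        vals = dict(zip(prof.offsets, prof.values))
        assert vals[0] == 1.0 and vals[-10] == 1.0


class TestSignalAggregation:
    def test_constant_track_normalizes_to_one(self):
        track = SignalTrack({"c": np.full(1000, 7.3)}, step=10)
        prof = signal_aggregation([("c", 5000)], track, window=1000, bin_size=10)
        np.testing.assert_allclose(prof.values, 1.0)

    def test_anchors_at_sinusoid_troughs_dip_at_zero(self):
        x = np.arange(100_000)
        track = SignalTrack({"c": 1 + 0.8 * np.sin(2 * np.pi * x / 150)}, step=1)
        # troughs where sin = -1: x = 112.5 + 150k
        anchors = [("c", int(112 + 150 * k)) for k in range(50, 400)]
        prof = signal_aggregation(anchors, track, window=1000, bin_size=10)
        center = prof.value_at_zero()
        assert center < 0.7  # well below the flat-track value of 1

    def test_missing_bases_excluded_from_numerator_and_denominator(self):
        arr = np.full(300, np.nan)
        arr[100] = 5.0  # only bases 100..101 (step 1) carry data
        track = SignalTrack({"c": arr}, step=1)
        prof = signal_aggregation([("c", 100)], track, window=100, bin_size=10)
        vals = dict(zip(prof.offsets, prof.values))
        assert vals[0] == pytest.approx(1.0)  # only available base -> mean 5/norm 5
        assert np.isnan(vals[-100])

    def test_no_signal_anywhere_rejected(self):
        track = SignalTrack({"c": np.full(10, np.nan)}, step=10)
        with pytest.raises(ValueError):
            signal_aggregation([("c", 50)], track)


class TestBoundaryAnchoring:
    def test_one_element_two_anchors(self):
        starts, ends = element_boundary_anchors([Interval("c", 100, 400)])
        assert starts == [("c", 100)] and ends == [("c", 400)]

    def test_constant_track_interior_mean_is_one(self):
        track = SignalTrack({"c": np.full(2000, 3.0)}, step=10)
        bp = element_boundary_profile(
            [Interval("c", 5000, 8000)], track, window=1000, bin_size=10
        )
        assert bp.interior_mean == pytest.approx(1.0)
        assert np.all(bp.upstream.offsets < 0)
        assert np.all(bp.downstream.offsets >= 0)
        np.testing.assert_allclose(bp.upstream.values, 1.0)


class TestReplicationTime:
    def test_constant_track(self):
        track = SignalTrack({"c": np.full(100, 1.3)}, step=100)
        assert mean_replication_time(("c", 5000), track) == pytest.approx(1.3)

    def test_step_track_symmetry(self):
        arr = np.concatenate([np.full(50, -1.0), np.full(50, 1.0)])
        track = SignalTrack({"c": arr}, step=100)
        assert mean_replication_time(("c", 5000), track) == pytest.approx(0.0)

    def test_window_truncated_at_chromosome_start(self):
        arr = np.arange(10, dtype=float)  # value v over bases [100v, 100v+100)
        track = SignalTrack({"c": arr}, step=100)
        got = mean_replication_time(("c", 100), track)
        expected = np.mean([v // 100 for v in range(0, 600)])
        assert got == pytest.approx(expected)

    def test_no_data_returns_nan(self):
        track = SignalTrack({"c": np.full(10, np.nan)}, step=100)
        assert np.isnan(mean_replication_time(("c", 500), track))


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_matches_ecdf_supremum_oracle(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 1, 30)
        d, _ = ks_two_sample(x, y)
        grid = np.concatenate([x, y])
        ecdf_x = np.array([(x <= g).mean() for g in grid])
        ecdf_y = np.array([(y <= g).mean() for g in grid])
        assert d == pytest.approx(np.abs(ecdf_x - ecdf_y).max())

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_cluster_duplicate_merges_first(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 50)
        samples = {"m1": a, "m2": a.copy(), "m3": rng.normal(5, 1, 50)}
        res = ks_cluster(samples)
        assert res.merge_heights()[0] == 0.0
        assert abs(res.leaf_order.index("m1") - res.leaf_order.index("m2")) == 1

    def test_early_vs_late_clusters(self):
        rng = np.random.default_rng(4)
        early = {f"e{i}": rng.normal(1.5, 0.3, 80) for i in range(2)}
        late = {f"l{i}": rng.normal(-1.5, 0.3, 80) for i in range(2)}
        res = ks_cluster({**early, **late})
        order = res.leaf_order
        e_pos = sorted(order.index(k) for k in early)
        l_pos = sorted(order.index(k) for k in late)
        assert max(e_pos) < min(l_pos) or max(l_pos) < min(e_pos)

    def test_single_mechanism_rejected(self):
        with pytest.raises(ValueError):
            ks_cluster({"only": [1.0, 2.0]})


class TestClassificationRules:
    @pytest.mark.parametrize(
        "mh,mi,expected",
        [(5, 0, "NHrepl"), (0, 11, "NHrepl"), (0, 0, "NHEJ"),
         (2, 5, "ambiguous"), (1, 0, "ambiguous"), (2, 10, "ambiguous"),
         (3, 0, "NHrepl")],
    )
    def test_junction_signatures(self, mh, mi, expected):
        assert classify_nonhomologous(mh, mi) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            classify_nonhomologous(-1, 0)

    @pytest.mark.parametrize(
        "length,expected",
        [(300, "close"), (375, "away"), (410, "close"), (350, "close"),
         (351, "away"), (200, "close"), (225, "away")],
    )
    def test_pseudogene_periodicity(self, length, expected):
        assert classify_pseudogene_periodicity(length) == expected
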