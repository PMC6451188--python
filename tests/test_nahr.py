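"""Homology search, rejection sampling and compartment matching."""

import numpy as np
import pytest
from scipy import stats

from svchrom.core import GenomeLayout, Interval, SegmentationTrack, SVRecord
from svchrom.nahr import (
    HomologousPair,
    KmerIndex,
    _largest_remainder,
    find_homologous_target,
    length_pdf_from_svs,
    length_rejection_sample,
    match_compartment_proportions,
    repeat_enrichment,
    sample_seed_loci,
)


class ArraySource:
    """Minimal in-memory sequence source for planted-homology tests."""

    def __init__(self, sequences: dict[str, np.ndarray]):
        self._seq = {c: np.asarray(v, dtype=np.uint8) for c, v in sequences.items()}
        self.layout = GenomeLayout(tuple((c, len(v)) for c, v in self._seq.items()))

    def codes(self, chrom):
        return self._seq[chrom]


def planted_source(length=3_000_000, plants=(), seed=0):
    """Random genome with (pos_origin, pos_target, repeat_len, identity, inverted)."""
    rng = np.random.default_rng(seed)
    seq = rng.integers(0, 4, size=length).astype(np.uint8)
    for origin, target, rep_len, identity, inverted in plants:
        copy = seq[origin : origin + rep_len].copy()
        mut = rng.random(rep_len) < (1 - identity)
        copy[mut] = (copy[mut] + rng.integers(1, 4, size=rep_len)[mut]) % 4
        if inverted:
            copy = (3 - copy)[::-1]  # reverse complement
        seq[target : target + rep_len] = copy
    return ArraySource({"chr1": seq})


class TestSeedSampling:
    def test_avoids_assembly_gaps(self):
        seq = np.zeros(5000, dtype=np.uint8)
        seq[1000:3000] = 4  # N run
        src = ArraySource({"chr1": seq})
        loci = sample_seed_loci(src, 50, seed=1)
        for iv in loci:
            assert not np.any(src.codes("chr1")[iv.start : iv.end] == 4)

    def test_deterministic(self):
        src = planted_source(length=10_000)
        assert sample_seed_loci(src, 10, seed=3) == sample_seed_loci(src, 10, seed=3)

    def test_genome_too_short(self):
        with pytest.raises(ValueError):
            sample_seed_loci(ArraySource({"chr1": np.zeros(50, dtype=np.uint8)}), 1)


class TestHomologySearch:
    def test_identical_planted_pair_found(self):
        src = planted_source(plants=[(50_000, 60_000, 300, 1.0, False)])
        idx = KmerIndex(src)
        seed_iv = Interval("chr1", 50_000, 50_100)
        pair = find_homologous_target(seed_iv, src, idx, seed=0)
        assert pair is not None
        assert pair.identity == 1.0
        assert pair.target.start >= 60_000 and pair.target.end <= 60_300 + 100
        assert pair.separation == 10_000

    def test_pair_beyond_one_megabase_rejected(self):
        src = planted_source(plants=[(100_000, 2_100_000, 300, 1.0, False)])
        idx = KmerIndex(src)
        assert find_homologous_target(Interval("chr1", 100_000, 100_100), src, idx) is None

    def test_inverted_copy_rejected(self):
        src = planted_source(plants=[(100_000, 150_000, 300, 1.0, True)])
        idx = KmerIndex(src)
        assert find_homologous_target(Interval("chr1", 100_000, 100_100), src, idx) is None

    def test_low_identity_rejected(self):
        src = planted_source(plants=[(100_000, 150_000, 300, 0.70, False)])
        idx = KmerIndex(src)
        pair = find_homologous_target(Interval("chr1", 100_000, 100_100), src, idx)
        assert pair is None or pair.identity > 0.85  # never a below-threshold pair

    def test_short_homology_rejected(self):
        src = planted_source(plants=[(100_000, 150_000, 45, 1.0, False)])
        idx = KmerIndex(src)
        assert find_homologous_target(Interval("chr1", 100_000, 100_100), src, idx) is None

    def test_recovery_rate_of_threshold_passing_pairs(self):
        # only homology in the genome: planted pairs passing all thresholds
        plants = [
            (i * 120_000, i * 120_000 + 30_000 + 997 * i, 300, 0.95, False)
            for i in range(1, 21)
        ]
        src = planted_source(plants=plants, seed=4)
        idx = KmerIndex(src)
        found = 0
        for origin, target, rep_len, _, _ in plants:
            pair = find_homologous_target(
                Interval("chr1", origin, origin + 100), src, idx, seed=0
            )
            if pair is not None and abs(pair.target.start - target) < 400:
                found += 1
        assert found >= 19  # >= 95% of 20

    def test_all_emitted_pairs_satisfy_thresholds(self, default_world):
        from svchrom.nahr import simulate_homologous_breakpoints

        idx = KmerIndex(default_world)
        pairs = simulate_homologous_breakpoints(default_world, 500, seed=9, index=idx)
        for p in pairs:
            assert p.orientation == "same"
            assert p.alignment_length > 50
            assert p.identity > 0.85
            assert 100 <= p.separation <= 1_000_000


def _pair(chrom, a, b):
    return HomologousPair(
        Interval(chrom, a, a + 100), Interval(chrom, b, b + 100), "same", 90, 0.95, abs(b - a)
    )


class TestLengthRejection:
    def test_uniform_density_accepts_uniformly(self):
        svs = [SVRecord(Interval("c", 0, l), "NAHR") for l in (1000, 2000, 4000, 8000)]
        pdf = length_pdf_from_svs(svs, n_bins=1)  # single bin: flat density
        pairs = [_pair("c", 0, 1000 + 300 * i) for i in range(20)]
        assert length_rejection_sample(pairs, pdf, seed=0) == pairs

    def test_zero_density_always_rejected(self):
        svs = [SVRecord(Interval("c", 0, l), "NAHR") for l in range(1000, 1100, 10)]
        pdf = length_pdf_from_svs(svs)
        pairs = [_pair("c", 0, 900_000)]  # far outside observed lengths
        assert length_rejection_sample(pairs, pdf, seed=0) == []

    def test_accepted_lengths_match_target_distribution(self):
        rng = np.random.default_rng(5)
        target_lengths = rng.normal(5000, 400, 2000).clip(3000, 7000).astype(int)
        svs = [SVRecord(Interval("c", 0, int(l)), "NAHR") for l in target_lengths]
        pdf = length_pdf_from_svs(svs)
        pairs = [_pair("c", 0, int(l)) for l in rng.integers(3000, 7000, 6000)]
        kept = length_rejection_sample(pairs, pdf, seed=6)
        assert len(kept) > 200
        _, p = stats.ks_2samp([k.implied_length for k in kept], target_lengths)
        assert p > 0.01


class TestCompartmentMatching:
    def _track(self):
        return SegmentationTrack(
            [(Interval("c", 0, 100_000), "A1"), (Interval("c", 100_000, 200_000), "B3")],
            label_set=("A1", "B3"),
        )

    def test_exact_proportions_without_rounding(self):
        track = self._track()
        real = [SVRecord(Interval("c", 10, 500), "NAHR"),
                SVRecord(Interval("c", 150_000, 150_500), "NAHR")]
        pairs = [_pair("c", 1000 * i, 1000 * i + 500) for i in range(1, 80)] + [
            _pair("c", 100_000 + 700 * i, 100_000 + 700 * i + 500) for i in range(1, 80)
        ]
        out = match_compartment_proportions(pairs, real, track, seed=0, size=100)
        labels = [track.assign(p.origin.chrom, p.origin.start) for p in out]
        assert labels.count("A1") == 50 and labels.count("B3") == 50

    def test_largest_remainder_rounding(self):
        alloc = _largest_remainder(np.array([0.334, 0.333, 0.333]), 100)
        assert alloc.sum() == 100
        assert list(alloc) == [34, 33, 33]

    def test_empty_pool_with_nonzero_proportion_errors(self):
        track = self._track()
        real = [SVRecord(Interval("c", 10, 500), "NAHR")]  # all breakpoints in A1
        pairs = [_pair("c", 150_000, 150_500)]  # pool only in B3
        with pytest.raises(ValueError, match="A1"):
            match_compartment_proportions(pairs, real, track, seed=0, size=1)


class TestRepeatEnrichment:
    def test_all_breakpoints_in_repeats_covering_ten_percent(self):
        layout = GenomeLayout((("c", 1_000_000),))
        repeats = [Interval("c", 0, 100_000)]
        pairs = [_pair("c", 1000 * i, 1000 * i + 500) for i in range(1, 50)]
        fold, p = repeat_enrichment(pairs, repeats, layout)
        assert fold == pytest.approx(10.0)
        assert p < 1e-4

    def test_uniform_breakpoints_fold_near_one(self):
        layout = GenomeLayout((("c", 1_000_000),))
        rng = np.random.default_rng(0)
        repeats = [Interval("c", int(s), int(s) + 500) for s in range(0, 999_000, 2000)]
        pairs = [_pair("c", int(a), int(a) + 150) for a in rng.integers(0, 998_000, 500)]
        fold, _ = repeat_enrichment(pairs, repeats, layout)
        assert 0.8 < fold < 1.2

    def test_zero_repeat_coverage_rejected(self):
        layout = GenomeLayout((("c", 1000),))
        with pytest.raises(ValueError):
            repeat_enrichment([_pair("c", 0, 200)], [], layout)
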