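"""Simulated NAHR breakpoints: homology search, length rejection sampling,
and compartment-proportion matching.

A simulated NAHR event is a pair of homologous loci that could recombine:
a randomly sampled 100 bp seed plus a nearby homologous target found by an
exact-12-mer-seeded ungapped extension search.  Retained pairs must be in
the same orientation, have an alignment longer than 50 bp at >85% identity,
and lie within 1 Mb (but at least 100 bp) of each other.  The pair set is
then thinned so its implied deletion lengths follow the empirical length
distribution of real NAHR deletions ("simulated homologous breakpoints" ->
length-matched), and finally subsampled so breakpoint compartment
proportions match the real set ("advanced simulated NAHR").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy import stats

from .core import GenomeLayout, Interval, SegmentationTrack, SVRecord, UNASSIGNED

__all__ = [
    "SequenceSource",
    "HomologousPair",
    "LengthPDF",
    "KmerIndex",
    "sample_seed_loci",
    "find_homologous_target",
    "simulate_homologous_breakpoints",
    "length_pdf_from_svs",
    "length_rejection_sample",
    "match_compartment_proportions",
    "repeat_enrichment",
]

SEED_LENGTH = 100
KMER = 12
MIN_ALIGNMENT = 50  # alignment length must exceed this
MIN_IDENTITY = 0.85  # identity must exceed this
MIN_SEPARATION = 100
MAX_SEPARATION = 1_000_000

# base codes: A=0 C=1 G=2 T=3, N (assembly gap) = 4
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_BASES = np.array(list("ACGTN"))


class SequenceSource(Protocol):
    """Anything that can hand out per-chromosome 2-bit base codes."""

    @property
    def layout(self) -> GenomeLayout: ...

    def codes(self, chrom: str) -> np.ndarray: ...


@dataclass(frozen=True)
class HomologousPair:
    """Two homologous loci treated as the breakpoints of a simulated NAHR.

    ``separation`` is measured origin-start to target-start, which is also
    the implied length of the simulated deletion.
    """

    origin: Interval
    target: Interval
    orientation: str
    alignment_length: int
    identity: float
    separation: int

    @property
    def implied_length(self) -> int:
        return self.separation

    @property
    def breakpoints(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.origin.chrom, self.origin.start), (self.target.chrom, self.target.start))


class KmerIndex:
    """Sorted index of all exact 12-mers of a genome (linear coordinates)."""

    def __init__(self, source: SequenceSource, k: int = KMER):
        self.k = k
        self.layout = source.layout
        offs = self.layout.offsets
        all_kmers, all_pos = [], []
        for chrom, length in self.layout.chromosomes:
            c = source.codes(chrom)
            if c.size < k:
                continue
            km, valid = _kmer_codes(c, k)
            pos = np.flatnonzero(valid) + offs[chrom]
            all_kmers.append(km[valid])
            all_pos.append(pos)
        kmers = np.concatenate(all_kmers) if all_kmers else np.empty(0, dtype=np.int64)
        pos = np.concatenate(all_pos) if all_pos else np.empty(0, dtype=np.int64)
        order = np.argsort(kmers, kind="stable")
        self._kmers = kmers[order]
        self._pos = pos[order]

    def query(self, kmer_code: int) -> np.ndarray:
        """Linear genome positions whose 12-mer equals ``kmer_code``."""
        lo = np.searchsorted(self._kmers, kmer_code, side="left")
        hi = np.searchsorted(self._kmers, kmer_code, side="right")
        return self._pos[lo:hi]


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mer integer codes and a validity mask (no N in window)."""
    n = codes.size - k + 1
    val = np.zeros(n, dtype=np.int64)
    has_n = np.zeros(n, dtype=bool)
    for t in range(k):
        window = codes[t : t + n]
        val = val * 4 + np.minimum(window, 3)
        has_n |= window == 4
    return val, ~has_n


def sample_seed_loci(
    source: SequenceSource, n: int, seed: int = 0
) -> list[Interval]:
    """Uniform random 100 bp loci avoiding assembly gaps (N runs)."""
    if n < 1:
        raise ValueError("need n >= 1 seed loci")
    layout = source.layout
    if all(l < SEED_LENGTH for _, l in layout.chromosomes):
        raise ValueError("no chromosome long enough for a 100 bp seed")
    rng = np.random.default_rng(seed)
    total = layout.total_length
    out = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            raise RuntimeError("could not place seed loci outside assembly gaps")
        lin = int(rng.integers(0, total))
        chrom, pos = layout.from_linear(lin)
        if pos + SEED_LENGTH > layout.chrom_length(chrom):
            continue
        window = source.codes(chrom)[pos : pos + SEED_LENGTH]
        if np.any(window == 4):
            continue
        out.append(Interval(chrom, pos, pos + SEED_LENGTH))
    return out


def _best_diagonal_alignment(
    seed: np.ndarray, target: np.ndarray
) -> tuple[int, int, float]:
    """Best-scoring ungapped local alignment of two equal-length windows.

    Kadane-style scan with match +1 / mismatch -1; returns (start, length,
    identity) of the best segment.
    """
    n = min(seed.size, target.size)
    match = (seed[:n] == target[:n]) & (seed[:n] != 4) & (target[:n] != 4)
    score = np.where(match, 1, -1)
    best = (0, 0)  # (start, end)
    best_score = -1
    cur_start, cur = 0, 0
    for i, s in enumerate(score):
        cur += s
        if cur <= 0:
            cur, cur_start = 0, i + 1
            continue
        if cur > best_score:
            best_score = cur
            best = (cur_start, i + 1)
    a, b = best
    length = b - a
    if length == 0:
        return 0, 0, 0.0
    identity = float(match[a:b].sum() / length)
    return a, length, identity


def find_homologous_target(
    seed_locus: Interval,
    source: SequenceSource,
    index: KmerIndex,
    seed: int | np.random.Generator = 0,
) -> HomologousPair | None:
    """Find a same-orientation homologous partner for a 100 bp seed locus.

    Candidate diagonals come from shared exact 12-mers; each is scored by
    ungapped extension over the 100 bp window.  Survivors must exceed 50 bp
    alignment length and 85% identity and lie 100 bp - 1 Mb from the seed
    (start to start); the trivial self-alignment is excluded.  One survivor
    is chosen uniformly at random; ``None`` when there is none.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    layout = source.layout
    chrom = seed_locus.chrom
    chrom_off = layout.offsets[chrom]
    chrom_len = layout.chrom_length(chrom)
    seed_codes = source.codes(chrom)[seed_locus.start : seed_locus.end]
    s_lin = chrom_off + seed_locus.start

    diagonals: set[int] = set()
    kms, valid = _kmer_codes(seed_codes, index.k)
    for t in np.flatnonzero(valid):
        for hit in index.query(int(kms[t])):
            diagonals.add(int(hit) - int(t))
    candidates = []
    for diag in sorted(diagonals):
        sep = abs(diag - s_lin)
        if sep < MIN_SEPARATION or sep > MAX_SEPARATION:
            continue
        t_pos = diag - chrom_off
        if t_pos < 0 or t_pos + SEED_LENGTH > chrom_len:
            continue  # same-chromosome targets only
        target_codes = source.codes(chrom)[t_pos : t_pos + SEED_LENGTH]
        a, length, identity = _best_diagonal_alignment(seed_codes, target_codes)
        if length > MIN_ALIGNMENT and identity > MIN_IDENTITY:
            candidates.append(
                HomologousPair(
                    origin=seed_locus,
                    target=Interval(chrom, t_pos + a, t_pos + a + length),
                    orientation="same",
                    alignment_length=length,
                    identity=identity,
                    separation=sep,
                )
            )
    if not candidates:
        return None
    return candidates[int(rng.integers(0, len(candidates)))]


def simulate_homologous_breakpoints(
    source: SequenceSource,
    n_seeds: int,
    seed: int = 0,
    index: KmerIndex | None = None,
) -> list[HomologousPair]:
    """Sample seeds and search each for a homologous partner."""
    if index is None:
        index = KmerIndex(source)
    rng = np.random.default_rng(seed)
    loci = sample_seed_loci(source, n_seeds, seed=int(rng.integers(0, 2**31)))
    pairs = []
    for locus in loci:
        pair = find_homologous_target(locus, source, index, seed=rng)
        if pair is not None:
            pairs.append(pair)
    return pairs


@dataclass
class LengthPDF:
    """Binned empirical density of NAHR deletion lengths (log-spaced bins)."""

    bin_edges: np.ndarray
    density: np.ndarray  # per-bin density; integrates to 1 over bins
    max_density: float

    def __post_init__(self):
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    def density_at(self, length: float) -> float:
        if length < self.bin_edges[0] or length >= self.bin_edges[-1]:
            return 0.0
        i = int(np.searchsorted(self.bin_edges, length, side="right")) - 1
        return float(self.density[i])


def length_pdf_from_svs(svs: Sequence[SVRecord], n_bins: int = 25) -> LengthPDF:
    """Empirical length density of real NAHR deletions on log-spaced bins."""
    lengths = np.array([sv.interval.length for sv in svs], dtype=float)
    if lengths.size == 0:
        raise ValueError("no SVs to build a length distribution from")
    lo, hi = lengths.min(), lengths.max()
    if lo == hi:
        hi = lo * 1.001 + 1
    edges = np.geomspace(lo, hi + 1e-9, n_bins + 1)
    density, edges = np.histogram(lengths, bins=edges, density=True)
    return LengthPDF(edges, density, float(density.max()))


def length_rejection_sample(
    pairs: Sequence[HomologousPair], pdf: LengthPDF, seed: int = 0
) -> list[HomologousPair]:
    """Accept each pair with probability density(length) / max_density."""
    if pdf.max_density <= 0:
        raise ValueError("degenerate length distribution")
    rng = np.random.default_rng(seed)
    out = []
    for pair in pairs:
        u = rng.random()
        if u <= pdf.density_at(pair.implied_length) / pdf.max_density:
            out.append(pair)
    return out


def _largest_remainder(proportions: np.ndarray, size: int) -> np.ndarray:
    """Integer allocation of ``size`` by largest-remainder rounding."""
    raw = proportions * size
    alloc = np.floor(raw).astype(int)
    short = size - alloc.sum()
    if short > 0:
        order = np.argsort(-(raw - alloc), kind="stable")
        alloc[order[:short]] += 1
    return alloc


def match_compartment_proportions(
    pairs: Sequence[HomologousPair],
    real_nahr: Sequence[SVRecord],
    track: SegmentationTrack,
    seed: int = 0,
    size: int | None = None,
) -> list[HomologousPair]:
    """Subsample pairs so compartment proportions match real NAHR breakpoints.

    Each simulated event is classified by the compartment of its origin
    breakpoint; target proportions are those of real NAHR breakpoints (both
    ends, unassigned excluded and renormalized).  Counts per compartment
    follow largest-remainder rounding of proportion x size; selection is
    uniform without replacement within each compartment.
    """
    labels = [l for l in track.labels if l != UNASSIGNED]
    real_counts = np.zeros(len(labels))
    for sv in real_nahr:
        for chrom, pos in sv.breakpoints:
            lab = track.assign(chrom, pos)
            if lab in labels:
                real_counts[labels.index(lab)] += 1
    if real_counts.sum() == 0:
        raise ValueError("no real NAHR breakpoint falls in any compartment")
    proportions = real_counts / real_counts.sum()

    pools: dict[str, list[HomologousPair]] = {l: [] for l in labels}
    for pair in pairs:
        lab = track.assign(pair.origin.chrom, pair.origin.start)
        if lab in pools:
            pools[lab].append(pair)

    if size is None:
        feasible = [
            int(len(pools[l]) / p) for l, p in zip(labels, proportions) if p > 0
        ]
        size = min(feasible) if feasible else 0
    alloc = _largest_remainder(proportions, size)
    deficits = {
        l: int(a - len(pools[l]))
        for l, a in zip(labels, alloc)
        if a > len(pools[l])
    }
    if deficits:
        raise ValueError(
            f"compartment pools too small for requested proportions: {deficits}"
        )
    rng = np.random.default_rng(seed)
    out: list[HomologousPair] = []
    for l, a in zip(labels, alloc):
        if a == 0:
            continue
        chosen = rng.choice(len(pools[l]), size=a, replace=False)
        out.extend(pools[l][i] for i in chosen)
    return out


def repeat_enrichment(
    pairs: Sequence[HomologousPair],
    repeats: Sequence[Interval],
    layout: GenomeLayout,
) -> tuple[float, float]:
    """Fold enrichment of simulated breakpoints in repeats vs uniform.

    fold = (fraction of breakpoints inside repeats) / (fraction of the
    genome covered by repeats); p from a chi-square test of the observed
    in/out counts against the uniform expectation.
    """
    merged: dict[str, list[list[int]]] = {}
    for r in sorted(repeats, key=lambda r: (r.chrom, r.start)):
        rows = merged.setdefault(r.chrom, [])
        if rows and r.start <= rows[-1][1]:
            rows[-1][1] = max(rows[-1][1], r.end)
        else:
            rows.append([r.start, r.end])
    covered = sum(e - s for rows in merged.values() for s, e in rows)
    if covered == 0:
        raise ValueError("repeats cover zero bases")
    genome_frac = covered / layout.total_length

    points = [bp for pair in pairs for bp in pair.breakpoints]
    n_in = 0
    for chrom, pos in points:
        rows = merged.get(chrom, [])
        starts = [s for s, _ in rows]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < rows[i][1]:
            n_in += 1
    n = len(points)
    if n == 0:
        raise ValueError("no breakpoints supplied")
    fold = (n_in / n) / genome_frac
    expected = np.array([n * genome_frac, n * (1 - genome_frac)])
    observed = np.array([n_in, n - n_in])
    chi2, p = stats.chisquare(observed, f_exp=expected)
    return float(fold), float(p)
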