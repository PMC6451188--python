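"""Aggregated peak-fraction and signal profiles around anchor point sets.

Profiles answer "how much DNase / DSB peak / nucleosome signal sits at a
given offset from a class of breakpoints, on average".  Bins are half-open:
bin k covers ``[pos + k*bin, pos + (k+1)*bin)``, so offset 0 labels the
first bin to the right of the anchor and there is no bin centered on it.

Also houses the replication-time averaging with KS-based clustering and two
small deterministic classifiers (NHEJ/NHrepl junction signatures and
pseudogene nucleosome periodicity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import Interval, SignalTrack
from .enrichment import ClusterResult

__all__ = [
    "AggregationProfile",
    "peak_aggregation",
    "regulatory_aggregation",
    "signal_aggregation",
    "element_boundary_anchors",
    "element_boundary_profile",
    "BoundaryProfile",
    "mean_replication_time",
    "ks_two_sample",
    "ks_cluster",
    "classify_nonhomologous",
    "classify_pseudogene_periodicity",
]


@dataclass
class AggregationProfile:
    """Offset-binned normalized values around a set of anchors."""

    offsets: np.ndarray  # bin start offsets in bp (symmetric about 0)
    values: np.ndarray
    n_anchors: int
    mode: str  # "peak-fraction" or "signal"
    bin_size: int

    def value_at_zero(self) -> float:
        """Mean of the two bins flanking offset 0."""
        idx = np.flatnonzero(np.isin(self.offsets, [-self.bin_size, 0]))
        if idx.size == 0:
            raise ValueError("profile has no bins adjacent to offset 0")
        return float(np.nanmean(self.values[idx]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"offset": self.offsets, "value": self.values, "n_anchors": self.n_anchors}
        )


class _Coverage:
    """Per-chromosome merged-peak coverage with prefix sums.

    F(x) = number of peak-covered bases in [0, x), so covered bases in
    [a, b) = F(b) - F(a).
    """

    def __init__(self, peaks: Sequence[Interval]):
        self._by: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by: dict[str, list[tuple[int, int]]] = {}
        for p in peaks:
            by.setdefault(p.chrom, []).append((p.start, p.end))
        for chrom, ivs in by.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            s = np.array([m[0] for m in merged], dtype=np.int64)
            e = np.array([m[1] for m in merged], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(e - s)])
            self._by[chrom] = (s, e, cum)

    def covered(self, chrom: str, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        entry = self._by.get(chrom)
        if entry is None:
            return np.zeros(np.asarray(a).shape, dtype=np.int64)
        return self._F(entry, b) - self._F(entry, a)

    @staticmethod
    def _F(entry, x: np.ndarray) -> np.ndarray:
        s, e, cum = entry
        x = np.asarray(x, dtype=np.int64)
        i = np.searchsorted(s, x, side="right")
        im1 = np.clip(i - 1, 0, None)
        partial = np.clip(x - s[im1], 0, (e - s)[im1])
        return cum[im1] * (i > 0) + np.where(i > 0, partial, 0)


def _bin_grid(window: int, bin_size: int) -> np.ndarray:
    if window % bin_size:
        raise ValueError("window must be a multiple of bin size")
    k = window // bin_size
    return np.arange(-k, k) * bin_size


def peak_aggregation(
    anchors: Sequence[tuple[str, int]],
    peaks: Sequence[Interval],
    window: int = 2500,
    bin_size: int = 100,
    chrom_lengths: Mapping[str, int] | None = None,
) -> AggregationProfile:
    """Fraction of bases covered by peaks, per offset bin, averaged over anchors.

    Bins truncated by a chromosome end contribute their available covered
    bases over the full bin width (``chrom_lengths`` bounds the right edge).
    """
    if len(anchors) == 0:
        raise ValueError("no anchors supplied")
    offsets = _bin_grid(window, bin_size)
    cov = _Coverage(peaks)
    total = np.zeros(offsets.size)
    by: dict[str, list[int]] = {}
    for chrom, pos in anchors:
        by.setdefault(chrom, []).append(pos)
    for chrom, positions in by.items():
        pos = np.asarray(positions, dtype=np.int64)[:, None]
        lo = pos + offsets[None, :]
        hi = lo + bin_size
        lo = np.clip(lo, 0, None)
        if chrom_lengths is not None and chrom in chrom_lengths:
            hi = np.clip(hi, None, chrom_lengths[chrom])
        hi = np.maximum(hi, lo)
        covered = cov.covered(chrom, lo, hi)
        total += covered.sum(axis=0) / bin_size
    return AggregationProfile(
        offsets, total / len(anchors), len(anchors), "peak-fraction", bin_size
    )


def regulatory_aggregation(
    sites: Sequence[Interval],
    peaks: Sequence[Interval],
    window: int = 2500,
    bin_size: int = 10,
    chrom_lengths: Mapping[str, int] | None = None,
) -> AggregationProfile:
    """Peak aggregation anchored at regulatory-site midpoints (10 bp bins)."""
    anchors = [(s.chrom, s.midpoint) for s in sites]
    return peak_aggregation(anchors, peaks, window, bin_size, chrom_lengths)


def signal_aggregation(
    anchors: Sequence[tuple[str, int]],
    track: SignalTrack,
    window: int = 1000,
    bin_size: int = 10,
    norm_window: int = 2000,
    sides: str = "both",
) -> AggregationProfile:
    """Mean signal per offset bin, normalized so a flat track reads 1.0.

    Per bin and anchor, the raw signal over available bases is averaged;
    bins are aggregated over anchors and divided by the number of anchors
    with any available signal; the profile is finally divided by its mean
    over the ``norm_window`` region around the anchor.

    ``sides`` restricts aggregation to "left" (negative offsets) or
    "right" (positive offsets) for element-boundary anchoring.
    """
    if len(anchors) == 0:
        raise ValueError("no anchors supplied")
    offsets = _bin_grid(window, bin_size)
    if sides == "left":
        offsets = offsets[offsets < 0]
    elif sides == "right":
        offsets = offsets[offsets >= 0]
    elif sides != "both":
        raise ValueError(f"unknown sides {sides!r}")
    sums = np.zeros(offsets.size)
    counts = np.zeros(offsets.size, dtype=np.int64)
    n_with_signal = 0
    for chrom, pos in anchors:
        vals = track.base_values(chrom, pos + int(offsets[0]), pos + int(offsets[-1]) + bin_size)
        vals = vals.reshape(offsets.size, bin_size)
        ok = ~np.isnan(vals)
        if not ok.any():
            continue
        n_with_signal += 1
        n_avail = ok.sum(axis=1)
        bin_mean = np.where(
            n_avail > 0, np.nansum(vals, axis=1) / np.maximum(n_avail, 1), 0.0
        )
        sums += bin_mean
        counts += n_avail > 0
    if n_with_signal == 0:
        raise ValueError("no anchor has any available signal")
    values = sums / n_with_signal
    in_norm = (offsets >= -norm_window // 2) & (offsets < norm_window // 2)
    norm = values[in_norm & (counts > 0)].mean() if np.any(in_norm & (counts > 0)) else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        values = values / norm
    values[counts == 0] = np.nan
    return AggregationProfile(offsets, values, len(anchors), "signal", bin_size)


def element_boundary_anchors(
    elements: Sequence[Interval],
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Anchor sets at element starts and ends.

    Start anchors aggregate only upstream (negative offsets); end anchors
    only downstream, avoiding the length-conservation bias of
    retrotransposed elements.
    """
    starts = [(e.chrom, e.start) for e in elements]
    ends = [(e.chrom, e.end) for e in elements]
    return starts, ends


@dataclass
class BoundaryProfile:
    """Flank profiles around element boundaries plus the interior mean."""

    upstream: AggregationProfile  # negative offsets from element starts
    downstream: AggregationProfile  # positive offsets from element ends
    interior_mean: float


def element_boundary_profile(
    elements: Sequence[Interval],
    track: SignalTrack,
    window: int = 1000,
    bin_size: int = 10,
    norm_window: int = 2000,
) -> BoundaryProfile:
    starts, ends = element_boundary_anchors(elements)
    up = signal_aggregation(starts, track, window, bin_size, norm_window, sides="left")
    down = signal_aggregation(ends, track, window, bin_size, norm_window, sides="right")
    # interior mean on the same normalization scale as the flanks
    interior_vals = [track.window_mean(e.chrom, e.start, e.end) for e in elements]
    interior_vals = [v for v in interior_vals if not np.isnan(v)]
    raw_flank = np.nanmean(
        [
            track.window_mean(c, p - window, p + window)
            for c, p in starts + ends
        ]
    )
    interior = float(np.mean(interior_vals) / raw_flank) if interior_vals else float("nan")
    return BoundaryProfile(up, down, interior)


def mean_replication_time(
    point: tuple[str, int], rt: SignalTrack, flank: int = 500
) -> float:
    """Mean replication time over the 1000 bases around a breakpoint.

    Averages available bases in [pos - flank, pos + flank); NaN when the
    window holds no data.
    """
    chrom, pos = point
    return rt.window_mean(chrom, pos - flank, pos + flank)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def ks_cluster(samples: Mapping[str, Sequence[float]]) -> ClusterResult:
    """Cluster mechanisms by pairwise KS D on their replication-time samples."""
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least two mechanisms")
    n = len(names)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = ks_two_sample(samples[names[i]], samples[names[j]])
            dmat[i, j] = dmat[j, i] = d
    link = hierarchy.linkage(squareform(dmat), method="average")
    order = hierarchy.leaves_list(link)
    return ClusterResult([names[i] for i in order], link, names)


def classify_nonhomologous(
    micro_homology_bp: int, micro_insertion_bp: int
) -> str:
    """Junction-signature classification of non-homologous deletions.

    Micro-homology >2 bp or micro-insertion >10 bp indicates replication
    errors (NHrepl); absence of both indicates NHEJ; anything in between is
    ambiguous and excluded from downstream analyses.
    """
    if micro_homology_bp < 0 or micro_insertion_bp < 0:
        raise ValueError("micro-homology/insertion must be non-negative")
    if micro_homology_bp > 2 or micro_insertion_bp > 10:
        return "NHrepl"
    if micro_homology_bp == 0 and micro_insertion_bp == 0:
        return "NHEJ"
    return "ambiguous"


def classify_pseudogene_periodicity(length_bp: int) -> str:
    """Is a processed pseudogene's length close to nucleosome periodicity?

    With a ~150 bp nucleosome repeat, a length whose remainder mod 150
    falls in [0, 50] or [100, 150) is "close" to a whole number of periods,
    otherwise "away" (leaving excess linker-scale sequence exposed).
    """
    if length_bp <= 0:
        raise ValueError("length must be positive")
    r = length_bp % 150
    return "close" if (r <= 50 or r >= 100) else "away"
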