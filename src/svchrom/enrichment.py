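"""Circular-permutation null model and Z-score enrichment of SV classes.

The null model treats the genome as a circle of sequentially arranged
chromosomes.  One shared random offset per replicate shifts every SV along
that circle, preserving SV count, lengths and the inter-SV spacing
structure; 1000 replicates give the background mean and standard deviation
from which per-category Z scores are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .core import (
    UNASSIGNED,
    GenomeLayout,
    Interval,
    SegmentationTrack,
    SVRecord,
)

__all__ = [
    "PermutedSV",
    "circular_permute",
    "background_ensemble",
    "category_fractions",
    "enrichment_zscores",
    "encompassing_zscores",
    "zscore_cluster",
    "ClusterResult",
]

DEFAULT_N_PERMUTATIONS = 1000


@dataclass(frozen=True)
class PermutedSV:
    """An SV after circular shifting, mapped back to (chrom, pos) space.

    An SV that wraps across a chromosome junction (or the genome end) keeps
    its two breakpoints at their mapped positions and is represented as the
    per-chromosome pieces of its circular arc.
    """

    mechanism: str
    breakpoints: tuple[tuple[str, int], tuple[str, int]]
    pieces: tuple[Interval, ...]

    @property
    def interval(self) -> Interval:
        if len(self.pieces) != 1:
            raise ValueError("permuted SV wraps a junction; use .pieces")
        return self.pieces[0]


def _arc_pieces(layout: GenomeLayout, lin_start: int, length: int) -> tuple[Interval, ...]:
    """Split the circular arc [lin_start, lin_start+length) at chromosome cuts."""
    total = layout.total_length
    offs = layout.offset_array()
    names = layout.names
    pieces = []
    pos = lin_start
    remaining = length
    while remaining > 0:
        pos %= total
        i = int(np.searchsorted(offs, pos, side="right")) - 1
        chrom_end = int(offs[i + 1])
        take = min(remaining, chrom_end - pos)
        pieces.append(Interval(names[i], int(pos - offs[i]), int(pos - offs[i] + take)))
        pos += take
        remaining -= take
    return tuple(pieces)


def circular_permute(
    svs: Sequence[SVRecord], layout: GenomeLayout, offset: int
) -> list[PermutedSV]:
    """Shift every SV by one shared offset along the circularized genome."""
    total = layout.total_length
    if not 0 <= offset < total:
        raise ValueError(f"offset {offset} outside [0, {total})")
    out = []
    for sv in svs:
        lin = layout.linear(sv.interval.chrom, sv.interval.start) + offset
        length = sv.interval.length
        pieces = _arc_pieces(layout, lin % total, length)
        bp1 = layout.from_linear(lin % total)
        bp2 = layout.from_linear((lin + length) % total)
        out.append(PermutedSV(sv.mechanism, (bp1, bp2), pieces))
    return out


def background_ensemble(
    svs: Sequence[SVRecord],
    layout: GenomeLayout,
    n: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> Iterator[list[PermutedSV]]:
    """Yield ``n`` independently shifted SV sets (deterministic given seed)."""
    if n < 1:
        raise ValueError("need at least one permutation")
    for offset in _draw_offsets(layout, n, seed):
        yield circular_permute(svs, layout, int(offset))


def _draw_offsets(layout: GenomeLayout, n: int, seed: int) -> np.ndarray:
    # offsets drawn uniformly from [1, total_length - 1]
    rng = np.random.default_rng(seed)
    return rng.integers(1, layout.total_length, size=n)


# ---------------------------------------------------------------------------
# linearized segmentation for fast vectorized assignment


class _LinearSegments:
    def __init__(self, track: SegmentationTrack, layout: GenomeLayout):
        offs = layout.offsets
        starts, ends, codes = [], [], []
        self.labels = [l for l in track.labels if l != UNASSIGNED]
        code_of = {l: i for i, l in enumerate(self.labels)}
        for iv, lab in track.segments:
            if iv.chrom not in offs:
                continue
            starts.append(offs[iv.chrom] + iv.start)
            ends.append(offs[iv.chrom] + iv.end)
            codes.append(code_of[lab])
        order = np.argsort(starts)
        self.starts = np.asarray(starts, dtype=np.int64)[order]
        self.ends = np.asarray(ends, dtype=np.int64)[order]
        self.codes = np.asarray(codes, dtype=np.int64)[order]

    def assign(self, positions: np.ndarray) -> np.ndarray:
        """Label codes for linear positions; -1 when in a gap."""
        i = np.searchsorted(self.starts, positions, side="right") - 1
        ok = (i >= 0) & (positions < self.ends[np.clip(i, 0, None)])
        out = np.where(ok, self.codes[np.clip(i, 0, None)], -1)
        return out

    def label_counts(self, positions: np.ndarray) -> np.ndarray:
        codes = self.assign(positions)
        return np.bincount(codes[codes >= 0], minlength=len(self.labels))

    def coverage_prefix(self, code: int):
        """Return F(x) = bases of this label in [0, x), vectorized."""
        sel = self.codes == code
        s, e = self.starts[sel], self.ends[sel]
        if s.size == 0:
            return lambda x: np.zeros(np.asarray(x).shape, dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(e - s)])

        def F(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=np.int64)
            i = np.searchsorted(s, x, side="right")
            partial = np.clip(x - s[np.clip(i - 1, 0, None)], 0, (e - s)[np.clip(i - 1, 0, None)])
            partial = np.where(i > 0, partial, 0)
            return cum[np.clip(i - 1, 0, None)] * (i > 0) + partial

        return F


def category_fractions(
    points: Sequence[tuple[str, int]], track: SegmentationTrack
) -> dict[str, float]:
    """Fraction of points residing in each label.

    Points falling in gaps count in the denominator only, so fractions can
    sum to less than 1.
    """
    if len(points) == 0:
        raise ValueError("no points supplied")
    counts = {l: 0 for l in track.labels if l != UNASSIGNED}
    for chrom, pos in points:
        lab = track.assign(chrom, pos)
        if lab in counts:
            counts[lab] += 1
    n = len(points)
    return {l: c / n for l, c in counts.items()}


# ---------------------------------------------------------------------------
# Z-score enrichment


def _as_mechanism_dict(
    svs: Sequence[SVRecord] | Mapping[str, Sequence[SVRecord]]
) -> dict[str, list[SVRecord]]:
    if isinstance(svs, Mapping):
        return {m: list(v) for m, v in svs.items()}
    by: dict[str, list[SVRecord]] = {}
    for sv in svs:
        by.setdefault(sv.mechanism, []).append(sv)
    return by


def _zscore_frame(
    rows: list[dict], n_perm: int
) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (df["observed"] - df["bg_mean"]) / df["bg_sd"]
    z = z.where(df["bg_sd"] > 0, np.nan)
    df["z"] = z
    df["p"] = 2 * stats.norm.sf(np.abs(z))
    n_tests = len(df)
    df["p_adj"] = np.minimum(1.0, df["p"] * n_tests)
    df.attrs["n_permutations"] = n_perm
    return df


def enrichment_zscores(
    svs: Sequence[SVRecord] | Mapping[str, Sequence[SVRecord]],
    track: SegmentationTrack,
    layout: GenomeLayout,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    unit: str = "breakpoint",
) -> pd.DataFrame:
    """Per-(mechanism, label) enrichment against the circular-permutation null.

    Parameters
    ----------
    unit
        ``"breakpoint"`` scores both SV ends as points; ``"region"`` scores
        the bases of each SV interval per label instead.

    Returns a DataFrame with columns mechanism, label, observed, bg_mean,
    bg_sd, z, p, p_adj; Bonferroni family = all (mechanism, label) tests
    in this call.
    """
    if n_perm < 2:
        raise ValueError("need n_perm >= 2 for a background standard deviation")
    if unit not in ("breakpoint", "region"):
        raise ValueError(f"unknown unit {unit!r}")
    by_mech = _as_mechanism_dict(svs)
    segs = _LinearSegments(track, layout)
    labels = segs.labels
    total = layout.total_length
    offsets = _draw_offsets(layout, n_perm, seed)

    rows = []
    for mech, mech_svs in by_mech.items():
        if not mech_svs:
            continue
        lin_start = np.array(
            [layout.linear(s.interval.chrom, s.interval.start) for s in mech_svs],
            dtype=np.int64,
        )
        lengths = np.array([s.interval.length for s in mech_svs], dtype=np.int64)
        if unit == "breakpoint":
            pts = np.concatenate([lin_start, (lin_start + lengths) % total])
            denom = pts.size
            obs = segs.label_counts(pts) / denom
            bg = np.empty((n_perm, len(labels)))
            for k, off in enumerate(offsets):
                bg[k] = segs.label_counts((pts + off) % total) / denom
        else:
            denom = float(lengths.sum())
            Fs = [segs.coverage_prefix(c) for c in range(len(labels))]

            def _region_fracs(starts: np.ndarray) -> np.ndarray:
                ends = starts + lengths
                wrap = ends > total
                out = np.empty(len(labels))
                for c, F in enumerate(Fs):
                    cov = F(np.minimum(ends, total)) - F(starts)
                    if wrap.any():
                        cov = cov + np.where(wrap, F(ends % total), 0)
                    out[c] = cov.sum() / denom
                return out

            obs = _region_fracs(lin_start)
            bg = np.empty((n_perm, len(labels)))
            for k, off in enumerate(offsets):
                bg[k] = _region_fracs((lin_start + off) % total)

        mean, sd = bg.mean(axis=0), bg.std(axis=0, ddof=1)
        for c, lab in enumerate(labels):
            rows.append(
                dict(
                    mechanism=mech,
                    label=lab,
                    observed=float(obs[c]),
                    bg_mean=float(mean[c]),
                    bg_sd=float(sd[c]),
                )
            )
    return _zscore_frame(rows, n_perm)


def _containment_counts(
    starts: np.ndarray,
    lengths: np.ndarray,
    pts: np.ndarray,
    total: int,
) -> np.ndarray:
    """Number of points strictly inside each circular arc (open interval)."""
    ends = starts + lengths
    lo = np.searchsorted(pts, starts, side="right")
    nowrap_hi = np.searchsorted(pts, np.minimum(ends, total), side="left")
    n_inside = np.maximum(0, nowrap_hi - lo)
    wrap = ends > total
    if wrap.any():
        extra = np.searchsorted(pts, ends[wrap] - total, side="left")
        n_inside = n_inside.astype(np.int64)
        n_inside[wrap] = (pts.size - lo[wrap]) + extra
    return n_inside


def encompassing_zscores(
    svs: Sequence[SVRecord] | Mapping[str, Sequence[SVRecord]],
    points: Sequence[tuple[str, int]],
    layout: GenomeLayout,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment of SVs strictly containing annotation points.

    The observed statistic counts SVs whose open interval (start, end)
    contains at least one point (TAD boundary or loop anchor); an SV
    containing several points counts once.  A shifted SV wrapping a
    chromosome junction is treated as per-chromosome sub-intervals, so a
    point at the junction itself is never contained.
    """
    if n_perm < 2:
        raise ValueError("need n_perm >= 2 for a background standard deviation")
    by_mech = _as_mechanism_dict(svs)
    total = layout.total_length
    cuts = set(int(c) for c in layout.offset_array()[:-1])
    pts = np.array(
        sorted(
            layout.linear(c, p)
            for c, p in points
            if layout.linear(c, p) not in cuts
        ),
        dtype=np.int64,
    )
    offsets = _draw_offsets(layout, n_perm, seed)
    rows = []
    for mech, mech_svs in by_mech.items():
        if not mech_svs:
            continue
        lin_start = np.array(
            [layout.linear(s.interval.chrom, s.interval.start) for s in mech_svs],
            dtype=np.int64,
        )
        lengths = np.array([s.interval.length for s in mech_svs], dtype=np.int64)
        obs = int((_containment_counts(lin_start, lengths, pts, total) > 0).sum())
        bg = np.empty(n_perm)
        for k, off in enumerate(offsets):
            shifted = (lin_start + off) % total
            bg[k] = (_containment_counts(shifted, lengths, pts, total) > 0).sum()
        rows.append(
            dict(
                mechanism=mech,
                label="encompassing",
                observed=float(obs),
                bg_mean=float(bg.mean()),
                bg_sd=float(bg.std(ddof=1)),
            )
        )
    return _zscore_frame(rows, n_perm)


@dataclass
class ClusterResult:
    """Agglomerative clustering of mechanisms by enrichment profile."""

    leaf_order: list[str]
    linkage: np.ndarray
    mechanisms: list[str]

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def zscore_cluster(z_matrix: pd.DataFrame) -> ClusterResult:
    """Cluster mechanisms (rows) by their per-label Z profiles.

    Euclidean distance, average linkage.  Rows containing undefined Z are
    excluded with a warning.
    """
    keep = z_matrix.dropna(axis=0)
    dropped = set(z_matrix.index) - set(keep.index)
    if dropped:
        warnings.warn(f"excluding rows with undefined Z: {sorted(dropped)}")
    if len(keep) < 2:
        raise ValueError("need at least two mechanisms with defined Z profiles")
    link = hierarchy.linkage(keep.values, method="average", metric="euclidean")
    order = hierarchy.leaves_list(link)
    mechs = list(keep.index)
    return ClusterResult([mechs[i] for i in order], link, mechs)
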