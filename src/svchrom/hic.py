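"""Knight-Ruiz balancing, obs/exp transformation, and breakpoint-pair
interaction analysis of intra-chromosomal Hi-C contact matrices.

The normalization cascade is: raw counts -> KR-balanced -> obs/exp
(divide by the distance-expected mean) -> divide by the compartment- and
distance-specific average interaction.  The last step removes the overall
stronger interactions of B compartments so breakpoint-pair contact values
of SV classes with different compartment composition stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomeLayout, SegmentationTrack, SVRecord
from .aggregation import ks_two_sample

__all__ = [
    "ContactMatrix",
    "kr_balance",
    "obs_exp",
    "CompartmentDistanceProfile",
    "compartment_distance_profile",
    "sv_interaction",
    "sv_interactions",
    "compare_interactions",
]

MIXED = "mixed"


@dataclass
class ContactMatrix:
    """Symmetric intra-chromosomal contact matrix at fixed resolution."""

    chrom: str
    resolution: int
    counts: np.ndarray  # dense symmetric, float
    mask: np.ndarray = field(default=None)  # True = excluded bin

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.counts.shape[0]
        if self.counts.shape != (n, n):
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_of(self, pos: int) -> int:
        return pos // self.resolution

    # -- text I/O: sparse upper-triangle triples with a resolution header --

    def to_triples(self, path: str | Path) -> None:
        i, j = np.nonzero(np.triu(self.counts))
        lines = [f"# chrom={self.chrom} resolution={self.resolution} bins={self.n_bins}"]
        lines += [f"{a}\t{b}\t{self.counts[a, b]:g}" for a, b in zip(i, j)]
        Path(path).write_text("".join(l + "\n" for l in lines))

    @classmethod
    def from_triples(cls, path: str | Path) -> "ContactMatrix":
        lines = Path(path).read_text().splitlines()
        header = dict(
            kv.split("=") for kv in lines[0].lstrip("# ").split() if "=" in kv
        )
        chrom = header["chrom"]
        res = int(header["resolution"])
        n = int(header["bins"])
        m = np.zeros((n, n))
        for line in lines[1:]:
            if not line.strip():
                continue
            a, b, v = line.split("\t")
            a, b, v = int(a), int(b), float(v)
            m[a, b] = v
            m[b, a] = v
        cm = cls(chrom, res, m)
        cm.mask = m.sum(axis=0) == 0
        return cm


def kr_balance(
    matrix: ContactMatrix, tolerance: float = 1e-6, max_iter: int = 3000
) -> tuple[ContactMatrix, np.ndarray]:
    """Knight-Ruiz matrix balancing.

    Finds a positive scaling vector x so that D(x) M D(x) has all unmasked
    row sums equal (to 1); fully-zero rows are masked automatically first.
    Returns the balanced matrix and the full-length scaling vector (NaN on
    masked bins).

    Implemented as the inner-outer Newton iteration of the KR algorithm;
    raises on non-convergence with a hint to mask sparse rows.
    """
    M = matrix.counts
    mask = matrix.mask | (M.sum(axis=0) == 0)
    keep = ~mask
    A = M[np.ix_(keep, keep)]
    n = A.shape[0]
    if n == 0:
        raise ValueError("all bins masked; nothing to balance")

    x = _kr_vector(A, tol=tolerance, max_iter=max_iter)

    full_x = np.full(matrix.n_bins, np.nan)
    full_x[keep] = x
    balanced = np.zeros_like(M)
    balanced[np.ix_(keep, keep)] = A * np.outer(x, x)
    out = ContactMatrix(matrix.chrom, matrix.resolution, balanced, mask)
    return out, full_x


def _kr_vector(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Newton-type KR iteration on a symmetric non-negative matrix."""
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5
    v = x * (A @ x)
    rk = 1 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    it = 0
    while rout > stop_tol**2 and it < max_iter:
        it += 1
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, stop_tol**2)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 200:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta = g * rat
        eta = min(max(eta, stop_tol / res_norm if res_norm > 0 else etamax), etamax)
    if rout > stop_tol**2:
        raise RuntimeError(
            "KR balancing did not converge; consider masking sparse rows"
        )
    return x


def obs_exp(balanced: ContactMatrix) -> ContactMatrix:
    """Divide each entry by the mean balanced value at its bin distance.

    The expected value at distance d is the mean over unmasked bin pairs of
    that distance; entries at distances with no unmasked pairs are NaN, as
    are masked bins.
    """
    M = balanced.counts
    n = balanced.n_bins
    keep = ~balanced.mask
    out = np.full_like(M, np.nan)
    expected = np.full(n, np.nan)
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        ok = keep[i] & keep[j]
        if not ok.any():
            continue
        vals = M[i[ok], j[ok]]
        exp_d = vals.mean()
        expected[d] = exp_d
        if exp_d > 0:
            out[i[ok], j[ok]] = vals / exp_d
            out[j[ok], i[ok]] = out[i[ok], j[ok]]
    cm = ContactMatrix(balanced.chrom, balanced.resolution, np.nan_to_num(out), balanced.mask)
    cm.counts = out  # keep NaN semantics (ContactMatrix validation uses finite copy)
    cm.expected = expected
    return cm


def _bin_labels(
    n_bins: int, resolution: int, chrom: str, track: SegmentationTrack
) -> list[str]:
    """Compartment label of each bin, assigned by bin midpoint."""
    return [
        track.assign(chrom, i * resolution + resolution // 2) for i in range(n_bins)
    ]


@dataclass
class CompartmentDistanceProfile:
    """Mean obs/exp per (compartment, bin distance), pooled over chromosomes.

    ``pooled`` holds the distance-specific mean over all same-compartment
    pairs regardless of label, used as fallback for mixed-compartment SV
    ends.  Distances backed by fewer than ``min_pairs`` pairs are undefined.
    """

    per_label: dict[str, np.ndarray]
    pooled: np.ndarray
    min_pairs: int

    def value(self, label: str, distance_bins: int) -> float:
        arr = self.per_label.get(label)
        if arr is None or distance_bins >= arr.size:
            return float("nan")
        return float(arr[distance_bins])

    def pooled_value(self, distance_bins: int) -> float:
        if distance_bins >= self.pooled.size:
            return float("nan")
        return float(self.pooled[distance_bins])


def compartment_distance_profile(
    obsexp_matrices: Sequence[ContactMatrix],
    track: SegmentationTrack,
    min_pairs: int = 10,
) -> CompartmentDistanceProfile:
    """Average obs/exp per (same-compartment label, distance).

    An interaction contributes only when both bins carry the same
    compartment label; mixed pairs are excluded.
    """
    labels = [l for l in track.labels]
    max_d = max(cm.n_bins for cm in obsexp_matrices)
    sums = {l: np.zeros(max_d) for l in labels}
    cnts = {l: np.zeros(max_d, dtype=np.int64) for l in labels}
    pooled_sum = np.zeros(max_d)
    pooled_cnt = np.zeros(max_d, dtype=np.int64)
    for cm in obsexp_matrices:
        bl = np.array(_bin_labels(cm.n_bins, cm.resolution, cm.chrom, track))
        keep = ~cm.mask
        n = cm.n_bins
        for d in range(n):
            i = np.arange(n - d)
            j = i + d
            ok = keep[i] & keep[j] & (bl[i] == bl[j])
            vals = cm.counts[i[ok], j[ok]]
            finite = np.isfinite(vals)
            vals = vals[finite]
            labs = bl[i[ok]][finite]
            for l in np.unique(labs):
                if l not in sums:
                    continue
                sel = labs == l
                sums[l][d] += vals[sel].sum()
                cnts[l][d] += sel.sum()
            good = np.isin(labs, labels)
            pooled_sum[d] += vals[good].sum()
            pooled_cnt[d] += good.sum()
    per_label = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for l in labels:
            arr = np.where(cnts[l] >= min_pairs, sums[l] / np.maximum(cnts[l], 1), np.nan)
            per_label[l] = arr
        pooled = np.where(
            pooled_cnt >= min_pairs, pooled_sum / np.maximum(pooled_cnt, 1), np.nan
        )
    return CompartmentDistanceProfile(per_label, pooled, min_pairs)


@dataclass
class NormalizedInteraction:
    """Fully normalized breakpoint-pair interaction of one SV."""

    sv: SVRecord
    bins: tuple[int, int]
    obs_exp: float
    compartment: str  # shared label, or "mixed"
    distance_bp: int
    value: float


def sv_interaction(
    sv: SVRecord,
    obsexp: ContactMatrix,
    profile: CompartmentDistanceProfile,
    track: SegmentationTrack,
    min_length: int = 5000,
) -> NormalizedInteraction | str:
    """Normalized interaction of an SV's two end bins, or an exclusion reason.

    SVs not longer than ``min_length``, with both ends in one bin, with a
    masked end bin, or at a distance with undefined expected interaction
    are excluded (a reason string is returned rather than raising).
    """
    iv = sv.interval
    if iv.chrom != obsexp.chrom:
        return "wrong-chromosome"
    if iv.length <= min_length:
        return "too-short"
    i, j = obsexp.bin_of(iv.start), obsexp.bin_of(iv.end)
    if i == j:
        return "same-bin"
    if j >= obsexp.n_bins:
        j = obsexp.n_bins - 1
    if obsexp.mask[i] or obsexp.mask[j]:
        return "masked-bin"
    oe = obsexp.counts[i, j]
    if not np.isfinite(oe):
        return "undefined-obs-exp"
    d = abs(j - i)
    li = track.assign(iv.chrom, i * obsexp.resolution + obsexp.resolution // 2)
    lj = track.assign(iv.chrom, j * obsexp.resolution + obsexp.resolution // 2)
    if li == lj and li != "unassigned":
        comp = li
        denom = profile.value(li, d)
        if not np.isfinite(denom):
            denom = profile.pooled_value(d)
            comp = MIXED
    else:
        comp = MIXED
        denom = profile.pooled_value(d)
    if not np.isfinite(denom) or denom <= 0:
        return "undefined-expected-at-distance"
    return NormalizedInteraction(
        sv, (i, j), float(oe), comp, d * obsexp.resolution, float(oe / denom)
    )


def sv_interactions(
    svs: Sequence[SVRecord],
    obsexp_by_chrom: Mapping[str, ContactMatrix],
    profile: CompartmentDistanceProfile,
    track: SegmentationTrack,
    min_length: int = 5000,
) -> tuple[list[NormalizedInteraction], pd.Series]:
    """Vector form of :func:`sv_interaction`; returns values + exclusion tally."""
    kept, reasons = [], []
    for sv in svs:
        cm = obsexp_by_chrom.get(sv.interval.chrom)
        if cm is None:
            reasons.append("no-matrix")
            continue
        res = sv_interaction(sv, cm, profile, track, min_length)
        if isinstance(res, str):
            reasons.append(res)
        else:
            kept.append(res)
    return kept, pd.Series(reasons, dtype=object).value_counts()


def compare_interactions(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Two-sample KS comparison of normalized interaction value sets.

    Returns (D, p, (sorted_a, sorted_b)); the sorted arrays are the ECDF
    supports for cumulative-density plotting.
    """
    a = np.sort(np.asarray(values_a, dtype=float))
    b = np.sort(np.asarray(values_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both value sets must be nonempty")
    d, p = ks_two_sample(a, b)
    return d, p, (a, b)
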