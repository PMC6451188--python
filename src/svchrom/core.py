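"""Coordinate conventions, interval arithmetic, and plain-text genomic I/O.

All coordinates are 0-based half-open (BED convention) internally.  Input
files declared as 1-based can be converted on read with ``one_based=True``.

The linear coordinate system concatenates chromosomes in layout order, which
is what the circular-permutation null model shifts along.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MECHANISMS",
    "GenomeLayout",
    "Interval",
    "SVRecord",
    "SegmentationTrack",
    "SignalTrack",
    "BedFormatError",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_sv_table",
    "write_sv_table",
    "read_bedgraph",
    "write_bedgraph",
    "read_points",
    "linear_coordinate",
    "from_linear",
    "assign_label",
    "overlap_bases",
    "select_nonvariable_alus",
]

#: Fixed vocabulary of SV mechanism-of-origin labels.
MECHANISMS = (
    "NAHR",
    "NHEJ",
    "NHrepl",
    "MEI-Alu",
    "MEI-L1",
    "TDUP",
    "VNTR",
    "MTE-del",
    "Alu/L1-del",
)

UNASSIGNED = "unassigned"


class BedFormatError(ValueError):
    """A malformed line in a BED-like file; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths; defines the circular linear axis.

    Each chromosome gets a fixed offset equal to the summed lengths of the
    chromosomes preceding it, so (chrom, pos) maps bijectively onto
    [0, total_length).
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes.items()))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    @property
    def offsets(self) -> dict[str, int]:
        out, acc = {}, 0
        for name, length in self.chromosomes:
            out[name] = acc
            acc += length
        return out

    def offset_array(self) -> np.ndarray:
        """Chromosome start offsets followed by total length (len n+1)."""
        lengths = np.array([l for _, l in self.chromosomes], dtype=np.int64)
        return np.concatenate([[0], np.cumsum(lengths)])

    def linear(self, chrom: str, pos: int) -> int:
        return linear_coordinate(self, chrom, pos)

    def from_linear(self, lin: int) -> tuple[str, int]:
        return from_linear(self, lin)

    def chrom_length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class SVRecord:
    """A structural variant: an interval plus a mechanism-of-origin label.

    The SV's two breakpoints are ``interval.start`` and ``interval.end``.
    """

    interval: Interval
    mechanism: str
    allele_frequency: float | None = None
    micro_homology_bp: int | None = None
    micro_insertion_bp: int | None = None

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}"
            )
        if self.allele_frequency is not None and not 0 <= self.allele_frequency <= 1:
            raise ValueError("allele_frequency outside [0, 1]")

    @property
    def breakpoints(self) -> tuple[tuple[str, int], tuple[str, int]]:
        iv = self.interval
        return ((iv.chrom, iv.start), (iv.chrom, iv.end))


class SegmentationTrack:
    """Non-overlapping labeled intervals (compartment bins, chromHMM states).

    Parameters
    ----------
    segments
        Iterable of ``(Interval, label)``.
    label_set
        Declared label vocabulary; defaults to the labels observed.
    """

    def __init__(
        self,
        segments: Iterable[tuple[Interval, str]],
        label_set: Sequence[str] | None = None,
    ):
        segs = sorted(segments, key=lambda s: (s[0].chrom, s[0].start))
        self.segments: list[tuple[Interval, str]] = segs
        observed = []
        for _, lab in segs:
            if lab not in observed:
                observed.append(lab)
        self.labels: tuple[str, ...] = tuple(label_set) if label_set else tuple(observed)
        unknown = set(observed) - set(self.labels)
        if unknown:
            raise ValueError(f"segment labels {sorted(unknown)} outside declared label set")
        # per-chromosome sorted arrays for O(log n) point assignment
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        by: dict[str, list[tuple[Interval, str]]] = {}
        for iv, lab in segs:
            by.setdefault(iv.chrom, []).append((iv, lab))
        for chrom, items in by.items():
            starts = np.array([iv.start for iv, _ in items], dtype=np.int64)
            ends = np.array([iv.end for iv, _ in items], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping segments on {chrom}")
            self._by_chrom[chrom] = (starts, ends, [lab for _, lab in items])

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def assign(self, chrom: str, pos: int) -> str:
        """Label of the segment containing (chrom, pos), else 'unassigned'."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return UNASSIGNED
        starts, ends, labels = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return labels[i]
        return UNASSIGNED

    def total_bases(self, label: str | None = None) -> int:
        return sum(
            iv.length for iv, lab in self.segments if label is None or lab == label
        )


class SignalTrack:
    """Per-chromosome numeric signal at a fixed step, NaN marking missing data.

    ``values[chrom][i]`` covers bases ``[i*step, (i+1)*step)``.
    """

    def __init__(self, values: dict[str, np.ndarray], step: int = 1):
        if step < 1:
            raise ValueError("step must be >= 1")
        self.step = int(step)
        self.values = {c: np.asarray(v, dtype=float) for c, v in values.items()}
        for c, v in self.values.items():
            finite = v[~np.isnan(v)]
            if finite.size and not np.all(np.isfinite(finite)):
                raise ValueError(f"non-finite signal values on {c}")

    def base_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end), NaN outside data or track."""
        n = end - start
        out = np.full(n, np.nan)
        arr = self.values.get(chrom)
        if arr is None or n <= 0:
            return out
        bases = np.arange(max(start, 0), min(end, arr.size * self.step))
        if bases.size == 0:
            return out
        out[bases - start] = arr[bases // self.step]
        return out

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean over available bases in [start, end); NaN when none."""
        vals = self.base_values(chrom, start, end)
        ok = ~np.isnan(vals)
        if not ok.any():
            return float("nan")
        return float(vals[ok].mean())


# ---------------------------------------------------------------------------
# coordinate arithmetic


def linear_coordinate(layout: GenomeLayout, chrom: str, pos: int) -> int:
    """Map (chrom, pos) to the concatenated linear axis."""
    length = layout.chrom_length(chrom)
    if not 0 <= pos < length:
        raise ValueError(f"position {pos} outside [0, {length}) on {chrom}")
    return layout.offsets[chrom] + pos


def from_linear(layout: GenomeLayout, lin: int) -> tuple[str, int]:
    """Inverse of :func:`linear_coordinate`."""
    if not 0 <= lin < layout.total_length:
        raise ValueError(f"linear coordinate {lin} outside [0, {layout.total_length})")
    offs = layout.offset_array()
    i = int(np.searchsorted(offs, lin, side="right")) - 1
    return layout.names[i], int(lin - offs[i])


def assign_label(point: tuple[str, int], track: SegmentationTrack) -> str:
    return track.assign(*point)


def overlap_bases(a: Interval, b: Interval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def select_nonvariable_alus(
    alus: Sequence[Interval],
    svs: Sequence[SVRecord],
    min_length: int = 280,
    max_length: int = 350,
) -> list[Interval]:
    """Alu elements of 280-350 bp with zero overlap with any SV interval.

    These fixed (non-variable) elements are the homology substrate the
    NAHR simulation is benchmarked against.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for sv in svs:
        by_chrom.setdefault(sv.interval.chrom, []).append(
            (sv.interval.start, sv.interval.end)
        )
    arrs = {
        c: (
            np.array(sorted(s for s, _ in ivs), dtype=np.int64),
            np.array([e for _, e in sorted(ivs)], dtype=np.int64),
        )
        for c, ivs in by_chrom.items()
    }
    kept = []
    for alu in alus:
        if not min_length <= alu.length <= max_length:
            continue
        entry = arrs.get(alu.chrom)
        if entry is not None:
            starts, ends = entry
            # any SV with start < alu.end and end > alu.start overlaps
            i = np.searchsorted(starts, alu.end, side="left")
            if i > 0 and np.any(ends[:i] > alu.start):
                continue
        kept.append(alu)
    return kept


# ---------------------------------------------------------------------------
# I/O


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    chroms = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise BedFormatError("expected 2 tab-separated columns", ln)
        chroms.append((parts[0], int(parts[1])))
    return GenomeLayout(tuple(chroms))


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{l}\n" for c, l in layout.chromosomes)
    )


def read_bed(
    path: str | Path,
    layout: GenomeLayout | None = None,
    one_based: bool = False,
) -> list[Interval]:
    """Read BED3/BED6 intervals; validates the half-open convention.

    ``one_based=True`` shifts starts by -1 for files using 1-based inclusive
    start coordinates.
    """
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise BedFormatError(
                f"expected >=3 tab-separated columns, got {len(parts)}", ln
            )
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise BedFormatError(f"non-integer coordinate: {exc}", ln) from None
        if one_based:
            start -= 1
        name = parts[3] if len(parts) > 3 and parts[3] != "." else None
        score = None
        if len(parts) > 4 and parts[4] not in (".", ""):
            score = float(parts[4])
        strand = parts[5] if len(parts) > 5 else "."
        if start >= end:
            raise BedFormatError(f"empty or inverted interval {start}-{end}", ln)
        if layout is not None:
            if chrom not in layout.lengths:
                raise BedFormatError(f"unknown chromosome {chrom!r}", ln)
            if end > layout.chrom_length(chrom):
                raise BedFormatError(
                    f"interval end {end} beyond chromosome length", ln
                )
        out.append(Interval(chrom, start, end, strand, name, score))
    return out


def write_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    lines = []
    for iv in intervals:
        cols = [iv.chrom, str(iv.start), str(iv.end)]
        if iv.name is not None or iv.score is not None or iv.strand != ".":
            cols.append(iv.name if iv.name is not None else ".")
            cols.append(format(iv.score, "g") if iv.score is not None else ".")
            cols.append(iv.strand)
        lines.append("\t".join(cols))
    Path(path).write_text("".join(l + "\n" for l in lines))


SV_COLUMNS = (
    "chrom",
    "start",
    "end",
    "mechanism",
    "allele_frequency",
    "micro_homology_bp",
    "micro_insertion_bp",
)


def read_sv_table(
    path: str | Path,
    layout: GenomeLayout | None = None,
    one_based: bool = False,
) -> list[SVRecord]:
    """Read the tab-separated SV schema (header required, see SV_COLUMNS)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise BedFormatError("empty SV file")
    header = lines[0].lstrip("#").split("\t")
    idx = {name: i for i, name in enumerate(header)}
    for req in ("chrom", "start", "end", "mechanism"):
        if req not in idx:
            raise BedFormatError(f"SV table missing required column {req!r}", 1)
    out = []
    for ln, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        chrom = parts[idx["chrom"]]
        start, end = int(parts[idx["start"]]), int(parts[idx["end"]])
        if one_based:
            start -= 1
        if start >= end:
            raise BedFormatError(f"empty or inverted SV interval {start}-{end}", ln)
        if layout is not None and chrom not in layout.lengths:
            raise BedFormatError(f"unknown chromosome {chrom!r}", ln)

        def _opt(col, cast):
            i = idx.get(col)
            if i is None or i >= len(parts) or parts[i] in (".", "", "NA"):
                return None
            return cast(parts[i])

        out.append(
            SVRecord(
                Interval(chrom, start, end),
                parts[idx["mechanism"]],
                allele_frequency=_opt("allele_frequency", float),
                micro_homology_bp=_opt("micro_homology_bp", int),
                micro_insertion_bp=_opt("micro_insertion_bp", int),
            )
        )
    return out


def write_sv_table(svs: Sequence[SVRecord], path: str | Path) -> None:
    lines = ["\t".join(SV_COLUMNS)]
    for sv in svs:
        iv = sv.interval
        lines.append(
            "\t".join(
                [
                    iv.chrom,
                    str(iv.start),
                    str(iv.end),
                    sv.mechanism,
                    "." if sv.allele_frequency is None else format(sv.allele_frequency, ".17g"),
                    "." if sv.micro_homology_bp is None else str(sv.micro_homology_bp),
                    "." if sv.micro_insertion_bp is None else str(sv.micro_insertion_bp),
                ]
            )
        )
    Path(path).write_text("".join(l + "\n" for l in lines))


def read_bedgraph(path: str | Path, step: int | None = None) -> SignalTrack:
    """Read a fixed-step bedGraph into a SignalTrack.

    Every interval must span exactly one step (the common fixed-step export);
    gaps become NaN.
    """
    rows: dict[str, list[tuple[int, int, float]]] = {}
    inferred = step
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise BedFormatError("bedGraph needs 4 columns", ln)
        chrom, start, end, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if inferred is None:
            inferred = end - start
        if end - start != inferred or start % inferred:
            raise BedFormatError(
                f"bedGraph not at fixed step {inferred}", ln
            )
        rows.setdefault(chrom, []).append((start, end, val))
    if inferred is None:
        raise BedFormatError("empty bedGraph")
    values = {}
    for chrom, items in rows.items():
        n = max(e for _, e, _ in items) // inferred
        arr = np.full(n, np.nan)
        for s, _, v in items:
            arr[s // inferred] = v
        values[chrom] = arr
    return SignalTrack(values, step=inferred)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    lines = []
    for chrom, arr in track.values.items():
        for i, v in enumerate(arr):
            if math.isnan(v):
                continue
            lines.append(
                f"{chrom}\t{i * track.step}\t{(i + 1) * track.step}\t{v:g}"
            )
    Path(path).write_text("".join(l + "\n" for l in lines))


def read_points(path: str | Path) -> list[tuple[str, int]]:
    """Read point anchors (TAD boundaries, loop anchors) from BED.

    Each interval is reduced to its midpoint.
    """
    return [(iv.chrom, iv.midpoint) for iv in read_bed(path)]


def read_segmentation(
    path: str | Path, label_set: Sequence[str] | None = None
) -> SegmentationTrack:
    """Read a labeled BED (4th column = label) into a SegmentationTrack."""
    ivs = read_bed(path)
    segs = []
    for iv in ivs:
        if iv.name is None:
            raise BedFormatError("segmentation BED requires a label in column 4")
        segs.append((iv, iv.name))
    return SegmentationTrack(segs, label_set=label_set)


def write_segmentation(track: SegmentationTrack, path: str | Path) -> None:
    write_bed(
        [replace(iv, name=lab) for iv, lab in track.segments],
        path,
    )
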