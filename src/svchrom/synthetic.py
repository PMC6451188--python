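"""Self-contained synthetic genome with planted ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a multi-chromosome genome partitioned into A/B compartment bins;
DNase peaks concentrated in A compartments, a subset occupied by TF
binding sites; spontaneous DSB peaks co-localizing with TF-occupied DNase
sites; meiotic DSB peaks weakly enriched in B1; homologous (Alu-like)
repeat pairs enriched in A compartments; per-mechanism SV sets with
planted compartment biases; NAHR deletions whose breakpoints coincide with
the members of a repeat pair, preferentially near spontaneous DSBs, with a
planted minority fraction at meiotic DSBs; Hi-C contact matrices with
power-law distance decay, compartment structure and an elevated contact
between NAHR breakpoint pairs; and replication-timing and nucleosome
signal tracks.

Everything is deterministic given the seed.  The truth record (planted
enrichments, the meiotic fraction x_true, per-NAHR provenance) is carried
alongside the data and is never consumed by analysis stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    GenomeLayout,
    Interval,
    SVRecord,
    SegmentationTrack,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_segmentation,
    write_sv_table,
)
from .hic import ContactMatrix

__all__ = ["WorldConfig", "SyntheticWorld", "RepeatPair", "generate_world",
           "generate_contact_matrix", "write_world"]

COMPARTMENT_LABELS = ("A1", "A2", "B1", "B2", "B3")


def _uniform(value: float) -> dict[str, float]:
    return {l: value for l in COMPARTMENT_LABELS}


@dataclass
class WorldConfig:
    """Parameters of the synthetic world (defaults are the study conditions)."""

    # genome
    n_chromosomes: int = 4
    chromosome_length: int = 5_000_000
    compartment_bin: int = 100_000
    compartment_proportions: dict[str, float] = field(
        default_factory=lambda: {"A1": 0.15, "A2": 0.25, "B1": 0.15, "B2": 0.15, "B3": 0.30}
    )
    n_gaps_per_chromosome: int = 1
    gap_length: int = 10_000

    # regulatory peaks
    dnase_density_per_mb: dict[str, float] = field(
        default_factory=lambda: {"A1": 60.0, "A2": 40.0, "B1": 15.0, "B2": 10.0, "B3": 8.0}
    )
    dnase_width: int = 300
    tfbs_fraction: float = 0.3
    tfbs_width: int = 20

    # double-strand-break peaks
    n_spontaneous_dsb: int = 3000
    spontaneous_dsb_width: int = 400
    spontaneous_dsb_colocalization: float = 0.7  # fraction at TF-occupied DNase
    n_meiotic_dsb: int = 800
    meiotic_dsb_width: int = 1500
    meiotic_b1_bias: float = 1.5

    # homologous repeat pairs
    repeat_density_per_mb: dict[str, float] = field(
        default_factory=lambda: {"A1": 70.0, "A2": 50.0, "B1": 20.0, "B2": 20.0, "B3": 12.0}
    )
    repeat_length: int = 300
    repeat_pair_identity: float = 0.95
    repeat_pair_separation: tuple[int, int] = (20_000, 500_000)

    # SV sets
    sv_counts: dict[str, int] = field(
        default_factory=lambda: {
            "NAHR": 300,
            "NHEJ": 400,
            "NHrepl": 400,
            "TDUP": 200,
            "MEI-Alu": 300,
            "MEI-L1": 150,
            "VNTR": 150,
            "MTE-del": 100,
            "Alu/L1-del": 200,
        }
    )
    sv_compartment_enrichment: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "NHEJ": {"B2": 2.0, "B3": 2.0},
            "NHrepl": {"B2": 2.0, "B3": 2.0},
            "MEI-Alu": {"B2": 1.5, "B3": 1.5},
            "MEI-L1": {"B3": 2.0},
            "VNTR": {},
            "TDUP": {},
            "MTE-del": {"A1": 1.5, "A2": 1.5},
            "Alu/L1-del": {},
        }
    )
    sv_length_range: tuple[int, int] = (500, 50_000)
    x_true: float = 0.10  # planted meiotic fraction of NAHR deletions
    nahr_spont_coupling: bool = True  # choose NAHR pairs near spontaneous DSBs
    nahr_spont_window: int = 5_000
    nahr_spont_peak_rate: float = 0.8  # plant a spont peak at HDR NAHR breakpoints

    # TADs and loops
    tad_boundary_spacing: int = 500_000
    n_loop_anchors: int = 200

    # contact matrices
    contact_resolution: int = 10_000
    contact_decay_alpha: float = 1.0
    contact_scale: float = 1000.0
    compartment_contact_boost: float = 1.5
    nahr_contact_boost: float = 2.0
    contact_noise: bool = True
    unmappable_bin_rate: float = 0.02

    # signal tracks
    replication_means: dict[str, float] = field(
        default_factory=lambda: {"A1": 1.5, "A2": 1.0, "B1": -0.2, "B2": -0.8, "B3": -1.5}
    )
    replication_noise_sd: float = 0.3
    replication_step: int = 1000
    nucleosome_period: int = 150
    nucleosome_step: int = 5

    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.compartment_proportions.values()) - 1) > 1e-9:
            raise ValueError("compartment proportions must sum to 1")
        if not 0 <= self.x_true <= 1:
            raise ValueError("x_true must lie in [0, 1]")
        for name, d in [
            ("dnase_density_per_mb", self.dnase_density_per_mb),
            ("repeat_density_per_mb", self.repeat_density_per_mb),
        ]:
            if any(v < 0 for v in d.values()):
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "WorldConfig":
        """A world with every planted bias switched off (calibration runs)."""
        cfg = cls(
            dnase_density_per_mb=_uniform(25.0),
            tfbs_fraction=0.3,
            spontaneous_dsb_colocalization=0.0,
            meiotic_b1_bias=1.0,
            repeat_density_per_mb=_uniform(34.0),
            sv_compartment_enrichment={m: {} for m in cls().sv_compartment_enrichment},
            x_true=0.0,
            nahr_spont_coupling=False,
            nahr_spont_peak_rate=0.0,
            compartment_contact_boost=1.0,
            nahr_contact_boost=1.0,
            seed=seed,
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


@dataclass(frozen=True)
class RepeatPair:
    """Two homologous Alu-like repeat copies planted in the sequence."""

    member1: Interval
    member2: Interval
    identity: float


class SyntheticWorld:
    """Generated genome, annotations, SV sets, tracks and truth record.

    Sequence and contact matrices are generated lazily (deterministically)
    on first access; everything else is materialized by
    :func:`generate_world`.
    """

    def __init__(self, config: WorldConfig):
        self.config = config
        self.layout: GenomeLayout = None
        self.compartments: SegmentationTrack = None
        self.dnase: list[Interval] = []
        self.tfbs: list[Interval] = []
        self.spontaneous_dsb: list[Interval] = []
        self.meiotic_dsb: list[Interval] = []
        self.repeat_pairs: list[RepeatPair] = []
        self.svs: dict[str, list[SVRecord]] = {}
        self.tad_boundaries: list[tuple[str, int]] = []
        self.loop_anchors: list[tuple[str, int]] = []
        self.replication: SignalTrack = None
        self.nucleosome: SignalTrack = None
        self.gaps: list[Interval] = []
        self.truth: dict = {}
        self._seq_cache: dict[str, np.ndarray] = {}
        self._contact_cache: dict[str, ContactMatrix] = {}
        self._nahr_pair_index: list[int] = []  # repeat pair index per NAHR

    # -- SequenceSource protocol --

    def codes(self, chrom: str) -> np.ndarray:
        if chrom not in self._seq_cache:
            self._seq_cache[chrom] = self._build_sequence(chrom)
        return self._seq_cache[chrom]

    def _build_sequence(self, chrom: str) -> np.ndarray:
        cfg = self.config
        ci = self.layout.names.index(chrom)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(101, ci))
        )
        seq = rng.integers(0, 4, size=self.layout.chrom_length(chrom)).astype(np.uint8)
        for k, pair in enumerate(self.repeat_pairs):
            if pair.member1.chrom != chrom:
                continue
            m1, m2 = pair.member1, pair.member2
            copy = seq[m1.start : m1.end].copy()
            mrng = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.seed, spawn_key=(102, k))
            )
            mut = mrng.random(copy.size) < (1 - pair.identity)
            shift = mrng.integers(1, 4, size=copy.size).astype(np.uint8)
            copy[mut] = (copy[mut] + shift[mut]) % 4
            seq[m2.start : m2.end] = copy
        for gap in self.gaps:
            if gap.chrom == chrom:
                seq[gap.start : gap.end] = 4
        return seq

    def contact_matrix(self, chrom: str) -> ContactMatrix:
        if chrom not in self._contact_cache:
            self._contact_cache[chrom] = generate_contact_matrix(self, chrom)
        return self._contact_cache[chrom]

    def all_svs(self) -> list[SVRecord]:
        return [sv for svs in self.svs.values() for sv in svs]


def _compartment_segments(
    rng: np.random.Generator, layout: GenomeLayout, cfg: WorldConfig
) -> SegmentationTrack:
    labels = list(cfg.compartment_proportions)
    probs = np.array([cfg.compartment_proportions[l] for l in labels])
    segs = []
    for chrom, length in layout.chromosomes:
        n_bins = length // cfg.compartment_bin
        draw = rng.choice(len(labels), size=n_bins, p=probs)
        for i, c in enumerate(draw):
            segs.append(
                (
                    Interval(chrom, i * cfg.compartment_bin, (i + 1) * cfg.compartment_bin),
                    labels[c],
                )
            )
        # a final partial bin stays unannotated (a gap), like real bin tracks
    return SegmentationTrack(segs, label_set=labels)


def _segment_arrays(track: SegmentationTrack) -> dict[str, list[Interval]]:
    by: dict[str, list[Interval]] = {}
    for iv, lab in track.segments:
        by.setdefault(lab, []).append(iv)
    return by


def _sample_in_segments(
    rng: np.random.Generator, segments: Sequence[Interval], n: int
) -> list[tuple[str, int]]:
    """n positions uniform over the union of segments."""
    lengths = np.array([s.length for s in segments], dtype=float)
    if lengths.sum() == 0 or n == 0:
        return []
    idx = rng.choice(len(segments), size=n, p=lengths / lengths.sum())
    out = []
    for i in idx:
        seg = segments[i]
        out.append((seg.chrom, int(rng.integers(seg.start, seg.end))))
    return out


def _peak_at(
    layout: GenomeLayout, chrom: str, center: int, width: int
) -> Interval | None:
    half = width // 2
    start = max(0, center - half)
    end = min(layout.chrom_length(chrom), center + width - half)
    if end - start <= 0:
        return None
    return Interval(chrom, start, end)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Build the full synthetic world; deterministic given ``config.seed``."""
    config.validate()
    world = SyntheticWorld(config)
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,)))

    layout = GenomeLayout(
        tuple((f"chr{i + 1}", cfg.chromosome_length) for i in range(cfg.n_chromosomes))
    )
    world.layout = layout
    world.compartments = _compartment_segments(rng, layout, cfg)
    by_label = _segment_arrays(world.compartments)

    # ------------------------------------------------------------------ DNase
    dnase, tfbs = [], []
    for label, segs in by_label.items():
        mb = sum(s.length for s in segs) / 1e6
        n = rng.poisson(cfg.dnase_density_per_mb.get(label, 0.0) * mb)
        for chrom, pos in _sample_in_segments(rng, segs, n):
            peak = _peak_at(layout, chrom, pos, cfg.dnase_width)
            if peak is None:
                continue
            dnase.append(peak)
            if rng.random() < cfg.tfbs_fraction:
                site = _peak_at(layout, chrom, peak.midpoint, cfg.tfbs_width)
                if site is not None:
                    tfbs.append(site)
    world.dnase, world.tfbs = dnase, tfbs
    # a DNase site is TF-occupied when a TFBS midpoint falls inside it;
    # by construction TFBS were planted at DNase midpoints
    tf_mid = {(t.chrom, t.midpoint) for t in tfbs}
    tf_occupied_dnase = [d for d in dnase if (d.chrom, d.midpoint) in tf_mid]

    # ------------------------------------------------------- spontaneous DSBs
    spont = []
    all_segs = [iv for iv, _ in world.compartments.segments]
    for _ in range(cfg.n_spontaneous_dsb):
        if tf_occupied_dnase and rng.random() < cfg.spontaneous_dsb_colocalization:
            site = tf_occupied_dnase[int(rng.integers(0, len(tf_occupied_dnase)))]
            center = site.midpoint
            chrom = site.chrom
        else:
            chrom, center = _sample_in_segments(rng, all_segs, 1)[0]
        peak = _peak_at(layout, chrom, center, cfg.spontaneous_dsb_width)
        if peak is not None:
            spont.append(peak)

    # ----------------------------------------------------------- meiotic DSBs
    meiotic = []
    weights = {l: (cfg.meiotic_b1_bias if l == "B1" else 1.0) for l in by_label}
    lab_names = list(by_label)
    lab_bases = np.array([sum(s.length for s in by_label[l]) for l in lab_names], float)
    lab_w = np.array([weights[l] for l in lab_names]) * lab_bases
    lab_w /= lab_w.sum()
    for _ in range(cfg.n_meiotic_dsb):
        label = lab_names[int(rng.choice(len(lab_names), p=lab_w))]
        chrom, center = _sample_in_segments(rng, by_label[label], 1)[0]
        peak = _peak_at(layout, chrom, center, cfg.meiotic_dsb_width)
        if peak is not None:
            meiotic.append(peak)

    # ------------------------------------------------------------ repeat pairs
    pairs: list[RepeatPair] = []
    sep_lo, sep_hi = cfg.repeat_pair_separation
    for label, segs in by_label.items():
        mb = sum(s.length for s in segs) / 1e6
        n = rng.poisson(cfg.repeat_density_per_mb.get(label, 0.0) * mb)
        placed = 0
        attempts = 0
        while placed < n and attempts < 50 * n + 100:
            attempts += 1
            chrom, pos = _sample_in_segments(rng, segs, 1)[0]
            sep = int(rng.integers(sep_lo, sep_hi + 1))
            if rng.random() < 0.5:
                sep = -sep
            other = pos + sep
            clen = layout.chrom_length(chrom)
            if not (0 <= other and other + cfg.repeat_length <= clen):
                continue
            if pos + cfg.repeat_length > clen:
                continue
            a, b = sorted([pos, other])
            if b - a < cfg.repeat_length:  # members must not overlap
                continue
            pairs.append(
                RepeatPair(
                    Interval(chrom, a, a + cfg.repeat_length),
                    Interval(chrom, b, b + cfg.repeat_length),
                    cfg.repeat_pair_identity,
                )
            )
            placed += 1
    world.repeat_pairs = pairs

    # ------------------------------------------------------------------- gaps
    gaps = []
    pair_spans = [(p.member1.chrom, p.member1.start, p.member2.end) for p in pairs]
    for chrom, length in layout.chromosomes:
        placed = 0
        attempts = 0
        while placed < cfg.n_gaps_per_chromosome and attempts < 200:
            attempts += 1
            start = int(rng.integers(0, max(1, length - cfg.gap_length)))
            gap = Interval(chrom, start, start + cfg.gap_length)
            if any(
                c == chrom and gap.start < e and s < gap.end for c, s, e in pair_spans
            ):
                continue
            gaps.append(gap)
            placed += 1
    world.gaps = gaps

    # --------------------------------------------------------------- NAHR SVs
    n_nahr = cfg.sv_counts.get("NAHR", 0)
    if n_nahr > len(pairs):
        raise ValueError(
            f"requested {n_nahr} NAHR deletions but only {len(pairs)} repeat pairs"
        )
    if cfg.nahr_spont_coupling and spont:
        centers_by_chrom: dict[str, np.ndarray] = {}
        for s in spont:
            centers_by_chrom.setdefault(s.chrom, []).append(s.midpoint)
        centers_by_chrom = {
            c: np.sort(np.array(v)) for c, v in centers_by_chrom.items()
        }
        w = np.zeros(len(pairs))
        for k, p in enumerate(pairs):
            centers = centers_by_chrom.get(p.member1.chrom)
            if centers is None:
                continue
            lo = np.searchsorted(centers, p.member1.start - cfg.nahr_spont_window)
            hi = np.searchsorted(centers, p.member1.start + cfg.nahr_spont_window)
            w[k] = hi - lo
        # small floor keeps selection feasible when few pairs sit near a DSB
        w = w + 0.05
        w = w / w.sum()
        chosen = rng.choice(len(pairs), size=n_nahr, replace=False, p=w)
    else:
        chosen = rng.choice(len(pairs), size=n_nahr, replace=False)

    nahr = []
    meiotic_flags = []
    for k in chosen:
        pair = pairs[k]
        start, end = pair.member1.start, pair.member2.start
        sv = SVRecord(
            Interval(pair.member1.chrom, start, end),
            "NAHR",
            allele_frequency=float(rng.random()),
        )
        is_meiotic = bool(rng.random() < cfg.x_true)
        meiotic_flags.append(is_meiotic)
        for _, bp in sv.breakpoints:
            if is_meiotic:
                peak = _peak_at(layout, sv.interval.chrom, bp, cfg.meiotic_dsb_width)
                if peak is not None:
                    meiotic.append(peak)
            elif rng.random() < cfg.nahr_spont_peak_rate:
                peak = _peak_at(layout, sv.interval.chrom, bp, cfg.spontaneous_dsb_width)
                if peak is not None:
                    spont.append(peak)
        nahr.append(sv)
    world.svs["NAHR"] = nahr
    world._nahr_pair_index = [int(k) for k in chosen]
    world.spontaneous_dsb = spont
    world.meiotic_dsb = meiotic

    # -------------------------------------------------------------- other SVs
    base_weights = {l: sum(s.length for s in by_label[l]) for l in by_label}
    lo_len, hi_len = cfg.sv_length_range
    for mech, count in cfg.sv_counts.items():
        if mech == "NAHR":
            continue
        enrich = cfg.sv_compartment_enrichment.get(mech, {})
        w = np.array(
            [base_weights[l] * enrich.get(l, 1.0) for l in lab_names], dtype=float
        )
        w /= w.sum()
        svs = []
        guard = 0
        while len(svs) < count and guard < 50 * count + 1000:
            guard += 1
            label = lab_names[int(rng.choice(len(lab_names), p=w))]
            chrom, pos = _sample_in_segments(rng, by_label[label], 1)[0]
            length = int(np.exp(rng.uniform(np.log(lo_len), np.log(hi_len))))
            if pos + length >= layout.chrom_length(chrom):
                continue
            mh = mi = None
            if mech == "NHEJ":
                mh, mi = 0, 0
            elif mech == "NHrepl":
                if rng.random() < 0.5:
                    mh, mi = int(rng.integers(3, 11)), 0
                else:
                    mh, mi = 0, int(rng.integers(11, 31))
            svs.append(
                SVRecord(
                    Interval(chrom, pos, pos + length),
                    mech,
                    allele_frequency=float(rng.random()),
                    micro_homology_bp=mh,
                    micro_insertion_bp=mi,
                )
            )
        world.svs[mech] = svs

    # ------------------------------------------------------------ TADs, loops
    for chrom, length in layout.chromosomes:
        for pos in range(cfg.tad_boundary_spacing, length, cfg.tad_boundary_spacing):
            world.tad_boundaries.append((chrom, pos))
    for chrom, pos in _sample_in_segments(rng, all_segs, cfg.n_loop_anchors):
        world.loop_anchors.append((chrom, pos))

    # ----------------------------------------------------------- signal tracks
    rt_values = {}
    for chrom, length in layout.chromosomes:
        n = length // cfg.replication_step
        arr = np.empty(n)
        for i in range(n):
            lab = world.compartments.assign(chrom, i * cfg.replication_step)
            mean = cfg.replication_means.get(lab, 0.0)
            arr[i] = mean
        arr += rng.normal(0, cfg.replication_noise_sd, size=n)
        rt_values[chrom] = arr
    world.replication = SignalTrack(rt_values, step=cfg.replication_step)

    nuc_values = {}
    for chrom, length in layout.chromosomes:
        n = length // cfg.nucleosome_step
        x = np.arange(n) * cfg.nucleosome_step
        phase = rng.uniform(0, 2 * np.pi)
        arr = 1.0 + 0.5 * np.sin(2 * np.pi * x / cfg.nucleosome_period + phase)
        arr += rng.normal(0, 0.05, size=n)
        nuc_values[chrom] = np.clip(arr, 0, None)
    world.nucleosome = SignalTrack(nuc_values, step=cfg.nucleosome_step)

    # ------------------------------------------------------------ truth record
    world.truth = {
        "x_true": cfg.x_true,
        "n_nahr": n_nahr,
        "n_meiotic_nahr": int(sum(meiotic_flags)),
        "nahr_meiotic_flags": [bool(f) for f in meiotic_flags],
        "nahr_repeat_pair_index": world._nahr_pair_index,
        "planted_sv_enrichment": cfg.sv_compartment_enrichment,
        "compartment_contact_boost": cfg.compartment_contact_boost,
        "nahr_contact_boost": cfg.nahr_contact_boost,
        "seed": cfg.seed,
    }
    return world


def generate_contact_matrix(world: SyntheticWorld, chrom: str) -> ContactMatrix:
    """Poisson contact matrix with distance decay and planted boosts.

    Expected contact at bin distance d is proportional to (d+1)^(-alpha);
    same-compartment bin pairs and NAHR breakpoint bin pairs receive their
    configured multiplicative boosts; a configured fraction of bins is
    zeroed (unmappable) and flagged for balancing exclusion.
    """
    cfg = world.config
    layout = world.layout
    ci = layout.names.index(chrom)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(201, ci))
    )
    res = cfg.contact_resolution
    length = layout.chrom_length(chrom)
    n = -(-length // res)  # final partial bin included
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    expected = cfg.contact_scale * (d + 1.0) ** (-cfg.contact_decay_alpha)

    labels = np.array(
        [world.compartments.assign(chrom, i * res + res // 2) for i in range(n)]
    )
    same = (labels[:, None] == labels[None, :]) & (labels[:, None] != "unassigned")
    expected = np.where(same, expected * cfg.compartment_contact_boost, expected)

    for sv in world.svs.get("NAHR", []):
        if sv.interval.chrom != chrom:
            continue
        i, j = sv.interval.start // res, sv.interval.end // res
        if i != j and i < n and j < n:
            expected[i, j] *= cfg.nahr_contact_boost
            expected[j, i] *= cfg.nahr_contact_boost

    if cfg.contact_noise:
        upper = np.triu(rng.poisson(expected)).astype(float)
        counts = upper + np.triu(upper, 1).T
    else:
        counts = expected.copy()

    mask = rng.random(n) < cfg.unmappable_bin_rate
    counts[mask, :] = 0
    counts[:, mask] = 0
    cm = ContactMatrix(chrom, res, counts)
    cm.mask = mask | (counts.sum(axis=0) == 0)
    return cm


def write_world(
    world: SyntheticWorld,
    directory: str | Path,
    include_contacts: bool = True,
    include_sequence: bool = False,
) -> dict[str, Path]:
    """Emit the world as the plain-text formats the pipeline consumes.

    The truth record goes to a separate ``truth.json`` that no analysis
    stage reads.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def _reg(key: str, name: str) -> Path:
        files[key] = d / name
        return files[key]

    write_chrom_sizes(world.layout, _reg("chrom_sizes", "genome.chrom.sizes"))
    write_segmentation(world.compartments, _reg("compartments", "compartments.bed"))
    write_bed(world.dnase, _reg("dnase", "dnase.bed"))
    write_bed(world.tfbs, _reg("tfbs", "tfbs.bed"))
    write_bed(world.spontaneous_dsb, _reg("spontaneous_dsb", "spontaneous_dsb.bed"))
    write_bed(world.meiotic_dsb, _reg("meiotic_dsb", "meiotic_dsb.bed"))
    repeats = [m for p in world.repeat_pairs for m in (p.member1, p.member2)]
    write_bed(repeats, _reg("repeats", "repeats.bed"))
    with open(_reg("repeat_pairs", "repeat_pairs.tsv"), "w") as fh:
        fh.write("chrom\tstart1\tend1\tstart2\tend2\tidentity\n")
        for p in world.repeat_pairs:
            fh.write(
                f"{p.member1.chrom}\t{p.member1.start}\t{p.member1.end}"
                f"\t{p.member2.start}\t{p.member2.end}\t{p.identity:g}\n"
            )
    write_sv_table(world.all_svs(), _reg("svs", "svs.tsv"))
    write_bed(
        [Interval(c, p, p + 1) for c, p in world.tad_boundaries],
        _reg("tad_boundaries", "tad_boundaries.bed"),
    )
    write_bed(
        [Interval(c, p, p + 1) for c, p in world.loop_anchors],
        _reg("loop_anchors", "loop_anchors.bed"),
    )
    write_bedgraph(world.replication, _reg("replication", "replication_timing.bedgraph"))
    write_bedgraph(world.nucleosome, _reg("nucleosome", "nucleosome.bedgraph"))

    if include_contacts:
        for chrom in world.layout.names:
            world.contact_matrix(chrom).to_triples(
                _reg(f"contacts_{chrom}", f"contacts_{chrom}.txt")
            )
    if include_sequence:
        from .nahr import CODE_BASES

        with open(_reg("fasta", "genome.fa"), "w") as fh:
            for chrom in world.layout.names:
                fh.write(f">{chrom}\n")
                seq = "".join(CODE_BASES[world.codes(chrom)])
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    with open(_reg("truth", "truth.json"), "w") as fh:
        json.dump(world.truth, fh, indent=1)
    return files
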