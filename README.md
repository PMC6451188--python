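# svchrom

Structural variants (SVs) arise through distinct mechanisms — non-allelic
homologous recombination (NAHR), non-homologous end joining (NHEJ),
replication errors (NHrepl), retrotransposition — and those mechanisms leave
distinct footprints in the chromatin landscape. `svchrom` is a toolkit for
quantifying those footprints: it tests where breakpoints of each SV class sit
relative to Hi-C compartments, TAD boundaries, DNase hypersensitive sites and
double-strand-break (DSB) hotspots, simulates where homology alone would
allow NAHR to occur, measures the physical contact between the two
breakpoints of a deletion, and estimates what fraction of NAHR deletions are
of meiotic (vs. homology-directed-repair) origin.

It is written for genomicists who have breakpoint calls with mechanism
labels, peak sets and Hi-C matrices, and want the statistics — and for anyone
who wants to exercise the same statistics on a fully synthetic genome with
planted ground truth (no downloads needed).

## Methods at a glance

- **Circular-permutation null model.** The genome is treated as a circle of
  concatenated chromosomes; each of 1000 replicates shifts every SV by one
  shared random offset, preserving SV count, lengths and spacing. Per
  category (compartment, chromHMM-like state, TAD-boundary containment) the
  observed statistic is compared to the permutation background:
  `Z = (obs − mean_bg) / sd_bg`, with two-sided normal p-values and
  Bonferroni correction across the (mechanism × category) family.
- **Simulated NAHR.** Random 100 bp seeds are searched for homologous
  partners (exact 12-mer seeding + ungapped extension; same orientation,
  alignment > 50 bp, identity > 85%, 100 bp–1 Mb apart). Pairs are thinned by
  rejection sampling against the empirical NAHR deletion-length density, then
  subsampled to match the compartment proportions of real NAHR breakpoints.
- **Aggregation profiles.** Fraction of peak-covered bases per 100 bp bin
  within ±2.5 kb of breakpoints (10 bp bins at regulatory-site midpoints);
  signal tracks are averaged per 10 bp bin within ±1 kb and normalized by the
  2 kb mean so a flat track reads 1.0.
- **Hi-C interaction of breakpoint pairs.** Raw intra-chromosomal contact
  matrices are Knight–Ruiz balanced, converted to observed/expected by
  distance, and further divided by the compartment- and distance-specific
  average, so SV classes living in different compartments stay comparable.
  SVs ≤ 5 kb are excluded; class distributions are compared by two-sample KS.
- **Meiotic-fraction estimator.** Modelling the aggregated meiotic-DSB signal
  at NAHR breakpoints as a mixture of a meiotic component (signal 1, capture
  fraction f_m) and an HDR background component (signal b, capture f_s):

      f_m·x + b·(1 − x)·f_s = S_obs  ⟹  x = (S_obs − b·f_s) / (f_m − b·f_s)

  With S_obs = 0.08 and b = 0.04 the estimate stays in ≈ [0.04, 0.125] for
  any capture fractions in [0.5, 1.0].

## Worked example

```python
import svchrom as sc
from svchrom.aggregation import peak_aggregation
from svchrom.regression import estimate_from_profiles

world = sc.generate_world(sc.WorldConfig(seed=0))   # synthetic genome + truth
df = sc.enrichment_zscores(
    {m: world.svs[m] for m in ("NAHR", "NHEJ")},
    world.compartments, world.layout, n_perm=1000, seed=1,
)
print(df[["mechanism", "label", "observed", "z", "p_adj"]].round(3).to_string(index=False))
```

```
mechanism label  observed      z  p_adj
     NAHR    A1     0.242  4.194  0.000
     NAHR    A2     0.357  3.790  0.002
     NAHR    B1     0.105 -1.494  1.000
     NAHR    B2     0.123 -3.351  0.008
     NAHR    B3     0.173 -3.274  0.011
     NHEJ    A1     0.138 -1.499  1.000
     NHEJ    A2     0.188 -3.494  0.005
     NHEJ    B1     0.106 -1.289  1.000
     NHEJ    B2     0.248  2.758  0.058
     NHEJ    B3     0.321  3.152  0.016
```

NAHR breakpoints are significantly enriched in the open A1/A2 compartments
and depleted in closed chromatin, while NHEJ shows the opposite pattern —
the planted biases of the synthetic world, recovered by the permutation
test. Continuing with the estimator on the same world (true planted
meiotic fraction 0.10):

```python
anchors = [bp for sv in world.svs["NAHR"] for bp in sv.breakpoints]
nahr_prof = peak_aggregation(anchors, world.meiotic_dsb, chrom_lengths=world.layout.lengths)
controls = [peak_aggregation([bp for sv in world.svs[m] for bp in sv.breakpoints],
                             world.meiotic_dsb, chrom_lengths=world.layout.lengths)
            for m in ("NHEJ", "NHrepl")]
est = estimate_from_profiles(nahr_prof, controls, f_m=1.0, f_s=1.0)
print(f"S_obs={est.s_obs:.4f} background={est.background:.4f} x={est.x:.4f}")
```

```
S_obs=0.1496 background=0.0585 x=0.0967
```

The meiotic-DSB signal at NAHR breakpoints (0.150) exceeds the NHEJ/NHrepl
background (0.059), and the mixture model attributes x ≈ 0.097 of NAHR
deletions to meiotic DSBs — recovering the planted 10%.

The same stages are available from the shell:

```sh
svchrom make-synthetic --seed 0 --out world/
svchrom enrich --svs world/svs.tsv --track world/compartments.bed \
       --layout world/genome.chrom.sizes --n-perm 1000 --seed 1 --out enrich.tsv
svchrom run-all --synthetic --seed 7 --out run/
svchrom meiotic-fraction --fm 1.0 --fs 1.0 --range 0.5,1.0
```

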