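# Methods

This note documents the models and procedures `svchrom` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Coordinate conventions

All coordinates are 0-based half-open (BED convention) internally; readers
accept 1-based inputs via a flag, since published SV tables vary. A point at
a segment boundary belongs to the segment whose half-open interval contains
it — deterministic, with no double counting. Length windows quoted as ranges
(non-variable Alu selection at 280–350 bp, Alu/L1 deletions at 250–450 bp)
are inclusive on both ends. The linear coordinate system concatenates
chromosomes in layout order; it is a bijection between (chrom, pos) pairs
and [0, total length), which the permutation engine relies on.

## Circular-permutation null model

The null hypothesis for every enrichment statistic is "the SV set as a
whole, with its internal spacing intact, placed anywhere on the genome".
Each replicate draws one offset uniformly from [1, L−1] (L = total genome
length) and shifts every SV by it around the circularized genome; 1000
replicates by default. The permutation unit is deliberately the whole set —
per-SV independent shifts would destroy SV clustering and understate the
background variance.

An SV pushed across a chromosome junction (or the genome end) keeps its two
breakpoints at their mapped positions and is treated as the per-chromosome
pieces of its circular arc. For containment statistics (TAD boundaries, loop
anchors) a point is contained when it lies strictly inside a piece's open
interval; a point exactly at a junction is therefore never contained.

Z scores are (observed − background mean)/background sd; a zero background
sd leaves Z undefined (reported as missing, never ±inf). p-values are
two-sided normal (a Z-test, not the empirical permutation p), Bonferroni-
corrected over all (mechanism × category) tests issued in one call. The
deleted-region variant (`unit="region"`) scores bases of each deletion per
label via per-label coverage prefix sums instead of breakpoint counts.

Clustering of mechanisms by Z profile uses Euclidean distance with average
linkage (the choice is recorded in the result object and easily swapped);
replication-time clustering uses the two-sample KS D statistic as the
pairwise distance.

## Simulated NAHR

The homology search replaces an external aligner with an exact-12-mer-seeded
ungapped extension: candidate diagonals are positions sharing any 12-mer
with the 100 bp seed; each diagonal is scored by a Kadane-style best-segment
scan (match +1, mismatch −1) and the segment's identity is matches /
alignment columns. Retained pairs must be same-orientation, alignment
length > 50 bp, identity > 85%, and lie 100 bp–1 Mb from the seed (measured
start-to-start; the same quantity serves as the implied deletion length).
The aligner is gapless by design: the synthetic world plants homology as
substitution-mutated copies, for which gapless extension is exact, and a
hook accepts precomputed pair files for users with external alignments.
Only same-chromosome targets are considered (the 1 Mb separation cap makes
cross-chromosome neighbours a measure-zero edge case on real genomes).

Length matching uses rejection sampling against the empirical NAHR
deletion-length density on 25 log-spaced bins (NAHR lengths span orders of
magnitude); a pair of implied length ℓ is accepted with probability
density(ℓ)/max density. Compartment matching treats each simulated event as
one unit anchored at its origin breakpoint (the sampled seed is the
accept/reject unit throughout the simulation); per-compartment counts follow
largest-remainder rounding of the real NAHR breakpoint proportions, and
selection is uniform without replacement within compartments, with an
explicit per-compartment deficit error when a pool is too small.

## Aggregation profiles

Bins are half-open on a grid anchored at the breakpoint: bin k covers
[pos + k·b, pos + (k+1)·b), so offset 0 labels the first bin to the right
and "the value at the breakpoint" is defined as the mean of the two bins
flanking 0. Peak profiles are the fraction of bin bases covered by ≥1 peak
(2.5 kb window, 100 bp bins; 10 bp bins at regulatory-site midpoints,
midpoint = (start+end)//2), averaged over anchors; bins truncated by a
chromosome end contribute available bases over the full bin width. Signal
profiles average available bases per bin (missing bases leave both numerator
and denominator), divide by the number of anchors with any signal, then by
the mean over the 2 kb around the anchor — a flat track reads exactly 1.0.
For deletions both ends contribute as anchors; for retrotransposed elements
and pseudogenes, profiles anchor at element starts (upstream only) and ends
(downstream only) to avoid length-conservation bias, with the interior
reported as a single mean on the same normalization scale.

Replication time per breakpoint is the mean over the 1000 bases centred on
it (500 each side), truncated at chromosome ends.

Two deterministic classifiers: non-homologous deletions are NHrepl when
micro-homology > 2 bp or micro-insertion > 10 bp, NHEJ when both are zero,
and ambiguous (excluded downstream) in between — the ambiguous band is
whatever the two definitions leave uncovered, with no invented thresholds.
A processed pseudogene's length is "close" to nucleosome periodicity when
length mod 150 falls in [0, 50] or [100, 150); the upper boundary is open
because a remainder of 150 cannot occur, and 50 is included as the only
self-consistent reading of a 0–50 band.

## Hi-C normalization cascade

Raw symmetric intra-chromosomal count matrices (text triples plus a
resolution header) are balanced by a Newton-type Knight–Ruiz iteration so
all unmasked row sums equal 1; fully zero rows are masked automatically and
a row-count threshold for additional masking is configurable (at synthetic
scale only zero rows need masking; real Rao-style matrices warrant sparsity
filtering, and MAPQ ≥ 30 read filtering is assumed upstream). The balanced
matrix is divided by the distance-expected value (mean over unmasked pairs
at each bin distance); distances backed by fewer than 10 unmasked pairs have
undefined expected values and SVs landing there are excluded and reported.

The compartment/distance profile is the mean obs/exp over pairs whose two
bins share a compartment label (mixed pairs excluded), pooled over
chromosomes. An SV's interaction value is obs/exp at its two end bins
divided by the profile at (shared label, distance). When the two ends lie in
different compartments the divisor falls back to the distance-specific mean
pooled over all same-compartment pairs — a recorded package decision, since
the treatment of mixed-end SVs is otherwise unspecified. SVs ≤ 5 kb, SVs
whose ends share a bin, and SVs touching masked bins are excluded. The
cascade is neutral by construction: on a pure distance-decay matrix, SV
values have median ≈ 1 regardless of which compartment the SVs occupy.

## Regression and the meiotic-fraction estimator

Bin fractions put each point set on the compartment-bin grid; peak sets
enter as midpoints, SVs as both breakpoints (the least ambiguous reduction
for each). OLS (with intercept) is fitted singly and jointly; collinear
designs raise an error naming the dependent columns. Discordant bins are
those whose residual deviates from the residual mean by more than k = 3
standard deviations, with the sign distinguishing under- from
over-prediction.

The estimator treats the aggregated meiotic-DSB signal at NAHR breakpoints
as a two-component mixture (see README for the closed form). S_obs is the
NAHR profile's breakpoint value, the background b is the mean breakpoint
value of the NHEJ and NHrepl control profiles, and f_m, f_s are the capture
fractions of the meiotic and spontaneous DSB experiments. An estimate
outside [0, 1] is reported with a model-violation warning, never silently
clamped. Because no single (f_m, f_s) is privileged, the range of x over a
capture-fraction box (extrema over a dense grid; they sit at the corners
since x is monotone in each argument) is reported alongside any point
estimate.

## The synthetic world

Defaults are desk scale: 4 chromosomes × 5 Mb, 100 kb compartment bins
(labels A1/A2/B1/B2/B3 at proportions 0.15/0.25/0.15/0.15/0.30), 10 kb
contact resolution — every stage completes in seconds. Planted structure:

- DNase peaks (300 bp) at compartment-dependent densities (60/Mb in A1 down
  to 8/Mb in B3); 30% carry a TF binding site at their midpoint.
- Spontaneous DSB peaks (400 bp, n = 3000): 70% centred on TF-occupied
  DNase sites, the rest uniform.
- Meiotic DSB peaks (1.5 kb, n = 800) with a weak 1.5× B1 bias.
- Homologous repeat pairs (300 bp copies, 95% identity, 20–500 kb apart,
  substitution-only mutations) at A-enriched densities; sequence is
  generated lazily (random background with the pair copies overlaid, plus
  one 10 kb N-gap per chromosome), so only homology-search stages pay for it.
- NAHR deletions sit exactly on repeat pairs (both breakpoints are pair
  members), selected with probability proportional to the number of
  spontaneous DSBs within 5 kb — the HDR coupling. A Bernoulli(x_true = 0.10)
  subset is flagged meiotic and gets a meiotic DSB peak centred on each
  breakpoint; the remaining (HDR) deletions get spontaneous DSB peaks at
  rate 0.8. Other mechanisms get planted compartment biases (NHEJ/NHrepl 2×
  B2/B3, etc.) and log-uniform lengths in 0.5–50 kb.
- Contact matrices: Poisson counts around an expectation proportional to
  (d+1)^(−1), scaled to 1000 at the diagonal, with a 1.5× same-compartment
  boost, a 2× boost on NAHR breakpoint bin pairs, and 2% unmappable bins.
- Replication timing: compartment means (+1.5 in A1 to −1.5 in B3) plus
  N(0, 0.3) noise at 1 kb steps; nucleosome signal: a phase-jittered 150 bp
  sinusoid at 5 bp steps.

The generator's capture fractions are implicitly 1 — every planted peak is
"observed" — which is what makes f_m = f_s = 1 the known values in recovery
runs. The truth record (planted enrichments, x_true, per-NAHR provenance) is
written to a separate `truth.json` that no analysis stage reads.

What the world does **not** emulate: realistic sequence composition or
repeat families (so homology-search sensitivity on real genomes is not
certified by these tests), indel divergence between repeat copies (the
aligner is gapless), read-level noise or peak-caller artefacts, loop/TAD
contact structure beyond planted boundary points, and inter-chromosomal
contacts. Passing tests therefore demonstrate correctness of the statistics
and recoverability of planted effects at desk scale, not performance on
full-size human data.

## Problem sizes and reproducibility

Default analysis sizes are those above: 1000 permutations, 12 000 homology
seeds for the simulated-NAHR stages, 20 independent worlds for calibration
and recovery checks. One global seed expands into fixed per-stage seeds
(via spawn keys on a seed sequence) so any stage can be rerun in isolation;
every stage is bit-reproducible given its seed, and the pipeline manifest
echoes all seeds and parameters consumed.

## Known limitations

- The Bonferroni family is the set of tests issued in one call; callers
  combining panels must correct across calls themselves.
- The KR implementation targets dense matrices at synthetic scale; very
  large (≥ 10⁵-bin) chromosomes would need a sparse backend.
- `chromHMM`-style state tracks are structurally supported (any labeled
  segmentation works in the enrichment engine) but the generator plants
  only compartment labels.
- The estimator's background term multiplies b by f_s as printed in its
  closed form; when b is measured from control profiles it already reflects
  experimental capture, so f_s ≠ 1 double-counts capture slightly. The
  package reports the range over a capture box rather than a single
  headline value for exactly this reason.
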