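# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would want to know.

## Coordinates and scale

All internal coordinates are 1-based inclusive (SAM convention); BED files
are converted to/from 0-based half-open at the I/O boundary. The default
synthetic world is a single 2 Mb chromosome that shrinks the published
geometry of the *Arabidopsis* ring-mini system by one linear factor of 10:
the 13–19 Mb mini source region maps to 1.3–1.9 Mb, the CENH3 centromere
15–17 Mb to 1.5–1.7 Mb, and the ~1.3 Mb internal deletion at 16–17.3 Mb to
1.6–1.73 Mb. Bin sizes used for dosage profiles (25 kb) and pattern
clustering (100 kb) scale with the genome (2.5 kb / 10 kb); parameters that
describe *reads* rather than the genome — the 2000 bp minimum split-segment
separation, the 5 kb pseudo-junction bins, the 1 kb/10 kb enrichment
windows — are used unscaled, because read length, insert size and depth are
simulated at their real values (150 bp paired-end, ~400 bp inserts, 10×).

## Synthetic worlds

`generate_reference` draws a uniform-random base sequence and places gene
and repeat tracks by alternating gamma-length features (shape 4, mean
1.5 kb) with drift-corrected gaps, so the realized covered fraction tracks
the request within a few percent even in 100 kb regions. Defaults give the
annotation contrast the enrichment stage needs: repeats 60% inside the
centromere analog vs 10% outside; genes 5% vs 35%. Diagnostic SNPs (default
1 per 500 bp, an ecotype-cross scale) store a background allele (equal to
the reference base) and a mini-haplotype allele.

`build_mini` composes a ring as a circular chain of oriented segments via a
breakpoint-graph walk. Every junction — circularization, the deletion
adjacency, and user-injected extras — is one oriented adjacency
`(pos_a, side_a, pos_b, side_b)` where `side` names the retained flank;
an inversion is supplied as its two adjacencies. The walk starts at the
region start, stops at each retained flank, jumps to the partner flank and
continues in the implied direction; configurations whose adjacencies do not
compose into a single circle with disjoint segments raise
`InvalidConfiguration`. Orientation classes: left+right = head-to-tail
(both colinear directions folded together), left+left = tail-to-tail,
right+right = head-to-head.

`simulate_individual` emits the diploid background at depth *d* and each
mini copy at *d*/2 (one haplotype-copy's worth), so the expected normalized
dosage over retained mini bins is `2 + copies`. Fragments are
normal(insert, 0.1·insert) truncated below at the read length; reads are
error-free by default (a uniform substitution rate is available) because
sequencing error is not what this pipeline studies. A read crossing a
junction is emitted the way a short-read aligner reports it: the longest
mapped piece as a soft-clipped primary record, other pieces ≥ 20 bp as
supplementary records with `SA` tags (pieces shorter than 20 bp — about the
minimum seed of common aligners — are silently clipped). Identical seeds
give byte-identical SAM streams.

What the generator does **not** emulate: GC- or mappability-dependent
coverage, indels and alignment artifacts, chimeric PCR duplicates,
repeat-induced mismapping (reads are placed at their true origin), and the
unmappable centromeric-array junction of the real system. A green test on
synthetic data therefore establishes the correctness of the *computations*,
not robustness to alignment noise in repeat space.

## Dosage model

`bin_coverage` counts each primary alignment once, at its leftmost mapped
position (supplementary/secondary records are skipped). Count-based binning
rather than per-base pileup matches the normalization that follows and is
insensitive after it.

`normalize_dosage` forms per-bin count ratios `r_b = s_b / c_b` against a
non-carrier control (bins with zero control count become missing, never 0)
and rescales so the euploid level sits at the diploid convention of 2. The
default anchor is the **dominant mode** of the ratio distribution,
estimated by an iteratively re-windowed median (3 passes, ±25% relative
window — half a one-copy ratio step). Rationale: with a 0.6 Mb mini on a
2 Mb toy genome, mini bins are ~30% of all bins, which biases both
total-read scaling (~15%) and the plain median (~6%); the windowed-median
mode stays on the euploid peak with √n efficiency. At a realistic scale
(6 Mb mini in a 135 Mb genome) all three scalings agree within ~2%, and
`scaling="total"` / `"median"` remain available.

`classify_mini_type` compares mini-region dosage to six templates built
from copy arithmetic — retained level `2 + n_full + n_deleted`, deletion
interval `2 + n_full` — with fractional expectations for bins partially
covering region or deletion edges; distance is the mean absolute deviation
and > 20% missing bins makes a sample unclassifiable. The template
classifier is the primary caller; `pca_cluster` (PCA of mini-region dosage,
Ward linkage, cluster count by silhouette over k ∈ [2, 8], k = 1 reserved
for numerically identical profiles where silhouette is undefined) is
exploratory, since there is no published rule for labeling clusters.
`estimate_deleted_interval` reports the longest run (≥ 2 bins) of bins more
than 0.5 dosage units — half a copy step — below the region median.

## Junction calling

Split segments of a read are ordered by their offset in the sequenced read;
each consecutive pair whose inferred breakpoints lie ≥ 2000 bp apart
(boundary inclusive) or on different chromosomes yields one evidence item,
with breakpoints at the clipped segment ends. Evidence agreeing within
10 bp on both sides (and in orientation) merges into a candidate at the
member-median position; 10 bp is ample for exact-coordinate synthetic data
and tolerates micro-homology wobble on real data.

The support floor is the pseudo-junction threshold: the mean number of
primary alignments spanning an internal 5 kb bin boundary, halved, because
a genuine novel junction lies on one of two homologous copies. Thresholds
are computed per sample and a candidate passes if its support in at least
one carrier reaches that carrier's own threshold **and** it has zero
supporting reads in every control. Note a structural asymmetry this
inherits from the source method: threshold boundaries count *any* spanning
read, while split evidence needs ≥ 20 bp mapped on both sides, so a
single-copy junction's expected support is ~0.74 of one haplotype-depth and
sits slightly *below* the threshold; junctions on two-copy minis clear it
comfortably. Orientation uniformity over the three classes is tested by a
chi-square goodness of fit with df = 2.

## Validation and haplotype assignment

Cross-junction reads are assembled greedily by maximal exact suffix–prefix
overlap (≥ 20 bp, both orientations of both pieces considered, contained
reads absorbed, ties broken lexicographically); with short, error-free,
single-junction read sets this matches the exhaustive merge-order optimum,
which the test suite checks. A contig validates against a junction when it
aligns (local alignment, match 1 / mismatch −2 / gap −4,−1) at ≥ 0.95
identity to the expected chimeric flank sequence with ≥ 30 bp on each side
of the junction point and within ±50 bp positional slack — and does *not*
align contiguously (≥ 95% of its length) to a single reference locus,
which is the signature of a false candidate. Anchor length, identity and
slack are this package's choices; no published values exist.

Haplotype assignment inspects the junction's split reads and their mates
within ±1 kb of either breakpoint, tallies mini vs background alleles at
diagnostic SNP sites, and calls `mini_haplotype` when ≥ 2 reads carry mini
alleles and none carry background alleles (symmetrically for
`background`); everything else — including zero covered informative
sites — is `indeterminate`. With error-free reads a determinate call cannot
be wrong; the practical failure mode is indeterminacy when the ±150 bp
read footprints contain no SNP.

## Enrichment statistics

Feature tracks are merged before counting so overlapping annotation records
are not double-counted. Window density is feature bases in
`[pos − w/2, pos + w/2)` divided by the (end-truncated) window span. The
null draws `n_pseudo = 10,000` uniform positions from the control region
(default: the 1.3–2.0 Mb analog of the pericentromeric 13–20 Mb block) per
repetition, `reps = 1,000` repetitions, vectorized over a coverage prefix
sum. Both breakpoints of every junction enter the real set independently.
The ratio divides the mean real density by the null grand mean; the
one-sample t-test compares per-breakpoint real densities to that same
grand mean (two-sided) — the grand mean serves both roles because the
source method is ambiguous about whether the repetition distribution feeds
the test. Identical real densities make the t-test degenerate; p is then
reported as 1 with a warning rather than NaN. Gene-body disruption uses an
upper-tail binomial with success probability equal to the gene-base
fraction of the region — the simplest null consistent with the reported
analysis, which does not name its model.

## Pipeline defaults

| parameter | default | note |
|---|---|---|
| depth | 10× | cohort screening depth |
| read length / insert | 150 bp / 400 bp | paired-end |
| profile / cluster bins | 2.5 kb / 10 kb | scaled analogs of 25/100 kb |
| pseudo-junction bin | 5 kb | unscaled (read-scale quantity) |
| min split separation | 2000 bp | boundary inclusive |
| cluster tolerance | 10 bp | merge radius per side |
| enrichment windows | 1 kb, 10 kb | |
| null size | 10,000 × 1,000 | pseudo-breakpoints × reps |
| α | 0.05 | significance marker |

A pipeline run is reproducible from its config and seeds alone; the report
carries a config digest and all per-sample thresholds. The command-line
interface is a thin layer over these functions (exit codes: 0 ok,
2 configuration error, 3 input format error). Plotting is deliberately
omitted: the dosage TSV loads directly into any plotting tool, and no
figure is part of the computational contract.

## Known limitations

- The dosage anchor assumes euploid bins dominate (< ~40% copy-variant
  genome); whole-genome aneuploidy would need an external anchor.
- Junction detection uses split reads only (no discordant-insert signal),
  so events whose breakpoints fall in unmappable repeat arrays are
  invisible — as in the real system's centromeric-array deletion.
- The haplotype caller reads alleles through simple M/S CIGARs; indel
  alignments would need per-base aligned-pair mapping.
- The assembler is exact-overlap greedy: adequate for error-free or
  near-error-free cross-junction read sets, not a general-purpose
  assembler.
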