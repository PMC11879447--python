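# Methods

## Coordinates and interval algebra

All internal coordinates are 0-based half-open (BED-native). GFF3's
1-based inclusive convention is converted at the parsing boundary, where
TSS/TES are resolved by strand (TSS is the 5' end, so for a minus-strand
gene the TSS is the larger coordinate). Chromosome names are matched by
exact string equality; no "chr" aliasing is attempted.

Merging unions overlapping **and bookended** intervals ([1,5) + [5,9) →
[1,9)), matching the default of the common BED merge utility; this choice
propagates into the "mutually exclusive region" counts downstream, which
would differ slightly under a strict-overlap merge. Reciprocal overlap at
fraction f keeps an interval of A when some interval of B shares at least
f·len(A-interval) and f·len(B-interval) base pairs. The merge, intersect
and complement routines are implemented in-package (the conventions are
contract-bearing here) and are validated in the test suite against a
per-base coverage bitmap and cross-checked against the `bedtools` CLI.

## Mirror-repeat scanning

Definition: for every arm/arm boundary position p in 0..len(seq) and every
spacer length s in 0..max_spacer, the arms extend maximally outward — the
largest k with seq[p−1−i] = seq[p+s+i] (case-insensitive) for all i < k,
stopping at sequence edges and at any non-ACGT character. One repeat is
reported per (p, s) with k ≥ min_arm, spanning [p−k, p+s+k). Consequences
of this convention:

- Nested shorter arms at the same center are not reported separately
  (extend-from-center maximality).
- Overlapping repeats from distinct (p, s) are all reported, so the raw
  motif count exceeds the merged-region count.
- Any motif whose span contains a character outside {A,C,G,T} (any case)
  is discarded; ambiguity codes never match during extension.
- Soft-masked (lowercase) sequence is treated identically to uppercase.

Published genome-wide motif counts from other annotation tools are
sensitive to their (undocumented) sub-repeat enumeration and deduplication
conventions; this package documents its own convention above and treats
exact reproduction of other tools' counts as out of scope.

The scanner is vectorized (numpy): for each spacer, all boundary positions
extend in lockstep and positions drop out at their first mismatch, so
total work is O(n + Σ arm lengths) per spacer — about 15 s for 10 Mb on
one core. `oracle_scan` recomputes the same output by direct per-center
character comparison in pure Python and is used throughout the tests as an
independent reference; it refuses inputs beyond 5 kb.

Defaults (all CLI-exposed): min_arm = 10 bp, max_spacer = 7 bp (spacer
< 8), min_purity = 0.90, max_at = 0.80, max_arm unlimited.

## H-DNA classification

purity = max(AG fraction, CT fraction) computed over the **whole motif**
(arms + spacer), not arms only: the filter applies to sequences, and a
≤7 bp spacer cannot move a ≥21 bp motif across the 90% threshold by more
than about one letter. The thresholds are purity ≥ 0.90 (inclusive) and
AT fraction < 0.80 (exclusive at 0.80, i.e. motifs with ≥ 0.8 AT are
excluded). The filter is strand-symmetric: AG-rich on one strand is
CT-rich on the other, and taking the max of the two fractions makes the
H-DNA set invariant under reverse complement (verified as a property
test). Whether the spacer itself must lack symmetry is not enforced.

## STRs and G-quadruplexes

The STR scanner implements a transparent exact-tandem definition: all
maximal runs with primitive unit length 1–9 bp and ≥ 2 full copies (the
final copy may be partial), no mismatches; a run is reported once, under
its smallest period. This replaces dedicated tandem-repeat finders whose
parameters are tool-internal; bp-overlap fractions between H-DNA and STR
tracks therefore approximate, not reproduce, numbers derived from those
tools.

G-quadruplex propensity uses the canonical G/C-run score: each base in a
run of L consecutive Gs scores +min(L, 4), C-runs score −min(L, 4), other
bases 0 (the complement strand's array is the exact negation). Regions
are called where a sliding-window mean reaches the threshold on either
sign, overlapping qualifying windows are merged, and the merged span is
trimmed to the longest sub-span whose mean still meets the threshold.
Defaults: window 25 bp, threshold 1.5 — the published defaults of the
windowed G/C-run method; both are CLI-exposed, and results depending on
them should be read as sensitive to that choice.

## Densities, bins, folds

Density is motif bp over region bp (reported per kB) plus merged-region
count per Mb; motifs are merged first so overlapping motifs contribute
each base once (merged regions are the density currency; raw motif counts
are reported alongside). Chromosome bin profiles use
bin(x) = 1 + floor(N·x / chrom_size), N = 2000, clamped to [1, N] so the
legal half-open end coordinate x = chrom_size falls in the last bin; a
motif whose start and end land in different bins increments every
intermediate bin. rDNA-array profiles use N = 3500 bins in array-relative
coordinates with count-over-total normalization and 18S/5.8S/28S overlay
bin ranges. Fold enrichment = (fraction of motifs in region)/(fraction of
genome); note it saturates at 1/(genome fraction), so it is only a sharp
readout for small regions. For planted-fold recovery on synthetic data the
package instead compares array vs background (complement) densities
directly, which is bound-free.

Fisher's exact test is applied at site level ({sites in region, sites
elsewhere} × {≥1 motif overlap, none}); a bp-level table can be built from
the same primitives but is not the default, since site-level is the
construction used in the enrichment analyses this package supports.

## Positional metaprofiles

Anchors are (chrom, position, strand) triples; peak anchors are the floor
of the interval midpoint. The profile counts motif bp at each signed
offset in ±half_window (default 3000), flipping signs for minus-strand
anchors, and divides by the window mean (mean enrichment = 1 when
defined). Window parts beyond the chromosome edge contribute nothing
rather than discarding the anchor. Bootstrap bands resample anchors with
replacement (N = 1000 default) and take the empirical 0.025/0.975
quantiles of the per-position enrichment; a seed is mandatory, and equal
seeds give bit-identical bands. The maximum-enrichment classification
reports the peak offset and whether |offset| ≤ 250 bp, ties resolving
toward the smallest |offset| (negative side first on exact ties).

Arm PWMs collect first-arm sequences of motifs intersecting any anchor
window, take the modal arm length L, and compute per-position base
frequencies over arms of length ≥ L truncated to L (shorter arms are
excluded rather than padded).

## Synthetic genomes

The generator emulates the structure the analysis assumes, not real
sequence evolution: an i.i.d. background at 41% GC (human-like), five
50 kb rDNA-like arrays (5 kb unit × 10 exact tandem copies) on a 10 Mb
chromosome, each unit carrying 18S/5.8S/28S placeholders and three CT-rich
H-DNA motifs (arm CTCTCTCTGT, spacer C — reconstructing the modal rDNA
21-mer) at fixed intergenic-spacer offsets, so the planted signal is
periodic at the unit length. Background plantings are sized so the
array-vs-background motif density ratio equals `array_fold` (default 40×,
the enrichment scale reported for human rDNA arrays). Mirror-only plants
(mixed-composition arms) and decoys (near-mirror with a broken second arm)
exercise the classifier's negative paths.

Every planted locus is validated at generation time against the scanner:
planted H-DNAs must be recoverable at their exact coordinates, and decoys
must not overlap any detectable mirror repeat; offending flanks (12 bp a
side) are redrawn locally until validation passes. At the default scale,
unplanned chance motifs elsewhere in the background are allowed (about
10⁻⁵ per position per spacer for arm ≥ 10 in random sequence, and far
rarer after the compositional filter), and recovery is judged on planted
loci only. What passing recovery tests shows is that the scanner and the
coordinate bookkeeping are exact; it does not show robustness to real
genomic features the generator omits — mutation-degenerate repeats,
soft-masked assembly artifacts, compositional heterogeneity, or
chromosome-scale GC gradients.

Synthetic peaks center a stated fraction on planted motifs (±10 bp
jitter), draw the rest uniformly, and assign q-values so an exact count
passes the strict q < 0.005 filter.

## Problem sizes and numerical choices

The test suite and the acceptance script run on synthetic genomes of
0.2–10 Mb; the bootstrap calibration study uses 500 replicates of 200
Gaussian units at N = 1000 (percentile intervals are first-order accurate,
and their small-sample undercoverage is visible below ~100 units, so the
study size sits where the nominal level is meaningful). The null-profile
calibration bins the ±3 kb window into thirds before checking that the
bootstrap band covers 1: per-bp offsets are too sparse for a meaningful
band, and a small number of bins keeps the joint "all bins" check
compatible with 95% pointwise intervals. Degenerate inputs are flagged
rather than guessed at: zero-length regions, empty motif sets and
all-zero windows yield NaN densities/enrichments, and the all-zero Fisher
table returns (NaN, NaN).

## Known limitations

- Mirror arms are exact; mismatch-tolerant arms, other non-B classes
  (Z-DNA, cruciforms, slipped structures) and thermodynamic triplex
  stability are out of scope.
- Genome-wide counts from full assemblies depend on the scanning
  convention (see above) and on upstream annotation tracks consumed as
  BED; the package computes the quantities but does not claim numeric
  identity with other tools' outputs.
- BAM/CRAM, VCF and binary browser formats are not read; ChIP-seq peak
  calling, liftover and repeat masking are upstream of this package.
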