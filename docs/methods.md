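# Methods

## The deletion transcriptome

For one gene, the reference is the canonical transcript plus every transcript
obtained by removing a single consecutive run of internal exons. Edge exons
are excluded because splicing events do not occur beyond the transcript ends;
their loss is better seen by exon/gene-level expression analysis. For N exons
the internal runs are all (i, j) with 2 ≤ i ≤ j ≤ N−1, i.e. C(N−1, 2)
transcripts, enumerated in ascending (i, j) order and named `del{i}`/
`del{i}_{j}` with ordinals in transcript orientation. A gene needs N ≥ 3 for
any deletion to exist; the builder warns and emits nothing below that.

Coordinates are BED-style throughout (genomic 0-based half-open, transcript
0-based). On the minus strand, exon 1 is the 5′-most exon (highest genomic
coordinate): transcript orientation is the only convention under which "first
and last exon" is biologically meaningful, and all enumeration uses it. Each
record in the BED12 input is treated as one independent gene with one
canonical transcript; GTF/GFF input and multi-isoform canonical models are
out of scope. Each deletion transcript records its `junction_offset`, the
transcript coordinate of the first base after the novel junction; it is used
by the analytic oracles and reporting, not by the mapper itself.

## Index

The contract is a plain hash map from k-mer to the set of transcript ordinals
containing it, over forward-strand k-mers only; reads are queried in both
orientations. A compacted De Bruijn graph would be an optimization with the
same semantics, which a single-gene reference (tens of kb) does not need.
k defaults to 31, standard for pseudoalignment; it must be below the read
length, and junction discrimination needs roughly k ≤ read length − overhang.
k-mers containing non-ACGT characters are skipped at build and query time.
Exons shorter than k−1 are allowed at build time (junction k-mers may then
span three exons); with ≥ k−1 bp flanks every deletion has at least one
uniquely mapping junction k-mer, a property the tests check.

Serialization stores k, the transcript records (IDs, gene, lengths,
sequences) as versioned gzipped JSON and rebuilds the k-mer map on load;
round-trip identity of the map is tested.

## Mapping

A read's equivalence class is the intersection of the transcript sets of its
matching k-mers, computed in the orientation (forward or reverse complement)
with more matching k-mers, ties preferring forward. An empty intersection or
no matching k-mer means unmapped; reads shorter than k are unmapped and
tracked separately. ECs spanning transcripts of different genes are discarded
as ambiguous — the method is targeted, not a competitive multi-gene aligner.

Reads with a singleton EC are the deletion signal and get two extra checks:

* **Full coverage.** The read is anchored by any exact-matching k-mer and
  Hamming-compared end-to-end against the transcript at the implied offset;
  it must fit entirely within the transcript with at most `mismatch`
  substitutions (default 2). Indels are not modelled. A read failing this is
  demoted to the gene-level (non-unique) EC rather than dropped — it is still
  expression evidence.
* **Trim test.** With `trim` bases (default 5) removed from each end the read
  must re-classify to the *identical* singleton EC. This removes reads whose
  junction support is a small end-overhang or soft-clip-like artefact, and
  guarantees mismatched bases are never the sole junction evidence — hence
  the constraint trim ≥ mismatch, enforced at parameter construction.
  Strict EC equality means a read needs strictly more than `trim` bases on
  each side of the junction to survive, i.e. the effective minimum overhang
  is trim + 1; with the default trim 5 this is within one base of the
  nominal 5 bp overhang rule, and the `min_overhang` parameter is kept for
  reporting and the analytic oracles rather than as a separate check.

For pairs, the mate with the smaller EC determines the pair (uniqueness is
favoured); identical ECs merge trivially; equal-size differing ECs are
intersected but kept non-unique even if the intersection is a singleton,
since neither mate individually passed the unique-read checks; disjoint ECs
demote the pair to gene-level. A pair counts once.

Tallying: UC[d] = reads/pairs uniquely and robustly supporting deletion d;
TC = all *other* mapped reads/pairs of the gene, trim-failures included.
"Total" therefore excludes UC — the two are disjoint and
UC total + TC = mapped reads exactly (a conservation law the tests assert).

## Quantification

scaled = (UC/TC) × L_gene / (L_read × 2 if paired else L_read), with L_gene
the canonical transcript length (not the genomic span). The read length is
user-nominated, defaulting to the mode of observed lengths. Rows with TC = 0
are emitted with zero proportions and a `low_expression` flag so cohort
matrices stay rectangular. Proportions are written at full floating
precision.

The scale factor is a length heuristic, not an unbiased abundance estimator:
roughly, UC/TC ≈ p·L_read/L_del (p the deletion isoform's read fraction), so
the canonical-length scaling over-estimates p by about L_gene/L_del. For a
single-exon deletion this bias is small (~15% in the tested 8×200 bp
geometry) and the recovery-within-factor-2 property holds across
p ∈ [0.05, 0.9]; for a half-gene deletion like del4_7 it approaches 2×.
Scores are monotone in p and depth-free in expectation either way, which is
what the cohort layer consumes.

## Cohort statistics

Z-scores standardize each deletion column with the sample (n−1) standard
deviation; a zero-variance column maps to all-zero z, and at least two
samples are required. Outliers require z ≥ 3 **and** UC > 10; applying the
count filter per sample-deletion pair induces the deletion-level display
filter (only deletions with at least one outlier are worth showing). Band
boundaries (0.1 / 0.01 / 0.001) are inclusive. The low band is reported with
no further action: at that level single junction reads dominate and false
positives from technical or biological artefact are expected. ROC evaluation
(scikit-learn trapezoid, ties collapsed onto one threshold) is provided for
calibrating thresholds against validated labels; its AUC is cross-checked in
the tests against an exhaustive concordant-pair computation. Single-sample
mode scores a new sample against a frozen background (stored per-deletion
mean/sd) without re-centering the cohort.

## Simulator

The generator emulates a targeted bulk RNA-seq experiment over one gene:
i.i.d. uniform ACGT exons embedded in a toy genome with fixed introns; reads
drawn by choosing a source transcript proportional to its abundance, then a
uniform fragment start; i.i.d. per-base substitution errors (no indels,
matching the mapper's contract). Paired mode draws a fragment and reads both
ends, the second mate reverse-complemented; a pair counts as junction
support if either mate spans the junction with the required overhang.

Deliberately absent: positional/GC/fragmentation bias, indels, quality-value
structure, intron-retention or partial-exon events, multi-gene backgrounds.
Passing tests therefore demonstrate the counting and scoring logic under the
method's own model assumptions, not robustness to every artefact of real
libraries — the trim/mismatch machinery is exercised through controlled
substitution errors and constructed boundary reads.

`expected_junction_reads` gives the exact binomial mean of junction-spanning
reads from geometry alone: E = n_reads × abundance × valid_starts /
total_starts, with a start valid when the read covers the junction with
≥ min_overhang bases on each side (for a 100 bp read and overhang 5 that is
91 of the possible starts). End-to-end tests require mapped UC within 4
binomial standard deviations of this expectation across seeds; suite-level
simulations use 2,000–50,000 reads per sample, sizes at which the binomial
bands are tight enough to be informative while the whole suite stays fast.

## Numerical and degenerate-input choices

* Deterministic everywhere: numpy `default_rng(seed)` in the simulator; the
  mapper is seed-free and byte-stable across reruns.
* Hamming comparison early-exits past the mismatch budget; among candidate
  anchor offsets the minimum-distance one is reported.
* Ties in read-length mode resolve to the smaller length; orientation ties
  prefer forward.
* TC = 0 → flagged zero rows (never NaN); sd = 0 → z = 0; single-class ROC
  labels → error.
* Truncated or foreign index/background files raise typed load errors.

## Known limitations

Substitution-only error model (no indel tolerance in mapper or simulator);
one canonical isoform per gene, so genuine annotated alternative splicing
(e.g. IKZF1 exon-4/exon-6 skipping) appears among the deletion calls and must
be interpreted via the cohort background; the scaled proportion's
deletion-length bias described above; absolute band thresholds transfer to
new genes or cohorts only after re-calibration against validated samples.
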