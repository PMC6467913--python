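# Methods

`svharmonize` implements the bespoke computational calculus behind
haplotype-aware structural-variant (SV) discovery and multi-platform
integration in trio studies: Strand-seq inversion discovery, genotyping and
phase classification; cross-platform inversion unification; multi-caller
breakpoint consensus; long-read/optical-map/depth validation; haplotype- and
method-level SV merging; and caller-combination benchmarking via the
non-concordance rate. Every stage is exercised end to end on synthetic data
with known truth. This note records the models, the parameters that matter,
the numerical choices, and what passing tests do and do not show.

## Strand-seq inversion model

A *composite file* pools oriented reads from many single cells of one
individual. Each read is a point (its 5′ position) with an orientation
relative to the reference and an optional haplotype tag (H1/H2) inherited
from a phased SNV it covers. At a locus, the **read ratio** r = non-reference
reads / total reads is a dosage proxy: r ≈ b on reference homozygotes (b is
the orientation-error background), r ≈ 0.5 on heterozygotes, r ≈ 1 − b on
inverted homozygotes. An inverted duplication with k extra direct copies on
the carrier haplotype produces (1+k)-fold local read density on that
haplotype of which only the 1/(1+k) fraction is inverted, so a het event sits
at r ≈ 1/(2+k) — the depressed intermediate ratios characteristic of complex
events (k = 1 gives 1/3).

**Discovery.** Windows of `window_reads = 250` consecutive reads slide in
steps of `window_step = 50`; a window triggers when its non-reference
fraction exceeds `nonref_trigger = 0.15`, and maximal runs of triggering
windows merge into one candidate. Because windows live in read-index space,
run edges are fuzzy in bp: a run begins up to ~0.7 windows before a het
event. Left as-is, that flank dilutes the locus read ratio (a 5 kb het event
would measure r ≈ 0.36 instead of 0.5, and a goodness-of-fit test against
0.5 would reject it). Boundaries are therefore refined inside the run with a
small `refine_window = 25`-read scan at `refine_trigger = 0.25` (midway
between the 2% background and the het expectation), then trimmed to the
first/last non-reference read. Residual slop is ~10 reads per side, which is
negligible against the binomial noise of any genotypeable locus.

**Genotyping.** The observed (n_ref, n_nonref) is compared against three
exact-binomial models with non-reference proportions {b, 0.5, 1 − b},
b = `background` = 0.02; the genotype is the likelihood argmax, with at
least `min_genotype_reads = 50` reads required. Two-sided exact-test
p-values against each model are always reported. An optional rejection rule
(`reject_alpha`) untypes a locus whose best model is rejected; it defaults
to *off* because it is statistically incompatible with complex inversions:
an inverted duplication at r ≈ 0.31 with hundreds of reads is genuinely
heterozygous, yet any fixed-α test against p = 0.5 rejects it with
probability → 1 as coverage grows. Argmax model selection keeps such loci
het (the closest diploid model) and leaves the complex/simple distinction
to the phase signature, which is the discriminating statistic.

**Phase classification.** Per strand (orientation), the **haplotype ratio**
is #H1/(#H1+#H2) among tagged reads, defined only with
`min_phased_reads = 10` tags. Signatures (bounds `hap_lo = 0.25`,
`hap_hi = 0.75`, strict inequalities):

- *simple_hom*: hom genotype, both haplotypes on the non-reference strand
  (ratio in (0.25, 0.75));
- *simple_het*: het genotype, opposite single haplotypes on the two strands;
  the non-reference-strand ratio > 0.75 phases the inversion to H1 ("1/0"),
  < 0.25 to H2 ("0/1");
- *complex* (inverted duplication): het genotype, a single haplotype on the
  non-reference strand but both on the reference strand.

Known limitation: at k = 3 the carrier contributes 3 of every 4
reference-strand reads, so the reference-strand haplotype ratio sits exactly
at the 0.25/0.75 boundary and the "both haplotypes ≈ 0.5" signature
degrades; high-copy inverted duplications are intrinsically hard for this
classifier, and a small fraction land unclassified.

**Misorient flagging.** Loci matched across individuals at ≥ 50% reciprocal
overlap and genotyped hom-inverted in *every* individual are flagged as
likely reference-assembly misorientations and removed.

## Cross-platform inversion unification

Calls from the five discovery technologies (short-read WGS, long-insert
WGS, long reads, optical maps, Strand-seq) gain support three ways:
(1) > 50% reciprocal overlap with a call from a different platform;
(2) re-genotyping in the composite file at a reduced 25-read threshold
(supported iff het/hom-inverted; < 25 reads = ungenotyped, recorded);
(3) Strand-seq phase classification itself. Supported calls chain into
non-redundant loci by > 50% reciprocal-overlap single linkage. Each locus
carries the outer interval (outermost bounds of all predictions), inner
breakpoints (the bounding span of bases covered by at least half of the
distinct predictions; equal to the outer interval when there is only one),
a consensus genotype (strict majority, one vote per platform, else
"ambiguous"), and a simple/complex class (complex iff a supporting
Strand-seq call is complex or an external copy-number flag is set).
Pericentric loci (overlapping the centromere annotation) and loci with
tandem-repeat fraction > 0.9 are removed; both filters are idempotent.

## Multi-caller breakpoint consensus

Each short-read caller's breakpoint error is profiled empirically: calls are
matched to a base-pair-resolved gold set at > 50% reciprocal overlap, signed
offsets (caller − gold) are collected per side, and the caller's CI is the
[10th, 90th] percentile (linear interpolation between order statistics;
callers with < 30 matches fall back to a configurable ±500 bp default).
Breakpoints whose CIs overlap (closed ends) chain into groups. A group with
a common intersection becomes one cluster with the minimized CI
[max lo, min hi]; otherwise the CIs are stacked, the coverage step function
over sorted unique endpoints is computed, each local-maximum run extended
through its right-neighbor run becomes a candidate CI, and each breakpoint
joins its nearest candidate (ties to the left). The consensus breakpoint is
the modal proposed coordinate, ties broken by the smallest coordinate.
Consensus calls are labeled with precedence telomere/centromere → oversize
(> 1 Mb) → redundancy (a single-algorithm call reciprocally overlapping a
multi-algorithm cluster) → PASS.

**Combination benchmarking.** For combinations of up to three callers
(union-of-two, union-of-three, two-of-three), calls merge across callers at
50% reciprocal overlap and the **non-concordance rate** NCR = 1 −
(fraction of merged calls with orthogonal support) serves as an FDR proxy.
On synthetic callsets with planted false positives and Poisson read-support
evidence (means 20 true / 1 false, > 4-read threshold), measured NCR tracks
the planted FDR to well within 2 percentage points.

## Long-read validation and merging

- **Read haplotype assignment**: per-read haplotype scores are products over
  covered SNVs of (1 − q) for a matching base and q for a mismatch (q =
  base-error probability), compared in log10 space; a read is assigned iff
  the phred-scaled gap 10·|log₁₀ S₁/S₂| exceeds 10, else ambiguous (always
  ambiguous with no SNVs).
- **Contig merging**: local assemblies become DAG vertices; an edge joins
  assemblies in genomic order separated by ≤ 100 kb with overlap alignments
  ≥ 10 kb (overlap defaults to genomic-interval overlap; an explicit
  alignment-overlap map may be supplied). The contig per weakly connected
  component is the path maximizing total spanned (union) length; off-path
  assemblies are absorbed.
- **Read-support validation (PBRC)**: SVs cluster when boundaries lie
  within 250 bp; the cluster's evaluation interval runs 1 kb upstream of the
  first variant to 1 kb downstream of the last variant's end (deletion) or
  start (insertion). A cluster validates with > 4 alt-supporting alignments
  (counting only alignments ≥ 1.5 kb, enforced upstream).
- **Optical-map concordance**: f_BN = |L_BN − L_PB| / L_BN against the
  single candidate minimizing f_BN (summing candidate events was tried by
  the field and concords worse); validated iff f_BN < 0.1, strict.
- **Depth validation (deletions)**: minimum sliding-window mean coverage at
  the SV length must be < 30 (against a 40-fold background).
- **Short-read concordance filter**: a call is concordant if any of
  (1) max length concordance min/max ≥ 0.5 with a long-read or optical-map
  target (sequence targets gathered within 1 kb of the breakpoints; optical
  targets by position-interval overlap), (2) ≥ 3 read-level calls at ≥ 0.7
  concordance, (3) deletion with mean long-read depth < 25, (4) a pluggable
  raw-read predicate, default never-supported (raw-read dotplot realignment
  is out of scope).
- **Haplotype merging**: tandem-repeat loci (annotation padded 20 bp)
  hosting ≥ 6 SVs on either haplotype are set aside whole. Remaining
  cross-haplotype pairs merge as homozygous at reciprocal overlap ≥ 0.10
  outside tandem repeats (breakpoints are reproducible there, so a loose
  threshold merges aggressively) and ≥ 0.50 inside (degenerate alignments);
  insertions pair by anchor distance ≤ 250 bp plus length concordance at
  the same TR-aware threshold. Unmatched calls remain heterozygous.
- **Unified long-read callset**: ordered inclusion of (a) optical-map
  validated representatives (f_BN < 0.1, regardless of read support,
  choosing the method representation by minimal f_BN), then (b) primary-
  method calls with PBRC > 3, then (c) secondary-method calls ≥ 10 kb from
  any primary call; 250 bp boundary windows deduplicate across tiers.
- **Pan-SV integration**: concordant matches link the filtered short-read,
  filtered optical-map and unified long-read callsets; connected components
  become provenance-tagged records partitioning the input, represented by
  the long-read variant when available, else short-read, else optical-map.

## Synthetic data: what it emulates and what it does not

The generator provides a small multi-chromosome genome (default fixture:
2 × 2.5 Mb; the inversion-recovery experiment: 5 × 10 Mb) with a centromere,
tandem-repeat/segdup tracks (uniform placement, exponential lengths) and
het SNVs at exponential spacing (mean 1.2 kb, matching the phased-SNV
spacing of trio composite files). Composite files are sampled per haplotype
at `read_density/2` reads per kb; the default 50 reads/kb corresponds to
~5× coverage of ~100 bp reads, the regime of real composite files.
Orientation error (default 2%, equal to the genotyper background by
construction), net haplotag probability 0.12 (SNV spacing × read span),
inverted-duplication copy counts k ∈ {1, 2, 3} with probabilities
{0.6, 0.3, 0.1} (event read ratios ~0.33–0.2, bracketing the observed
median of ~0.31). Planted events keep a 10 kb mutual gap — about two
window spans — so adjacent events never merge for placement reasons alone.
Caller profiles impose Bernoulli sensitivity, Gaussian breakpoint jitter and
Poisson false positives per Mb; validation evidence draws Poisson read
support (means 20 true / 1 false), relative optical-length errors, and
per-bp Poisson coverage with het/hom deletion dips.

Not emulated: base-level sequence, alignment artifacts, sister-chromatid
exchanges and BrdU chemistry, per-cell composite structure (cells are merged
upstream in practice and the generator emits merged composites only),
segmental-duplication-mediated mismapping, and the spatial clustering of
real SVs in repeats. Passing tests therefore demonstrate the *decision
calculus* — windowing, model comparison, phase signatures, CI clustering,
validation thresholds, merge semantics — not robustness to alignment
pathology on real data.

## Numerical choices and degenerate inputs

0-based half-open coordinates everywhere; 1-based only at the VCF boundary
(reader derives the end from SVLEN and flags END/SVLEN-inconsistent records,
skipping them with a logged error). One labeled RNG substream per generator
(seeded `numpy` `SeedSequence([seed, crc32(label)])`), so outputs are
independent of call order and bit-identical across reruns. Genotype ties at
exact likelihood equality (only possible at symmetric counts) resolve
hom-ref > het > hom-inv. Empty intervals raise; a zero-read locus is an
error for the read ratio and "ungenotyped" for re-genotyping. Strict vs
inclusive boundaries follow the sources: reciprocal overlap > 0.5 for
support/merging, homozygosity at RO ≥ threshold, PBRC > 4 (validate) and
> 3 (unify), f_BN < 0.1, depth < 30, ≥ 50 reads to genotype, ≥ 10 phased
reads per strand, ≥ 25 reads to re-genotype.

## Problem sizes

Defaults are desk-scale: the packaged pipeline fixture (2 × 2.5 Mb genome,
12 inversions, 250 SVs, ~260 k composite reads) runs in a few seconds; the
planted-inversion experiment (50 Mb, 100 inversions, ~2.6 M reads) in under
half a minute; the full test suite in well under a minute of compute per
heavy test. The experiment genome is 50 Mb because 100 log-uniform
5–500 kb events have an expected total length of ~10.8 Mb and must be
placed without overlap at moderate occupancy.
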