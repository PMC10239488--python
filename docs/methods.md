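# Methods

## Divergence as insertion age

All downstream statistics treat the substitution distance between a TE copy
and its subfamily consensus as a proxy for insertion age. The distance is
the Kimura 2-parameter model's: with transition proportion *P* and
transversion proportion *Q* over usable aligned columns,

    K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)].

Columns with a gap or an ambiguous base on either side are excluded from the
site count; ambiguity codes other than N are treated as N rather than given
pairing rules. When *1 − 2P − Q* or *1 − 2Q* is non-positive the distance is
undefined (saturation) and the computation raises rather than clamping.
An optional CpG mode drops every column inside a consensus CpG dinucleotide
from both the numerator and denominator, mirroring the CpG-adjusted
divergence some annotation pipelines report; plain K2P (`cpg_mode=include`)
is the default since landscapes are conventionally drawn from it.

Divergence is preferentially computed from `.align` alignment blocks. When
only a `.out` table is available the analysis falls back to its mismatch
percent column — which is a raw proportion, not a K2P distance — and says so
with a warning, so real annotation lacking alignments still flows through.

## Fragment merging

Annotators report interrupted insertions as several fragments sharing one
integer identifier. Fragments are grouped by the (sequence name, identifier)
pair — identifiers recur across sequences in real output, so the pair is the
safe key — and merged into one insertion event: total bp is the sum of
fragment lengths, class and family come from the longest fragment (conflicts
are logged), and divergence is the length-weighted mean of fragment
distances. Rows flagged `*` (lower-scoring overlaps) are kept by default
with an exclusion switch, since annotation practice varies on whether they
belong in insertion counts. Overlapping insertions are not deduplicated
beyond the identifier merge.

## Landscapes and content

The landscape accumulates insertion bp into half-open 1%-wide divergence
bins over [0, 50]% per TE class (DNA, Helitron, SINE, LINE, LTR, Unknown,
Other), with an overflow bin above 50%. Cell values are percent of the
assembly; the default denominator is the non-N assembly length (a switch
selects total length). Internally the landscape stores exact integer bp per
cell, so cell sums reconcile with total merged TE bp without float drift.
Content summaries report each class as percent of the assembly, with class
Other (satellites, simple repeats, low complexity, RNA genes) listed but
excluded from the TE total.

## Density of insertion and the lifespan-paired test

DI = (number of LINE+SINE insertions with divergence strictly below 3%) /
(assembly size in Gb). The 3% cutoff is strict (`< 0.03`), and the DI
denominator is the *declared assembly size*, not the non-N length, following
the definition's wording. Species pairs are every ordered combination whose
long-lived member's maximum lifespan is at least two-fold the short-lived
member's (the boundary ratio counts), sorted deterministically by name. With
the packaged 10-species table this yields exactly 25 pairs. The bundled
lifespans are the five values printed for the rodents plus *M. molossus*
(31, 12, 4, 3.8, 5.6 y) and the five remaining bat values from the AnAge
longevity database (37.1, 34, 30.5, 22.9, 20.9 y).

The paired DI differences are tested with the Wilcoxon signed-rank test.
Zero differences are dropped before ranking; ties in |difference| get
average ranks. With untied ranks and n ≤ 30 the p-value is exact: the null
distribution of the positive-rank sum is built by the subset-sum dynamic
programme over ranks 1..n (equivalent to full 2^n sign enumeration, which
the tests verify up to n = 12). Otherwise a normal approximation with tie
correction and continuity correction is used. Both one-sided alternatives
and the two-sided test are exposed; the cohort-level helper defaults to
`less` (long-lived species having lower DI). For 25 same-sign differences
with distinct magnitudes the exact minimum is 1/2^25 ≈ 2.98e-8 one-sided and
2/2^25 ≈ 5.96e-8 two-sided.

**Independence caveat.** One species contributes to many pairs (10 species
make 25 pairs; three short-lived species sit in 21 of them), so the paired
differences are strongly dependent and the signed-rank null — which assumes
independent sign flips — is anti-conservative at the cohort level. The test
suite includes a null-cohort calibration that measures this directly: with
every species drawing recent insertions from one common rate, the one-sided
test at α = 0.05 rejects far more often than α, because a single unusual
species swings many differences together. The pairing procedure is
reproduced as designed; cohort p-values should be read as descriptive of
this design, not as calibrated error rates. Calibration of the test
implementation itself on *independent* null differences is verified
separately and is accurate.

## Windows, correlations, gene-rich/poor contrast

Fixed-size windows (defaults 0.5, 1 and 1.5 Mb) tile each chromosome
without overlap; the trailing window may be short and densities are
normalized per Mb of actual window length. An insertion or feature counts
in the window containing its start — fractional assignment of
boundary-spanning elements is not attempted. Gene, exon, intron (gene minus
exon) and intergenic (chromosome minus gene) interval sets are derived by
half-open interval algebra; exons extending outside genes are clipped with
a warning. TE-vs-feature association uses Spearman rank correlation
(t-approximation p; exact permutation enumeration available for n ≤ 8).
Windows at or below the 0.25 quantile of gene density are gene-poor, at or
above the 0.75 quantile gene-rich, using the linear-interpolation quantile
definition; if the two thresholds coincide (e.g. all densities equal) every
window is labelled neither. The rich-vs-poor TE-density contrast uses the
Mann-Whitney rank-sum test, exact for small untied samples.

## LINE ORF screening

Annotated LINE loci are extracted from the assembly with minus-strand loci
reverse-complemented. All six reading frames are scanned for ORFs running
from the first ATG after the previous stop to a required stop codon;
ORFs shorter than 300 aa are discarded (configurable; the default sits well
below the ~1275 aa of an intact ORF2 and above random expectation). Each
ORF peptide is locally aligned (BLOSUM62, gap open −11/extend −1) against a
reverse-transcriptase and an endonuclease reference peptide. A domain is
complete when the alignment covers ≥ 90% of the profile at ≥ 50% identity
over aligned columns (both configurable); an ORF is intact when the same
reading frame passes both domains, and a species has intact LINE machinery
when any locus carries such an ORF. Requiring both domains in one frame
follows ORF2 biology, where EN and RT are one polypeptide.

The bundled reference peptides are deterministic synthetic sequences (files
named `synthetic_*`), not curated biological domain models: they make the
screen fully testable against the generator, which plants the same
peptides. Sensitivity/specificity measured on synthetic panels therefore
characterises the screening logic, not the detection of real L1 domains;
for biological use, point `load_domain_profiles` at curated RT/EN consensus
peptides.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale (defaults: 300 kb genomes; 200 kb per species in cohorts):

- Background sequence at GC 0.41 (mammal-like) carrying non-overlapping TE
  copies of consensus sequences (LINE 3 kb, SINE 300 bp, LTR 500 bp,
  DNA 800 bp, Helitron 1 kb; ~45% TE content overall, LINE-dominated).
- Insertion ages drawn from a two-component Gaussian mixture over
  divergence percent: an ancient peak at mean 25, sd 3 — the 20–30%
  accumulation peak of real mammalian landscapes — and a recent component
  at mean 1, sd 0.7 with weight `w_recent` (default 0.3), applied to the
  non-LTR classes only; the other classes are ancient relics.
- Substitution-only mutation with transition:transversion odds κ = 2,
  per-site rates solved (Brent root-finding) so the expected substitution
  proportions invert the K2P formula to the target distance; the realized
  alignment is exact by construction and targets beyond 95% of the K2P
  domain boundary are rejected as unreachable.
- Optional fragmentation splits a copy into 2–3 fragments (each ≥ 200 bp,
  keeping per-fragment divergence estimates well inside the K2P domain)
  separated by unannotated background spacers of 50–200 bp, all sharing one
  insertion identifier — the minimal mimic of nested/interrupted insertions.
- Gene annotations with uniform or two-cluster gene starts; LINE loci whose
  single ORF back-translates EN + linker + RT with uniform synonymous
  codons, disrupted on demand by a premature stop, a 1-nt frameshift, or an
  in-frame deletion of half the RT domain.
- Cohorts assign each species a lifespan and a `w_recent`; the default
  cohort uses the packaged lifespans with long-lived species at half the
  short-lived recent weight (0.15 vs 0.30), emulating a roughly two-fold DI
  contrast.

Everything is deterministic under a fixed seed, and emitted `.out`/`.align`
files parse back bit-exactly. What the generator does *not* emulate: indels
and truncated 5' ends (real L1 copies are mostly 5'-truncated), nested
insertion hierarchies, CpG hypermutation, non-uniform insertion preference,
assembly gaps and collapse of young repeats. Passing tests therefore
demonstrate correctness of the computation chain on cleanly structured
input, not robustness to every artefact of real assemblies.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere internally; conversion
  happens only at format boundaries, and strand "C" maps to "-" in BED.
- Landscape bins are half-open [k, k+1); divergence exactly 50% and above
  goes to the overflow bin.
- Unrecognized repeat class labels demote to Other with a log message
  rather than failing, since library labels vary across releases.
- Exact signed-rank enumeration is limited to n ≤ 30 (the DP is O(n³) in
  rank-sum support and exact only without ties).
- `mutate_copy` at target 0 returns an identical copy; empty fragment lists,
  all-zero difference vectors, constant correlation inputs, and empty
  rank-sum groups raise informative errors instead of returning NaN.
- Problem sizes in the test suite (200 kb cohort genomes, 200-replicate
  recovery runs, 500-replicate calibrations) were chosen so the whole suite
  completes in well under a minute of compute per module while keeping
  binomial/Monte-Carlo error comfortably inside the asserted tolerances.

## Known limitations

- The cohort-level signed-rank p-value inherits the pairing design's
  dependence problem (see the independence caveat above).
- The `.align` reader targets the dialect the emitter writes plus common
  variants; exotic annotator versions may need adjustment.
- The ORF screen is alignment-based, not profile-HMM-based; remote homologs
  of real domains would require curated profiles and lower identity
  thresholds than the defaults.
- DI uses declared assembly size, so assemblies padded with N inflate the
  denominator; the landscape denominator (non-N) does not.
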