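# Methods

This note documents the models, parameter choices and numerical conventions
behind each module, what the synthetic-data generators do and do not
emulate, and the known limitations.

## K-mer genome-size estimation

A read of length *L* contributes *L − K + 1* k-mers (default K = 17;
windows containing N are skipped). The estimator is *G = K_num / K_depth*,
with *K_num* the total k-mer occurrence count and *K_depth* the modal
multiplicity of the spectrum once the sequencing-error peak is excluded.

**Canonical counting.** K-mers are strand-folded by default (each k-mer
replaced by the lexicographic minimum of itself and its reverse
complement). This is not cosmetic: shotgun reads sample both strands, so
strand-specific counting splits every genomic k-mer across two hash keys,
halving the modal multiplicity while leaving *K_num* unchanged — the
estimate doubles. With canonical counting the modal multiplicity matches
the per-base k-mer coverage *c·(L−K+1)/L* and the estimator is unbiased to
within the ±1 quantization of the integer mode (±4% at 25×). A
`canonical=False` option exists for comparing against strand-specific
counters.

**Error-peak exclusion.** The spectrum of real (or error-injected) reads is
bimodal: a decaying error peak from multiplicity 1 and a roughly Poisson
coverage peak. `find_peak_depth` walks multiplicities in increasing order
and takes the argmax restricted to multiplicities beyond the first local
minimum; a monotone-decreasing histogram (no valley) falls back to the
global argmax. This is the simplest rule that is exact on clean simulated
data; heavily contaminated spectra may need smoothing, which is out of
scope.

**Read filtering.** A pair is dropped when either mate exceeds the
N-fraction cap (10% short-insert / 20% long-insert), exceeds the
low-quality cap (40% / 30% of bases at Q ≤ 7), matches ≥ 10 bp of the
adapter with ≤ 2 mismatches, when short-insert mates overlap ≥ 10 bp
(suffix of read 1 equal to a prefix of the reverse-complemented read 2; the
250-bp-insert/PE150 combination is exempt), or when the pair is an exact
byte-level duplicate of an earlier pair. Drop counts are attributed to the
first failing rule in that fixed order, so kept + dropped always equals the
input count. Mate overlap is tested as an exact match because only the
length threshold is principled; allowing mismatches there would need an
error model the rule does not define.

## Local alignment

`align.local_align` is a seed-and-extend local aligner: exact 11-mer seeds,
clustered by diagonal and proximity, each cluster extended by an
affine-gap Smith-Waterman restricted to a ±60-bp window around the cluster
(scores +1/−1, gap open −3, extend −1; N scores as a mismatch against
everything, including N). Percent identity is matches over aligned columns
with gap columns included, which keeps externally produced 12-column
tabular hits interchangeable with internal ones. Downstream rules consume
identity and coverage, not raw scores, so any consistent scoring scheme
gives the same calls; the test suite checks the top-hit score against a
full-matrix Smith-Waterman on planted instances. Translated (protein-level)
search is not implemented; TE scanning runs at the nucleotide level and
accepts external translated-search hits in tabular form where higher
sensitivity is needed.

## Retrogene cascade

Thresholds: duplicate loci need ≥ 75% nucleotide identity and > 70% query
coverage; a call needs a parent with ≥ 2 exons and ≥ 70% CDS coverage at
the copy. Hits are merged into loci when their genomic intervals fall
within 1 kb of each other — large enough to bridge introns inside the
parent's own locus (so the self-locus counts as *one* locus), small enough
to keep a retrocopy parked near another gene distinct. "Intronless" is
operationalized as: the merged alignment at the copy has no internal break
greater than 30 bp. The 30-bp tolerance admits small indels while staying
well under typical minimal intron sizes (~60 bp). An ORF of ≥ 100 aa is
re-checked inside the copy span. Lineage specificity is tested against
user-supplied outgroup sequence sets with the same duplicate thresholds;
this keeps the stage self-contained — real multi-genome annotation sets can
be supplied where available.

## Transposable elements

Tier 50 collects regions of scaffolds ≥ 5 kb aligning to any library
element at ≥ 50% identity; hits overlapping or within 10 bp merge into
maximal regions whose identity is the alignment-length-weighted mean (the
"contiguous sequence" notion is not quantified anywhere authoritative, so
the 10-bp abutment is a declared convention). Each region is re-aligned
with 500 bp of flank, clipped at scaffold ends, and adopts the refined
interval. Tier 80 assigns a family when some element aligns at ≥ 80%
identity over ≥ 80 contiguous bp, preferring the longest qualifying span,
then higher identity, then the lexicographically first family name.
Summaries report per-family bp at both tiers and as a percentage of
scaffold bp (total bp by default; a contig-bp denominator that excludes N
gaps is available), plus the DNA/RNA class split. Density tracks count TE
bp per non-overlapping 100-kb window on scaffolds ≥ 5 Mb (both
parameterizable); the last partial window is kept and flagged, and window
values conserve total overlap bp exactly.

## Gene-family dynamics and enrichment

Δ = focal count − median of the comparison group, with the standard median
(mean of the middle pair for even groups), so Δ may be fractional;
labels use Δ ≥ 2 (expanded) and Δ ≤ −2 (contracted). Three canonical
comparison groups (all other species; a basal paraphyletic group; the
focal subgroup) are evaluated together, and families consistent across all
three are reported as the strongest lineage-specific candidates. Nested
group definitions are allowed; partially overlapping ones are rejected.

EASE enrichment: for each term, the one-sided Fisher exact p is the
hypergeometric upper tail P(X ≥ a) for a list hits among the annotated
background; the EASE score decrements the list-hit cell by one (floor 0),
making a single supporting gene never significant. Genes without
annotation are excluded from both list and background. No multiple-testing
correction is applied to the ≤ 0.1 EASE threshold, matching the tool
convention this mirrors; a Benjamini-Hochberg column is emitted for
information only.

## Codon evolution

`li93_kaks` implements the unbiased pairwise estimator over degeneracy
classes: each codon position is nondegenerate (0 synonymous alternatives),
twofold (1–2), or fourfold (3), with threefold Ile sites conventionally
twofold; site totals average the two sequences (half-sites when the codons
disagree). Transitions and transversions are accumulated per class;
multi-substitution codons average over their minimal mutational pathways,
skipping pathways through stop codons when any stop-free pathway exists,
and each step is attributed half to the site class before and half after
the step, which makes the estimate exactly symmetric in the two sequences.
Per class, Kimura two-parameter distances A (transitions) and B
(transversions) are computed; then

    dS = (L2·A2 + L4·A4)/(L2 + L4) + B4
    dN = A0 + (L0·B0 + L2·B2)/(L0 + L2)

Saturation (a non-positive logarithm argument) yields a flagged NaN result
rather than an exception. Gapped and ambiguous codons are skipped.

GC3 counts G/C at third positions of synonymous codons only (ATG, TGG and
stops excluded). CBI is (N_opt − N_rand)/(N_tot − N_rand) over amino acids
with ≥ 2 codons, N_rand being the optimal count expected under uniform
synonymous usage; the default optimal set is a Drosophila-style C/G-ending
table (one codon per amino acid) and is fully configurable, since
published CBI implementations embed species tables that are not reprinted
anywhere convenient.

Mann-Whitney comparisons use exact enumeration when both groups have n ≤ 8
and the normal approximation otherwise, two-sided. The Monte-Carlo
chi-square fixes both margins of the 2×2 table (hypergeometric null),
simulates 1,000,000 tables by default, and reports
p = (#{χ²_sim ≥ χ²_obs} + 1)/(n_sims + 1); it is bit-reproducible given a
seed.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their seed and parameters, and every
planted feature is recorded in a `SyntheticTruth` object sufficient to
score recall and precision without re-derivation.

- `simulate_genome`: uniform-random background; non-overlapping genes with
  2–6 exons (exon pieces ≥ 60 bp so each is alignable; the count is capped
  by CDS length), introns of 60–200 bp, ATG…stop open reading frames of
  120–400 codons, random strands.
- `plant_retrogenes`: spliced (intron-free) parental CDS, point-mutated to
  the requested identity. The start codon is preserved and stop-creating
  substitutions are redrawn, because the objects being emulated are
  functional retrogenes with complete ORFs — and the caller legitimately
  re-checks an ORF. Copies overwrite intergenic background ≥ 1.1 kb away
  from genes (so a copy is never merged into a parent's locus by the 1-kb
  locus-merging rule), leaving coordinates of existing features unchanged.
- `plant_tes`: full or partial (≥ 120 bp) library elements, mutated
  uniformly into the requested identity range, random strand, intergenic.
- `simulate_reads`: uniform fragment positions, exact 5'/3' pair ends,
  optional uniform substitution errors, N injection and exact pair
  duplication. No quality-by-cycle structure, no indel errors, no
  insert-size dispersion.
- `simulate_expression`: biased genes are constructed to satisfy the
  two-clause rule (fold drawn from 2.5–30, higher sex ≥ 2.5 FPKM) and
  unbiased genes to violate it (fold < 2), so the caller's recovery is
  exact by construction — this validates the rule's implementation, not its
  biological discriminating power.
- `simulate_family_matrix`: group counts near a random baseline, adjusted
  so the group median is integral; the focal count is median + planted Δ
  (groups are shifted up when a contraction would go negative).
- `evolve_codon_pair`: a random sense-codon ancestor evolved along two
  branches under a Kimura mutation process (transition/transversion ratio
  κ = 2) with nonsynonymous changes accepted at probability dN/dS and
  stop-creating changes rejected; the per-site mutation distance equals the
  dS target, so synonymous divergence per synonymous site is dS and
  nonsynonymous divergence per nonsynonymous site is dN in expectation.
  Rejection at stop-adjacent codons and synonymous transversions at
  threefold sites bias the estimator recovery by a few percent, within the
  10% calibration band used in the tests.

Uniform substitution with no indels keeps planted identity an unambiguous
Hamming quantity for oracle checks; an indel-bearing generator would need
an alignment-based identity definition and is deliberately out of scope.
Passing tests on these data show the implementations apply their stated
rules correctly at realistic signal levels; they do not show robustness to
real-data artefacts (repeats, segmental duplications, GC-skewed error
profiles, isoform structure).

## Problem sizes and determinism

The test and acceptance workloads use a 100-kb genome at 30× for the
genome-size recovery, 200-kb genomes with 20 genes and 5 planted
retrocopies (identity ≥ 90%) for the retrogene recall/precision checks, a
500-kb scaffold with 30 planted fragments at 82–95% identity against an
8-element library for the TE checks, and 10,000-codon pairs for estimator
calibration — sizes chosen so each property is measured at comfortable
statistical resolution while the whole suite runs on a laptop in a couple
of minutes. Every stochastic step takes an explicit seed; given the seed,
all outputs are bit-reproducible.

## Known limitations

- The aligner is a deliberately minimal stand-in for a production
  search tool: no translated search, no E-values, no repeat masking;
  sensitivity below ~70% identity depends on an exact 11-mer seed landing
  in the conserved stretch.
- The intronless test assumes the paper-thin margin between indel (≤ 30
  bp) and intron (≥ 60 bp) scales; species with micro-introns would need a
  different threshold.
- Family assignment resolves ties lexicographically, which is arbitrary
  but deterministic.
- `bias_summary`'s "expressed" denominator is supplied by the caller; the
  package does not define expressedness beyond max(FPKM) > 0 in its CLI
  default, which is the least restrictive reading.
- The Li estimator's known small-sample and composition biases are not
  corrected beyond the class-weighted formulas above.
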