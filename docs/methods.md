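# Methods

## The problem being modelled

After a whole-genome duplication, chromosome pairs (homeologs) diverge
slowly and unevenly; in salmonids some arms remain >90% identical and
recombine homeologously (residual tetraploidy). Two consequences drive
everything in this package:

1. **Assembly collapse.** Where homeologs are nearly identical the
   assembler may emit one sequence for both. Reads from both copies then
   align to the single copy, doubling its read depth and turning every
   fixed difference between the copies (paralogous sequence variant,
   PSV) into an apparent heterozygous SNP shared by all individuals.
2. **A doubled haploid as a detector.** A doubled haploid (DH) carries
   two identical chromosome sets, so it cannot be truly heterozygous.
   Any heterozygous call in a DH marks co-mapping paralogy, and the DH's
   depth profile exposes collapsed spans as ~2× windows.

## Collapsed-region detection

Depth is averaged in fixed windows (default 1 Mbp; 10 kbp for
association-peak checks; terminal partial windows are kept only when
they cover ≥50% of a window). A window is *collapsed* when its mean
depth exceeds mean + k·SD (k = 2) of **all other** windows. "All other"
is honoured by iterating: flagged windows are excluded, the reference
mean/SD recomputed over the remainder, and flagging repeated to a fixed
point (≤25 rounds; a single-pass variant is available via
`iterative=False`). The threshold is strictly greater-than, so a
zero-variance track flags nothing. Only elevated windows form regions;
depressed windows are classed "below" for plotting but never merged.
Adjacent collapsed windows merge with no gap tolerance, and regions
shorter than 3 Mbp (inclusive bound; boundary cases logged) are
dropped before enrichment analyses.

Because the iterative rule judges tails against a shrinking SD, isolated
Poisson-tail windows can be flagged on clean data; the region length
filter is what makes the final call specific. The parameter-recovery
test quantifies this: on the default synthetic genome the called
regions match the planted 3 Mbp span exactly at 100 kbp windows.

## The SNP filter chain

Ordered passes, each auditable (input/removed/output counts and the
first failing pass per site): biallelic SNPs only → missingness ≤10%
(strict >10% removes) → DH-heterozygote (PSV) removal (missing DH
genotype never removes; counted separately) → MAF ≥0.05 over called
alleles → mean depth within [5, 100], both bounds inclusive (the
conventional reading of "between"; boundary sites logged). LD pruning
(20 kbp window, pairwise dosage r² > 0.4, greedy left-to-right removal
of the right-hand member, monomorphic r² defined as 0) exists only for
the association/ordination path and never precedes impact profiling.

## Impact statistics

The minimal annotator translates reference and alternate codons on the
coding strand (Bio.Seq), classifying stop gained/lost and start lost as
HIGH/nonsense, amino-acid changes as MODERATE/missense, synonymous
changes as LOW/silent; in-gene non-CDS sites are intron/MODIFIER,
flanking sites (±5 kbp, the snpEff default flank) upstream/downstream,
the rest intergenic. Sites may annotate several genes/transcripts.
Supplied snpEff `ANN` fields are consumed verbatim when present (only
allele, effect term, impact and gene id are used; fine-grained effects
collapse onto this five-region scheme).

Per-gene moderate-impact metrics use the annotation span (introns
included) as gene length: density = moderate annotations / length ×
1000 (variants/kbp) and the raw count. Outlier sets take mean + 2·SD
over genes with ≥1 moderate annotation — that population matches the
published mean-per-gene arithmetic (73,405/22,914 = 3.2) — with the
sample SD (n−1); the denominator is configurable and recorded. Both
per-annotation and per-distinct-site moderate totals are emitted, since
the two countings legitimately differ.

## GO enrichment

Direct gene→term assignments are closed under is_a/part_of ancestry
(true-path rule). Each term with ≥1 study and population gene gets a
hypergeometric upper-tail p (scipy, computed in log space), BH-adjusted
across the terms tested in that run (statsmodels), enriched at adjusted
p ≤ 0.05. The background is all GO-annotated genes; unannotated study
genes are dropped with a count. Collapsed-region study sets are genes
whose span intersects a retained region; per-region and pooled views
are both reported. The term-for-term test (not parent–child) is used,
matching the common default of GO tools for this analysis.

## Sex-linkage screen

Presence/absence of a male-specific contig is called per sample from
genotype missingness (absent at ≥80% missing, present at ≤20%,
ambiguous between) or from zero-depth base fraction. Association with
sex uses a 2×2 chi-square combined across sampling-site strata — the
Cochran variant of the Mantel–Haenszel statistic (per-stratum variance
R1·R2·C1·C2/N³, no continuity correction), which reduces exactly to
the Pearson chi-square for a single stratum and attains its maximum N
for perfect presence/absence association. Strata containing one sex
contribute nothing. Family-wise correction is max-T permutation of sex
labels *within* strata (seeded; reruns are bit-identical; adjusted p is
monotone in the statistic). This replaces a covariate logistic
regression: for a binary trait with a categorical covariate the
stratified test controls the same structure while remaining exact and
dependency-light.

Candidate peaks are screened two ways. (1) Coverage: each 10 kbp window
mean is normalised by the sex's genome-wide mean (sex contigs
excludable); male/female ratio ≥2 flags the window, a zero female
window flags as infinite. (2) Sequence context: the 2·50+1 bp window
centred on the SNP is searched as a literal string across the assembly,
both strands, case-insensitively; more than two exact occurrences marks
a repetitive context (the locus itself always matches once; palindromic
probes count once per position). Literal matching, not alignment, is
deliberate: the contract is *exact* copies.

## The synthetic data generator

`synthio` emulates the study conditions rather than reads: for each
homeolog pair an ancestral random sequence is duplicated and the second
copy point-mutated at 9% (≈91% identity, the residual-tetraploidy
regime); within configured collapsed spans the assembly carries one
copy (the sister haplotype, diverged at 1%, exists only as doubled
depth and PSV heterozygotes in *every* sample, with balanced allele
depths); the second copy's sequence loses the span. An alignment table
(blast6) in ~100 kbp chunks carries the exact Hamming identity of the
emitted copies. Cohort genotypes: allele frequencies Beta(0.5, 1.5)
(rare-skewed, a stand-in for a neutral frequency spectrum), binomial
diploid draws, 2% genotype missingness, the DH homozygous everywhere
allelic. Genes are multi-exon (3 × 300 bp CDS on a 4 kbp span), on both
strands; coding variants of known class (missense/silent/stop-gain) are
planted by codon editing against a literal codon table kept separate
from the annotator's Bio.Seq route; a tandem block of hotspot genes
receives ≥13 missense variants each at intermediate frequencies
(0.15–0.85, the haploblock regime seen in tandem immune-gene clusters)
so they survive the MAF filter, and one generated GO term is truly
enriched among them. The sex system is a male-specific contig (depth λ
and called genotypes in males; 0 and missing in females) plus a 2 kbp
repeat unit copied exactly to the contig and to n autosomal windows,
where males get ~10× window depth and a male-correlated heterozygous
site — the repeat-driven false-positive mode.

Depth is simulated per window (Poisson(λ), 2λ in collapsed spans), not
by read placement: the collapse detector only consumes windowed means,
so read-level simulation would add an aligner dependency without
testable structure. Everything derives from one seeded numpy Generator
with fixed iteration order, so a config reproduces every file
byte-for-byte. Defaults are desk scale — 4 pairs × 10 Mbp, one 3 Mbp
collapsed span on pair 1, 20 diploids (10 male, 10 female, two sites) +
1 DH female, λ = 30, 10 kbp depth windows — which exercises every
threshold in seconds; tests that need many replicates use a 2-pair ×
1 Mbp miniature with a 300 kbp span and scale the region-length filter
accordingly.

What the generator does **not** model — and hence what passing tests do
not establish about real data: indels and structural variants, read
mapping biases and depth overdispersion beyond Poisson, linkage
disequilibrium beyond planted duplicates, soft collapse onset at region
edges (spans are hard-bounded; real collapse likely ramps), population
structure beyond the site labels, and gene annotation error.

## Numerical and design choices

- Internal coordinates are 0-based half-open everywhere; VCF/GFF3/blast6
  convert at the I/O boundary. Filtered VCF output copies input records
  verbatim, so filters diff bit-exactly against their input.
- "Longer than 10 kb" and "greater than 15 Mbp" are strict; the 3 Mbp
  region minimum is inclusive (the two published phrasings disagree;
  boundary regions are logged). Identity bins partition (80, 100];
  values ≤80 are counted in a below-range bucket, excluded from bins
  but retained in pair-length sums.
- Combined pair length sums retained alignment lengths without overlap
  merging; an overlap-merged companion view is provided for comparison.
  Reciprocal A→B/B→A duplicates are collapsed keeping the higher
  bitscore before summing.
- Marker placement tie-breaks: bitscore, then identity, then smallest
  sequence id, then smallest start — deterministic and logged.
- Degenerate cases: zero depth variance flags nothing; zero outlier-SD
  makes all at-mean genes qualify (warned); empty cohorts yield zero
  ratios with a warning; a CDS whose length is not a codon multiple
  skips that transcript with a warning rather than failing the run.

## Known limitations

- The collapse caller assumes a unimodal background depth; assemblies
  with widespread segmental duplication would inflate the reference SD
  and lose sensitivity.
- The annotator handles SNPs only (no indels/MNVs) and one canonical
  transcript interpretation per CDS set; splice-region effects are not
  modelled.
- The flank census is exact-match by design; diverged repeat copies
  (<100% identity over the probe) are invisible to it and are instead
  caught by the coverage ratio.
- Permutation p-values are bounded below by 1/(n_perm + 1); genome-wide
  scans needing smaller FWER thresholds need more permutations.
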