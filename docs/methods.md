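# Methods

This note records the models, conventions and numerical choices behind
ssrkit, and what the synthetic-data generators do and do not emulate.

## Perfect SSR detection

A locus is a maximal run of a repeat unit of length *k* ∈ 1..6 in which
`seq[i] == seq[i+k]` holds contiguously over valid (ACGT) bases. For each
unit length the scanner finds these period-*k* match runs (vectorised over
the whole sequence), so a reported run is extendable on neither side by even
a partial unit. Conventions:

* **Thresholds.** Minimum repeat counts default to 12/7/5/4/4/4 for
  mono- through hexanucleotide units, the usual mammalian genome-survey
  setting; comparison is `>=`.
* **Repeat count and length.** `repeat_count = floor(run_length / k)`; a
  trailing partial unit extends neither `length_bp` nor the count, so
  `length_bp = repeat_count * unit_len` exactly. The locus starts at the
  run's leftmost base, which fixes the reading frame of `motif_observed`.
* **Primitivity.** Units that are powers of shorter strings are skipped —
  an (AT)₈ tract is one dinucleotide locus, never also an "ATAT" locus.
  Each unit length is scanned independently; containment cannot occur
  within a unit length, and adjacent maximal runs of the same period may
  share at most *k*−1 boundary bases (a partial tail of one run can be the
  phase-shifted head of the next; trimming it would misreport counts).
* **Ambiguity and masking.** Any non-ACGT character breaks a run, so no SSR
  spans an assembly gap. Soft-masked lowercase is folded to uppercase by
  default, since repeat surveys scan the full assembly.
* **Motif classes.** The class representative is the lexicographically
  smallest string among all rotations of the unit and of its reverse
  complement. This partitions the 4^k units; the dinucleotide classes are
  exactly {AC, AG, AT, CG}, and mononucleotides collapse to {A, C}.
* **Coordinates.** 1-based inclusive everywhere in reports.

## Region classification

Annotated classes are 5′UTR, CDS, intron, 3′UTR and TE; intergenic is the
residual (positions covered by none). Intervals are merged per class before
length computation; introns are derived as transcript span minus exons when
not annotated explicitly. An SSR is assigned **every** class it overlaps by
at least 1 bp — multi-counting is deliberate, since a repeat inside a TE
insertion within an intron genuinely belongs to both, and per-class totals
are therefore allowed to exceed the distinct-locus count. The overlap rule
is symmetric and the simplest testable choice for boundary-straddling loci.
Region summaries report each region's own merged length as the abundance
denominator, alongside the value, because annotated classes overlap and no
single genome denominator is recoverable from published tables.

## Marker candidate filters

Tetranucleotide loci are screened with all filters evaluated on every locus
(no short-circuit), so attrition per criterion can be tabulated:

* repeat count within [10, 22] — long enough to be polymorphic, short
  enough to genotype cleanly;
* 200 bp flanks either side (truncated at contig edges), each at least
  20 bp;
* flanks must not be repetitive: fail when more than half of the flank's
  21-mers occur more than 5 times genome-wide (both strands). The flag is
  named `flank_not_single_copy` after the field wording of the criterion,
  which reads inverted as printed; the implemented direction (flanks must
  be near-unique) is the one consistent with primer design;
* novelty against known markers: fail when the flank k-mer set (15-mers;
  repeat-tract k-mers masked, so sharing only the repeat motif never
  counts) overlaps a known marker's k-mer set by ≥ 0.8. This alignment-free
  screen replaces interactive alignment tools; it is deterministic and
  adequate for flagging redundancy against small published marker sets.
* amplicon sizes count as expected within ±30% of target, inclusive at the
  boundary; `target_product_len` is repeat length + 220 bp clamped into
  [100, 400] — bookkeeping only, since primer design is out of scope.

## Marker statistics

* **He.** The unbiased small-sample form 2N/(2N−1)·(1−Σp²) is the primary
  estimate (the convention of the widely used genotyping software);
  the plain gene diversity is exposed as `He_plain`, and the PIC ≤ He
  inequality is stated against the plain form.
* **Allelic richness.** Hypergeometric rarefaction
  AR(g) = Σᵢ [1 − C(2N−Nᵢ, g)/C(2N, g)], computed in log space (gammaln).
  The panel default is g = 2 × (smallest per-locus N), under which the
  least-typed locus reports AR = k exactly.
* **HWE.** Exact-test statistic: the conditional probability of the
  genotype table given allele counts (Levene's distribution). For
  2N ≤ 12 all tables are enumerated and the p-value is the exact tail mass;
  otherwise the null is sampled by shuffling the 2N alleles among genotype
  slots, with the add-one Monte-Carlo estimator (1 + #{tables ≤ obs})/(1+B)
  so p is never 0 and the estimator is valid at any B. Allele counts are
  permutation-invariant, so only the heterozygote term and the table
  factorials enter the comparison. Monomorphic loci return p = 1 by
  convention; the quality-filter alpha is 0.01. Ties in table probability
  are compared with a 1e−9 log-space tolerance.
* **Identity probabilities.** PID and PIDsib closed forms as above;
  per-locus values multiply across independent loci. The package does not
  test linkage; users should place panel loci on different
  scaffolds/chromosomes, which is how published panels mitigate LD.
* **Quality filters.** Drop reasons are: faecal amplification success
  < 50%, monomorphism, HWE deviation at alpha = 0.01, and blood/faecal
  discordance in matched samples (a mismatch at any mutually non-missing
  paired call; missing calls are never mismatches). Thresholds are
  inclusive on the keep side (exactly 50% or p = 0.01 survives).

## Panel selection and identification

Seed loci (in practice the most reliably amplifying markers) come first in
the given order; remaining loci follow by decreasing He (ties by locus id) —
the ranking column is pluggable because published panels do not follow any
single printed column exactly. `n_required` is the smallest prefix with
cumulative PIDsib below the threshold; the curve is monotone non-increasing
by construction.

Identification matches two samples when they share at least
`min_loci_compared` mutually non-missing panel loci (default: the full
panel) with at most `max_mismatch` disagreements (default 0); clusters are
connected components of the match graph. Pairs below the comparison floor
are reported "uncomparable" and never merged — degraded faecal samples must
not be joined on thin evidence. Relaxed settings exist for degraded data and
are recorded in the comparison table.

Where published per-locus allele frequencies are unavailable but k, N and
He are printed, frequencies are reconstructed from a one-parameter geometric
family pᵢ ∝ rⁱ with r solved (bisection, 200 iterations) so that Σp² matches
the He-implied homozygosity. This is a declared modelling step: it fixes the
two moments that drive PID/PIDsib (allele count and homozygosity) and is
used only for panel-sizing reconstructions, never for primary estimation.

## Synthetic data

The genome generator plants exact SSR tracts into i.i.d. background
(default GC 0.42, a mammalian-like composition), forbids partial-unit
extension at tract boundaries, and then rescans the whole assembly,
resampling any background positions that produced a non-planted qualifying
locus until scanner output equals the truth table exactly. Gene models are
minimal (one gene per plant, two exons when an intron is requested), TE
intervals go to BED, and a deliberate intron∩TE overlap case is supported.
It does not emulate chromosome-scale structure, repeat families, GC
isochores or sequencing error — passing recall tests therefore demonstrate
detector correctness, not robustness to assembly artefacts.

The genotype generator draws two alleles per individual per locus under
HWE. Errors are per-call and independent: dropout converts a heterozygote
to a homozygote for one of its alleles, a false allele replaces one allele
with a different member of the locus repertoire, missingness blanks the
call; replicates share the true genotype with independent errors. Real
faecal data have correlated, per-sample quality effects that this model
omits, so error-model tests show mechanism correctness, not field error
rates.

## Problem sizes and determinism

Every stochastic routine takes a seed (NumPy `default_rng`); fixed seeds
give byte-identical generator output and reproducible p-values. The test
suite and the acceptance script run at desk scale: oracle equivalence on
200 random 2-kb sequences, 50 planted loci across five 12-kb scaffolds,
panels of 25–10,000 individuals, 10⁵ simulated pairs for identity
probabilities, and 1,000 simulated panels at 150 shuffles for the HWE
null-uniformity check — sizes chosen so the whole battery completes in
seconds while keeping Monte-Carlo tolerances (3 SE; KS < 0.05) meaningful.

## Known limitations

* Only perfect, single-motif repeats are detected; interrupted and compound
  microsatellites are out of scope by design.
* The uniqueness and novelty screens are k-mer heuristics with exposed
  parameters, not alignment; they flag repetitiveness and redundancy but do
  not guarantee primer specificity.
* Null alleles, stutter and large-allele dropout diagnostics are not
  inferred from data (the quality surface is amplification rate,
  concordance and HWE); allele binning from raw fragment sizes is assumed
  done upstream.
* Genome-scale absolute counts depend on the assembly scanned; the package
  reports its denominators alongside every abundance for that reason.
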