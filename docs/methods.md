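# Methods

## Design and data model

The unit of data is the per-SNP allele-count table: for every informative
biallelic SNP between the B (reference) and D strains, the number of reads
carrying the B base, the D base, or any third base, in each sequenced F1
pool. The default study grid is four pools — BxD and DxB reciprocal
crosses, one male and one female pool each, with the maternal strain named
first (so the maternal allele is B in BxD and D in DxB; the convention can
be flipped with `SimulationConfig.mother_first`).

Counts are aggregated to SNP, exon or gene units (gene by default: summing
SNP counts over the haplotype is markedly more robust than SNP-by-SNP
testing) and reshaped into a matrix with one *pseudo-sample* per
(pool × allele). The two alleles of a pool are treated as independent
replicate libraries. This ignores the within-pool pairing of the two
alleles; a paired test would gain some power and is noted as future work.

## Counting and reference bias

Alignment is out of scope: the counter consumes SAM produced by any
aligner (or by the generator, pre-placed). Reads are filtered on
uniqueness (NH tag > 1 or MAPQ 0 rejected by default), edit distance
(NM ≤ 3 by default, matching common RNA-seq practice for 50 bp reads) and
base quality at the SNP (≥ 20 by default; the threshold is a choice, not a
measurement). Under the default `fragment_once` policy, a properly paired
fragment whose mates both cover a SNP contributes one count, and
disagreeing mates are tallied as `other`; `mates_independent` (each mate
counted, as in single-end processing of paired data) is also supported and
on non-overlapping mates the two agree exactly.

Reference mapping bias — the excess of reads supporting the reference
allele because non-reference reads carry an extra mismatch — is mitigated
upstream by N-masking every SNP position in the reference
(`mask_reference`; idempotent, SNPs only) and monitored downstream by
`mapping_ratio` (pooled B/D count ratio per sample, optionally on a
greedily thinned SNP set so no read spans two retained SNPs) and
`bias_report` (masked vs unmasked fold reduction of the log allelic ratio).
Because the generator places reads directly rather than re-aligning them,
synthetic data carry no aligner bias; the masked/unmasked comparison on
synthetic reads is a negative control (fold reduction 1), not a
demonstration of masking efficacy.

## The test

Size factors are DESeq-style median-of-ratios over units with all-positive
counts (a pseudo-reference fallback that ignores zeros is available by
flag). Crucially, because B and D columns are normalized separately, a
global allelic mapping bias lands in the size factors and cancels out of
the fold changes.

Per-unit dispersion: with normalized counts pooled across the two
conditions (pooled within-condition variance v, grand mean mu, size
factors s),

    alpha_hat = max(0, (v - mu * mean(1/s)) / mu^2)

The `mu * mean(1/s)` term is the shot-noise floor; it reduces to the plain
`(v - mu)/mu^2` moment formula when all size factors are 1. A trend
`alpha(mu) = a0 + a1/mu` is fitted by gamma-family GLM (identity link) over
units with positive `alpha_hat` (ordinary least squares as fallback), and
the working dispersion is `max(alpha_hat, fitted)`. This "maximum" sharing
is deliberately conservative: with 3 degrees of freedom per condition the
moment estimate is noisy, and taking the maximum inflates roughly half the
working values. Measured consequence (see the acceptance measurements):
the null is controlled well below nominal FDR, at the cost of ~10
percentage points of power at a 2-fold effect relative to an oracle that
knows the dispersion.

The p-value is the NB conditional exact test for the two condition sums
K_A, K_B: each sum is modelled as NB with mean `mu_hat * S_c` and variance
`mu_hat * S_c + alpha * mu_hat^2 * sum_j s_j^2` (S_c the condition's
size-factor sum), and the two-sided p sums the probabilities of all splits
of K_A + K_B no more probable than the observed one, normalized over all
splits; p is in (0, 1] and equals 1 for a zero total. For totals above
10,000 the NB split masses are replaced by normal densities with the same
moments; at the boundary the two agree to within a few percent (tested).
As dispersion → 0 with equal size factors the test reduces to the
two-sided binomial exact test (tested to 10^-4 relative).

Fold changes are `log2((m_num + c)/(m_den + c))` on normalized condition
means with pseudocount c = 0.5 (numerator D in strain mode, maternal in
parent mode). FDR control is Benjamini–Hochberg; `alpha = 0.05` throughout.
Sex-restricted analyses re-estimate size factors and dispersion from the
subset only.

### The Fisher baseline

The classical alternative tests each unit per sample with a 2×2 Fisher
exact test against the rest of that sample's library (conditioning on
library totals absorbs global allelic bias), adjusts within sample, and
calls a unit only when significant with concordant direction in every
sample. The pipeline stores the per-sample adjusted p-values so the call
threshold can be swept without re-testing. The intersection rule ignores
biological replicate variance, which both loses power on consistent
moderate effects and admits false positives from single-sample
fluctuations; the NB test dominates it in true positives at matched
realized FDR on matched simulations.

## Quality control

* `filter_exclusive` / `exclusive_report`: SNPs (and genes whose every
  informative SNP) show one allele only, across all samples, are the
  signature of genotyping errors in the variant catalogue rather than
  biology; they are removed before testing and reported per gene. A gene
  must have total coverage ≥ 8 across samples before being declared
  exclusive, to avoid calling noise at depth 1–2.
* `discordant_pairs`: SNPs in one exon (or exons in one gene) must agree in
  direction; pairs that are each significant with opposite signs bound the
  empirical error rate (expected ≈ alpha² × pairs under the null). At exon
  level the per-gene known-isoform count is attached, since true
  isoform-specific regulation requires multiple isoforms.
* `stop_codon_ase`: variants annotated stop-gain/stop-loss (D-referenced,
  so the D allele is the impaired one in both classes) are summarized by
  their impaired/intact expression ratio `2^log2fc`; "marked reduction"
  means ratio ≤ 0.5 (a 2-fold threshold — the choice of threshold is ours).
* `ase_concordance`: R² and slope of allelic fold changes across two result
  sets (tissues, sexes, datasets), with optional external grouping labels.

## Regulatory overlap

DNase I peaks from two replicates are reduced to conserved peaks (a rep1
interval is kept when it overlaps rep2 by ≥ 1 bp; its signal becomes the
mean of the rep1 signalValue and the best-overlapping rep2 signalValue —
keeping the rep1 geometry rather than the intersection is a choice). Peaks
are partitioned into *intact* (no B/D SNP or indel overlaps them; indel
span is the REF footprint `[pos, pos+len(ref))`) and *polymorphic*. Genes
collect all conserved peaks within their span ± a window (default 10 kb,
sweepable over 0–10 kb), and the per-gene **F ratio** is the fraction of
DNase signal coming from intact peaks. Groups (B-up / D-up / not
significant, from padj and fold-change sign) are compared by two-sided
rank-sum tests on F ratios and two-proportion z-tests on pooled
intact-peak fractions.

Set comparisons against external local-eQTL tables use the one-sided
hypergeometric overlap test (plus three-set Venn counts), a p-value
threshold sweep (if poor overlap reflected lack of power, stricter cutoffs
would raise the overlap fraction), and effect-size summaries by overlap
category, with ASE effect `2^|log2fc|` and exclusive-expression genes
excluded (their ratio is unbounded).

## The synthetic-data generator

The generator emulates the study conditions, not any particular dataset:
a toy chromosome of ~1.5 kb genes (1–8 exons of 200–400 bp), ≥ 1 exonic
SNP per gene (Poisson-distributed, ~3/gene), and per-gene coverage drawn
lognormally with mean 500 allele-informative read pairs per pool (shape
0.5). Effects: 10% of genes carry a cis log2 fold change ~ N(1, 0.25) with
balanced signs (5% of those sex-restricted), 2% are imprinted at magnitude
2, and 2% are genotyping-error genes. A global factor 1.2 multiplies
B-allele means only (the order of the post-masking mapping ratios in real
F1 data). The NB law (variance mu + 0.05 mu²) is realised as a
Poisson-gamma mixture with one gamma factor per (gene, pool, allele), so
SNP counts within a gene are positively correlated — as they are in real
data where nearby SNPs share reads — and gene-level aggregates keep the
same dispersion. The ±L/2 symmetric split of allelic means keeps total
gene expression invariant under imbalance, isolating the allelic signal.

Genotyping-error genes have *all* their SNPs emit zero D counts (every
read carries the reference base): a catalogue error makes the site
non-polymorphic, and gene-level exclusivity is what the QC screens for.
Stop-codon annotations are assigned to a small fraction of SNPs
(~0.1%/0.025% gain/loss, matching their rarity among exonic SNPs).

What the generator does **not** emulate: splice-isoform structure,
base-call sequencing errors, aligner behaviour (reads are pre-placed, so
mapping bias exists only as the global mean factor, not as a per-read
phenomenon), fragment-length distributions, or linkage between genes.
Passing tests therefore demonstrate the statistics and bookkeeping, not
robustness to alignment artifacts.

`gen_reads` emits single-end reads by default (mirroring the treat-pairs-
as-two-single-ends processing the design assumes), or proper pairs of two
adjacent non-overlapping mates; a configurable fraction of reads is
flagged multi-mapped (NH:i:2, MAPQ 0) to exercise unique-read filtering.
All stages are deterministic given the configuration seed, with
independent substreams per stage so regenerating counts does not perturb
the annotation.

## Numerical and design choices

* Coordinates are 0-based half-open internally; VCF is converted at the
  boundary. Strand is read but ignored by counting.
* Indels are carried for peak intactness only, never for allele counting
  or masking.
* SNPs overlapping two genes are counted in both and flagged; ties in the
  exact test's split probabilities are included in the rejection mass
  (p-values are conservative at ties).
* The exact-test enumeration cap (10,000) trades a < 15% relative error in
  a regime where p-values are far from any decision boundary for a bounded
  run time.
* Degenerate inputs: zero-total units give p = 1; zero-margin Fisher
  tables give p = 1; an undefined mapping ratio (no D counts) is NaN.
* Problem sizes in the test suite and acceptance measurements (2000-gene
  studies, 20 null replicates, 50-fixture counting oracle) were chosen so
  the full measurement set completes in about a minute on one CPU while
  keeping binomial standard errors on the measured fractions below ~0.02.

## Known limitations

* Pseudo-samples are unpaired; a within-pool paired test would be more
  powerful.
* The conservative `max(empirical, fitted)` dispersion rule caps power
  around 0.78 at a 2-fold effect with 4+4 replicates and dispersion 0.05
  (an oracle knowing the dispersion reaches ~0.9 under the same
  conditions); the trade was made for strict null control.
* Gene-level aggregation can mask isoform-specific regulation; the
  exon-level mode and the discordance QC are the mitigation, not a cure.
* The Fisher baseline's intersection rule is one published practice among
  several; other aggregation rules (e.g. majority voting) are not
  implemented.
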