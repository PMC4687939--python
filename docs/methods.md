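# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical choices a maintainer would want to know.

## Expression and differential expression

FPKM is computed as `counts × 10⁹ / (length_bp × total_mapped[sample])`;
when total mapped reads are not supplied they default to the column sums,
which makes `Σ_g FPKM·length_kb = 10⁶` hold exactly per sample.  All
log-scale quantities use log₂(FPKM + 0.25); the offset stabilises zeros
and is configurable everywhere it appears.  Group A is the
lexicographically first design label, which makes "IB" the reference
against "IBxDU" under the standard naming; a negative signed fold change
therefore means higher expression in the purebred line.

The three DE filters follow their quoted wording literally: the
expression filter is strict (a group mean of exactly 0.5 FPKM fails), the
fold-change and p filters are inclusive (|FC| = 1.5 and p = 0.01 pass).
Two numerical guards keep the inclusive boundaries sharp: the fold change
used in filtering is the exact ratio of group means whenever both means
are positive (the pseudocount, default 10⁻³, replaces only zero means),
and the comparison allows a 10⁻¹² relative tolerance for float artifacts
such as 0.3/0.2 evaluating just below 1.5.

The count test is a conditional negative-binomial exact test on the group
sums: under the null of equal relative abundance, Y₁ and Y₂ are NB with
means proportional to the group library-size totals and dispersion φ/n
(sum of n equidispersed NB variables); the observed split of the total is
scored against its conditional distribution by summing the probability of
every outcome no more likely than the observed one.  Support is truncated
at ±12 conditional standard deviations — the omitted mass is far below
double precision — which keeps the test O(window) per gene.  Dispersions
are method-of-moments per gene, shrunk toward a common value with 40
pseudo-degrees of freedom; the common value solves the Pearson-χ² moment
equation (mean within-group χ² per residual degree of freedom = 1), which
is markedly less biased than averaging per-gene moment estimates at n = 6
per group.  Null simulations at 10⁴ genes put the empirical rejection
rate within binomial 99% bounds of the nominal level at α = 0.05 and
α = 0.01.  The engine is a documented substitute for a count-based DE
package, not a re-implementation of one; replacing it only changes the
p-value source, not the filter semantics.

## Regulatory Impact Factors

RIF1 and RIF2 are computed exactly as defined (see README), with
correlations taken within each genotype on the log₂ scale.  Choices where
the procedure is underdetermined:

* **Correlation**: Pearson by default, Spearman available.  Zero-variance
  profiles get the sentinel correlation 0, which keeps the sums defined.
* **Expression scale for e, a, d**: log₂(FPKM + 0.25); the metrics weight
  by abundance and differential expression, and log abundance is the
  scale on which co-expression is usually assessed.
* **Standardisation**: sample (n−1) standard deviation over regulators;
  degenerate all-equal inputs yield all-zero z-scores with a warning.
* **Bootstrap null**: each of the (default 10,000) repetitions draws the
  stated number of genes uniformly *without replacement* — a "set" of
  genes denotes distinct genes — from the expressed pool *excluding* the
  candidate regulators, avoiding self-correlation artifacts.  The per-draw
  statistics (a, d, e1, e2, correlations) are re-derived from the drawn
  genes rather than recycled from the observed DE set.  z-scores are
  pooled over regulators and repetitions and the interval bounds are
  percentiles of the pooled distribution (2.5/97.5 and 0.5/99.5); per-
  regulator intervals are not computed because a single pooled interval
  per metric is what the procedure reports.  Significance is a strict
  outside-the-interval test.

The vectorised implementation is checked against a naive double-loop
evaluation of the defining formulas to 10⁻¹² relative error.

## qPCR model

y = Cp·log₂E enters a joint linear mixed model with fixed gene×genotype
cell means TG_gi, a random pig-within-gene intercept B_gk, a random
sample intercept D_k common to all genes, and a residual.  Estimation is
REML through a variance-components mixed model; when the data are
degenerate (zero residual variance, non-convergence, non-finite
covariance) the fit falls back to ordinary least squares on the cell
means, which coincides with the mixed estimate in balanced designs.
Replicate wells enter as repeated measures by default; a `mean_cp` switch
reproduces the pre-averaged variant.  The normalised contrast uses the
arithmetic mean of the reference genes' contrasts on the y scale, which
is equivalent to geometric-mean normalisation on the quantity scale.  The
t-test uses containment degrees of freedom (n_animals − 2); with all
E = 2 and a noiseless balanced design the contrast equals the classical
ΔΔCt exactly, and FC = 2^(−diff_TG) round-trips to 10⁻¹².

Reference-gene stability M_g is the mean over other candidates h of the
SD across samples of log₂(q_g/q_h); the two lowest-M genes define the
per-sample normalisation factor as the geometric mean of their
quantities.

## Variants

Locus identity for cross-genotype comparison is the exact
(chrom, pos, ref, alt) tuple — the conservative choice when the pairing
rule is otherwise unspecified.  Coordinates are 1-based inclusive
throughout (VCF/GFF3 convention).  The quoted "under 30 reads / under 5%"
filters are strict removals, so boundary values survive; fixation at
γ ≥ 90% is inclusive.  Consequence annotation trims the shared allele
prefix, removes the reference bases mapped into the CDS and splices the
alternate bases in at the edit point (reverse-complemented for
minus-strand transcripts); indels whose net CDS length change is a
multiple of three are in-frame and report the gained/lost residues
obtained by trimming the common protein prefix/suffix, others are
frameshift.  Stop-codon changes are reported as missense with the residue
change in the detail string rather than as a separate class.  Annotation
is per-transcript; multi-transcript collapsing is left to the caller.

## Synthetic data

The generators emulate the study design: two genotypes × 6 animals,
negative-binomial counts with log-normal gene means (log-normal σ = 1.3,
NB dispersion 0.1 — typical bulk RNA-seq values), mean library size
500,000 over the simulated gene panel, DE fold changes log-uniform on
[1.9, 12] (the range reported for the upregulated genes), gene lengths
uniform on [300, 10000] bp, triplicate qPCR wells with pig/sample random
effects (defaults σ_pig = 0.3, σ_sample = 0.2, σ_resid = 0.2 cycles on
the y scale), and variant allele-frequency spectra with group-specific
fixation probabilities.  One integer seed drives one root generator;
every generator derives a deterministic sub-stream, so equal seeds give
byte-identical outputs across the whole pipeline.

Planted regulators are implemented as a shared per-sample latent factor
on the log scale: the regulator and a disjoint block of 30 same-direction
DE targets share the factor in group A, while in group B the targets'
coupling flips sign.  Same-direction targets matter because RIF1 weights
by the signed product a_j·d_j — mixed-direction targets cancel; the sign
flip guarantees r1 ≠ r2 strongly enough to be detectable at n = 6, where
sample correlations are very noisy.  The latent factor is rescaled to its
nominal spread (σ = 1.2 on log₂) within each draw so that recovery does
not hinge on the luck of a six-sample draw.  Under the default
configuration at least two of the three planted regulators escape the
RIF1 95% bootstrap interval in well over 80% of replicates.

What the simulations do **not** emulate: read-level error, mapping
artifacts, GC/length biases, sample-level batch structure, linkage or
haplotype structure among variants, and correlated expression beyond the
planted blocks.  Passing tests therefore certify the statistical
machinery under the stated model, not robustness to the full messiness of
real RNA-seq.

## Problem sizes used in the checks

The test suite and the acceptance script run scaled-down but structurally
faithful versions of the procedures: null calibration at 10⁴ genes,
bootstrap self-consistency at 1,000 repetitions on 2,000 genes with 50
regulators, planted-regulator recovery over 50 replicates of the default
2,000-gene configuration with 200 bootstrap repetitions each, and qPCR
parameter recovery/type-I simulations at 500 datasets.  These sizes give
Monte-Carlo errors comfortably inside the asserted tolerances while
keeping a full run in a few minutes.

## Known limitations

* The DE engine shares the exact-test idea with established count-based
  packages but not their numerics (no quantile adjustment, no empirical
  Bayes trend); p-values agree in calibration, not value-for-value.
* The bootstrap interval is pooled across regulators, so per-regulator
  multiplicity is not addressed beyond the null-calibrated 5%/1% rates.
* Mixed-model degrees of freedom use the containment rule rather than
  Satterthwaite/Kenward-Roger; with 12 animals the difference is small
  but real.
* Fatty-acid sums cover only the supplied components.  Published
  composition tables are not always internally consistent (the IBxDU
  monounsaturated total differs from the sum of its listed rows by 0.15
  g/100 g, and the printed Σn-3 exceeds the listed n-3 rows); the module
  reports what the inputs imply and leaves reconciliation to the caller.
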